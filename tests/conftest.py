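import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

RM_OUT_FIXTURE = """\
   SW   perc perc perc  query    position in query         matching  repeat         position in repeat
score   div. del. ins.  sequence begin end (left)          repeat    class/family   begin end (left) ID

 1306   15.6  6.2  0.0  contig1        101       235  (165) +  B1F            SINE/Alu               1   135    (0)      1
  950    8.0  1.0  0.5  contig1        400       500  (100)   C  ID             SINE/ID              (0)   135      1      2
  500    2.0  0.0  0.0  contig2         51       150  (250) +  L1Md           LINE/L1                1   100  (6000)     3 *
"""


@pytest.fixture
def rm_out_text():
    return RM_OUT_FIXTURE


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free five-taxon simulation: 6 Castorimorpha-branch and 5
    mouse-related-clade insertions, no substitutions, no ILS."""
    from retroscreen import simulate

    return simulate(
        seed=20170303 % 2**31,
        subst_rate=0.0,
        ils_prob=0.0,
        insertions={
            ("beaver", "kangaroo_rat"): 6,
            ("beaver", "kangaroo_rat", "mouse"): 5,
        },
    )


CASTORIMORPHA_PATTERNS = {
    "castorimorpha": {
        "kangaroo_rat": "present",
        "beaver": "present",
        "mouse": "absent",
        "guinea_pig": "absent",
        "ground_squirrel": "absent",
    },
    "mouse_beaver": {
        "mouse": "present",
        "beaver": "present",
        "kangaroo_rat": "absent",
        "guinea_pig": "absent",
        "ground_squirrel": "absent",
    },
    "mouse_krat": {
        "mouse": "present",
        "kangaroo_rat": "present",
        "beaver": "absent",
        "guinea_pig": "absent",
        "ground_squirrel": "absent",
    },
}

MOUSE_RELATED_PATTERNS = {
    "mouse_related": {
        "mouse": "present",
        "kangaroo_rat": "present",
        "guinea_pig": "absent",
        "ground_squirrel": "absent",
    },
    "gp_krat": {
        "guinea_pig": "present",
        "kangaroo_rat": "present",
        "mouse": "absent",
        "ground_squirrel": "absent",
    },
    "gp_mouse": {
        "guinea_pig": "present",
        "mouse": "present",
        "kangaroo_rat": "absent",
        "ground_squirrel": "absent",
    },
}

OUTGROUPS = ["guinea_pig", "ground_squirrel"]


def screen_from_dataset(dataset, pattern_table, reference="beaver", **kwargs):
    """Build a ScreenConfig from simulator output and run the screen."""
    from retroscreen.axt import parse_axt
    from retroscreen.repeatmasker import parse_repeatmasker_out
    from retroscreen.screen import ScreenConfig, screen
    from retroscreen.simulate import emit_axt, emit_repeatmasker

    repeats = parse_repeatmasker_out(emit_repeatmasker(dataset, reference).splitlines())
    alignments = {
        taxon: parse_axt(emit_axt(dataset, reference, taxon).splitlines())
        for taxon in dataset.taxa
        if taxon != reference
    }
    config = ScreenConfig(
        reference=reference,
        repeats=repeats,
        alignments=alignments,
        pattern_table=pattern_table,
        outgroups=OUTGROUPS,
        **kwargs,
    )
    return screen(config)
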