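"""Presence calls, flank filters, pattern classification, and the full screen."""

import pytest

from conftest import (
    CASTORIMORPHA_PATTERNS,
    MOUSE_RELATED_PATTERNS,
    OUTGROUPS,
    screen_from_dataset,
)
from retroscreen.axt import ProjectedSlice
from retroscreen.screen import (
    ABSENT,
    AMBIGUOUS,
    CONFLICTING,
    PRESENT,
    UNCOVERED,
    UNINFORMATIVE,
    PresenceCall,
    call_presence,
    classify_pattern,
    flank_clean,
)
from retroscreen.simulate import truth_markers
from test_repeatmasker import make_record


def make_slice(n_cols, n_gaps, covered_fraction=1.0):
    ref = "A" * n_cols
    qry = "-" * n_gaps + "A" * (n_cols - n_gaps)
    covered = round(covered_fraction * n_cols)
    return ProjectedSlice(
        ref_aln=ref, query_aln=qry,
        interval_length=n_cols if covered == n_cols else round(n_cols / covered_fraction),
        covered_columns=n_cols,
    )


class TestCallPresence:
    def test_all_gap_is_absent(self):
        assert call_presence(make_slice(100, 100)).state == ABSENT

    def test_no_gap_is_present(self):
        assert call_presence(make_slice(100, 0)).state == PRESENT

    def test_exact_seventy_percent_is_not_absent(self):
        call = call_presence(make_slice(100, 70))
        assert call.gap_fraction == pytest.approx(0.70)
        assert call.state != ABSENT
        assert call.state == AMBIGUOUS

    def test_just_above_seventy_percent_is_absent(self):
        assert call_presence(make_slice(100, 71)).state == ABSENT
        assert call_presence(make_slice(1000, 701)).state == ABSENT

    def test_low_coverage_is_uncovered(self):
        slice_ = ProjectedSlice(ref_aln="A" * 50, query_aln="-" * 50,
                                interval_length=100, covered_columns=50)
        assert call_presence(slice_).state == UNCOVERED

    def test_empty_slice_is_uncovered(self):
        empty = ProjectedSlice(ref_aln="", query_aln="", interval_length=100, covered_columns=0)
        assert call_presence(empty).state == UNCOVERED

    def test_monotone_in_gap_columns(self):
        """Adding query-gap columns never moves the call toward presence."""
        order = {PRESENT: 0, AMBIGUOUS: 1, ABSENT: 2}
        previous = -1
        for gaps in range(0, 101):
            state = call_presence(make_slice(100, gaps)).state
            assert order[state] >= previous
            previous = order[state]

    def test_exhaustive_boundary_grid(self):
        """The absence boundary is strict at every denominator up to 200."""
        for n_cols in range(10, 201, 10):
            for n_gaps in range(n_cols + 1):
                state = call_presence(make_slice(n_cols, n_gaps)).state
                if n_gaps / n_cols > 0.70:
                    assert state == ABSENT
                else:
                    assert state != ABSENT


class TestFlankClean:
    def focal(self):
        return make_record(begin=1001, end=1135, element_id=1, name="B1F")

    def test_isolated_element_is_clean(self):
        assert flank_clean(self.focal(), [self.focal()])

    def test_thirty_nt_overlap_fails(self):
        # neighbour [921, 980] 1-based overlaps the left flank [950, 1000] by 30
        neighbour = make_record(begin=921, end=980, element_id=2, name="L1")
        assert not flank_clean(self.focal(), [self.focal(), neighbour])

    def test_exact_ten_nt_overlap_passes(self):
        neighbour = make_record(begin=901, end=960, element_id=2, name="L1")
        assert flank_clean(self.focal(), [self.focal(), neighbour])

    def test_offset_grid_boundary(self):
        """Sliding a 60-nt repeat towards the flank: <=10 nt overlap passes, 11 fails."""
        focal = self.focal()
        for overlap in range(0, 25):
            # repeat ending `overlap` nt inside the left flank window [951, 1000]
            end = 950 + overlap
            neighbour = make_record(begin=end - 59, end=max(end, 1), element_id=2, name="L1")
            clean = flank_clean(focal, [focal, neighbour])
            assert clean == (overlap <= 10), overlap

    def test_right_flank_checked_too(self):
        for overlap in (10, 11):
            neighbour = make_record(begin=1136 + 50 - overlap, end=1300, element_id=2, name="L1")
            assert flank_clean(self.focal(), [self.focal(), neighbour]) == (overlap <= 10)

    def test_own_fragments_exempt(self):
        fragment = make_record(begin=960, end=1000, element_id=1, name="B1F")
        assert flank_clean(self.focal(), [self.focal(), fragment])


def calls(**states):
    return {t: PresenceCall(species=t, state=s, gap_fraction=0.0, covered_fraction=1.0)
            for t, s in states.items()}


class TestClassifyPattern:
    def test_castorimorpha_pattern(self):
        result = classify_pattern(
            calls(beaver=PRESENT, kangaroo_rat=PRESENT, mouse=ABSENT,
                  guinea_pig=ABSENT, ground_squirrel=ABSENT),
            CASTORIMORPHA_PATTERNS, OUTGROUPS,
        )
        assert result == "castorimorpha"

    def test_all_absent_uninformative(self):
        result = classify_pattern(
            calls(beaver=ABSENT, kangaroo_rat=ABSENT, mouse=ABSENT,
                  guinea_pig=ABSENT, ground_squirrel=ABSENT),
            CASTORIMORPHA_PATTERNS, OUTGROUPS,
        )
        assert result == UNINFORMATIVE

    def test_outgroup_presence_violates_plesiomorphy(self):
        result = classify_pattern(
            calls(beaver=PRESENT, kangaroo_rat=PRESENT, mouse=ABSENT,
                  guinea_pig=ABSENT, ground_squirrel=PRESENT),
            CASTORIMORPHA_PATTERNS, OUTGROUPS,
        )
        assert result == UNINFORMATIVE

    def test_uncovered_taxon_uninformative(self):
        result = classify_pattern(
            calls(beaver=PRESENT, kangaroo_rat=UNCOVERED, mouse=ABSENT,
                  guinea_pig=ABSENT, ground_squirrel=ABSENT),
            CASTORIMORPHA_PATTERNS, OUTGROUPS,
        )
        assert result == UNINFORMATIVE

    def test_missing_taxon_is_error(self):
        with pytest.raises(ValueError, match="mouse"):
            classify_pattern(
                calls(beaver=PRESENT, kangaroo_rat=PRESENT,
                      guinea_pig=ABSENT, ground_squirrel=ABSENT),
                CASTORIMORPHA_PATTERNS, OUTGROUPS,
            )

    def test_non_nested_sharing_conflicts(self):
        # beaver and guinea pig... no: two ingroups sharing without a hypothesis
        table = {"h1": {"a": PRESENT, "b": PRESENT, "c": ABSENT, "d": ABSENT, "out": ABSENT}}
        result = classify_pattern(
            calls(a=PRESENT, b=ABSENT, c=PRESENT, d=ABSENT, out=ABSENT),
            table, ["out"],
        )
        assert result == CONFLICTING


class TestScreen:
    def test_clean_dataset_recovers_castorimorpha_markers(self, clean_dataset):
        result = screen_from_dataset(clean_dataset, CASTORIMORPHA_PATTERNS)
        assert result.counts_vector() == [6, 0, 0]
        truth = truth_markers(clean_dataset, ["beaver", "kangaroo_rat"])
        found = {(c.start, c.end) for c in result.candidates
                 if c.pattern_label == "castorimorpha"}
        expected = {(start, end) for ev, start, end in clean_dataset.elements["beaver"]
                    if ev in truth}
        assert found == expected  # recall and precision both 1.0

    def test_clean_dataset_recovers_mouse_related_markers(self, clean_dataset):
        result = screen_from_dataset(clean_dataset, MOUSE_RELATED_PATTERNS)
        assert result.counts_vector() == [5, 0, 0]

    def test_counts_partition_candidates(self, clean_dataset):
        result = screen_from_dataset(clean_dataset, CASTORIMORPHA_PATTERNS)
        assert sum(result.pattern_counts.values()) == len(result.candidates)

    def test_zero_insertions_zero_candidates(self):
        from retroscreen.simulate import simulate

        empty = simulate(seed=5, insertion_rate=0.0, subst_rate=0.0, ils_prob=0.0)
        result = screen_from_dataset(empty, CASTORIMORPHA_PATTERNS)
        assert result.candidates == []

    def test_missing_alignment_is_config_error(self, clean_dataset):
        from retroscreen.axt import parse_axt
        from retroscreen.repeatmasker import parse_repeatmasker_out
        from retroscreen.screen import ScreenConfig, screen
        from retroscreen.simulate import emit_axt, emit_repeatmasker

        repeats = parse_repeatmasker_out(
            emit_repeatmasker(clean_dataset, "beaver").splitlines())
        alignments = {"mouse": parse_axt(
            emit_axt(clean_dataset, "beaver", "mouse").splitlines())}
        config = ScreenConfig(
            reference="beaver", repeats=repeats, alignments=alignments,
            pattern_table=CASTORIMORPHA_PATTERNS, outgroups=OUTGROUPS,
        )
        with pytest.raises(ValueError, match="no alignment configured"):
            screen(config)

    def test_ils_produces_alternative_pattern_hits(self):
        """Markers drift to non-focal patterns at a rate rising with ILS."""
        from retroscreen.simulate import simulate

        off_focal = []
        for ils in (0.0, 0.5, 1.0):
            drifted = 0
            for rep in range(4):
                ds = simulate(
                    seed=1000 + rep, subst_rate=0.0, ils_prob=ils,
                    insertions={("beaver", "kangaroo_rat", "mouse"): 8},
                )
                result = screen_from_dataset(ds, CASTORIMORPHA_PATTERNS)
                drifted += (result.pattern_counts["mouse_beaver"]
                            + result.pattern_counts["mouse_krat"]
                            + result.pattern_counts[CONFLICTING]
                            + result.pattern_counts["castorimorpha"])
            off_focal.append(drifted)
        assert off_focal[0] == 0
        assert off_focal[-1] > 0
        assert off_focal == sorted(off_focal)
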