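"""Multi-directional presence/absence screening of pairwise alignments.

Each annotated SINE on a reference genome is projected through the 2-way
alignments to every other taxon.  A diagnostic *absence* requires more
than 70% of the element's reference columns to sit opposite a gap in the
other species; loci whose 50-nt flanks contain other repeats (beyond a
10-nt tolerated overlap) are discarded; and absence in the outgroup
defines the plesiomorphic, insertion-free state.  The per-taxon states
are then matched against a table of candidate presence/absence patterns,
one per tree hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .axt import AxtBlock, ProjectedSlice, project_interval
from .fastcoex import DEFAULT_FAMILIES
from .repeatmasker import RepeatRecord, filter_families, merge_fragments

__all__ = [
    "PRESENT",
    "ABSENT",
    "AMBIGUOUS",
    "UNCOVERED",
    "CONFLICTING",
    "UNINFORMATIVE",
    "PresenceCall",
    "MarkerCandidate",
    "ScreenConfig",
    "ScreenResult",
    "call_presence",
    "flank_clean",
    "classify_pattern",
    "screen",
]

PRESENT = "present"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"
UNCOVERED = "uncovered"

CONFLICTING = "conflicting"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class PresenceCall:
    species: str
    state: str
    gap_fraction: float
    covered_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gap_fraction <= 1.0 and 0.0 <= self.covered_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")


def call_presence(
    slice_: ProjectedSlice,
    absence_threshold: float = 0.70,
    presence_threshold: float = 0.30,
    min_coverage: float = 0.80,
    species: str = "",
) -> PresenceCall:
    """Call presence/absence of the element in the aligned species.

    ``gap_fraction`` is the fraction of covered element reference columns
    opposite a query gap.  Absence requires *strictly more* than
    ``absence_threshold`` (the >70% rule); presence requires strictly
    less than ``presence_threshold``; in between the call is ambiguous.
    Below ``min_coverage`` alignment coverage the locus is uncovered.
    """
    covered = slice_.covered_fraction
    gap_cols = 0
    ref_cols = 0
    for r, q in zip(slice_.ref_aln, slice_.query_aln):
        if r != "-":
            ref_cols += 1
            if q == "-":
                gap_cols += 1
    gap_fraction = gap_cols / ref_cols if ref_cols else 0.0
    if covered < min_coverage:
        state = UNCOVERED
    elif gap_fraction > absence_threshold:
        state = ABSENT
    elif gap_fraction < presence_threshold:
        state = PRESENT
    else:
        state = AMBIGUOUS
    return PresenceCall(
        species=species, state=state, gap_fraction=gap_fraction, covered_fraction=covered
    )


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def flank_clean(
    element: RepeatRecord,
    records: Iterable[RepeatRecord],
    flank: int = 50,
    max_overlap: int = 10,
) -> bool:
    """True when no other repeat intrudes into the element's flank windows.

    Each ``flank``-nt window adjacent to the element is checked against
    the full (unfiltered) repeat annotation; any other repeat may overlap
    a window by at most ``max_overlap`` nt (inclusive).  Fragments of the
    focal element itself (same element ID, or nested inside it) are
    exempt.
    """
    start, end = element.interval()
    left = (start - flank, start)
    right = (end, end + flank)
    for r in records:
        if r.seq_id != element.seq_id:
            continue
        r_start, r_end = r.interval()
        if r.element_id == element.element_id or (start <= r_start and r_end <= end):
            continue
        if _overlap(r_start, r_end, *left) > max_overlap:
            return False
        if _overlap(r_start, r_end, *right) > max_overlap:
            return False
    return True


def classify_pattern(
    calls: Mapping[str, PresenceCall],
    pattern_table: Mapping[str, Mapping[str, str]],
    outgroups: Iterable[str],
) -> str:
    """Match per-taxon calls against the configured hypothesis patterns.

    Returns the unique matching hypothesis label; ``uninformative`` when a
    required taxon is ambiguous/uncovered, when an outgroup carries the
    element (plesiomorphy violated), or when the element is present in
    every ingroup (it predates the trichotomy); ``conflicting`` when at
    least two ingroups (a non-nested subset) carry it but no configured
    hypothesis matches.
    """
    outgroup_set = set(outgroups)
    table_taxa: set[str] = set()
    for required in pattern_table.values():
        table_taxa.update(required)
    for taxon in sorted(table_taxa):
        if taxon not in calls:
            raise ValueError(f"pattern table references taxon {taxon!r} missing from calls")

    matches = [
        label
        for label, required in pattern_table.items()
        if all(calls[taxon].state == state for taxon, state in required.items())
    ]
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        return CONFLICTING

    if any(calls[t].state in (AMBIGUOUS, UNCOVERED) for t in table_taxa):
        return UNINFORMATIVE
    if any(calls[t].state == PRESENT for t in table_taxa & outgroup_set):
        return UNINFORMATIVE
    ingroups = table_taxa - outgroup_set
    present = {t for t in ingroups if calls[t].state == PRESENT}
    if len(present) >= 2 and present != ingroups:
        return CONFLICTING
    return UNINFORMATIVE


@dataclass(frozen=True)
class MarkerCandidate:
    seq_id: str
    start: int
    end: int
    family: str
    calls: Mapping[str, PresenceCall]
    pattern_label: str
    flank_clean: bool


@dataclass
class ScreenConfig:
    """Inputs for one multi-directional screen.

    ``alignments`` maps each non-reference taxon to its AXT blocks
    against the reference; ``pattern_table`` maps hypothesis labels to
    the required state per taxon; ``outgroups`` name the taxa whose
    absence defines the plesiomorphic condition.
    """

    reference: str
    repeats: Sequence[RepeatRecord]
    alignments: Mapping[str, Sequence[AxtBlock]]
    pattern_table: Mapping[str, Mapping[str, str]]
    outgroups: Sequence[str]
    families: frozenset[str] = DEFAULT_FAMILIES
    absence_threshold: float = 0.70
    presence_threshold: float = 0.30
    min_coverage: float = 0.80
    flank: int = 50
    max_overlap: int = 10


@dataclass
class ScreenResult:
    candidates: list[MarkerCandidate]
    pattern_counts: dict[str, int]
    pattern_labels: tuple[str, ...]

    def counts_vector(self) -> list[int]:
        """Marker counts in pattern-table order (input to the significance test)."""
        return [self.pattern_counts.get(label, 0) for label in self.pattern_labels]


def _flank_clean_tree(
    element: RepeatRecord, tree: IntervalTree, flank: int, max_overlap: int
) -> bool:
    start, end = element.interval()
    for win_start, win_end in ((start - flank, start), (end, end + flank)):
        for hit in tree.overlap(win_start, win_end):
            r: RepeatRecord = hit.data
            r_start, r_end = r.interval()
            if r.element_id == element.element_id or (start <= r_start and r_end <= end):
                continue
            if _overlap(r_start, r_end, win_start, win_end) > max_overlap:
                return False
    return True


def screen(config: ScreenConfig) -> ScreenResult:
    """Run the multi-directional screen over all annotated SINEs.

    Family-filtered, fragment-merged, flank-clean elements on the
    reference are projected into every aligned taxon, called
    present/absent, and classified against the pattern table.  Output
    order is deterministic: ``(seq_id, start)``.
    """
    screened_taxa = set()
    for required in config.pattern_table.values():
        screened_taxa.update(required)
    screened_taxa.update(config.outgroups)
    screened_taxa.discard(config.reference)
    for taxon in sorted(screened_taxa):
        if taxon not in config.alignments:
            raise ValueError(f"no alignment configured for taxon {taxon!r}")

    merged = merge_fragments(config.repeats)
    elements = sorted(
        filter_families(merged, set(config.families)),
        key=lambda r: (r.seq_id, r.interval()[0]),
    )

    # one interval tree of the full annotation per reference sequence
    trees: dict[str, IntervalTree] = {}
    for r in merged:
        r_start, r_end = r.interval()
        trees.setdefault(r.seq_id, IntervalTree()).addi(r_start, r_end, r)

    blocks_by_taxon_seq: dict[tuple[str, str], list[AxtBlock]] = {}
    for taxon in sorted(screened_taxa):
        for block in config.alignments[taxon]:
            blocks_by_taxon_seq.setdefault((taxon, block.ref_name), []).append(block)

    candidates: list[MarkerCandidate] = []
    counts: dict[str, int] = {label: 0 for label in config.pattern_table}
    counts[CONFLICTING] = 0
    counts[UNINFORMATIVE] = 0
    for element in elements:
        if not _flank_clean_tree(element, trees[element.seq_id], config.flank, config.max_overlap):
            continue
        start, end = element.interval()
        calls: dict[str, PresenceCall] = {
            config.reference: PresenceCall(
                species=config.reference, state=PRESENT, gap_fraction=0.0, covered_fraction=1.0
            )
        }
        for taxon in sorted(screened_taxa):
            blocks = blocks_by_taxon_seq.get((taxon, element.seq_id), [])
            slice_ = project_interval(blocks, (start, end))
            calls[taxon] = call_presence(
                slice_,
                absence_threshold=config.absence_threshold,
                presence_threshold=config.presence_threshold,
                min_coverage=config.min_coverage,
                species=taxon,
            )
        label = classify_pattern(calls, config.pattern_table, config.outgroups)
        counts[label] += 1
        candidates.append(
            MarkerCandidate(
                seq_id=element.seq_id,
                start=start,
                end=end,
                family=element.repeat_name,
                calls=calls,
                pattern_label=label,
                flank_clean=True,
            )
        )
    return ScreenResult(
        candidates=candidates,
        pattern_counts=counts,
        pattern_labels=tuple(config.pattern_table),
    )


def write_candidate_table(result: ScreenResult, handle) -> None:
    taxa: list[str] = []
    if result.candidates:
        taxa = sorted(result.candidates[0].calls)
    handle.write("seq_id\tstart\tend\tfamily\tpattern\t" + "\t".join(taxa) + "\n")
    for c in result.candidates:
        states = "\t".join(c.calls[t].state for t in taxa)
        handle.write(f"{c.seq_id}\t{c.start}\t{c.end}\t{c.family}\t{c.pattern_label}\t{states}\n")
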