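"""Coordinate extraction of SINE loci from assembled contigs.

Given a RepeatMasker annotation of a contig assembly, select retroposon
elements of chosen families that sit far enough from the contig edges to
carry usable flanking sequence (for PCR primers and for cross-species
comparison), and extract element-plus-flank sequences from the FASTA.

All coordinates here are 0-based half-open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .repeatmasker import RepeatRecord, filter_families, merge_fragments

__all__ = [
    "LocusSpec",
    "LocusSequence",
    "DEFAULT_FAMILIES",
    "select_informative",
    "extract_sequences",
    "family_count_summary",
    "read_contigs",
    "write_loci_fasta",
    "write_locus_table",
]

#: Rodent SINE families active on the lineage leading to beaver: the B1
#: family B1F, the B1-derived PB1D subfamilies, the geomyoid SP-D-Geo
#: family, and the whole SINE/ID class.
DEFAULT_FAMILIES: frozenset[str] = frozenset(
    {"B1F", "PB1D7", "PB1D9", "PB1D10", "PB1D11", "SP-D-Geo", "SINE/ID"}
)


@dataclass(frozen=True)
class LocusSpec:
    """A selected SINE element with its available flank geometry."""

    locus_id: str
    seq_id: str
    element_start: int
    element_end: int
    left_flank_len: int
    right_flank_len: int
    family: str

    def __post_init__(self) -> None:
        if not self.element_start < self.element_end:
            raise ValueError("element_start must be < element_end")
        if self.left_flank_len < 0 or self.right_flank_len < 0:
            raise ValueError("flank lengths must be >= 0")


@dataclass(frozen=True)
class LocusSequence:
    """An extracted locus: element plus flanks, with the element's offset."""

    locus_id: str
    seq_id: str
    family: str
    sequence: str
    start: int  # interval of `sequence` on the contig
    end: int
    element_offset: int
    element_length: int

    def __post_init__(self) -> None:
        if self.element_offset + self.element_length > len(self.sequence):
            raise ValueError("element extends past extracted sequence")

    @property
    def element_sequence(self) -> str:
        return self.sequence[self.element_offset : self.element_offset + self.element_length]


def _locus_id(seq_id: str, start: int, end: int) -> str:
    # deterministic function of coordinates: stable across re-runs
    return f"{seq_id}:{start}-{end}"


def select_informative(
    records: Iterable[RepeatRecord],
    contig_lengths: Mapping[str, int],
    families: frozenset[str] | set[str] = DEFAULT_FAMILIES,
    min_flank: int = 50,
    strict: bool = False,
    include_overlapped: bool = True,
) -> list[LocusSpec]:
    """Select family-filtered, fragment-merged elements with adequate flanks.

    An element qualifies when both its left and right flanks (distance to
    the contig edges) reach ``min_flank`` nucleotides — at least
    ``min_flank`` by default, strictly more with ``strict=True``.  Rows
    overlapped by a higher-scoring match (star flag) can be dropped with
    ``include_overlapped=False``.  Output is sorted by
    ``(seq_id, element_start)``.
    """
    merged = merge_fragments(records)
    kept = filter_families(merged, set(families))
    specs: list[LocusSpec] = []
    for r in kept:
        if not include_overlapped and r.star_flag:
            continue
        if r.seq_id not in contig_lengths:
            raise ValueError(f"record references unknown contig {r.seq_id!r}")
        length = contig_lengths[r.seq_id]
        start, end = r.interval()
        if end > length:
            raise ValueError(
                f"element {start}-{end} extends past contig {r.seq_id!r} (length {length})"
            )
        left = start
        right = length - end
        ok = (left > min_flank and right > min_flank) if strict else (
            left >= min_flank and right >= min_flank
        )
        if not ok:
            continue
        family = r.repeat_name if r.repeat_name in families else r.repeat_class
        specs.append(
            LocusSpec(
                locus_id=_locus_id(r.seq_id, start, end),
                seq_id=r.seq_id,
                element_start=start,
                element_end=end,
                left_flank_len=left,
                right_flank_len=right,
                family=family,
            )
        )
    specs.sort(key=lambda s: (s.seq_id, s.element_start))
    return specs


ContigSource = Union[Mapping[str, str], str, Path]


def read_contigs(source: ContigSource) -> dict[str, str]:
    """Load contigs as a name -> sequence map (FASTA path or pass-through dict)."""
    if isinstance(source, Mapping):
        return dict(source)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")}


def extract_sequences(
    contigs: ContigSource,
    specs: Sequence[LocusSpec],
    extract_flank: int = 250,
) -> list[LocusSequence]:
    """Extract each element plus up to ``extract_flank`` nt of flank per side.

    The flank actually taken on each side is ``min(available flank,
    extract_flank)``; the returned sequence is the verbatim contig
    substring (case preserved) with the element's position recorded.
    """
    seqs = read_contigs(contigs)
    out: list[LocusSequence] = []
    for spec in specs:
        if spec.seq_id not in seqs:
            raise ValueError(f"locus {spec.locus_id} references unknown contig {spec.seq_id!r}")
        contig = seqs[spec.seq_id]
        left = min(spec.left_flank_len, extract_flank)
        right = min(spec.right_flank_len, extract_flank)
        start = spec.element_start - left
        end = spec.element_end + right
        if start < 0 or end > len(contig):
            raise ValueError(
                f"locus {spec.locus_id}: interval [{start}, {end}) outside contig "
                f"of length {len(contig)}"
            )
        out.append(
            LocusSequence(
                locus_id=spec.locus_id,
                seq_id=spec.seq_id,
                family=spec.family,
                sequence=contig[start:end],
                start=start,
                end=end,
                element_offset=left,
                element_length=spec.element_end - spec.element_start,
            )
        )
    return out


@dataclass(frozen=True)
class FamilySummary:
    counts: tuple[tuple[str, int], ...]
    total: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


def family_count_summary(specs: Iterable[LocusSpec]) -> FamilySummary:
    """Per-family locus counts plus total (total always equals the sum)."""
    counter: Counter[str] = Counter(s.family for s in specs)
    counts = tuple(sorted(counter.items()))
    return FamilySummary(counts=counts, total=sum(counter.values()))


def write_loci_fasta(loci: Iterable[LocusSequence], handle: TextIO) -> None:
    records = [
        SeqRecord(
            Seq(locus.sequence),
            id=locus.locus_id,
            description=(
                f"family={locus.family} interval={locus.seq_id}:{locus.start}-{locus.end} "
                f"element_offset={locus.element_offset} element_length={locus.element_length}"
            ),
        )
        for locus in loci
    ]
    SeqIO.write(records, handle, "fasta")


def write_locus_table(specs: Iterable[LocusSpec], handle: TextIO) -> None:
    handle.write("locus_id\tseq_id\telement_start\telement_end\tfamily\tleft_flank\tright_flank\n")
    for s in specs:
        handle.write(
            f"{s.locus_id}\t{s.seq_id}\t{s.element_start}\t{s.element_end}\t"
            f"{s.family}\t{s.left_flank_len}\t{s.right_flank_len}\n"
        )
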