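"""UCSC AXT pairwise-alignment blocks and coordinate projection.

AXT files carry netted pairwise whole-genome alignments as blocks of two
gapped sequence lines under a nine-field header
(``index ref ref_start ref_end query query_start query_end strand score``,
coordinates 1-based inclusive).  For a ``-`` strand block the query
coordinates refer to the reverse-complemented query sequence, per the
format standard; they are kept in that frame here.

Internally all coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np

__all__ = ["AxtBlock", "AxtFormatError", "parse_axt", "write_axt", "project_interval", "ProjectedSlice"]

GAP = "-"


class AxtFormatError(ValueError):
    pass


@dataclass(frozen=True)
class AxtBlock:
    index: int
    ref_name: str
    ref_start: int  # 0-based half-open
    ref_end: int
    query_name: str
    query_start: int  # 0-based half-open, on the strand given below
    query_end: int
    query_strand: str
    score: int
    ref_aln: str
    query_aln: str

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.query_aln):
            raise AxtFormatError(
                f"block {self.index}: sequence lines differ in length "
                f"({len(self.ref_aln)} vs {len(self.query_aln)})"
            )
        ref_bases = len(self.ref_aln) - self.ref_aln.count(GAP)
        if ref_bases != self.ref_end - self.ref_start:
            raise AxtFormatError(
                f"block {self.index}: ungapped reference length {ref_bases} does not "
                f"match interval {self.ref_end - self.ref_start}"
            )
        query_bases = len(self.query_aln) - self.query_aln.count(GAP)
        if query_bases != self.query_end - self.query_start:
            raise AxtFormatError(
                f"block {self.index}: ungapped query length {query_bases} does not "
                f"match interval {self.query_end - self.query_start}"
            )
        if self.query_strand not in "+-":
            raise AxtFormatError(f"block {self.index}: bad strand {self.query_strand!r}")


def parse_axt(stream: TextIO | Iterable[str]) -> list[AxtBlock]:
    """Parse AXT text into validated blocks (internal coordinates)."""
    lines = [ln.rstrip("\n") for ln in stream]
    blocks: list[AxtBlock] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line or line.startswith("#"):
            i += 1
            continue
        fields = line.split()
        if len(fields) != 9:
            raise AxtFormatError(f"expected 9 header fields, got {len(fields)}: {line!r}")
        if i + 2 >= n:
            raise AxtFormatError(f"truncated block after header {line!r}")
        try:
            index = int(fields[0])
            ref_start, ref_end = int(fields[2]), int(fields[3])
            query_start, query_end = int(fields[5]), int(fields[6])
            score = int(fields[8])
        except ValueError:
            raise AxtFormatError(f"non-numeric field in header {line!r}") from None
        blocks.append(
            AxtBlock(
                index=index,
                ref_name=fields[1],
                ref_start=ref_start - 1,
                ref_end=ref_end,
                query_name=fields[4],
                query_start=query_start - 1,
                query_end=query_end,
                query_strand=fields[7],
                score=score,
                ref_aln=lines[i + 1].strip(),
                query_aln=lines[i + 2].strip(),
            )
        )
        i += 3
    return blocks


def write_axt(blocks: Iterable[AxtBlock]) -> str:
    out = []
    for b in blocks:
        out.append(
            f"{b.index} {b.ref_name} {b.ref_start + 1} {b.ref_end} "
            f"{b.query_name} {b.query_start + 1} {b.query_end} {b.query_strand} {b.score}"
        )
        out.append(b.ref_aln)
        out.append(b.query_aln)
        out.append("")
    return "\n".join(out) + ("\n" if out else "")


@dataclass(frozen=True)
class ProjectedSlice:
    """Alignment columns of a reference interval, concatenated across blocks."""

    ref_aln: str
    query_aln: str
    interval_length: int
    covered_columns: int  # reference positions of the interval found in a block

    @property
    def covered_fraction(self) -> float:
        if self.interval_length == 0:
            return 0.0
        return self.covered_columns / self.interval_length


def _slice_block(block: AxtBlock, start: int, end: int) -> tuple[str, str, int]:
    ref = np.frombuffer(block.ref_aln.encode(), dtype="S1")
    query = np.frombuffer(block.query_aln.encode(), dtype="S1")
    is_base = ref != b"-"
    # coordinate of each base column; for a gap column, the previous base's
    coord = block.ref_start + np.cumsum(is_base) - 1
    sel_base = is_base & (coord >= start) & (coord < end)
    # interior query-insertion columns: the gap sits after base `coord`
    sel_gap = ~is_base & (coord >= start) & (coord <= end - 2)
    sel = sel_base | sel_gap
    return (
        ref[sel].tobytes().decode(),
        query[sel].tobytes().decode(),
        int(sel_base.sum()),
    )


def project_interval(blocks: Sequence[AxtBlock], ref_interval: tuple[int, int]) -> ProjectedSlice:
    """Collect alignment columns whose reference coordinate falls in the interval.

    Blocks must be non-overlapping on the reference (true for net
    alignments); overlap raises ``ValueError``.  Reference positions not
    inside any block count as uncovered; columns where the reference has a
    gap (query insertions) are included only when interior to the
    interval.
    """
    start, end = ref_interval
    if not start < end:
        raise ValueError("ref_interval must be non-empty")
    ordered = sorted(blocks, key=lambda b: b.ref_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.ref_start < a.ref_end:
            raise ValueError(
                f"blocks {a.index} and {b.index} overlap on the reference "
                f"([{a.ref_start},{a.ref_end}) vs [{b.ref_start},{b.ref_end}))"
            )
    ref_parts: list[str] = []
    query_parts: list[str] = []
    covered = 0
    for block in ordered:
        if block.ref_end <= start or block.ref_start >= end:
            continue
        r, q, c = _slice_block(block, start, end)
        ref_parts.append(r)
        query_parts.append(q)
        covered += c
    return ProjectedSlice(
        ref_aln="".join(ref_parts),
        query_aln="".join(query_parts),
        interval_length=end - start,
        covered_columns=covered,
    )
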