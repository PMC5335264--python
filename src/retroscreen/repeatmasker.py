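"""RepeatMasker ``.out`` annotation tables.

RepeatMasker reports repeat copies in a genome as a whitespace-delimited
table with a three-line header.  Coordinates in the file are 1-based
inclusive; everything downstream of the parser works in 0-based half-open
coordinates, and the two explicit converters below are the only place the
conventions meet.

Reverse-strand rows are marked ``C`` and swap the order of the
repeat-consensus coordinate columns from ``begin end (left)`` to
``(left) end begin``; the parser normalises both orders into the same
record fields.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, TextIO

__all__ = [
    "RepeatRecord",
    "RepeatMaskerParseError",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "filter_families",
    "merge_fragments",
    "to_bed",
    "one_to_zero",
    "zero_to_one",
]

FORWARD = "+"
REVERSE = "-"

_HEADER = (
    "   SW   perc perc perc  query     position in query          matching"
    "  repeat       position in repeat\n"
    "score   div. del. ins.  sequence  begin end      (left)      repeat"
    "   class/family   begin end (left)  ID\n"
    "\n"
)


def one_to_zero(begin: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return begin - 1, end


def zero_to_one(start: int, end: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start + 1, end


class RepeatMaskerParseError(ValueError):
    """Raised for a malformed annotation row; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class RepeatRecord:
    """One RepeatMasker annotation row.

    ``begin``/``end`` are kept exactly as written in the file (1-based
    inclusive); use :meth:`interval` for the internal convention.
    ``element_id`` links fragments of a single insertion that RepeatMasker
    split across rows; ``star_flag`` marks a row overlapped by a
    higher-scoring match.
    """

    sw_score: int
    pct_div: float
    pct_del: float
    pct_ins: float
    seq_id: str
    begin: int
    end: int
    left_remaining: int
    strand: str
    repeat_name: str
    repeat_class: str
    rep_begin: int
    rep_end: int
    rep_left: int
    element_id: int
    star_flag: bool = False

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError(f"begin {self.begin} > end {self.end}")
        for field in ("pct_div", "pct_del", "pct_ins"):
            v = getattr(self, field)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{field}={v} outside [0, 100]")
        if self.element_id < 0:
            raise ValueError("element_id must be >= 0")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def interval(self) -> tuple[int, int]:
        """Element interval in 0-based half-open coordinates."""
        return one_to_zero(self.begin, self.end)

    @property
    def length(self) -> int:
        return self.end - self.begin + 1


def _parse_paren(token: str, line_number: int, what: str) -> int:
    if not (token.startswith("(") and token.endswith(")")):
        raise RepeatMaskerParseError(line_number, f"expected '({what})' column, got {token!r}")
    try:
        return int(token[1:-1])
    except ValueError:
        raise RepeatMaskerParseError(line_number, f"non-numeric {what} {token!r}") from None


def _parse_int(token: str, line_number: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise RepeatMaskerParseError(line_number, f"non-numeric {what} {token!r}") from None


def _parse_float(token: str, line_number: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise RepeatMaskerParseError(line_number, f"non-numeric {what} {token!r}") from None


def parse_repeatmasker_out(stream: TextIO | Iterable[str]) -> list[RepeatRecord]:
    """Parse a RepeatMasker ``.out`` table into records.

    The up-to-three leading header lines (column captions and a blank
    line) are skipped; blank lines elsewhere are ignored; an empty stream
    yields an empty list.  A row with the wrong column count or a
    non-numeric coordinate raises :class:`RepeatMaskerParseError` naming
    the offending line.
    """
    records: list[RepeatRecord] = []
    for line_number, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if line_number <= 3 and not tokens[0].lstrip("-").isdigit():
            continue  # header caption line
        star = False
        if tokens and tokens[-1] == "*":
            star = True
            tokens = tokens[:-1]
        if len(tokens) != 15:
            raise RepeatMaskerParseError(
                line_number, f"expected 15 columns (+ optional '*'), got {len(tokens)}"
            )
        strand_token = tokens[8]
        if strand_token == FORWARD:
            strand = FORWARD
            rep_begin = _parse_int(tokens[11], line_number, "repeat begin")
            rep_end = _parse_int(tokens[12], line_number, "repeat end")
            rep_left = _parse_paren(tokens[13], line_number, "repeat left")
        elif strand_token in ("C", REVERSE):
            strand = REVERSE
            rep_left = _parse_paren(tokens[11], line_number, "repeat left")
            rep_end = _parse_int(tokens[12], line_number, "repeat end")
            rep_begin = _parse_int(tokens[13], line_number, "repeat begin")
        else:
            raise RepeatMaskerParseError(line_number, f"bad strand column {strand_token!r}")
        try:
            record = RepeatRecord(
                sw_score=_parse_int(tokens[0], line_number, "SW score"),
                pct_div=_parse_float(tokens[1], line_number, "% divergence"),
                pct_del=_parse_float(tokens[2], line_number, "% deletion"),
                pct_ins=_parse_float(tokens[3], line_number, "% insertion"),
                seq_id=tokens[4],
                begin=_parse_int(tokens[5], line_number, "begin"),
                end=_parse_int(tokens[6], line_number, "end"),
                left_remaining=_parse_paren(tokens[7], line_number, "left"),
                strand=strand,
                repeat_name=tokens[9],
                repeat_class=tokens[10],
                rep_begin=rep_begin,
                rep_end=rep_end,
                rep_left=rep_left,
                element_id=_parse_int(tokens[14], line_number, "element ID"),
                star_flag=star,
            )
        except ValueError as exc:
            raise RepeatMaskerParseError(line_number, str(exc)) from None
        records.append(record)
    return records


def _format_row(r: RepeatRecord) -> str:
    if r.strand == FORWARD:
        strand_cols = f"+  {r.repeat_name:<14} {r.repeat_class:<18} {r.rep_begin:>5} {r.rep_end:>5} ({r.rep_left})"
    else:
        strand_cols = f"C  {r.repeat_name:<14} {r.repeat_class:<18} ({r.rep_left}) {r.rep_end:>5} {r.rep_begin:>5}"
    star = " *" if r.star_flag else ""
    return (
        f"{r.sw_score:>5} {r.pct_div:>5.1f} {r.pct_del:>4.1f} {r.pct_ins:>4.1f}  "
        f"{r.seq_id:<20} {r.begin:>9} {r.end:>9} ({r.left_remaining})  "
        f"{strand_cols} {r.element_id:>6}{star}"
    )


def write_repeatmasker_out(records: Iterable[RepeatRecord]) -> str:
    """Serialise records back to ``.out`` text (header included).

    Round-trips through :func:`parse_repeatmasker_out` with all fields
    preserved.
    """
    body = "\n".join(_format_row(r) for r in records)
    return _HEADER + (body + "\n" if body else "")


def filter_families(records: Iterable[RepeatRecord], families: set[str]) -> list[RepeatRecord]:
    """Keep records whose ``repeat_name`` or ``repeat_class`` is in *families*.

    Matching is exact and case-sensitive — class labels such as
    ``"SINE/ID"`` select whole classes while names such as ``"B1F"``
    select single families.  Input order is preserved.
    """
    if not families:
        raise ValueError("families must be non-empty")
    fam = set(families)
    return [r for r in records if r.repeat_name in fam or r.repeat_class in fam]


def merge_fragments(records: Iterable[RepeatRecord]) -> list[RepeatRecord]:
    """Merge rows sharing ``(seq_id, element_id, repeat_name)`` into one element.

    RepeatMasker splits a single insertion interrupted by other sequence
    into several rows linked by the element ID column; the merged element
    spans ``min(begin)..max(end)``.  Score and divergence come from the
    highest-scoring fragment; a merged element carries the star flag if
    any fragment did.  Output order follows first appearance.
    """
    groups: dict[tuple[str, int, str], list[RepeatRecord]] = {}
    order: list[tuple[str, int, str]] = []
    for r in records:
        key = (r.seq_id, r.element_id, r.repeat_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    merged: list[RepeatRecord] = []
    for key in order:
        frags = groups[key]
        if len(frags) == 1:
            merged.append(frags[0])
            continue
        best = max(frags, key=lambda f: f.sw_score)
        last = max(frags, key=lambda f: f.end)
        merged.append(
            replace(
                best,
                begin=min(f.begin for f in frags),
                end=max(f.end for f in frags),
                left_remaining=last.left_remaining,
                star_flag=any(f.star_flag for f in frags),
            )
        )
    return merged


def to_bed(records: Iterable[RepeatRecord]) -> str:
    """Emit records as BED6 text (0-based half-open)."""
    lines = []
    for r in records:
        start, end = r.interval()
        lines.append(
            f"{r.seq_id}\t{start}\t{end}\t{r.repeat_name}\t{r.sw_score}\t{r.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
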