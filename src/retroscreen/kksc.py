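"""Directional insertion significance test on diagnostic marker counts.

Three lineages meeting at a trichotomy can be resolved in three ways;
each phylogenetically diagnostic retroposon insertion supports exactly
one of them.  Under the polytomy null — markers sort into the three
topologies independently with equal probability 1/3, the limit of pure
incomplete lineage sorting — the observed counts ``[n1 n2 n3]`` are
Multinomial(n; 1/3, 1/3, 1/3).

The directional statistic implemented here is the focal excess

    D = n_focal - max(other two counts),

and the reported p-value is the exact tail P(D* >= D_observed) under the
null.  In the conflict-free case ``[n, 0, 0]`` the only outcome at least
as extreme is all-focal, so p = 3^-n exactly (e.g. 1/729 ~ 0.00137 for
six markers).  Counts up to n = 25 are evaluated with exact integer
arithmetic; larger counts use the same summation in log space.

The full population-genetic machinery of the original KKSC framework
(Wright-Fisher fixation probabilities, hybridization vs. ILS
discrimination, four-lineage tests) is intentionally out of scope; see
:func:`hybridization_test`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

__all__ = [
    "MarkerCounts",
    "SignificanceResult",
    "kksc_directional_p",
    "multidirectional_test",
    "null_distribution",
]

_EXACT_LIMIT = 25

def hybridization_test(*_args, **_kwargs):
    """Hybridization/diffusion extensions of the original framework (stub)."""
    raise NotImplementedError("only the polytomy-null directional test is implemented")


@dataclass(frozen=True)
class MarkerCounts:
    """Diagnostic marker counts for the three resolutions of a trichotomy."""

    n1: int
    n2: int
    n3: int
    labels: tuple[str, str, str] = ("topology1", "topology2", "topology3")

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3) < 0:
            raise ValueError("marker counts must be non-negative")
        if len(set(self.labels)) != 3:
            raise ValueError("topology labels must be distinct")

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n1, self.n2, self.n3)


def _coerce(counts: "MarkerCounts | Sequence[int]") -> MarkerCounts:
    if isinstance(counts, MarkerCounts):
        return counts
    values = tuple(int(c) for c in counts)
    if len(values) != 3:
        raise ValueError("expected exactly three marker counts")
    return MarkerCounts(*values)


def _compositions(n: int):
    """All (n1, n2, n3) with n1 + n2 + n3 = n."""
    for n1 in range(n + 1):
        for n2 in range(n - n1 + 1):
            yield n1, n2, n - n1 - n2


def _statistic(n1: int, n2: int, n3: int) -> int:
    return n1 - max(n2, n3)


def kksc_directional_p(counts: "MarkerCounts | Sequence[int]", focal: int = 0) -> float:
    """Exact tail probability of the focal topology's marker excess.

    ``focal`` indexes which of the three counts is the hypothesis under
    test.  Requires at least one marker in total.
    """
    c = _coerce(counts)
    n = c.total
    if n < 1:
        raise ValueError("no markers: total count must be >= 1")
    values = list(c.as_tuple())
    n_focal = values.pop(focal)
    d_obs = n_focal - max(values)
    if n <= _EXACT_LIMIT:
        numerator = 0
        for n1, n2, n3 in _compositions(n):
            if _statistic(n1, n2, n3) >= d_obs:
                numerator += math.comb(n, n1) * math.comb(n - n1, n2)
        return float(Fraction(numerator, 3**n))
    log_terms = []
    log3 = math.log(3.0)
    lg_n = math.lgamma(n + 1)
    for n1, n2, n3 in _compositions(n):
        if _statistic(n1, n2, n3) >= d_obs:
            log_terms.append(
                lg_n
                - math.lgamma(n1 + 1)
                - math.lgamma(n2 + 1)
                - math.lgamma(n3 + 1)
                - n * log3
            )
    m = max(log_terms)
    return float(math.exp(m) * sum(math.exp(t - m) for t in log_terms))


def null_distribution(n: int) -> dict[int, float]:
    """Exact pmf of D = N1 - max(N2, N3) under Multinomial(n; 1/3, 1/3, 1/3).

    Valid for 1 <= n <= 25 (exact integer arithmetic); masses sum to 1.
    """
    if not 1 <= n <= _EXACT_LIMIT:
        raise ValueError(f"n must be in [1, {_EXACT_LIMIT}], got {n}")
    masses: dict[int, Fraction] = {}
    denom = 3**n
    for n1, n2, n3 in _compositions(n):
        d = _statistic(n1, n2, n3)
        weight = math.comb(n, n1) * math.comb(n - n1, n2)
        masses[d] = masses.get(d, Fraction(0)) + Fraction(weight, denom)
    return {d: float(p) for d, p in sorted(masses.items())}


POLYTOMY_NOT_REJECTED = "polytomy-not-rejected"


@dataclass(frozen=True)
class SignificanceResult:
    counts: MarkerCounts
    p_directional: dict[str, float]
    alpha: float
    verdict: str  # "resolved" or "polytomy-not-rejected"
    resolved_topology: str | None

    def summary(self) -> str:
        lines = [
            f"marker counts: [{self.counts.n1} {self.counts.n2} {self.counts.n3}]",
            f"alpha: {self.alpha:g}",
        ]
        for label in self.counts.labels:
            lines.append(f"  p({label}) = {self.p_directional[label]:.6g}")
        if self.resolved_topology is not None:
            lines.append(f"verdict: resolved -> {self.resolved_topology}")
        else:
            lines.append(f"verdict: {POLYTOMY_NOT_REJECTED}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "counts": list(self.counts.as_tuple()),
            "labels": list(self.counts.labels),
            "p_directional": dict(self.p_directional),
            "alpha": self.alpha,
            "verdict": self.verdict,
            "resolved_topology": self.resolved_topology,
        }


def multidirectional_test(
    counts: "MarkerCounts | Sequence[int]", alpha: float = 0.05
) -> SignificanceResult:
    """Test all three topologies as focal; resolve when exactly one is significant."""
    c = _coerce(counts)
    p = {
        label: kksc_directional_p(c, focal=i) for i, label in enumerate(c.labels)
    }
    significant = [label for label in c.labels if p[label] < alpha]
    if len(significant) == 1:
        return SignificanceResult(
            counts=c,
            p_directional=p,
            alpha=alpha,
            verdict="resolved",
            resolved_topology=significant[0],
        )
    return SignificanceResult(
        counts=c,
        p_directional=p,
        alpha=alpha,
        verdict=POLYTOMY_NOT_REJECTED,
        resolved_topology=None,
    )
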