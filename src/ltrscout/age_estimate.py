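"""LTR-pair divergence and insertion-age estimation.

The two LTRs of an element are identical at insertion time and accumulate
substitutions independently afterwards, so their pairwise divergence dates
the insertion. The 5' and 3' LTRs are aligned globally, transition (P) and
transversion (Q) proportions are counted over ungapped, N-free columns, and
the Kimura two-parameter distance

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

corrects for multiple hits. Given a substitution rate r (per site per year),
the insertion age is T = d / (2 r): each LTR accumulates d/2 substitutions
per site.

Saturated pairs (1 - 2P - Q <= 0 or 1 - 2Q <= 0) are flagged, not dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from Bio import Align

#: Scoring of the LTR-LTR global alignment (end gaps penalized).
LTR_MATCH = 2.0
LTR_MISMATCH = -2.0
LTR_GAP_OPEN = -10.0
LTR_GAP_EXTEND = -0.5

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """K2P distance undefined: substitutions have saturated."""


@dataclass(frozen=True)
class SubstitutionCounts:
    """Transition/transversion counts over the ungapped, N-free columns."""

    n_sites: int
    transitions: int
    transversions: int
    gap_columns: int

    @property
    def P(self) -> float:
        return self.transitions / self.n_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.n_sites


@dataclass(frozen=True)
class AgeResult:
    """K2P divergence of an LTR pair, optionally converted to years."""

    d: float
    saturated: bool = False
    T: Optional[float] = None
    rate: Optional[float] = None
    counts: Optional[SubstitutionCounts] = None

    @property
    def T_mya(self) -> Optional[float]:
        return None if self.T is None else self.T / 1.0e6


_global_aligner = Align.PairwiseAligner(
    mode="global", match_score=LTR_MATCH, mismatch_score=LTR_MISMATCH,
    open_gap_score=LTR_GAP_OPEN, extend_gap_score=LTR_GAP_EXTEND,
)


def global_align_ltrs(ltr5: str, ltr3: str):
    """Optimal global alignment of the two LTRs (deterministic traceback)."""
    if not ltr5 or not ltr3:
        raise ValueError("cannot align an empty LTR sequence")
    return _global_aligner.align(ltr5, ltr3)[0]


def count_substitutions(alignment) -> SubstitutionCounts:
    """Classify aligned columns: gap or N columns are excluded; among the
    rest, A<->G and C<->T are transitions, every other mismatch a transversion."""
    a = str(alignment.sequences[0])
    b = str(alignment.sequences[1])
    blocks_a, blocks_b = alignment.aligned
    n_sites = transitions = transversions = 0
    aligned_cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        aligned_cols += ae - as_
        for x, y in zip(a[as_:ae], b[bs:be]):
            if x == "N" or y == "N":
                continue
            n_sites += 1
            if x == y:
                continue
            if {x, y} <= _PURINES or {x, y} <= _PYRIMIDINES:
                transitions += 1
            else:
                transversions += 1
    gap_columns = alignment.length - aligned_cols
    if n_sites == 0:
        raise ValueError("no comparable sites")
    return SubstitutionCounts(n_sites=n_sites, transitions=transitions,
                              transversions=transversions, gap_columns=gap_columns)


def k2p_distance(P: float, Q: float) -> float:
    """Kimura (1980) two-parameter distance; raises SaturationError outside
    the valid domain."""
    if 1.0 - 2.0 * P - Q <= 0.0 or 1.0 - 2.0 * Q <= 0.0:
        raise SaturationError(f"saturated: P={P}, Q={Q}")
    # log1p keeps full precision for nearly identical LTR pairs
    return -0.5 * math.log1p(-2.0 * P - Q) - 0.25 * math.log1p(-2.0 * Q)


def insertion_age(d: float, rate: float) -> float:
    """Insertion age in years: T = d / (2 r)."""
    if rate <= 0.0:
        raise ValueError("substitution rate must be positive")
    if d < 0.0:
        raise ValueError("divergence must be non-negative")
    return d / (2.0 * rate)


def estimate_ltr_divergence(ltr5: str, ltr3: str,
                            rate: Optional[float] = None) -> AgeResult:
    """Align, count, and convert: the full divergence/age stage for one pair."""
    aln = global_align_ltrs(ltr5, ltr3)
    counts = count_substitutions(aln)
    try:
        d = k2p_distance(counts.P, counts.Q)
    except SaturationError:
        return AgeResult(d=math.nan, saturated=True, counts=counts, rate=rate)
    T = insertion_age(d, rate) if rate is not None else None
    return AgeResult(d=d, saturated=False, T=T, rate=rate, counts=counts)
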