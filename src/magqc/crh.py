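"""Count ratio histograms (CRH): the stage-II feature transform.

The high-dimensional domain-count space is compressed into a histogram
of query/reference count ratios.  Bin centers are all distinct exact
rationals a/b with a, b in 1..c_max (so c_max controls the resolution;
c_max = 4 yields the 11 centers 1/4, 1/3, 1/2, 2/3, 3/4, 1, 4/3, 3/2,
2, 3, 4).  For every family in the union of the two supports:

* families absent from the query (ratio 0) fall into the left-most bin,
  which therefore doubles as the "missing from query" bin;
* families absent from the reference, or with ratio > c_max, fall into
  the overloaded right-most bin;
* every other ratio is assigned to its nearest center (exact rational
  comparison; ties go to the center closer to 1).

Frequencies are normalized by the union support size, so every CRH sums
to one.  A complete, uncontaminated query yields a single spike at
center 1; incompleteness shifts mass left, contamination shifts it
right.  The stage-II feature vector is the mean CRH over the K stage-I
neighbors with the two stage-I estimates appended.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .profiles import DomainProfile
from .stage1 import Stage1Result


@dataclass(frozen=True)
class BinCenters:
    """Sorted exact-rational bin centers for a given resolution c_max."""

    c_max: int
    centers: Tuple[Fraction, ...]

    def __len__(self) -> int:
        return len(self.centers)

    def labels(self) -> List[str]:
        return [f"crh_{c.numerator}/{c.denominator}" if c.denominator != 1
                else f"crh_{c.numerator}" for c in self.centers]


@dataclass
class CRHVector:
    """Normalized count-ratio histogram aligned with centers(c_max)."""

    c_max: int
    frequencies: np.ndarray
    n_families: int


@dataclass
class Stage2Features:
    """Mean CRH plus the two stage-I estimates, flattened."""

    mean_crh: CRHVector
    comp_stage1: float
    cont_stage1: float

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.mean_crh.frequencies, [self.comp_stage1, self.cont_stage1]]
        )


@lru_cache(maxsize=None)
def bin_centers(c_max: int) -> BinCenters:
    """All distinct ratios a/b with a, b in 1..c_max, sorted ascending."""
    if c_max < 1:
        raise ValueError(f"c_max must be >= 1, got {c_max}")
    centers = sorted(
        {Fraction(a, b) for a in range(1, c_max + 1) for b in range(1, c_max + 1)}
    )
    return BinCenters(c_max=c_max, centers=tuple(centers))


@lru_cache(maxsize=None)
def _assign_bin(c_q: int, c_r: int, c_max: int) -> int:
    """Bin index for a (query count, reference count) pair.

    Exact rational arithmetic throughout; cached because the same small
    count pairs recur across families and queries.
    """
    bc = bin_centers(c_max)
    last = len(bc) - 1
    if c_q == 0 and c_r == 0:
        raise ValueError("family absent from both profiles")
    if c_q == 0:
        return 0  # left-most bin doubles as the reference-only bin
    if c_r == 0:
        return last  # right-most bin doubles as the query-only bin
    ratio = Fraction(c_q, c_r)
    if ratio > c_max:
        return last
    centers = bc.centers
    i = bisect_left(centers, ratio)
    if i < len(centers) and centers[i] == ratio:
        return i
    if i == 0:
        return 0  # below the smallest center: nearest is the left-most bin
    if i == len(centers):
        return last
    lo, hi = centers[i - 1], centers[i]
    d_lo, d_hi = ratio - lo, hi - ratio
    if d_lo < d_hi:
        return i - 1
    if d_hi < d_lo:
        return i
    # exact midpoint: prefer the center closer to 1
    return i - 1 if abs(lo - 1) <= abs(hi - 1) else i


def compute_crh(q: DomainProfile, r: DomainProfile, c_max: int) -> CRHVector:
    """Histogram of count ratios C_q/C_r over the union of supports."""
    if len(r) == 0:
        raise ValueError("compute_crh requires a nonempty reference profile")
    bc = bin_centers(c_max)
    counts = np.zeros(len(bc), dtype=np.int64)
    families = set(q.counts) | set(r.counts)
    for fam in families:
        counts[_assign_bin(q.get(fam), r.get(fam), c_max)] += 1
    n = len(families)
    return CRHVector(c_max=c_max, frequencies=counts / n, n_families=n)


def mean_crh(
    q: DomainProfile, neighbors: Sequence[DomainProfile], c_max: int
) -> CRHVector:
    """Element-wise mean of the per-neighbor (normalized) CRH vectors."""
    if not neighbors:
        raise ValueError("mean_crh requires at least one neighbor")
    vectors = [compute_crh(q, nb, c_max) for nb in neighbors]
    freqs = np.mean([v.frequencies for v in vectors], axis=0)
    return CRHVector(
        c_max=c_max,
        frequencies=freqs,
        n_families=int(round(np.mean([v.n_families for v in vectors]))),
    )


def build_features(crh: CRHVector, stage1: Stage1Result) -> Stage2Features:
    """Assemble the stage-II feature vector: [CRH..., comp1, cont1].

    Uses the raw (unclamped) stage-I estimates, which carry information
    even when they exceed the valid output range.
    """
    if not (np.isfinite(stage1.completeness) and np.isfinite(stage1.contamination)):
        raise ValueError("stage-I estimates must be finite to build features")
    return Stage2Features(
        mean_crh=crh,
        comp_stage1=stage1.completeness,
        cont_stage1=stage1.contamination,
    )


def feature_names(c_max: int) -> List[str]:
    """Stable column names for an exported feature matrix."""
    return bin_centers(c_max).labels() + ["comp1", "cont1"]
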