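"""Composite spectral-similarity score for biotyping peak lists.

Two centroided, max-normalized peak lists (reference and test) are compared
by a one-to-one peak matching within a mass tolerance, from which three
values in [0, 1] are computed:

* ``v1`` — fraction of reference peaks with a matching partner in the test
  spectrum;
* ``v2`` — fraction of test peaks with a matching partner in the reference
  spectrum;
* ``v3`` — peak-height symmetry of the matched pairs, aggregated from
  per-pair min/max ratios of the normalized intensities.

The composite score is ``log10(1000 * v1 * v2 * v3)`` clamped below at 0,
giving the familiar 0-3 identification-score scale on which 3 means a
perfect self-match and values below 1.7 carry no identification value.

The matching itself is an optimal assignment: maximum cardinality first,
minimum total |delta m/z| among maximum-cardinality matchings, with a
deterministic preference for the lower reference index on exact ties.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import PeakList

__all__ = [
    "MatchResult",
    "ScoreComponents",
    "ScoringConfig",
    "RelatednessBand",
    "IdentificationBand",
    "ScoreInterpretation",
    "match_peaks",
    "score_components",
    "composite_score",
    "score_pair",
    "interpret_score",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Peak-matching tolerance and symmetry aggregation strategy.

    The tolerance for a reference peak at mass m is
    ``tol_const + tol_ppm * 1e-6 * m`` Da: linear-mode mass errors grow
    roughly proportionally with mass, so a constant floor plus a ppm term
    covers both ends of the 2-20 kDa window.  The ppm default covers ~3
    sigma of the mass difference between two independently acquired spectra
    at a single-spectrum reproducibility of ~300 ppm (pairwise sigma =
    sqrt(2)*300 = 424 ppm); a tighter window silently drops a material
    fraction of true peak matches at the high-mass end and turns mass
    drift into classification noise.
    """

    tol_const: float = 2.0    # Da
    tol_ppm: float = 1200.0
    symmetry_strategy: str = "mean_ratio"  # or "geometric_mean_ratio"

    def tolerance(self, ref_mz: float) -> float:
        return self.tol_const + self.tol_ppm * 1e-6 * ref_mz


@dataclass(frozen=True)
class MatchResult:
    """One-to-one pairing of reference and test peak indices within tolerance."""

    pairs: tuple[tuple[int, int], ...]
    n_ref: int
    n_test: int
    tol_ppm: float
    tol_const: float

    def __post_init__(self) -> None:
        refs = [i for i, _ in self.pairs]
        tests = [j for _, j in self.pairs]
        if len(set(refs)) != len(refs) or len(set(tests)) != len(tests):
            raise ValueError("matching must be one-to-one")


@dataclass(frozen=True)
class ScoreComponents:
    v1: float  # fraction of reference peaks matched
    v2: float  # fraction of test peaks matched
    v3: float  # peak-height symmetry of matched pairs

    def __post_init__(self) -> None:
        for name, v in (("v1", self.v1), ("v2", self.v2), ("v3", self.v3)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


# penalty for infeasible pairs; dominates any achievable sum of |delta mz|
_BIG = 1e9
# tiebreak epsilons: prefer lower reference index, then lower test index
_EPS_REF = 1e-7
_EPS_TEST = 1e-10


def match_peaks(ref: PeakList, test: PeakList,
                tol_ppm: float = 1200.0, tol_const: float = 2.0) -> MatchResult:
    """Optimal one-to-one peak matching within mass tolerance.

    Maximizes the number of matched pairs; among maximum-cardinality
    matchings, minimizes total |delta m/z|.  Solved as a rectangular
    assignment problem where infeasible pairs carry a prohibitive cost, so
    every feasible pair the assignment can add beats any re-routing of
    mass errors.  Deterministic: exact cost ties prefer the lower reference
    index.
    """
    rm, tm = ref.mz, test.mz
    n, m = len(rm), len(tm)
    if n == 0 or m == 0:
        return MatchResult((), n, m, tol_ppm, tol_const)
    d = np.abs(rm[:, None] - tm[None, :])
    tol = tol_const + tol_ppm * 1e-6 * rm[:, None]
    feasible = d <= tol
    cost = np.where(feasible, d, _BIG)
    cost = cost + _EPS_REF * np.arange(n)[:, None] + _EPS_TEST * np.arange(m)[None, :]
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple((int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j])
    return MatchResult(pairs, n, m, tol_ppm, tol_const)


def score_components(m: MatchResult, ref: PeakList, test: PeakList,
                     symmetry_strategy: str = "mean_ratio") -> ScoreComponents:
    """Directional match fractions and peak-height symmetry.

    Both peak lists must be max-normalized so the intensity ratios compare
    relative peak heights.  Conventions: an empty list makes its fraction 0;
    no matched pairs makes the symmetry 0.
    """
    if not ref.normalized or not test.normalized:
        raise ValueError("score_components requires normalized peak lists")
    k = len(m.pairs)
    v1 = k / m.n_ref if m.n_ref else 0.0
    v2 = k / m.n_test if m.n_test else 0.0
    if k == 0:
        v3 = 0.0
    else:
        ri, ti = ref.intensity, test.intensity
        ratios = [min(ri[i], ti[j]) / max(ri[i], ti[j]) for i, j in m.pairs]
        if symmetry_strategy == "mean_ratio":
            v3 = float(np.mean(ratios))
        elif symmetry_strategy == "geometric_mean_ratio":
            v3 = float(np.exp(np.mean(np.log(ratios))))
        else:
            raise ValueError(f"unknown symmetry strategy {symmetry_strategy!r}")
    return ScoreComponents(v1, v2, v3)


def composite_score(c: ScoreComponents) -> float:
    """log10 of the product of the three components scaled to 1000,
    clamped to the printed [0, 3] range.  (1, 1, 1) maps to exactly 3."""
    product = c.v1 * c.v2 * c.v3
    if product <= 1e-3:
        return 0.0
    return min(3.0, math.log10(1000.0 * product))


def score_pair(ref: PeakList, test: PeakList,
               config: ScoringConfig = ScoringConfig()) -> float:
    """Composite score of one reference/test peak-list pair."""
    m = match_peaks(ref, test, config.tol_ppm, config.tol_const)
    c = score_components(m, ref, test, config.symmetry_strategy)
    return composite_score(c)


class RelatednessBand(enum.Enum):
    VERY_CLOSE = "very_close"   # 2.3 - 3.0
    CLOSE = "close"             # 2.0 - 2.3
    MODERATE = "moderate"       # 1.7 - 2.0 (between close and low)
    LOW = "low"                 # < 1.7


class IdentificationBand(enum.Enum):
    SPECIES_LEVEL = "species_level"        # 2.300 - 3.000
    GENUS_SPECIES = "genus_species"        # 2.000 - 2.299
    GENUS_PROBABLE = "genus_probable"      # 1.700 - 1.999
    UNRELIABLE = "unreliable"              # 0.000 - 1.699


@dataclass(frozen=True)
class ScoreInterpretation:
    relatedness: RelatednessBand
    identification: IdentificationBand


def interpret_score(score: float) -> ScoreInterpretation:
    """Map a composite score to its relatedness and identification bands.

    Identification bands follow the standard guideline cutoffs:
    [2.300, 3.000] highly probable species-level identification;
    [2.000, 2.299] secure genus / probable species; [1.700, 1.999] probable
    genus; [0.000, 1.699] no reliable identification.
    """
    if not 0.0 <= score <= 3.0:
        raise ValueError(f"score {score} outside [0, 3]")
    if score >= 2.3:
        rel, ident = RelatednessBand.VERY_CLOSE, IdentificationBand.SPECIES_LEVEL
    elif score >= 2.0:
        rel, ident = RelatednessBand.CLOSE, IdentificationBand.GENUS_SPECIES
    elif score >= 1.7:
        rel, ident = RelatednessBand.MODERATE, IdentificationBand.GENUS_PROBABLE
    else:
        rel, ident = RelatednessBand.LOW, IdentificationBand.UNRELIABLE
    return ScoreInterpretation(rel, ident)
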