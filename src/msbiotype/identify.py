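"""Reference-panel identification: score, average per population, call the max.

Each test sample is scored against every replicate reference spectrum, the
scores are averaged per reference population, and the population with the
highest average is the identification call.  Blind-test accuracy gives full
credit to an untied correct call and splits credit 1/|tied set| when the
true population ties for the maximum (so a single two-way tie containing
the truth contributes 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PeakList, ScoreMatrix
from .scoring import ScoringConfig, score_pair

__all__ = [
    "ReferencePanel",
    "IdentificationCall",
    "build_score_matrix",
    "average_by_population",
    "call_identity",
    "accuracy",
    "cognate_average",
    "noncognate_bidirectional_average",
]


@dataclass
class ReferencePanel:
    """Replicate reference peak lists per population (quadruplicate by default)."""

    refs: dict[str, list[PeakList]]

    def __post_init__(self) -> None:
        if not self.refs:
            raise ValueError("reference panel must contain at least one population")
        for pop, pls in self.refs.items():
            if not pls:
                raise ValueError(f"population {pop!r} has no reference replicates")

    @property
    def populations(self) -> list[str]:
        return list(self.refs)


@dataclass(frozen=True)
class IdentificationCall:
    test_id: str
    population_averages: dict[str, float]
    call: str
    tied: bool
    tied_with: tuple[str, ...]


def build_score_matrix(tests: list[PeakList], panel: ReferencePanel,
                       config: ScoringConfig = ScoringConfig()) -> ScoreMatrix:
    """Score every test sample against every reference replicate."""
    if not panel.refs:
        raise ValueError("empty reference panel")
    ref_ids: list[str] = []
    ref_pop: dict[str, str] = {}
    flat_refs: list[PeakList] = []
    for pop, pls in panel.refs.items():
        for k, pl in enumerate(pls):
            rid = pl.sample_id or f"{pop}_ref{k + 1}"
            if rid in ref_pop:
                rid = f"{rid}#{len(ref_ids)}"
            ref_ids.append(rid)
            ref_pop[rid] = pop
            flat_refs.append(pl)
    scores = np.empty((len(tests), len(flat_refs)))
    for i, t in enumerate(tests):
        for j, r in enumerate(flat_refs):
            scores[i, j] = score_pair(r, t, config)
    truth = {t.sample_id: t.population for t in tests if t.population is not None}
    return ScoreMatrix(
        test_ids=[t.sample_id for t in tests],
        ref_ids=ref_ids,
        scores=scores,
        ref_population_of=ref_pop,
        true_population_of=truth or None,
    )


def average_by_population(sm: ScoreMatrix) -> ScoreMatrix:
    """Collapse reference-replicate columns to per-population means."""
    pops = sm.populations
    cols = []
    for pop in pops:
        idx = [j for j, r in enumerate(sm.ref_ids) if sm.ref_population_of[r] == pop]
        cols.append(sm.scores[:, idx].mean(axis=1))
    return ScoreMatrix(
        test_ids=list(sm.test_ids),
        ref_ids=pops,
        scores=np.column_stack(cols),
        ref_population_of={p: p for p in pops},
        true_population_of=sm.true_population_of,
    )


def call_identity(averages: dict[str, float], tie_tol: float = 0.0,
                  test_id: str = "") -> IdentificationCall:
    """Call the population with the highest average score.

    Populations within ``tie_tol`` of the maximum form the tied set (listed
    alphabetically); the call itself is the alphabetically first argmax so
    the result is deterministic even under exact ties.
    """
    if not averages:
        raise ValueError("no population averages to call from")
    top = max(averages.values())
    tied_with = tuple(sorted(p for p, v in averages.items() if top - v <= tie_tol))
    call = min((p for p, v in averages.items() if v == top))
    return IdentificationCall(
        test_id=test_id,
        population_averages=dict(averages),
        call=call,
        tied=len(tied_with) > 1,
        tied_with=tied_with,
    )


def calls_from_matrix(sm: ScoreMatrix, tie_tol: float = 0.0) -> list[IdentificationCall]:
    """Per-row identification calls from a population-averaged score matrix."""
    avg = average_by_population(sm)
    out = []
    for i, tid in enumerate(avg.test_ids):
        averages = dict(zip(avg.ref_ids, avg.scores[i]))
        out.append(call_identity(averages, tie_tol, test_id=tid))
    return out


def accuracy(calls: list[IdentificationCall],
             truth: dict[str, str]) -> tuple[float, int, float]:
    """Blind-test accuracy with fractional credit for ties.

    Returns (n_correct, n_total, percent).  An untied correct call scores 1;
    a tie whose tied set contains the true population scores 1/|tied set|;
    anything else 0.  Percent is rounded to the nearest integer, matching
    how such accuracies are conventionally reported.
    """
    credit = 0.0
    for c in calls:
        if c.test_id not in truth:
            raise KeyError(f"no truth label for test sample {c.test_id!r}")
        true_pop = truth[c.test_id]
        if c.tied:
            if true_pop in c.tied_with:
                credit += 1.0 / len(c.tied_with)
        elif c.call == true_pop:
            credit += 1.0
    n = len(calls)
    percent = round(100.0 * credit / n) if n else 0.0
    return credit, n, float(percent)


def cognate_average(sm: ScoreMatrix, truth: dict[str, str] | None = None) -> float:
    """Mean score of each test sample against its own population's references.

    ``sm`` must be population-averaged (one column per population).
    """
    truth = truth or sm.true_population_of
    if truth is None:
        raise ValueError("true populations required for cognate averaging")
    col = {r: j for j, r in enumerate(sm.ref_ids)}
    vals = [sm.scores[i, col[truth[t]]] for i, t in enumerate(sm.test_ids)]
    return float(np.mean(vals))


def noncognate_bidirectional_average(sm: ScoreMatrix, focus_population: str,
                                     truth: dict[str, str] | None = None) -> float:
    """Mean score over both directions of mismatch with one focus population.

    Union of cells: focus-population test samples vs every other reference
    column, plus every other population's test samples vs the focus
    reference column.  Quantifies how far the focus population sits from the
    rest of the panel.
    """
    truth = truth or sm.true_population_of
    if truth is None:
        raise ValueError("true populations required")
    if focus_population not in sm.ref_ids:
        raise ValueError(f"unknown population {focus_population!r}")
    col = {r: j for j, r in enumerate(sm.ref_ids)}
    vals: list[float] = []
    for i, t in enumerate(sm.test_ids):
        if truth[t] == focus_population:
            vals.extend(sm.scores[i, j] for r, j in col.items()
                        if r != focus_population)
        else:
            vals.append(sm.scores[i, col[focus_population]])
    if not vals:
        raise ValueError("no non-cognate cells (single-population matrix)")
    return float(np.mean(vals))
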