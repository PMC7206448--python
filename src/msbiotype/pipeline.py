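"""End-to-end orchestration: simulated or loaded study -> calls and statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .identify import (ReferencePanel, IdentificationCall, accuracy,
                       average_by_population, build_score_matrix,
                       calls_from_matrix, cognate_average,
                       noncognate_bidirectional_average)
from .io import PeakList, ScoreMatrix, Spectrum
from .preprocess import preprocess
from .simulate import SimulatedStudy
from .stats import (AnovaResult, TukeyResult, build_feature_matrix,
                    one_way_anova, run_pca, tukey_hsd)

__all__ = ["StudyResult", "run_study", "score_table_statistics"]


@dataclass
class StudyResult:
    replicate_scores: ScoreMatrix
    population_scores: ScoreMatrix
    calls: list[IdentificationCall]
    n_correct: float
    n_total: int
    percent: float
    test_peaklists: list[PeakList] = field(default_factory=list)
    reference_peaklists: dict[str, list[PeakList]] = field(default_factory=dict)


def run_study(study: SimulatedStudy, cfg: PipelineConfig = PipelineConfig()) -> StudyResult:
    """Preprocess every spectrum, score, average, call, and grade accuracy."""
    panel = ReferencePanel(refs={
        pop: [preprocess(s, cfg.preprocess) for s in specs]
        for pop, specs in study.reference_spectra.items()
    })
    tests = [preprocess(s, cfg.preprocess) for s in study.test_spectra]
    sm = build_score_matrix(tests, panel, cfg.scoring)
    avg = average_by_population(sm)
    calls = calls_from_matrix(sm, cfg.identify.tie_tol)
    n_correct, n_total, percent = accuracy(calls, study.truth)
    return StudyResult(
        replicate_scores=sm, population_scores=avg, calls=calls,
        n_correct=n_correct, n_total=n_total, percent=percent,
        test_peaklists=tests, reference_peaklists=panel.refs,
    )


def score_table_statistics(sm: ScoreMatrix, alpha: float = 0.05) -> dict:
    """ANOVA + Tukey per reference-population column of an averaged table.

    Observations are the per-test-sample averaged scores, grouped by the
    samples' true population.
    """
    if sm.true_population_of is None:
        raise ValueError("true populations required for score statistics")
    groups = [sm.true_population_of[t] for t in sm.test_ids]
    out: dict[str, dict] = {}
    for j, ref in enumerate(sm.ref_ids):
        col = sm.scores[:, j]
        anova: AnovaResult = one_way_anova(col, groups)
        tukey: TukeyResult = tukey_hsd(col, groups, alpha=alpha)
        out[ref] = {"anova": anova, "tukey": tukey}
    return out
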