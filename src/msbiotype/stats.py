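"""Downstream statistics: equal-weight PCA ordination, one-way ANOVA of
identification scores by population, and Tukey HSD with grouping letters.

PCA runs on a binned peak-intensity matrix, mean-centred but NOT
variance-scaled, so every peak enters with equal weight and no bin is
inflated merely for being quiet.  The ANOVA takes the per-test-sample
population-averaged scores as observations (24 samples, 4 populations in
the benchmark design, hence df = (3, 20)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import MASS_RANGE, PeakList

__all__ = [
    "FeatureMatrix",
    "PcaResult",
    "AnovaResult",
    "TukeyResult",
    "build_feature_matrix",
    "run_pca",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "plot_ordination",
]


@dataclass
class FeatureMatrix:
    """Samples x mass-bins matrix of normalized peak intensities (0 = absent)."""

    sample_ids: list[str]
    bin_centers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.bin_centers)):
            raise ValueError("values shape must be (n_samples, n_bins)")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("normalized intensities must lie in [0, 1]")


@dataclass
class PcaResult:
    scores: np.ndarray                       # samples x components
    loadings: np.ndarray                     # bins x components
    explained_variance_fraction: np.ndarray  # per component


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TukeyResult:
    """All-pairs studentized-range comparisons plus a compact letter display."""

    pairwise: dict[tuple[str, str], dict]
    letters: dict[str, str]
    alpha: float

    def significant(self, a: str, b: str) -> bool:
        key = (a, b) if (a, b) in self.pairwise else (b, a)
        return bool(self.pairwise[key]["significant"])


def build_feature_matrix(peaklists: list[PeakList], bin_width: float = 3.0,
                         mass_range: tuple[float, float] = MASS_RANGE) -> FeatureMatrix:
    """Assign peaks to fixed mass bins; bin value = max normalized intensity.

    Binning is the minimal peak-alignment scheme: peaks of different samples
    that fall in the same bin become the same feature.  All-zero columns are
    dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    for pl in peaklists:
        if not pl.normalized:
            raise ValueError("feature matrix requires normalized peak lists")
    lo, hi = mass_range
    n_bins = int(np.ceil((hi - lo) / bin_width))
    vals = np.zeros((len(peaklists), n_bins))
    for i, pl in enumerate(peaklists):
        for p in pl.peaks:
            b = min(int((p.mz - lo) // bin_width), n_bins - 1)
            if 0 <= b:
                vals[i, b] = max(vals[i, b], p.intensity)
    keep = vals.any(axis=0)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    return FeatureMatrix(
        sample_ids=[pl.sample_id for pl in peaklists],
        bin_centers=centers[keep],
        values=vals[:, keep],
    )


def run_pca(fm: FeatureMatrix, n_components: int = 2) -> PcaResult:
    """Unsupervised PCA on the mean-centred (unscaled) feature matrix.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making the ordination deterministic.
    """
    X = fm.values
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = _SkPCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # bins x components, orthonormal columns
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with df (k-1, n-k); p from the F
    distribution.  Degenerate zero within-group variance yields F = 0 when
    all group means coincide and F = inf otherwise.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    labels, inv = np.unique(g, return_inverse=True)
    k, n = len(labels), len(y)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 observations")
    grand = y.mean()
    means = np.array([y[inv == i].mean() for i in range(k)])
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(sum(np.sum((y[inv == i] - means[i]) ** 2) for i in range(k)))
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=float("inf"), df_between=df_b, df_within=df_w, p=0.0)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def compact_letter_display(groups: list[str],
                           significant: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are pairwise non-significant; every
    non-significant pair shares at least one letter.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for (a, b), sig in sorted(significant.items()):
        if not sig:
            continue
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            sa, sb = s - {b}, s - {a}
            for new in (sa, sb):
                if not any(new <= other for other in letter_sets):
                    letter_sets.append(new)
    # absorb: drop sets contained in others, then letter in a stable order
    letter_sets = [s for s in letter_sets
                   if not any(s < other for other in letter_sets)]
    letter_sets.sort(key=lambda s: sorted(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for li, s in enumerate(letter_sets):
        for g in sorted(s):
            out[g] += alphabet[li % len(alphabet)]
    return out


def plot_ordination(pca: PcaResult, labels, path) -> None:
    """Save a PC1-vs-PC2 scatter coloured by group label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    ev = pca.explained_variance_fraction
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in dict.fromkeys(labels.tolist()):
        sel = labels == lab
        ax.scatter(pca.scores[sel, 0], pca.scores[sel, 1], label=str(lab), s=30)
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)" if len(ev) > 1 else "PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tukey_hsd(values, groups, alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey HSD at ``alpha`` with grouping letters.

    Pairwise p-values come from the studentized range distribution; the
    letter display is derived from the significance map so that letters and
    pairwise calls can never disagree.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups).astype(str)
    res = pairwise_tukeyhsd(y, g, alpha=alpha)
    labels = [str(x) for x in res.groupsunique]
    pairwise: dict[tuple[str, str], dict] = {}
    sig: dict[tuple[str, str], bool] = {}
    idx = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            key = (labels[i], labels[j])
            pairwise[key] = {
                "difference": float(res.meandiffs[idx]),
                "p_adjusted": float(res.pvalues[idx]),
                "significant": bool(res.reject[idx]),
            }
            sig[key] = bool(res.reject[idx])
            idx += 1
    letters = compact_letter_display(labels, sig)
    return TukeyResult(pairwise=pairwise, letters=letters, alpha=alpha)
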