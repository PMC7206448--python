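"""Population-structured synthetic MALDI-TOF spectra.

Generates ground-truth peak templates for several populations with a
prescribed pairwise peak-sharing structure, then renders noisy replicate
profile spectra so the whole preprocessing / scoring / identification /
statistics chain can be exercised end-to-end with known truth.

The default study design mirrors a 4-population blind test: quadruplicate
reference samples and 6 blinded test samples per population (16 reference +
24 test spectra).  The default overlap structure makes populations 1 and 2
near-identical (90% shared peaks), population 3 intermediate (75% shared
with 1 and 2) and population 4 divergent (40% shared with everyone) —
i.e. two sister populations, one cousin and one outlier.

Each rendered spectrum draws, per retained template peak (peaks drop out
with a small probability), a Gaussian of fixed width at a mass jittered
proportionally to m/z and a log-normally perturbed intensity, then adds a
smooth exponential-decay chemical-noise baseline and white detector noise.
An optional intensity ceiling emulates detector saturation: peak tops are
clipped flat, distorting both centroids and relative peak heights.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .io import MASS_RANGE, Spectrum

__all__ = [
    "PopulationTemplate",
    "SimulationConfig",
    "SimulatedStudy",
    "make_templates",
    "simulate_spectrum",
    "apply_clipping",
    "simulate_study",
    "default_overlap_matrix",
]


class OverlapInfeasibleError(ValueError):
    """The requested pairwise-overlap structure admits no peak assignment."""


def default_overlap_matrix(n: int = 4) -> np.ndarray:
    """Two near-identical populations, one intermediate, one divergent.

    Pairwise shared-peak fractions: (P1,P2) = 0.9; P3 with P1/P2 = 0.75;
    P4 with everyone = 0.4.  For n != 4 the same graded pattern is
    truncated/extended sensibly.
    """
    o = np.full((n, n), 0.75)
    np.fill_diagonal(o, 1.0)
    if n >= 2:
        o[0, 1] = o[1, 0] = 0.9
    if n >= 4:
        o[3, :3] = o[:3, 3] = 0.4
    return o


@dataclass(frozen=True)
class PopulationTemplate:
    """Ground-truth peak set of one population: masses plus base intensities.

    ``peak_ids`` are global identifiers, shared across populations for
    shared peaks; ``shared_core_ids`` is the subset common to every
    population in the study.
    """

    population: str
    peak_masses: np.ndarray
    base_intensities: np.ndarray
    peak_ids: tuple[int, ...] = ()
    shared_core_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        m = np.asarray(self.peak_masses, dtype=float)
        if len(m) != len(self.base_intensities):
            raise ValueError("masses and intensities must have equal length")
        if len(m) >= 2 and not np.all(np.diff(m) > 0):
            raise ValueError("template masses must be strictly increasing")
        if np.any(m < MASS_RANGE[0]) or np.any(m > MASS_RANGE[1]):
            raise ValueError("template masses must lie within the mass window")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise magnitudes.

    Defaults emulate a well-behaved linear-mode acquisition: peak-rich
    spectra (80 template peaks, the regime in which panel identification is
    reliable; typical intact-protein peak lists run 60-100 peaks), ~300 ppm
    mass reproducibility, 25% biological+technical intensity CV, 10% peak
    dropout per replicate, a chemical-noise baseline at 5% and white noise
    at 0.5% of the strongest peak.  ``clip_ceiling`` (same arbitrary units
    as rendered intensities) is off by default; setting it emulates
    detector saturation.
    """

    n_populations: int = 4
    peaks_per_template: int = 80
    overlap_matrix: np.ndarray | None = None  # defaults to default_overlap_matrix
    n_reference_replicates: int = 4
    n_test_replicates: int = 6
    mass_jitter_ppm: float = 300.0
    intensity_cv: float = 0.25
    dropout_prob: float = 0.10
    baseline_amplitude: float = 0.05   # fraction of max peak amplitude
    noise_sd: float = 0.005            # fraction of max peak amplitude
    peak_sigma_da: float = 5.0
    clip_ceiling: float | None = None
    grid_step: float = 1.0
    seed: int = 0

    def overlaps(self) -> np.ndarray:
        o = (default_overlap_matrix(self.n_populations)
             if self.overlap_matrix is None else np.asarray(self.overlap_matrix, float))
        if o.shape != (self.n_populations, self.n_populations):
            raise ValueError("overlap matrix shape mismatch")
        if not np.allclose(o, o.T) or not np.allclose(np.diag(o), 1.0):
            raise ValueError("overlap matrix must be symmetric with unit diagonal")
        if o.min() < 0 or o.max() > 1:
            raise ValueError("overlap fractions must lie in [0, 1]")
        return o


@dataclass
class SimulatedStudy:
    templates: list[PopulationTemplate]
    reference_spectra: dict[str, list[Spectrum]]
    test_spectra: list[Spectrum]
    truth: dict[str, str]


# ---------------------------------------------------------------------------
# template construction


def _subset_counts(overlap: np.ndarray, n_peaks: int) -> dict[frozenset[int], int]:
    """Per-subset peak counts realizing the pairwise overlap targets.

    Peaks are typed by the subset S of populations carrying them; the
    pairwise constraints sum n_S over S containing both members of each
    pair, and each population's total must equal ``n_peaks``.  Solved as a
    linear program and rounded; infeasibility (e.g. triangle violations)
    raises :class:`OverlapInfeasibleError`.
    """
    k = overlap.shape[0]
    subsets = [frozenset(s) for r in range(1, k + 1)
               for s in itertools.combinations(range(k), r)]
    pairs = list(itertools.combinations(range(k), 2))
    n_var = len(subsets)
    A_eq, b_eq = [], []
    for i, j in pairs:
        A_eq.append([1.0 if (i in S and j in S) else 0.0 for S in subsets])
        b_eq.append(overlap[i, j] * n_peaks)
    for i in range(k):
        A_eq.append([1.0 if i in S else 0.0 for S in subsets])
        b_eq.append(float(n_peaks))
    # minimize total distinct peaks for a compact template pool
    c = np.ones(n_var)
    res = linprog(c, A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=[(0, None)] * n_var, method="highs")
    if not res.success:
        raise OverlapInfeasibleError(
            f"no peak assignment satisfies the overlap structure: {res.message}")
    counts = {S: int(round(x)) for S, x in zip(subsets, res.x) if round(x) > 0}
    # verify the rounding kept realized overlaps within the +-0.05 contract
    for i, j in pairs:
        got = sum(n for S, n in counts.items() if i in S and j in S) / n_peaks
        if abs(got - overlap[i, j]) > 0.05:
            raise OverlapInfeasibleError(
                f"rounded solution misses overlap target for pair {(i, j)}")
    for i in range(k):
        tot = sum(n for S, n in counts.items() if i in S)
        if abs(tot - n_peaks) > max(1, 0.05 * n_peaks):
            raise OverlapInfeasibleError(f"population {i} peak total off target")
    return counts


def make_templates(cfg: SimulationConfig) -> list[PopulationTemplate]:
    """Construct population templates realizing the pairwise overlap matrix.

    Every distinct peak gets a mass drawn uniformly in the interior of the
    window with a minimum 30 Da separation (well beyond the matching
    tolerance, so shared/unique status survives preprocessing) and a base
    intensity uniform in [0.1, 1]; shared peaks share both mass and base
    intensity across the populations carrying them.
    """
    overlap = cfg.overlaps()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    counts = _subset_counts(overlap, cfg.peaks_per_template)
    n_distinct = sum(counts.values())

    lo, hi = MASS_RANGE[0] + 200.0, MASS_RANGE[1] - 500.0
    min_gap = 30.0
    slack = (hi - lo) - (n_distinct - 1) * min_gap
    if slack <= 0:
        raise OverlapInfeasibleError(
            "too many distinct peaks for the mass window at minimum spacing")
    # uniform placement conditioned on the minimum gap: sorted uniforms in the
    # slack interval plus a fixed min_gap stride
    masses = lo + np.sort(rng.uniform(0.0, slack, size=n_distinct)) \
        + min_gap * np.arange(n_distinct)
    intensities = rng.uniform(0.1, 1.0, size=n_distinct)

    peak_ids = rng.permutation(n_distinct)  # decouple id order from mass order
    members: dict[int, frozenset[int]] = {}
    cursor = 0
    for S, n in sorted(counts.items(), key=lambda kv: sorted(kv[0])):
        for _ in range(n):
            members[int(peak_ids[cursor])] = S
            cursor += 1
    all_pops = frozenset(range(cfg.n_populations))
    core = frozenset(pid for pid, S in members.items() if S == all_pops)

    id_order = {int(pid): pos for pos, pid in enumerate(peak_ids)}
    templates = []
    for p in range(cfg.n_populations):
        ids = sorted((pid for pid, S in members.items() if p in S),
                     key=lambda pid: masses[id_order[pid]])
        templates.append(PopulationTemplate(
            population=f"pop{p + 1}",
            peak_masses=np.array([masses[id_order[i]] for i in ids]),
            base_intensities=np.array([intensities[id_order[i]] for i in ids]),
            peak_ids=tuple(ids),
            shared_core_ids=core,
        ))
    return templates


# ---------------------------------------------------------------------------
# spectrum rendering


def simulate_spectrum(t: PopulationTemplate, cfg: SimulationConfig,
                      replicate_seed: int, sample_id: str = "",
                      label_population: bool = True) -> Spectrum:
    """Render one noisy replicate profile spectrum of a template.

    Reproducible: the study seed, the template's population name and the
    replicate seed fully determine dropout, jitter, intensity perturbation,
    baseline and noise; replicate streams are independent across templates
    even at equal replicate seeds.
    """
    pop_tag = zlib.crc32(t.population.encode())
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1, pop_tag, replicate_seed]))
    lo, hi = MASS_RANGE
    grid = np.arange(lo, hi + cfg.grid_step / 2, cfg.grid_step)
    y = np.zeros_like(grid)

    keep = rng.random(len(t.peak_masses)) >= cfg.dropout_prob
    jitter = rng.normal(0.0, 1.0, len(t.peak_masses))
    sigma_ln = np.sqrt(np.log1p(cfg.intensity_cv ** 2))
    amp_noise = rng.lognormal(-0.5 * sigma_ln ** 2, sigma_ln, len(t.peak_masses))

    s = cfg.peak_sigma_da
    for m0, a0, k, j, an in zip(t.peak_masses, t.base_intensities,
                                keep, jitter, amp_noise):
        if not k:
            continue
        m = m0 * (1.0 + cfg.mass_jitter_ppm * 1e-6 * j)
        a = a0 * an
        w0 = np.searchsorted(grid, m - 6 * s)
        w1 = np.searchsorted(grid, m + 6 * s)
        y[w0:w1] += a * np.exp(-0.5 * ((grid[w0:w1] - m) / s) ** 2)

    top = y.max() if y.max() > 0 else 1.0
    tau = (hi - lo) / 4.0
    y += cfg.baseline_amplitude * top * np.exp(-(grid - lo) / tau)
    y += rng.normal(0.0, cfg.noise_sd * top, len(grid))
    y = np.maximum(y, 0.0)

    spec = Spectrum(grid, y, sample_id=sample_id or f"{t.population}_r{replicate_seed}",
                    population=t.population if label_population else None,
                    method_tag="synthetic")
    if cfg.clip_ceiling is not None:
        spec = apply_clipping(spec, cfg.clip_ceiling)
    return spec


def apply_clipping(s: Spectrum, ceiling: float) -> Spectrum:
    """Detector-saturation model: pointwise min with the ceiling (idempotent).

    Peaks taller than the ceiling come out flat-topped, which shifts
    centroids of grid-asymmetric peaks and compresses relative peak
    heights.
    """
    if ceiling <= 0:
        raise ValueError("clip ceiling must be positive")
    return s.replace(intensity=np.minimum(s.intensity, ceiling))


def median_peak_amplitude(study_or_templates, cfg: SimulationConfig) -> float:
    """Median rendered base amplitude across templates — the natural unit for
    choosing a clip ceiling."""
    templates = (study_or_templates.templates
                 if isinstance(study_or_templates, SimulatedStudy)
                 else study_or_templates)
    return float(np.median(np.concatenate(
        [t.base_intensities for t in templates])))


def simulate_study(cfg: SimulationConfig = SimulationConfig()) -> SimulatedStudy:
    """Full blinded study: reference replicates plus shuffled test samples.

    Test spectra carry no population label (blinding); the truth map is
    returned separately and only consulted at the accuracy step.
    """
    templates = make_templates(cfg)
    refs: dict[str, list[Spectrum]] = {}
    rep = 0
    for t in templates:
        refs[t.population] = []
        for r in range(cfg.n_reference_replicates):
            refs[t.population].append(simulate_spectrum(
                t, cfg, replicate_seed=rep,
                sample_id=f"{t.population}_ref{r + 1}"))
            rep += 1

    tests: list[Spectrum] = []
    truth: dict[str, str] = {}
    order = [(t, k) for t in templates for k in range(cfg.n_test_replicates)]
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    shuffle_rng.shuffle(order)
    for i, (t, _) in enumerate(order):
        sid = f"test{i + 1:02d}"
        spec = simulate_spectrum(t, cfg, replicate_seed=rep, sample_id=sid,
                                 label_population=False)
        rep += 1
        tests.append(spec)
        truth[sid] = t.population
    return SimulatedStudy(templates=templates, reference_spectra=refs,
                          test_spectra=tests, truth=truth)
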