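import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msbiotype.preprocess import preprocess
from msbiotype.scoring import (IdentificationBand, RelatednessBand,
                               ScoreComponents, ScoringConfig, composite_score,
                               interpret_score, match_peaks, score_components,
                               score_pair)
from msbiotype.simulate import SimulationConfig, make_templates, simulate_spectrum

from conftest import make_peaklist


def brute_force_match(ref_mz, test_mz, tol_ppm, tol_const):
    """Exhaustive optimum over all one-to-one matchings (lists <= 8 peaks):
    maximum cardinality, then minimum total |delta mz|."""
    feas = [(i, j) for i in range(len(ref_mz)) for j in range(len(test_mz))
            if abs(ref_mz[i] - test_mz[j]) <= tol_const + tol_ppm * 1e-6 * ref_mz[i]]
    best = (0, 0.0)
    for k in range(min(len(ref_mz), len(test_mz)), 0, -1):
        candidates = []
        for combo in itertools.combinations(feas, k):
            ri = [i for i, _ in combo]
            tj = [j for _, j in combo]
            if len(set(ri)) == k and len(set(tj)) == k:
                cost = sum(abs(ref_mz[i] - test_mz[j]) for i, j in combo)
                candidates.append(cost)
        if candidates:
            return k, min(candidates)
    return best


class TestMatchPeaks:
    def test_identical_lists_fully_paired(self):
        mzs = np.linspace(2500, 18000, 10)
        a = make_peaklist(mzs)
        m = match_peaks(a, a)
        assert len(m.pairs) == 10
        assert all(i == j for i, j in m.pairs)

    def test_out_of_tolerance_not_paired(self):
        ref = make_peaklist([5000.0])
        tol = 2.0 + 1200e-6 * 5000.0
        test = make_peaklist([5000.0 + 2 * tol])
        assert len(match_peaks(ref, test).pairs) == 0

    def test_nearest_partner_tie_break(self):
        # one test peak between two in-tolerance reference peaks: the
        # equally-distant pair resolves to the lower reference index
        ref = make_peaklist([4999.0, 5001.0])
        test = make_peaklist([5000.0])
        m = match_peaks(ref, test, tol_ppm=0.0, tol_const=2.0)
        assert m.pairs == ((0, 0),)

    def test_empty_lists_allowed(self):
        assert match_peaks(make_peaklist([]), make_peaklist([])).pairs == ()

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_brute_force_oracle_batches(self, trial):
        rng = np.random.default_rng(100 + trial)
        for _ in range(50):
            n, m = rng.integers(0, 9), rng.integers(0, 9)
            ref = np.sort(rng.uniform(2000, 20000, n))
            test = np.sort(rng.uniform(2000, 20000, m))
            # sprinkle near-collisions so matchings are nontrivial
            if n and m:
                k = rng.integers(0, min(n, m) + 1)
                test[:k] = np.sort(ref[rng.choice(n, k, replace=False)]
                                   + rng.normal(0, 5.0, k))
                test = np.sort(test)
            ref = ref[np.diff(ref, prepend=-np.inf) > 1e-6]
            test = test[np.diff(test, prepend=-np.inf) > 1e-6]
            got = match_peaks(make_peaklist(ref), make_peaklist(test),
                              tol_ppm=600.0, tol_const=2.0)
            cost = sum(abs(ref[i] - test[j]) for i, j in got.pairs)
            bk, bc = brute_force_match(ref, test, 600.0, 2.0)
            assert len(got.pairs) == bk
            assert cost == pytest.approx(bc, abs=1e-5)


class TestScoreComponents:
    def test_identical_lists_are_perfect(self):
        a = make_peaklist([3000.0, 5000.0], [1.0, 0.5], normalized=True)
        c = score_components(match_peaks(a, a), a, a)
        assert (c.v1, c.v2, c.v3) == (1.0, 1.0, 1.0)

    def test_disjoint_lists_are_zero(self):
        a = make_peaklist([3000.0], normalized=True)
        b = make_peaklist([9000.0], normalized=True)
        c = score_components(match_peaks(a, b), a, b)
        assert (c.v1, c.v2, c.v3) == (0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        ref = make_peaklist([5000.0, 6000.0], [1.0, 0.5], normalized=True)
        test = make_peaklist([5000.0, 6000.0, 7000.0], [1.0, 1.0, 0.2],
                             normalized=True)
        c = score_components(match_peaks(ref, test), ref, test)
        assert c.v1 == pytest.approx(1.0)
        assert c.v2 == pytest.approx(2 / 3)
        assert c.v3 == pytest.approx(0.75)

    def test_unnormalized_input_rejected(self):
        a = make_peaklist([3000.0], [2.0])
        with pytest.raises(ValueError):
            score_components(match_peaks(a, a), a, a)

    def test_geometric_mean_strategy(self):
        ref = make_peaklist([5000.0, 6000.0], [1.0, 0.5], normalized=True)
        test = make_peaklist([5000.0, 6000.0], [1.0, 1.0], normalized=True)
        c = score_components(match_peaks(ref, test), ref, test,
                             symmetry_strategy="geometric_mean_ratio")
        assert c.v3 == pytest.approx(math.sqrt(0.5))


class TestCompositeScore:
    @pytest.mark.parametrize("components,expected", [
        ((1.0, 1.0, 1.0), 3.0),
        ((0.1, 0.1, 0.1), 0.0),
        ((0.5, 0.5, 0.5), math.log10(125.0)),
    ])
    def test_closed_form_values(self, components, expected):
        assert composite_score(ScoreComponents(*components)) == \
            pytest.approx(expected, abs=1e-12)

    def test_floor_at_zero(self):
        assert composite_score(ScoreComponents(0.01, 0.01, 0.01)) == 0.0

    @given(st.tuples(*[st.floats(0, 1) for _ in range(3)]))
    @settings(derandomize=True, max_examples=200)
    def test_range_invariant(self, vs):
        assert 0.0 <= composite_score(ScoreComponents(*vs)) <= 3.0


class TestScorePair:
    def test_self_match_is_three(self):
        x = make_peaklist([2500.0, 7000.0, 15000.0], [0.3, 1.0, 0.7],
                          normalized=True)
        assert score_pair(x, x) == 3.0

    def test_disjoint_is_zero(self):
        a = make_peaklist([3000.0, 4000.0], normalized=True)
        b = make_peaklist([9000.0, 11000.0], normalized=True)
        assert score_pair(a, b) == 0.0

    def test_within_template_beats_cross_template(self):
        # low-noise acquisitions: a same-template replicate pair must always
        # outscore a pair drawn across the two near-identical templates
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, mass_jitter_ppm=100.0,
                                   intensity_cv=0.1, dropout_prob=0.02)
            tpls = make_templates(cfg)
            pls = [preprocess(simulate_spectrum(t, cfg, replicate_seed=r))
                   for t in tpls[:2] for r in range(2)]
            same = score_pair(pls[0], pls[1])
            cross = score_pair(pls[0], pls[2])
            assert same > cross

    def test_swap_symmetry_on_simulated_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n, m = rng.integers(1, 12), rng.integers(1, 12)
            a = np.sort(rng.uniform(2000, 20000, n))
            b = np.sort(rng.uniform(2000, 20000, m))
            a = a[np.diff(a, prepend=-np.inf) > 1.0]
            b = b[np.diff(b, prepend=-np.inf) > 1.0]
            ia, ib = rng.uniform(0.05, 1, len(a)), rng.uniform(0.05, 1, len(b))
            ia[rng.integers(len(a))] = 1.0
            ib[rng.integers(len(b))] = 1.0
            pa = make_peaklist(a, ia, normalized=True)
            pb = make_peaklist(b, ib, normalized=True)
            cfg = ScoringConfig(tol_ppm=0.0, tol_const=3.0)
            assert score_pair(pa, pb, cfg) == pytest.approx(
                score_pair(pb, pa, cfg), abs=1e-9)

    def test_removing_unmatched_test_peak_never_decreases_score(self):
        ref = make_peaklist([3000.0, 5000.0], [1.0, 0.8], normalized=True)
        test = make_peaklist([3000.0, 5000.0, 12000.0], [1.0, 0.8, 0.1],
                             normalized=True)
        trimmed = make_peaklist([3000.0, 5000.0], [1.0, 0.8], normalized=True)
        assert score_pair(ref, trimmed) >= score_pair(ref, test)

    def test_mass_noise_beyond_tolerance_kills_score(self):
        mzs = np.linspace(3000, 18000, 10)
        ref = make_peaklist(mzs, normalized=True)
        cfg = ScoringConfig(tol_ppm=0.0, tol_const=2.0)
        shifted = make_peaklist(mzs + 10.0, normalized=True)
        assert score_pair(ref, shifted, cfg) == 0.0


class TestInterpretation:
    @pytest.mark.parametrize("score,ident,rel", [
        (2.476, IdentificationBand.SPECIES_LEVEL, RelatednessBand.VERY_CLOSE),
        (1.768, IdentificationBand.GENUS_PROBABLE, RelatednessBand.MODERATE),
        (1.699, IdentificationBand.UNRELIABLE, RelatednessBand.LOW),
        (2.299, IdentificationBand.GENUS_SPECIES, RelatednessBand.CLOSE),
        (2.300, IdentificationBand.SPECIES_LEVEL, RelatednessBand.VERY_CLOSE),
        (3.0, IdentificationBand.SPECIES_LEVEL, RelatednessBand.VERY_CLOSE),
        (0.0, IdentificationBand.UNRELIABLE, RelatednessBand.LOW),
    ])
    def test_band_boundaries(self, score, ident, rel):
        out = interpret_score(score)
        assert out.identification is ident
        assert out.relatedness is rel

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_score(3.2)
        with pytest.raises(ValueError):
            interpret_score(-0.1)
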