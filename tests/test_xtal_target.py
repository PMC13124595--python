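import numpy as np
import pytest
from scipy.integrate import quad

from mlrefine.reciprocal import ReflectionSet
from mlrefine.structure_factors import ModelStructureFactors
from mlrefine.xtal_target import (
    SIGMA_A_MAX,
    SIGMA_A_MIN,
    SigmaABins,
    XtalTarget,
    _bin_llg_and_derivative,
    _refine_sigma_a_bin,
    conditional_density,
    llgi,
    llgi_terms,
    r_factors,
    refine_sigma_a,
)


def wilson_sample(n, sigma_a, rng, centric=False):
    """E_e drawn from the true conditional model given E_C, D_obs = 1."""
    if centric:
        ec = np.abs(rng.standard_normal(n))
        ee = np.abs(sigma_a * rng.choice([-1, 1], n) * ec
                    + np.sqrt(1 - sigma_a ** 2) * rng.standard_normal(n))
    else:
        zc = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
        noise = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
        ze = sigma_a * zc + np.sqrt(1 - sigma_a ** 2) * noise
        ec, ee = np.abs(zc), np.abs(ze)
    return ee, ec


class TestConditionalDensity:
    def test_zero_correlation_reduces_to_wilson_null(self):
        e = np.linspace(0.05, 3.0, 20)
        pa = conditional_density(e, 1.7, 0.0, np.zeros(20, bool))
        pc = conditional_density(e, 1.7, 0.0, np.ones(20, bool))
        assert np.allclose(pa, 2 * e * np.exp(-e ** 2), rtol=1e-12)
        assert np.allclose(pc, np.sqrt(2 / np.pi) * np.exp(-e ** 2 / 2),
                           rtol=1e-12)

    @pytest.mark.parametrize("centric", [False, True])
    @pytest.mark.parametrize("d", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("ec", [0.3, 1.0, 2.2])
    def test_normalizes_to_one(self, centric, d, ec):
        val, err = quad(
            lambda e: float(conditional_density(e, ec, d, np.asarray(centric))),
            0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_correlation_at_one_rejected(self):
        with pytest.raises(ValueError):
            conditional_density(1.0, 1.0, 1.0, np.asarray(False))

    def test_large_argument_stability(self):
        # would overflow a naive Bessel/cosh evaluation
        val = conditional_density(3.0, 3.0, 0.999, np.asarray(False),
                                  log=True)
        assert np.isfinite(val)


class TestLLGITerms:
    def test_zero_when_no_information(self):
        terms, _ = llgi_terms(np.array([0.4, 1.5]), np.array([1.0, 0.2]),
                              np.zeros(2), np.array([False, True]))
        assert np.allclose(terms, 0.0)

    def test_printed_worked_examples(self):
        # series-expansion I0 oracle gives 0.0240 / 0.0180 at
        # E_e = E_C = 1, d = 0.5
        acent, _ = llgi_terms(1.0, 1.0, 0.5, np.asarray(False))
        cent, _ = llgi_terms(1.0, 1.0, 0.5, np.asarray(True))
        assert acent == pytest.approx(0.0240, abs=5e-4)
        assert cent == pytest.approx(0.0180, abs=5e-4)

    def test_gradient_matches_finite_differences(self, rng):
        n = 100
        ee = rng.rayleigh(0.7, n)
        ec = rng.rayleigh(0.7, n)
        d = rng.uniform(0.05, 0.9, n)
        centric = rng.random(n) < 0.3
        _, grad = llgi_terms(ee, ec, d, centric)
        h = 1e-6
        tp, _ = llgi_terms(ee, ec + h, d, centric)
        tm, _ = llgi_terms(ee, ec - h, d, centric)
        fd = (tp - tm) / (2 * h)
        assert np.allclose(grad, fd, rtol=1e-5, atol=1e-9)


class TestSigmaARefinement:
    def test_recovers_planted_sigma_a(self):
        rng = np.random.default_rng(42)
        ee, ec = wilson_sample(2000, 0.7, rng)
        est, steps, grad = _refine_sigma_a_bin(ee, ec, np.ones(2000),
                                               np.zeros(2000, bool))
        assert est == pytest.approx(0.7, abs=0.03)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(9)
        for sigma_true in (0.3, 0.6, 0.9):
            ee, ec = wilson_sample(800, sigma_true, rng)
            est, _, _ = _refine_sigma_a_bin(ee, ec, np.ones(800),
                                            np.zeros(800, bool))
            grid = np.arange(SIGMA_A_MIN, SIGMA_A_MAX + 1e-9, 0.001)
            vals = [_bin_llg_and_derivative(ee, ec, np.ones(800),
                                            np.zeros(800, bool), g)[0]
                    for g in grid]
            assert abs(est - grid[int(np.argmax(vals))]) <= 0.002

    def test_independent_model_driven_to_bottom_of_range(self):
        # with E_C carrying no information the estimate collapses toward
        # the lower clamp (the likelihood is ~flat in sigma_A^2 near 0, so
        # the finite-sample MLE sits at O(n^-1/4), far below any signal)
        rng = np.random.default_rng(5)
        ee, _ = wilson_sample(2000, 0.0, rng)
        _, ec = wilson_sample(2000, 0.0, rng)
        est, _, _ = _refine_sigma_a_bin(ee, ec, np.ones(2000),
                                        np.zeros(2000, bool))
        assert est < 0.2

    def test_always_inside_clamp_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = 30
            ee = rng.rayleigh(0.7, n)
            ec = rng.rayleigh(0.7, n)
            est, _, _ = _refine_sigma_a_bin(
                ee, ec, rng.uniform(0.2, 1.0, n), rng.random(n) < 0.5,
                sigma0=rng.uniform(0.015, 0.99))
            assert SIGMA_A_MIN <= est <= SIGMA_A_MAX

    def test_binned_api_clamps_and_reports(self):
        rng = np.random.default_rng(3)
        n = 3000
        ee, ec = wilson_sample(n, 0.5, rng)
        hkl = np.stack([np.arange(1, n + 1), np.zeros(n, int),
                        np.zeros(n, int)], 1)
        refl = ReflectionSet(hkl=hkl, s=np.linspace(0.1, 0.4, n),
                             epsilon=np.ones(n), centric=np.zeros(n, bool))
        refl.bin_id = np.repeat(np.arange(3), n // 3)
        refl.E_e = ee
        refl.D_obs = np.ones(n)
        sf = ModelStructureFactors(F_c=ec.astype(complex))
        sf.E_C = ec
        bins = refine_sigma_a(refl, sf)
        assert bins.sigma_a.shape == (3,)
        assert np.all((bins.sigma_a >= SIGMA_A_MIN)
                      & (bins.sigma_a <= SIGMA_A_MAX))
        assert np.allclose(bins.sigma_a, 0.5, atol=0.1)


class TestLLGI:
    def _refl_sf(self, n=200, d=0.5, seed=0):
        rng = np.random.default_rng(seed)
        ee, ec = wilson_sample(n, d, rng)
        hkl = np.stack([np.arange(1, n + 1), np.zeros(n, int),
                        np.zeros(n, int)], 1)
        refl = ReflectionSet(hkl=hkl, s=np.linspace(0.1, 0.4, n),
                             epsilon=np.ones(n), centric=np.zeros(n, bool))
        refl.bin_id = np.zeros(n, int)
        refl.E_e = ee
        refl.D_obs = np.ones(n)
        sf = ModelStructureFactors(F_c=ec.astype(complex))
        sf.E_C = ec
        return refl, sf

    def test_zero_when_sigma_a_times_dobs_vanishes(self):
        refl, sf = self._refl_sf()
        refl.D_obs = np.zeros(len(refl))
        sig = SigmaABins(bin_s_centers=np.array([0.2]),
                         sigma_a=np.array([0.5]))
        value, grad = llgi(refl, sf, sig)
        assert value == 0.0
        assert np.allclose(grad, 0.0)

    def test_better_model_scores_higher(self):
        """LLGI prefers E_C closer to the generating truth (monotone
        improvement over 20 replicates)."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 400
            ee, ec = wilson_sample(n, 0.6, rng)
            refl, sf = self._refl_sf(n, 0.6, seed)
            refl.E_e = ee
            sig = SigmaABins(bin_s_centers=np.array([0.2]),
                             sigma_a=np.array([0.6]))
            sf.E_C = ec
            good, _ = llgi(refl, sf, sig)
            sf.E_C = np.abs(rng.standard_normal(n)
                            + 1j * rng.standard_normal(n)) / np.sqrt(2)
            bad, _ = llgi(refl, sf, sig)
            wins += good > bad
        assert wins >= 18

    def test_free_reflections_excluded(self):
        refl, sf = self._refl_sf()
        sig = SigmaABins(bin_s_centers=np.array([0.2]),
                         sigma_a=np.array([0.5]))
        full, _ = llgi(refl, sf, sig)
        refl.free_flag = np.zeros(len(refl), bool)
        refl.free_flag[:50] = True
        part, grad = llgi(refl, sf, sig)
        assert part != full
        assert np.allclose(grad[:50], 0.0)


class TestRFactors:
    def test_identity_gives_zero(self):
        f = np.array([1.0, 2, 3, 4, 5])
        rw, rf = r_factors(f, f, np.array([0, 0, 0, 1, 1], bool))
        assert rw == pytest.approx(0.0, abs=1e-12)
        assert rf == pytest.approx(0.0, abs=1e-12)

    def test_scale_absorbed(self):
        f = np.array([1.0, 2, 3, 4, 5])
        rw, _ = r_factors(2 * f, f, np.zeros(5, bool))
        assert rw == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy_table(self):
        fo = np.array([10.0, 8.0, 6.0, 4.0, 2.0])
        fc = np.array([9.0, 8.5, 5.0, 4.5, 2.5])
        free = np.array([0, 0, 0, 0, 1], bool)
        k = np.sum(fo[:4] * fc[:4]) / np.sum(fc[:4] ** 2)
        exp_work = np.sum(np.abs(fo[:4] - k * fc[:4])) / np.sum(fo[:4])
        exp_free = abs(fo[4] - k * fc[4]) / fo[4]
        rw, rf = r_factors(fo, fc, free)
        assert rw == pytest.approx(exp_work, rel=1e-12)
        assert rf == pytest.approx(exp_free, rel=1e-12)

    def test_empty_free_set_warns(self):
        f = np.array([1.0, 2, 3])
        with pytest.warns(UserWarning):
            _, rf = r_factors(f, f, np.zeros(3, bool))
        assert np.isnan(rf)


class TestXtalTargetGradients:
    def test_coordinate_and_b_gradients_match_fd(self, xtal_system):
        sys = xtal_system
        b = sys["b"]
        target = XtalTarget(sys["refl"], sys["cell"], b.elements,
                            b.occupancy)
        target.llg(b.xyz, b.b_iso)        # prime sigma_A
        target.refit_sigma_a = False
        _, gx, gb = target.loss_and_gradients(b.xyz, b.b_iso)
        h = 1e-5
        rng = np.random.default_rng(0)
        for _ in range(4):
            j = rng.integers(0, b.n_atoms)
            d = rng.integers(0, 3)
            xp, xm = b.xyz.copy(), b.xyz.copy()
            xp[j, d] += h
            xm[j, d] -= h
            fd = (target.llg(xp, b.b_iso) - target.llg(xm, b.b_iso)) / (2 * h)
            assert gx[j, d] == pytest.approx(fd, rel=1e-4)
        j = int(rng.integers(0, b.n_atoms))
        bp, bm = b.b_iso.copy(), b.b_iso.copy()
        bp[j] += h
        bm[j] -= h
        fd = (target.llg(b.xyz, bp) - target.llg(b.xyz, bm)) / (2 * h)
        assert gb[j] == pytest.approx(fd, rel=1e-4)

    def test_truth_model_beats_alternate_state(self, xtal_system):
        sys = xtal_system
        target = XtalTarget(sys["refl"], sys["cell"], sys["b"].elements,
                            sys["b"].occupancy)
        llg_truth = target.llg(sys["b"].xyz, sys["b"].b_iso)
        llg_other = target.llg(sys["a"].xyz, sys["a"].b_iso)
        assert llg_truth > llg_other

    def test_resolution_window_reduces_terms(self, xtal_system):
        sys = xtal_system
        target = XtalTarget(sys["refl"], sys["cell"], sys["b"].elements,
                            sys["b"].occupancy, d_min=3.0)
        full = XtalTarget(sys["refl"], sys["cell"], sys["b"].elements,
                          sys["b"].occupancy)
        assert target.res_mask.sum() < full.res_mask.sum()
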