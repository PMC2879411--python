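"""Elongation rate law, capping/sequestration curves, mechanism calls, exchange."""

import numpy as np
import pytest

from actinkit.equilibria import OneToOneSystem, complex_concentration
from actinkit.fitting import FitError
from actinkit.kinetics import (
    CappingModel,
    ElongationAssay,
    ExchangeModel,
    RateTitration,
    SequestrationModel,
    capping_curve,
    capping_curve_hyperbolic,
    discriminate_mechanism,
    elongation_rate,
    exchange_kobs,
    exchange_trace,
    fit_exchange_trace,
    fit_kcap,
    fit_kseq,
    ic50,
    seeds_from_rate,
    sequestration_curve,
)
import actinkit.simulate as sim


class TestElongationRateLaw:
    def test_zero_at_critical_concentration(self):
        assay = ElongationAssay(end="barbed", seeds0=2.0, A0=2.0)
        assert elongation_rate(assay, assay.Cc) == 0.0
        assert elongation_rate(assay, assay.Cc - 0.05) == 0.0

    def test_worked_rate_value(self):
        # 2 nM seeds, k+ = 10 /µM/s, 2 µM free actin, Cc = 0.1 µM -> 38 nM/s
        assay = ElongationAssay(end="barbed", seeds0=2.0, A0=2.0, Cc=0.1, kplus=10.0)
        assert elongation_rate(assay, 2.0) == pytest.approx(38.0)

    def test_linear_in_seed_concentration(self):
        a1 = ElongationAssay(end="barbed", seeds0=2.0, A0=2.0)
        a2 = ElongationAssay(end="barbed", seeds0=4.0, A0=2.0)
        assert elongation_rate(a2, 2.0) == pytest.approx(2 * elongation_rate(a1, 2.0))

    def test_seeds_from_rate_inverts_rate_law(self):
        assert seeds_from_rate(38.0, 2.0, 0.1, 10.0) == pytest.approx(2.0)
        assert seeds_from_rate(0.0, 2.0, 0.1) == 0.0
        rng = np.random.default_rng(3)
        for _ in range(50):
            seeds = 10 ** rng.uniform(-1, 2)
            C, Cc = rng.uniform(1, 5), rng.uniform(0.0, 0.6)
            assay = ElongationAssay(end="barbed", seeds0=seeds, A0=C + 1, Cc=Cc)
            V = elongation_rate(assay, C)
            assert seeds_from_rate(V, C, Cc, assay.kplus) == pytest.approx(seeds, rel=1e-12)

    def test_inversion_requires_supercritical_actin(self):
        with pytest.raises(ValueError):
            seeds_from_rate(10.0, 0.1, 0.1)


class TestCappingCurve:
    def test_control_is_full_rate(self):
        assert capping_curve(CappingModel(Kcap=15.0, ends0=2.0), [0.0])[0] == 100.0

    def test_hyperbolic_half_point_when_ends_dilute(self):
        # ends0 << Kcap: 50% at capper = Kcap
        val = capping_curve(CappingModel(Kcap=15.0, ends0=1e-6), [15.0])[0]
        assert val == pytest.approx(50.0, rel=1e-4)

    def test_depletion_value_matches_quadratic_oracle(self):
        ends0, kcap, x = 2.0, 15.0, 15.0
        c = complex_concentration(OneToOneSystem(ends0, x, kcap))
        expected = 100.0 * (ends0 - c) / ends0
        got = capping_curve(CappingModel(Kcap=kcap, ends0=ends0), [x])[0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(51.66, abs=0.01)

    def test_monotone_non_increasing_and_A0_invariant(self):
        grid = np.linspace(0, 200, 30)
        curve = capping_curve(CappingModel(Kcap=15.0, ends0=2.0), grid)
        assert np.all(np.diff(curve) <= 1e-12)
        # capping does not see the G-actin pool at all: same ends -> same curve
        assert np.allclose(curve, capping_curve(CappingModel(Kcap=15.0, ends0=2.0), grid))


class TestSequestrationCurve:
    def test_control_and_tight_binding_endpoint(self):
        assay = ElongationAssay(end="pointed", A0=2.0, Cc=0.6)
        model_tight = SequestrationModel(Kseq=1e-9)
        assert sequestration_curve(model_tight, assay, [0.0])[0] == 100.0
        # stoichiometric endpoint: S0 = A0 - Cc exhausts polymerizable actin
        end = sequestration_curve(model_tight, assay, [2.0 - 0.6])[0]
        assert end == pytest.approx(0.0, abs=1e-3)

    def test_worked_value_with_depletion(self):
        assay = ElongationAssay(end="pointed", A0=2.0, Cc=0.6)
        got = sequestration_curve(SequestrationModel(Kseq=2.5), assay, [2.0])[0]
        c = complex_concentration(OneToOneSystem(2.0, 2.0, 2.5))
        expected = 100.0 * (2.0 - c - 0.6) / 1.4
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(51.0, abs=0.5)

    def test_ic50_shifts_right_with_total_actin(self):
        model = SequestrationModel(Kseq=3.0)
        grid = np.linspace(0, 12, 200)
        lo = sequestration_curve(model, ElongationAssay(end="barbed", A0=2.0), grid)
        hi = sequestration_curve(model, ElongationAssay(end="barbed", A0=4.0), grid)
        assert ic50(grid, hi) > ic50(grid, lo)


class TestIC50:
    def test_hyperbolic_limit_returns_kcap(self):
        grid = np.linspace(0, 100, 2001)
        curve = capping_curve_hyperbolic(CappingModel(Kcap=15.0, ends0=0.0), grid)
        assert ic50(grid, curve) == pytest.approx(15.0, rel=1e-3)

    def test_tight_sequestration_half_point(self):
        # Kseq -> 0: rate hits 50% at S0 = (A0 - Cc)/2
        assay = ElongationAssay(end="pointed", A0=2.0, Cc=0.6)
        grid = np.linspace(0, 2, 4001)
        curve = sequestration_curve(SequestrationModel(Kseq=1e-9), assay, grid)
        assert ic50(grid, curve) == pytest.approx((2.0 - 0.6) / 2, rel=1e-3)

    def test_requires_crossing(self):
        with pytest.raises(ValueError):
            ic50([0, 1, 2], [100, 90, 80])


class TestFitters:
    def test_noiseless_kcap_roundtrip(self):
        data = sim.gen_rate_titration("capping", K=15.0, grid=np.linspace(0, 150, 12),
                                      noise=0.0, seed=0)[0]
        fit = fit_kcap(data, n_boot=0)
        assert fit.params["Kcap"] == pytest.approx(15.0, rel=1e-6)

    def test_noiseless_kseq_roundtrip(self):
        data = sim.gen_rate_titration("sequestration", K=2.5, noise=0.0, seed=0)[0]
        fit = fit_kseq(data, n_boot=0)
        assert fit.params["Kseq"] == pytest.approx(2.5, rel=1e-6)

    def test_flat_curve_raises_identifiability_error(self):
        assay = ElongationAssay(end="barbed")
        flat = RateTitration(np.linspace(0, 100, 8), np.full(8, 100.0), assay,
                             ligand_unit="nM")
        with pytest.raises(FitError):
            fit_kcap(flat, n_boot=0)

    def test_too_few_points_rejected(self):
        assay = ElongationAssay(end="barbed")
        data = RateTitration(np.array([0.0, 10.0, 30.0]), np.array([100.0, 60.0, 30.0]),
                             assay, ligand_unit="nM")
        with pytest.raises(FitError):
            fit_kcap(data, n_boot=0)

    def test_weak_sequestration_gives_wide_interval(self):
        # Kseq far above the sampled range leaves only a shallow, nearly
        # linear decline: at fixed absolute noise the interval blows up
        # relative to a well-determined titration
        rng = np.random.default_rng(5)
        assay = ElongationAssay(end="pointed", A0=2.0)
        grid = np.linspace(0, 4, 12)

        def fit_with_noise(kseq):
            clean = sequestration_curve(SequestrationModel(Kseq=kseq), assay, grid)
            rates = np.clip(clean + rng.normal(0, 2.0, size=grid.size), 0, None)
            rates[0] = 100.0
            data = RateTitration(grid, rates, assay, ligand_unit="uM")
            return fit_kseq(data, seed=5, n_boot=200)

        weak = fit_with_noise(50.0)
        strong = fit_with_noise(2.5)
        rel_width = lambda f, name: (f.ci[name][1] - f.ci[name][0]) / f.params[name]
        assert rel_width(weak, "Kseq") > 3 * rel_width(strong, "Kseq")


class TestDiscrimination:
    @staticmethod
    def make_pair(mechanism, K, seed):
        a_low = ElongationAssay(end="barbed", A0=2.0, seeds0=2.0)
        a_high = ElongationAssay(end="barbed", A0=4.0, seeds0=2.0)
        grid = np.linspace(0, 500, 12) if mechanism == "capping" else np.linspace(0, 8, 12)
        low = sim.gen_rate_titration(mechanism, K=K, assay=a_low, grid=grid,
                                     noise=0.02, seed=seed)[0]
        high = sim.gen_rate_titration(mechanism, K=K, assay=a_high, grid=grid,
                                      noise=0.02, seed=seed + 1)[0]
        return low, high

    def test_sequestration_pair_classified_by_rightward_shift(self):
        out = discriminate_mechanism(self.make_pair("sequestration", 3.0, 100))
        assert out["classification"] == "sequestration"
        assert out["ic50_shift_ratio"] > 1.2

    def test_capping_pair_classified_invariant_to_actin(self):
        out = discriminate_mechanism(self.make_pair("capping", 50.0, 200))
        assert out["classification"] == "capping"
        assert out["ic50_shift_ratio"] == pytest.approx(1.0, abs=0.3)

    def test_single_actin_concentration_rejected(self):
        a = ElongationAssay(end="barbed", A0=2.0)
        d = sim.gen_rate_titration("capping", K=50.0, assay=a,
                                   grid=np.linspace(0, 500, 12), noise=0.0, seed=0)[0]
        with pytest.raises(ValueError):
            discriminate_mechanism((d, d))


class TestExchange:
    def test_endpoints_of_kobs_titration(self):
        model = ExchangeModel(k_free=0.05, k_bound=0.01, Kd=0.5, A0=2.0)
        assert exchange_kobs(model, 0.0) == pytest.approx(0.05)
        assert exchange_kobs(model, 1e5) == pytest.approx(0.01, rel=1e-3)

    def test_fivefold_inhibition_at_saturation(self):
        model = ExchangeModel(k_free=0.05, k_bound=0.01, Kd=0.5, A0=2.0)
        assert exchange_kobs(model, 0.0) / exchange_kobs(model, 1e6) == pytest.approx(
            5.0, rel=1e-3
        )

    def test_kobs_monotone_between_limits(self):
        model = ExchangeModel(k_free=0.05, k_bound=0.01, Kd=0.5, A0=2.0)
        grid = np.geomspace(0.01, 100, 40)
        k = [exchange_kobs(model, x) for x in grid]
        assert np.all(np.diff(k) <= 1e-15)
        assert all(0.01 <= v <= 0.05 for v in k)

    def test_trace_shape_and_half_rise(self):
        t = np.linspace(0, 200, 400)
        y = exchange_trace(0.03, 1.0, t)
        assert y[0] == 0.0
        assert y[-1] == pytest.approx(1.0, abs=5e-3)
        t_half = np.log(2) / 0.03
        assert np.interp(t_half, t, y) == pytest.approx(0.5, abs=1e-3)

    def test_trace_fit_recovers_kobs(self):
        t = np.linspace(0, 150, 80)
        y = exchange_trace(0.04, 2.5, t)
        fit = fit_exchange_trace(t, y)
        assert fit.params["k_obs"] == pytest.approx(0.04, rel=1e-8)
        assert fit.params["amplitude"] == pytest.approx(2.5, rel=1e-8)
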