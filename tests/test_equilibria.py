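"""Binding-equilibrium solvers versus brute-force bisection oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from actinkit.equilibria import (
    CompetitionSystem,
    FluorescenceMap,
    OneToOneSystem,
    TwoSiteSystem,
    apparent_kd,
    competition_report,
    competition_solve,
    competitor_kd_from_apparent,
    complex_concentration,
    occupancy,
    predicted_signal,
    two_site_signal,
)


def bisect_complex(A0, L0, Kd):
    """Independent oracle: bisection on (A0-C)(L0-C) - Kd*C = 0."""
    if A0 == 0 or L0 == 0:
        return 0.0
    f = lambda c: (A0 - c) * (L0 - c) - Kd * c
    return brentq(f, 0.0, min(A0, L0), xtol=1e-16, rtol=8.9e-16, maxiter=200)


class TestComplexConcentration:
    def test_no_ligand_gives_no_complex(self):
        assert complex_concentration(OneToOneSystem(1.5, 0.0, 0.05)) == 0.0

    def test_tight_binding_stoichiometric_limit(self):
        c = complex_concentration(OneToOneSystem(1.5, 1.0, 1e-12))
        assert c == pytest.approx(1.0, rel=1e-6)

    def test_depletion_quadratic_worked_value(self):
        # equimolar 1.5 µM at Kd = 0.05 µM; frozen from the bisection oracle
        c = complex_concentration(OneToOneSystem(1.5, 1.5, 0.05))
        assert c == pytest.approx(1.25, rel=1e-12)
        assert c == pytest.approx(bisect_complex(1.5, 1.5, 0.05), rel=1e-12)

    def test_agrees_with_bisection_on_random_systems(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            A0 = 10 ** rng.uniform(-3, 2)
            L0 = 10 ** rng.uniform(-3, 2)
            Kd = 10 ** rng.uniform(-4, 2)
            c = complex_concentration(OneToOneSystem(A0, L0, Kd))
            assert c == pytest.approx(bisect_complex(A0, L0, Kd), rel=1e-10, abs=1e-15)
            assert 0.0 <= c <= min(A0, L0)

    @given(
        A0=st.floats(1e-3, 100.0),
        L0=st.floats(1e-3, 100.0),
        Kd=st.floats(1e-4, 100.0),
        dL=st.floats(1e-3, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_ligand_and_kd(self, A0, L0, Kd, dL):
        c0 = complex_concentration(OneToOneSystem(A0, L0, Kd))
        assert complex_concentration(OneToOneSystem(A0, L0 + dL, Kd)) >= c0 - 1e-12
        assert complex_concentration(OneToOneSystem(A0, L0, Kd * 2)) <= c0 + 1e-12

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            OneToOneSystem(-1.0, 1.0, 0.05)
        with pytest.raises(ValueError):
            OneToOneSystem(1.0, np.nan, 0.05)
        with pytest.raises(ValueError):
            OneToOneSystem(1.0, 1.0, 0.0)


class TestPredictedSignal:
    def test_baseline_and_saturation_bounds(self):
        fmap = FluorescenceMap(F0=100.0, dF=20.0)
        assert predicted_signal(OneToOneSystem(1.5, 0.0, 0.05), fmap) == 100.0
        sat = predicted_signal(OneToOneSystem(1.5, 1e5, 0.05), fmap)
        assert sat == pytest.approx(120.0, rel=1e-3)

    def test_mid_titration_from_complex_concentration(self):
        fmap = FluorescenceMap(F0=100.0, dF=20.0)
        expected = 100.0 + 20.0 * (1.25 / 1.5)
        got = predicted_signal(OneToOneSystem(1.5, 1.5, 0.05), fmap)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_zero_receptor_rejected(self):
        with pytest.raises(ValueError):
            predicted_signal(OneToOneSystem(0.0, 1.0, 0.05), FluorescenceMap())


class TestCompetitionSolve:
    def bisect_oracle(self, A0, E0, K_E, T0, K_T):
        f = lambda a: a + a * E0 / (K_E + a) + a * T0 / (K_T + a) - A0
        lo, hi = 0.0, A0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    def test_degenerate_reduces_to_one_to_one(self):
        sp = competition_solve(CompetitionSystem(1.5, 15.0, 7.5, 0.0, 3.0))
        assert sp["AT"] == 0.0
        assert sp["AE"] == pytest.approx(
            complex_concentration(OneToOneSystem(1.5, 15.0, 7.5)), rel=1e-9
        )
        sp = competition_solve(CompetitionSystem(1.5, 0.0, 7.5, 25.0, 3.0))
        assert sp["AE"] == 0.0
        assert sp["AT"] == pytest.approx(
            complex_concentration(OneToOneSystem(1.5, 25.0, 3.0)), rel=1e-9
        )

    def test_matches_bisection_oracle(self):
        a = self.bisect_oracle(1.5, 15.0, 7.5, 25.0, 3.0)
        sp = competition_solve(CompetitionSystem(1.5, 15.0, 7.5, 25.0, 3.0))
        assert sp["free_actin"] == pytest.approx(a, rel=1e-9)

    def test_conservation_on_random_systems(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            A0 = 10 ** rng.uniform(-2, 1.5)
            E0 = 10 ** rng.uniform(-2, 2)
            T0 = 10 ** rng.uniform(-2, 2)
            K_E = 10 ** rng.uniform(-2, 2)
            K_T = 10 ** rng.uniform(-2, 2)
            sp = competition_solve(CompetitionSystem(A0, E0, K_E, T0, K_T))
            scale = max(A0, E0, T0)
            assert abs(sp["free_actin"] + sp["AE"] + sp["AT"] - A0) < 1e-9 * scale
            assert abs(sp["free_E"] + sp["AE"] - E0) < 1e-9 * scale
            assert abs(sp["free_T"] + sp["AT"] - T0) < 1e-9 * scale
            oracle = self.bisect_oracle(A0, E0, K_E, T0, K_T)
            assert sp["free_actin"] == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_more_competitor_never_raises_rival_complex(self):
        base = competition_solve(CompetitionSystem(1.5, 15.0, 7.5, 25.0, 3.0))
        more = competition_solve(CompetitionSystem(1.5, 30.0, 7.5, 25.0, 3.0))
        assert more["AT"] <= base["AT"]


class TestApparentKd:
    def test_no_competitor_is_identity(self):
        assert apparent_kd(3.0, 0.0, 7.5) == 3.0

    def test_forward_values(self):
        assert apparent_kd(3.0, 15.0, 7.5) == pytest.approx(9.0)
        assert apparent_kd(3.0, 30.0, 7.5) == pytest.approx(15.0)

    def test_inversion_of_measured_pair(self):
        # K_T0 = 3 µM and K_app = 9 µM at E0 = 15 µM imply K_E = 7.5 µM
        assert competitor_kd_from_apparent(3.0, 9.0, 15.0) == pytest.approx(7.5)

    def test_report_flags_inconsistent_claimed_value(self):
        report = competition_report(3.0, [(15.0, 9.0), (30.0, 14.0)], claimed_K_E=3.0)
        assert report["pairs"][0]["K_E"] == pytest.approx(7.5)
        assert report["pairs"][1]["K_E"] == pytest.approx(30.0 / (14.0 / 3.0 - 1.0))
        assert not report["claimed_K_E_consistent"]
        consistent = competition_report(3.0, [(15.0, 9.0)], claimed_K_E=7.5)
        assert consistent["claimed_K_E_consistent"]

    def test_linear_approximation_matches_exact_when_actin_dilute(self):
        """IC50-style apparent Kd from the exact ternary solve in A0 << K regime."""
        A0, E0, K_E, K_T = 0.01, 15.0, 7.5, 3.0
        sat = complex_concentration(OneToOneSystem(A0, 1e6, K_T)) / A0

        def half_occupancy_T0():
            def f(T0):
                sp = competition_solve(CompetitionSystem(A0, E0, K_E, T0, K_T))
                return sp["AT"] / A0 - 0.5 * sat

            return brentq(f, 1e-6, 1e4)

        assert half_occupancy_T0() == pytest.approx(apparent_kd(K_T, E0, K_E), rel=0.10)


class TestTwoSiteSignal:
    def test_baseline_and_additive_saturation(self):
        sys0 = TwoSiteSystem(1.5, 0.0, 0.05, 0.0, 3.0, dF1=17.0, dF2=12.0)
        assert two_site_signal(sys0, F0=100.0) == 100.0
        sat = TwoSiteSystem(1.5, 1e6, 0.05, 1e6, 3.0, dF1=17.0, dF2=12.0)
        assert two_site_signal(sat, F0=100.0) == pytest.approx(129.0, rel=1e-4)

    def test_mid_range_composes_independent_one_to_one_solves(self):
        sys = TwoSiteSystem(1.5, 1.0, 0.05, 5.0, 3.0, dF1=17.0, dF2=12.0)
        th1 = occupancy(OneToOneSystem(1.5, 1.0, 0.05))
        th2 = occupancy(OneToOneSystem(1.5, 5.0, 3.0))
        assert two_site_signal(sys, F0=100.0) == pytest.approx(
            100.0 + 17.0 * th1 + 12.0 * th2, rel=1e-12
        )
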