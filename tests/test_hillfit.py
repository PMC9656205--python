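import numpy as np
import pytest
from hypothesis import given, strategies as st

from synercomb import (
    HillCurve,
    MuSyCSurface,
    absolute_ic50,
    curve_shift,
    fit_hill,
    hill_predict,
)
from synercomb.hillfit import DegenerateFitError
from synercomb.synthgen import SynthConfig, generate_matrix

MTS_GRID = np.array([0.0, 12.5, 25.0, 50.0, 100.0, 200.0])


class TestHillPredict:
    def test_zero_dose_returns_lower_asymptote(self, kill_curve):
        assert hill_predict(kill_curve, 0.0) == kill_curve.E0

    def test_midpoint_identity_at_ec50(self, kill_curve):
        assert hill_predict(kill_curve, kill_curve.C) == pytest.approx(
            (kill_curve.E0 + kill_curve.Emax) / 2
        )

    def test_negative_dose_rejected(self, kill_curve):
        with pytest.raises(ValueError):
            hill_predict(kill_curve, -1.0)

    @given(st.floats(min_value=0.0, max_value=1e4))
    def test_bounded_by_asymptotes(self, dose):
        curve = HillCurve(E0=0.0, Emax=80.0, C=10.0, h=1.3)
        y = hill_predict(curve, dose)
        assert 0.0 <= y <= 80.0

    def test_monotone_in_dose(self, kill_curve):
        doses = np.logspace(-2, 4, 100)
        y = hill_predict(kill_curve, doses)
        assert np.all(np.diff(y) >= 0)
        falling = HillCurve(E0=100.0, Emax=0.0, C=10.0, h=2.0)
        assert np.all(np.diff(hill_predict(falling, doses)) <= 0)


class TestFitHill:
    def test_noise_free_recovery_on_mts_grid(self):
        truth = HillCurve(E0=100.0, Emax=0.0, C=65.7, h=1.5)
        y = hill_predict(truth, MTS_GRID)
        fit = fit_hill(MTS_GRID, y)
        for name in ("E0", "C", "h"):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name), rel=1e-6)
        assert fit.Emax == pytest.approx(0.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_refit_reproduces_training_points(self, plateau_curve):
        doses = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 4.0])
        y = hill_predict(plateau_curve, doses)
        fit = fit_hill(doses, y)
        np.testing.assert_allclose(hill_predict(fit, doses), y, atol=1e-8)

    def test_flat_response_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_hill([0, 1, 2, 4, 8], [50.0] * 5)

    def test_resistant_plateau_read_from_emax(self):
        truth = HillCurve(E0=0.0, Emax=80.0, C=1.0, h=1.0)
        doses = np.array([0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 100.0])
        fit = fit_hill(doses, hill_predict(truth, doses))
        assert fit.resistant_fraction == pytest.approx(20.0, abs=1e-4)

    def test_r_squared_decreases_with_noise(self):
        truth = HillCurve(E0=0.0, Emax=100.0, C=10.0, h=1.0)
        doses = np.logspace(-1, 3, 12)
        rng = np.random.default_rng(7)
        r2 = []
        for sd in (0.0, 2.0, 10.0):
            noisy = hill_predict(truth, doses) + rng.normal(0, sd, doses.size)
            r2.append(fit_hill(doses, noisy).r_squared)
        assert r2[0] == pytest.approx(1.0, abs=1e-12)
        assert r2[0] > r2[1] > r2[2]

    def test_deterministic(self):
        doses = np.array([0.0, 1.0, 3.0, 10.0, 30.0])
        y = np.array([2.0, 10.0, 35.0, 70.0, 90.0])
        a, b = fit_hill(doses, y), fit_hill(doses, y)
        assert (a.E0, a.Emax, a.C, a.h) == (b.E0, b.Emax, b.C, b.h)


class TestAbsoluteIC50:
    def test_symmetric_curve_ic50_equals_ec50(self):
        curve = HillCurve(E0=0.0, Emax=100.0, C=65.7, h=1.5)
        assert absolute_ic50(curve) == pytest.approx(65.7)

    def test_unreachable_when_emax_below_50(self):
        assert absolute_ic50(HillCurve(E0=0.0, Emax=40.0, C=1.0, h=1.0)) is None

    def test_plateau_curve_solves_hill_form(self, plateau_curve):
        # 50 = 80 d / (1 + d)  =>  d = 5/3
        assert absolute_ic50(plateau_curve) == pytest.approx(5.0 / 3.0)
        assert hill_predict(plateau_curve, 5.0 / 3.0) == pytest.approx(50.0)


class TestCurveShift:
    @pytest.fixture()
    def potency_synergy_matrix(self):
        surface = MuSyCSurface(
            E0=1.0, E1=0.05, E2=0.1, E3=0.02, h1=1.2, h2=1.0,
            C1=50.0, C2=1.0, alpha12=8.0, alpha21=8.0,
        )
        cfg = SynthConfig(
            seed=0, surface=surface, noise_sd=0.0,
            doses_row=(6.25, 12.5, 25, 50, 100, 200, 400),
            doses_col=(0.06, 0.12, 0.25, 0.5, 1.0),
            timepoints=(72.0,), n_replicates=1,
        )
        return generate_matrix(cfg)[0]

    def test_zero_partner_column_equals_monotherapy(self, potency_synergy_matrix):
        m = potency_synergy_matrix
        table = curve_shift(m, along="row")
        mono = fit_hill(m.doses_row, m.response[:, 0])
        assert table[0]["partner_dose"] == 0.0
        assert table[0]["absolute_ic50"] == pytest.approx(absolute_ic50(mono), rel=1e-6)

    def test_ic50_decreases_with_partner_dose_under_potency_synergy(
        self, potency_synergy_matrix
    ):
        table = curve_shift(potency_synergy_matrix, along="row")
        ic50s = [e["absolute_ic50"] for e in table if e["absolute_ic50"] is not None]
        assert len(ic50s) >= 4
        assert all(b < a for a, b in zip(ic50s, ic50s[1:]))

    def test_additive_surface_keeps_monotherapy_ic50_at_low_partner_dose(self):
        surface = MuSyCSurface(
            E0=1.0, E1=0.05, E2=0.1, E3=0.005, h1=1.2, h2=1.0,
            C1=50.0, C2=1.0, alpha12=1.0, alpha21=1.0,
        )
        cfg = SynthConfig(
            seed=0, surface=surface, noise_sd=0.0,
            doses_row=(6.25, 12.5, 25, 50, 100, 200, 400),
            doses_col=(0.001, 0.002,  0.005, 0.01),   # far below C2: sub-EC10
            timepoints=(72.0,), n_replicates=1,
        )
        m = generate_matrix(cfg)[0]
        table = curve_shift(m, along="row")
        mono_ic50 = table[0]["absolute_ic50"]
        for entry in table[1:]:
            assert entry["absolute_ic50"] == pytest.approx(mono_ic50, rel=0.02)
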