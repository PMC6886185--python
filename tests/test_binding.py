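import numpy as np
import pytest

from ribofate.binding import (
    anisotropy_change,
    fit_competition,
    fit_exp_decay,
    fit_hill,
    solve_competition_equilibrium,
)
from ribofate.core import RibofateError


def hill_curve(x, baseline, amplitude, kd, h):
    x = np.asarray(x, dtype=float)
    return baseline + amplitude * x**h / (kd**h + x**h)


CONC = np.concatenate([[0.0], np.geomspace(1e-8, 40e-6, 11)])


class TestAnisotropyChange:
    def test_zero_at_baseline(self):
        d = anisotropy_change([0.05, 0.05], [0.0, 1e-6])
        np.testing.assert_allclose(d, [0.0, 0.0])

    def test_subtraction(self):
        d = anisotropy_change([0.05, 0.15], [0.0, 1e-6])
        np.testing.assert_allclose(d, [0.0, 0.10])

    def test_missing_zero_point_fatal(self):
        with pytest.raises(RibofateError):
            anisotropy_change([0.1, 0.2], [1e-7, 1e-6])

    def test_artifact_warning(self, caplog):
        with caplog.at_level("WARNING"):
            anisotropy_change([0.10, 0.05], [0.0, 1e-6])
        assert "artifact" in caplog.text


class TestFitHill:
    def test_half_saturation_identity(self):
        y = hill_curve(CONC, 0.02, 0.15, 0.5e-6, 1.0)
        fit = fit_hill(CONC, y)
        assert fit.converged
        kd = fit.params["kd"]
        yhat = hill_curve(
            kd, fit.params["baseline"], fit.params["amplitude"], kd,
            fit.params["hill_h"],
        )
        assert yhat == pytest.approx(
            fit.params["baseline"] + fit.params["amplitude"] / 2, rel=1e-6
        )

    def test_noiseless_recovery(self):
        y = hill_curve(CONC, 0.02, 0.15, 0.5e-6, 1.3)
        fit = fit_hill(CONC, y)
        assert fit.params["kd"] == pytest.approx(0.5e-6, rel=1e-4)
        assert fit.params["hill_h"] == pytest.approx(1.3, rel=1e-4)

    def test_parameter_recovery_under_noise(self):
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = hill_curve(CONC, 0.02, 0.15, 0.5e-6, 1.0)
            y = y + rng.normal(0, 0.02 * 0.15, y.size)
            fit = fit_hill(CONC, y)
            errors.append(abs(fit.params["kd"] - 0.5e-6) / 0.5e-6)
        assert np.median(errors) < 0.10

    def test_flat_data_not_converged(self):
        y = np.full(CONC.size, 0.05)
        assert not fit_hill(CONC, y).converged

    def test_max_at_lowest_concentration_not_converged(self):
        y = hill_curve(CONC, 0.02, 0.15, 0.5e-6, 1.0)[::-1]
        assert not fit_hill(CONC, y).converged

    def test_too_few_concentrations_fatal(self):
        with pytest.raises(RibofateError):
            fit_hill([0, 1e-6, 2e-6, 3e-6], [0, 0.1, 0.15, 0.18])

    def test_row_order_invariance(self, rng):
        y = hill_curve(CONC, 0.02, 0.15, 0.5e-6, 1.0)
        y = y + rng.normal(0, 0.003, y.size)
        perm = rng.permutation(CONC.size)
        f1 = fit_hill(CONC, y)
        f2 = fit_hill(CONC[perm], y[perm])
        assert f1.params["kd"] == pytest.approx(f2.params["kd"], rel=1e-9)

    def test_fixed_h_quadratic_regime_recovery(self):
        # ligand 10 nM << KD 0.5 uM: free-ligand Hill approximation valid
        kd, rtot = 0.5e-6, 10e-9
        b = CONC + rtot + kd
        bound = (b - np.sqrt(b * b - 4 * CONC * rtot)) / 2
        y = 0.15 * bound / rtot
        fit = fit_hill(CONC, y, fix_h=1.0)
        # quadratic binding shifts the half-saturation point to KD + R/2;
        # the fit recovers that apparent KD far inside 1%
        assert fit.params["kd"] == pytest.approx(kd + rtot / 2, rel=0.001)
        assert fit.params["kd"] == pytest.approx(kd, rel=0.011)


class TestFitExpDecay:
    T = np.linspace(0, 60, 13)

    def test_half_life_identity(self):
        y = 0.05 + 0.12 * np.exp(-0.1 * self.T)
        fit = fit_exp_decay(self.T, y)
        assert fit.half_life == pytest.approx(np.log(2) / 0.1, rel=1e-6)
        assert fit.params["t_half"] * 0 + fit.params["k"] * fit.params[
            "t_half"
        ] == pytest.approx(np.log(2))

    def test_noiseless_recovery(self):
        y = 0.05 + 0.12 * np.exp(-0.1 * self.T)
        fit = fit_exp_decay(self.T, y)
        assert fit.params["k"] == pytest.approx(0.1, rel=1e-3)

    def test_recovery_under_noise(self):
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 0.05 + 0.12 * np.exp(-0.05 * self.T)
            y = y + rng.normal(0, 0.03 * 0.12, y.size)
            fit = fit_exp_decay(self.T, y)
            errors.append(abs(fit.params["k"] - 0.05) / 0.05)
        assert np.median(errors) < 0.10

    def test_increasing_signal_not_converged(self):
        y = 0.05 + 0.12 * (1 - np.exp(-0.1 * self.T))
        assert not fit_exp_decay(self.T, y).converged

    def test_missing_t0_fatal(self):
        with pytest.raises(RibofateError):
            fit_exp_decay(self.T + 1.0, np.exp(-(self.T + 1.0)))


def bisection_oracle(P_total, RL_total, RC_total, KD_L, KD_C, tol=1e-15):
    """Independent bisection on the free-protein mass balance."""
    lo, hi = 0.0, P_total
    for _ in range(200):
        mid = (lo + hi) / 2
        val = (
            mid * (1 + RL_total / (KD_L + mid) + RC_total / (KD_C + mid)) - P_total
        )
        if val > 0:
            hi = mid
        else:
            lo = mid
    pf = (lo + hi) / 2
    return pf / (KD_L + pf), pf / (KD_C + pf)


class TestCompetitionEquilibrium:
    def test_reduces_to_single_site_quadratic(self):
        P, R, KD = 1e-6, 25e-9, 0.5e-6
        sol = solve_competition_equilibrium(P, R, 0.0, KD, 50e-6)
        b = P + R + KD
        complex_ = (b - np.sqrt(b * b - 4 * P * R)) / 2
        assert sol["frac_labeled_bound"] == pytest.approx(
            complex_ / R, rel=1e-9
        )

    def test_symmetry_equal_kds(self):
        sol = solve_competition_equilibrium(1e-6, 50e-9, 50e-9, 1e-6, 1e-6)
        assert sol["frac_labeled_bound"] == pytest.approx(
            sol["frac_competitor_bound"], rel=1e-12
        )

    def test_matches_bisection_oracle_random_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            P = 10 ** rng.uniform(-8, -5)
            RL = 10 ** rng.uniform(-9, -6)
            RC = 10 ** rng.uniform(-9, -5)
            KDL = 10 ** rng.uniform(-8, -5)
            KDC = 10 ** rng.uniform(-8, -4)
            sol = solve_competition_equilibrium(P, RL, RC, KDL, KDC)
            fl, fc = bisection_oracle(P, RL, RC, KDL, KDC)
            assert sol["frac_labeled_bound"] == pytest.approx(fl, rel=1e-6, abs=1e-9)
            assert sol["frac_competitor_bound"] == pytest.approx(fc, rel=1e-6, abs=1e-9)

    def test_mass_conservation(self):
        P, RL, RC, KDL, KDC = 2e-6, 25e-9, 500e-9, 0.4e-6, 3e-6
        sol = solve_competition_equilibrium(P, RL, RC, KDL, KDC)
        bound_L = sol["frac_labeled_bound"] * RL
        bound_C = sol["frac_competitor_bound"] * RC
        assert sol["P_free"] + bound_L + bound_C == pytest.approx(P, rel=1e-9)
        assert sol["RL_free"] + bound_L == pytest.approx(RL, rel=1e-9)
        assert sol["RC_free"] + bound_C == pytest.approx(RC, rel=1e-9)

    def test_invalid_parameters_fatal(self):
        with pytest.raises(RibofateError):
            solve_competition_equilibrium(0.0, 1e-9, 1e-9, 1e-6, 1e-6)


class TestFitCompetition:
    def _curves(self, excess, kd=0.5e-6, kd_c=50e-6, rl=25e-9):
        conc = np.concatenate([[0.0], np.geomspace(2e-8, 7e-6, 9)])
        frac = np.array(
            [
                0.0
                if p == 0
                else solve_competition_equilibrium(p, rl, excess * rl, kd, kd_c)[
                    "frac_labeled_bound"
                ]
                for p in conc
            ]
        )
        return conc, frac

    def test_zero_competitor_recovers_intrinsic_kd(self):
        conc, frac = self._curves(0)
        fit = fit_competition(conc, frac)
        assert fit.params["apparent_kd"] == pytest.approx(0.5e-6, rel=0.1)

    def test_weak_competitor_50x_within_20pct(self):
        conc, frac = self._curves(50, kd_c=100 * 0.5e-6)
        fit = fit_competition(conc, frac)
        assert fit.params["apparent_kd"] == pytest.approx(0.5e-6, rel=0.2)

    def test_apparent_kd_nondecreasing_in_excess(self):
        kds = []
        for excess in (0, 5, 20, 50):
            conc, frac = self._curves(excess, kd_c=2e-6)
            kds.append(fit_competition(conc, frac).params["apparent_kd"])
        assert all(b >= a * 0.999 for a, b in zip(kds, kds[1:]))

    def test_out_of_band_fraction_fatal(self):
        conc = np.concatenate([[0.0], np.geomspace(1e-8, 1e-5, 9)])
        with pytest.raises(RibofateError):
            fit_competition(conc, np.linspace(0, 1.5, conc.size))
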