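import numpy as np
import pytest

from mphpk.convolution_pk import (
    MG_PER_L_TO_NG_PER_ML,
    DispositionParams,
    default_grid,
    profile_metrics,
    simulate_amount,
    simulate_concentration,
)
from mphpk.release_models import SigmoidReleaseParams, cumulative_release

from conftest import convolution_quadrature


@pytest.fixture
def release():
    return SigmoidReleaseParams(ec=5.0, ga=3.0)


@pytest.fixture
def disp():
    return DispositionParams(kel=0.15, vd_f=2000.0)


class TestSimulateAmount:
    def test_matches_quadrature_oracle(self, release):
        kel, dose = 0.15, 100.0
        disp = DispositionParams(kel=kel, vd_f=2000.0)
        times = np.arange(0.0, 24.0 + 1e-9, 0.5)
        profile = simulate_amount(release, disp, dose, times)
        expected = convolution_quadrature(release, kel, dose, 10.0)
        got = profile.amounts[np.isclose(times, 10.0)][0]
        assert got == pytest.approx(expected, rel=1e-6)

    def test_no_elimination_limit(self, release):
        """As kel → 0 the body amount approaches Dose·r(t)."""
        disp = DispositionParams(kel=1e-9, vd_f=2000.0)
        times = np.linspace(0, 30, 61)
        profile = simulate_amount(release, disp, 100.0, times)
        np.testing.assert_allclose(
            profile.amounts, 100.0 * cumulative_release(release, times), rtol=1e-6, atol=1e-6
        )

    def test_dose_linearity(self, release, disp):
        times = np.linspace(0, 48, 97)
        a1 = simulate_amount(release, disp, 50.0, times).amounts
        a2 = simulate_amount(release, disp, 100.0, times).amounts
        np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-7, atol=1e-10)

    def test_mass_balance(self, release, disp):
        """Dose·r(T) = A(T) + kel·∫₀ᵀ A dt on a dense grid."""
        times = np.arange(0.0, 48.0 + 1e-9, 0.01)
        profile = simulate_amount(release, disp, 100.0, times)
        lhs = 100.0 * cumulative_release(release, 48.0)
        rhs = profile.amounts[-1] + disp.kel * np.trapezoid(profile.amounts, times)
        assert rhs == pytest.approx(lhs, rel=1e-5)

    def test_zero_before_admin_time(self, release, disp):
        times = np.linspace(-4, 24, 57)
        profile = simulate_amount(release, disp, 100.0, times, admin_time=2.0)
        assert np.all(profile.amounts[times <= 2.0] == 0.0)
        assert profile.amounts[-1] > 0

    def test_non_monotone_grid_rejected(self, release, disp):
        with pytest.raises(ValueError):
            simulate_amount(release, disp, 100.0, np.array([0.0, 2.0, 1.0]))

    def test_oracle_equivalence_random_draws(self, rng):
        """ODE solution vs adaptive-quadrature convolution on random draws."""
        for _ in range(20):
            release = SigmoidReleaseParams(
                ec=rng.uniform(2, 18), ga=rng.uniform(1.2, 9)
            )
            disp = DispositionParams(kel=rng.uniform(0.05, 0.5), vd_f=1000.0)
            dose = rng.uniform(20, 200)
            t_check = rng.uniform(2, 40)
            profile = simulate_amount(
                release, disp, dose, np.array([0.0, t_check])
            )
            expected = convolution_quadrature(release, disp.kel, dose, t_check)
            assert profile.amounts[-1] == pytest.approx(expected, rel=1e-6)


class TestConcentrationAndMetrics:
    def test_unit_conversion(self, release):
        """23.5 mg in an apparent volume of 1000 L is 23.5 ng/mL."""
        disp = DispositionParams(kel=0.15, vd_f=1000.0)
        profile = simulate_amount(release, disp, 100.0, np.array([0.0, 10.0]))
        profile.amounts = np.array([0.0, 23.5])
        conc = simulate_concentration(profile, disp).concentrations
        assert conc[-1] == pytest.approx(23.5, rel=1e-12)
        assert MG_PER_L_TO_NG_PER_ML == 1000.0

    def test_zero_amounts_zero_conc(self, release, disp):
        profile = simulate_amount(release, disp, 100.0, np.array([0.0, 0.5]))
        profile.amounts = np.zeros(2)
        assert np.all(simulate_concentration(profile, disp).concentrations == 0.0)

    def test_scaling_preserves_tmax(self, release, disp):
        times = default_grid(release, disp)
        profile = simulate_concentration(simulate_amount(release, disp, 100.0, times))
        m = profile_metrics(profile)
        amax = times[np.argmax(profile.amounts)]
        assert m.tmax == amax

    def test_auc_mass_balance_identity(self, release, disp):
        """AUC0-∞·vd·kel approaches the dose for any release function."""
        times = default_grid(release, disp, n_half_lives=12.0)
        profile = simulate_concentration(simulate_amount(release, disp, 100.0, times))
        m = profile_metrics(profile)
        dose_back = m.auc_0_inf * disp.vd_f * disp.kel / MG_PER_L_TO_NG_PER_ML
        assert dose_back == pytest.approx(100.0, rel=2e-3)

    def test_dose_doubling_doubles_cmax_and_auc(self, release, disp):
        times = default_grid(release, disp)
        m1 = profile_metrics(
            simulate_concentration(simulate_amount(release, disp, 50.0, times))
        )
        m2 = profile_metrics(
            simulate_concentration(simulate_amount(release, disp, 100.0, times))
        )
        assert m2.cmax == pytest.approx(2 * m1.cmax, rel=1e-6)
        assert m2.auc_0_inf == pytest.approx(2 * m1.auc_0_inf, rel=1e-6)
        assert m2.tmax == m1.tmax

    def test_fraction_absorbed_after_tmax_regime(self):
        """For a colonic-release-like input, ≥50% of absorption occurs after
        Cmax is reached (absorption-rate-limited kinetics)."""
        release = SigmoidReleaseParams(ec=12.0, ga=2.0)
        disp = DispositionParams(kel=0.35, vd_f=3000.0)
        times = default_grid(release, disp)
        profile = simulate_concentration(simulate_amount(release, disp, 100.0, times))
        m = profile_metrics(profile)
        assert m.frac_absorbed_after_tmax is not None
        assert m.frac_absorbed_after_tmax >= 0.5

    def test_coarse_grid_warns_but_returns(self, release, disp, caplog):
        times = np.arange(0.0, 48.0 + 1e-9, 0.5)
        profile = simulate_concentration(simulate_amount(release, disp, 100.0, times))
        with caplog.at_level("WARNING", logger="mphpk.convolution_pk"):
            m = profile_metrics(profile)
        assert m.cmax > 0
        assert any("grid step" in r.message for r in caplog.records)

    def test_invalid_vd_rejected(self):
        with pytest.raises(ValueError):
            DispositionParams(kel=0.2, vd_f=-5.0)
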