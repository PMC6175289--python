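"""Parametric map fitting: T1, monoexponential decay, noise estimation."""

import numpy as np
import pytest
from scipy.integrate import quad

from lamap import relaxometry as rx
from lamap.containers import AcquisitionSchedule, ImageSeries, NoiseEstimate
from lamap.phantom import T1_TR_ARRAY_S


def _sr_series(params, t_s=T1_TR_ARRAY_S, noise=0.0, rng=None):
    """Stack saturation-recovery voxels; params rows are (A, B, T1_ms)."""
    params = np.atleast_2d(params)
    t = np.asarray(t_s, dtype=float)
    S = params[:, 0:1] * (1 - params[:, 1:2] * np.exp(-t[None, :] * 1000.0
                                                      / params[:, 2:3]))
    if noise:
        rng = rng or np.random.default_rng(0)
        S = np.hypot(S + noise * rng.standard_normal(S.shape),
                     noise * rng.standard_normal(S.shape))
    data = S.reshape(1, -1, 1, t.size)
    return ImageSeries(data, AcquisitionSchedule("saturation-recovery-TR", t),
                       200.0, 1.0)


def _me_series(s0, tau, te_ms, noise=0.0, rng=None):
    s0 = np.atleast_1d(np.asarray(s0, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    te = np.asarray(te_ms, dtype=float)
    S = s0[:, None] * np.exp(-te[None, :] / tau[:, None])
    if noise:
        rng = rng or np.random.default_rng(0)
        S = np.hypot(S + noise * rng.standard_normal(S.shape),
                     noise * rng.standard_normal(S.shape))
    data = S.reshape(1, -1, 1, te.size)
    return ImageSeries(data, AcquisitionSchedule("multi-echo-TE", te),
                       200.0, 1.0)


# ----------------------------------------------------------------------
# T1 fitting
# ----------------------------------------------------------------------

@pytest.mark.parametrize("A,B,T1", [(1000.0, 1.0, 1000.0),
                                    (550.0, 0.9, 350.0),
                                    (800.0, 1.15, 500.0)])
def test_noiseless_t1_recovery_exact(A, B, T1):
    series = _sr_series([(A, B, T1)])
    pm = rx.fit_t1_map(series)
    assert pm.mask[0, 0, 0]
    assert pm.values[0, 0, 0] == pytest.approx(T1, rel=1e-6)
    assert pm.diagnostics["A"][0, 0, 0] == pytest.approx(A, rel=1e-6)
    assert pm.diagnostics["B"][0, 0, 0] == pytest.approx(B, rel=1e-6)
    assert pm.diagnostics["residual_norm"][0, 0, 0] < 1e-6 * A


def test_t1_scale_invariance():
    base = _sr_series([(1000.0, 1.0, 962.0)])
    scaled = ImageSeries(base.data * 37.5, base.schedule, 200.0, 1.0)
    t1a = rx.fit_t1_map(base).values[0, 0, 0]
    t1b = rx.fit_t1_map(scaled).values[0, 0, 0]
    assert t1b == pytest.approx(t1a, rel=1e-9)


def test_constant_signal_is_masked_as_nonconverged():
    t = T1_TR_ARRAY_S
    data = np.full((1, 1, 1, t.size), 500.0)
    series = ImageSeries(data, AcquisitionSchedule("saturation-recovery-TR", t),
                         200.0, 1.0)
    pm = rx.fit_t1_map(series)
    assert not pm.mask[0, 0, 0]
    assert pm.diagnostics["n_nonconverged"] == 1


def test_t1_needs_four_time_points():
    series = _sr_series([(1000.0, 1.0, 900.0)], t_s=[0.2, 1.0, 4.0])
    with pytest.raises(ValueError, match="4 time points"):
        rx.fit_t1_map(series)


def test_below_threshold_voxels_are_masked_and_counted():
    series = _sr_series([(1000.0, 1.0, 900.0), (10.0, 1.0, 900.0)])
    pm = rx.fit_t1_map(series, min_signal=100.0)
    assert pm.mask[0, 0, 0] and not pm.mask[0, 1, 0]
    assert pm.diagnostics["n_below_threshold"] == 1


def test_t1_monte_carlo_mean_within_two_percent_at_snr30():
    n = 3000
    A, T1 = 1000.0, 962.0
    series = _sr_series([(A, 1.0, T1)] * n, noise=A / 30.0,
                        rng=np.random.default_rng(42))
    pm = rx.fit_t1_map(series, min_signal=5 * A / 30.0)
    vals = pm.masked_values
    assert vals.size > 0.95 * n
    assert vals.mean() == pytest.approx(T1, rel=0.02)


def test_global_b_refit_reduces_t1_scatter():
    n = 2000
    A, T1 = 1000.0, 962.0
    rng = np.random.default_rng(3)
    series = _sr_series([(A, 1.0, T1)] * n, noise=25.0, rng=rng)
    free = rx.fit_t1_map(series)
    tied = rx.fit_t1_map(series, global_b=True)
    assert tied.diagnostics["B"][tied.mask].std() == 0.0
    assert tied.masked_values.std() < 0.8 * free.masked_values.std()
    assert tied.masked_values.mean() == pytest.approx(T1, rel=0.02)


# ----------------------------------------------------------------------
# monoexponential decay fitting
# ----------------------------------------------------------------------

def test_noiseless_monoexp_recovery_exact_48_echoes():
    te = 5.0 * np.arange(1, 49)
    series = _me_series([100.0], [20.0], te)
    pm = rx.fit_monoexp_map(series)
    assert pm.values[0, 0, 0] == pytest.approx(20.0, rel=1e-6)
    assert pm.diagnostics["S0"][0, 0, 0] == pytest.approx(100.0, rel=1e-6)
    assert pm.diagnostics["residual_norm"][0, 0, 0] < 1e-8 * 100.0


def test_monoexp_needs_three_echoes():
    series = _me_series([100.0], [20.0], [5.0, 10.0])
    with pytest.raises(ValueError, match="3 echoes"):
        rx.fit_monoexp_map(series)


def test_rician_model_requires_noise_estimate():
    series = _me_series([100.0], [20.0], [5.0, 10.0, 15.0])
    with pytest.raises(ValueError, match="NoiseEstimate"):
        rx.fit_monoexp_map(series, noise_model="rician")


def test_rician_fit_with_zero_sigma_matches_gaussian():
    te = 8.0 * np.arange(1, 13)
    series = _me_series([100.0, 80.0], [20.0, 45.0], te)
    g = rx.fit_monoexp_map(series, noise_model="gaussian")
    r = rx.fit_monoexp_map(series, noise=NoiseEstimate(0.0, 100, "known"),
                           noise_model="rician")
    np.testing.assert_allclose(r.values[r.mask], g.values[g.mask], rtol=1e-6)


def test_rician_fit_less_biased_than_gaussian_at_low_snr():
    te = 5.0 * np.arange(1, 25)
    n, tau, s0, sigma = 3000, 30.0, 100.0, 20.0  # SNR 5
    rng = np.random.default_rng(7)
    series = _me_series([s0] * n, [tau] * n, te, noise=sigma, rng=rng)
    ne = NoiseEstimate(sigma, 10000, "known")
    g = rx.fit_monoexp_map(series, noise_model="gaussian")
    r = rx.fit_monoexp_map(series, noise=ne, noise_model="rician")
    bias_g = abs(np.nanmean(g.values) - tau)
    bias_r = abs(np.nanmean(r.values) - tau)
    assert bias_r < bias_g


def test_residual_positive_on_noisy_data():
    te = 8.0 * np.arange(1, 13)
    series = _me_series([100.0], [25.0], te, noise=3.0,
                        rng=np.random.default_rng(1))
    pm = rx.fit_monoexp_map(series)
    assert pm.diagnostics["residual_norm"][0, 0, 0] > 0.1


# ----------------------------------------------------------------------
# Rician expected magnitude
# ----------------------------------------------------------------------

def _rician_mean_quadrature(nu, sigma):
    """Numerical-integration oracle for E[M]."""
    def integrand(m):
        return (m * m / sigma**2 * np.exp(-(m * m + nu * nu)
                                          / (2 * sigma**2))
                * np.i0(m * nu / sigma**2))
    # i0 overflows for large arguments; integrate the exp-scaled form
    def integrand_stable(m):
        from scipy.special import ive
        return (m * m / sigma**2
                * np.exp(-((m - nu) ** 2) / (2 * sigma**2))
                * ive(0, m * nu / sigma**2))
    return quad(integrand_stable, 0, nu + 12 * sigma)[0]


@pytest.mark.parametrize("nu", [0.0, 0.5, 2.0, 10.0, 200.0])
def test_rician_mean_matches_quadrature_oracle(nu):
    sigma = 2.0
    expected = _rician_mean_quadrature(nu, sigma)
    assert rx.rician_mean(nu, sigma) == pytest.approx(expected, rel=1e-8)


def test_rician_mean_limits():
    # nu = 0: Rayleigh mean; nu >> sigma: approaches nu
    assert rx.rician_mean(0.0, 3.0) == pytest.approx(3.0 * np.sqrt(np.pi / 2))
    assert rx.rician_mean(1e6, 3.0) == pytest.approx(1e6, rel=1e-6)
    assert rx.rician_mean(5.0, 0.0) == 5.0


# ----------------------------------------------------------------------
# background noise estimation
# ----------------------------------------------------------------------

def test_sigma_estimators_recover_known_scale():
    rng = np.random.default_rng(9)
    sigma = 5.0
    bg = np.hypot(sigma * rng.standard_normal((1, 100, 100, 2)),
                  sigma * rng.standard_normal((1, 100, 100, 2)))
    bg[0, 45:55, 45:55, :] = 1000.0  # a bright center so auto-detect works
    series = ImageSeries(bg, AcquisitionSchedule("multi-echo-TE", [5.0, 10.0]),
                         200.0, 1.0)
    est = rx.estimate_background_sigma(series)
    assert est.method == "rayleigh-mean"
    assert est.sigma == pytest.approx(sigma, rel=0.02)
    est2 = rx.estimate_background_sigma(series, method="second-moment")
    assert est2.sigma == pytest.approx(est.sigma, rel=0.03)


def test_zero_background_warns_and_reports_zero_sigma():
    data = np.zeros((1, 30, 30, 2))
    data[0, 10:20, 10:20, :] = 100.0
    series = ImageSeries(data, AcquisitionSchedule("multi-echo-TE", [5.0, 10.0]),
                         200.0, 1.0)
    with pytest.warns(UserWarning, match="degenerate"):
        est = rx.estimate_background_sigma(series)
    assert est.sigma == 0.0


def test_too_few_background_voxels_raises():
    data = np.full((1, 8, 8, 2), 100.0)
    series = ImageSeries(data, AcquisitionSchedule("multi-echo-TE", [5.0, 10.0]),
                         200.0, 1.0)
    with pytest.raises(ValueError, match="background"):
        rx.estimate_background_sigma(series,
                                     background_mask=np.zeros((1, 8, 8), bool))
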