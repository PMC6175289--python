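"""Pixel-wise parametric map fitting.

Three-parameter saturation-recovery T1 fitting S(t) = A(1 − B·exp(−t/T1)),
monoexponential transverse-decay fitting S(TE) = S0·exp(−TE/τ) with either a
plain (Gaussian) least-squares objective or a Rician-noise-aware one that
matches the expected magnitude E[M | ν, σ], and Rayleigh background noise
estimation.

The nonlinear fits use variable projection: for a fixed relaxation time the
amplitude parameters are linear and solved in closed form, leaving a 1-D
objective that is bracketed on a coarse logarithmic grid and refined by a
vectorised golden-section search over all voxels simultaneously.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import ive

from .containers import (
    KIND_ME_TE,
    KIND_SR_TR,
    ImageSeries,
    NoiseEstimate,
    ParametricMap,
)

log = logging.getLogger(__name__)

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
_SQRT_HALF_PI = np.sqrt(np.pi / 2.0)


# ----------------------------------------------------------------------
# Rician expected magnitude
# ----------------------------------------------------------------------

def rician_mean(nu, sigma: float):
    """Expected magnitude E[M] of a Rician variate with location ν, scale σ.

    Uses the closed form via exponentially scaled modified Bessel functions,
    which is overflow-free for any SNR; very high SNR falls back to the
    Gaussian-regime approximation sqrt(ν² + σ²).
    """
    nu = np.asarray(nu, dtype=float)
    if sigma == 0:
        return np.abs(nu)
    x = nu * nu / (2.0 * sigma * sigma)
    out = np.where(
        x > 1e8,
        np.sqrt(nu * nu + sigma * sigma),
        sigma
        * _SQRT_HALF_PI
        * ((1.0 + x) * ive(0, np.minimum(x, 1e8) / 2.0)
           + x * ive(1, np.minimum(x, 1e8) / 2.0)),
    )
    return out


def rician_mean_derivative(nu, sigma: float):
    """d E[M]/dν of the Rician expected magnitude (closed form)."""
    nu = np.asarray(nu, dtype=float)
    if sigma == 0:
        return np.sign(nu).astype(float)
    x = nu * nu / (2.0 * sigma * sigma)
    big = x > 1e8
    xs = np.minimum(x, 1e8)
    out = _SQRT_HALF_PI * (nu / (2.0 * sigma)) * (ive(0, xs / 2.0)
                                                  + ive(1, xs / 2.0))
    if np.any(big):
        out = np.where(big, nu / np.sqrt(nu * nu + sigma * sigma), out)
    return out


# ----------------------------------------------------------------------
# vectorised golden-section machinery
# ----------------------------------------------------------------------

def _golden_minimize(cost, lo, hi, n_iter: int = 70):
    """Vectorised golden-section search; ``cost(x)`` maps (V,) -> (V,).

    One new objective evaluation per iteration (the other probe point is
    inherited), over all voxels simultaneously.
    """
    a, b = lo.copy(), hi.copy()
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = cost(c), cost(d)
    for _ in range(n_iter):
        shrink = fc < fd
        b = np.where(shrink, d, b)
        a = np.where(shrink, a, c)
        new_c = b - _GOLDEN * (b - a)
        new_d = a + _GOLDEN * (b - a)
        # the surviving interior point keeps its objective value
        carry = np.where(shrink, fc, fd)
        probe = np.where(shrink, new_c, new_d)
        f_probe = cost(probe)
        fc = np.where(shrink, f_probe, carry)
        fd = np.where(shrink, carry, f_probe)
        c, d = new_c, new_d
    return 0.5 * (a + b)


def _t1_grid_costs(S, t, grid):
    """Residual norm² of the projected T1 model on a shared T1 grid.

    For a scalar T1 the basis is shared by every voxel, so the linear
    subproblem reduces to matrix-vector products; the least-squares cost is
    SS − θ̂ᵀXᵀS.
    """
    n = t.size
    SS = np.einsum("ij,ij->i", S, S)
    s1 = S.sum(axis=1)
    costs = np.empty((S.shape[0], grid.size))
    for gi, g in enumerate(grid):
        e = np.exp(-t / g)
        se = S @ e
        e1 = e.sum()
        ee = e @ e
        det = n * ee - e1 * e1
        A = (s1 * ee - se * e1) / det
        C = (s1 * e1 - n * se) / det
        costs[:, gi] = SS - (A * s1 - C * se)
    return costs


def _t1_linear(S, t, T1):
    """Closed-form (A, C) of S ≈ A − C·exp(−t/T1) and the residual norm²."""
    e = np.exp(-t[None, :] / T1[:, None])
    n = t.size
    s1 = S.sum(axis=1)
    se = (S * e).sum(axis=1)
    e1 = e.sum(axis=1)
    ee = (e * e).sum(axis=1)
    det = n * ee - e1 * e1
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    A = (s1 * ee - se * e1) / det
    C = (s1 * e1 - n * se) / det
    resid = S - A[:, None] + C[:, None] * e
    cost = np.einsum("ij,ij->i", resid, resid)
    cost = np.where(np.isfinite(cost), cost, np.sum((S - S.mean(1, keepdims=True)) ** 2, 1))
    return A, C, cost


def _t1_fixedb_costs(S, t, B, T1):
    """Residual norm² and amplitude of S ≈ A(1 − B e^{−t/T1}) with B fixed."""
    m = 1.0 - B * np.exp(-t[None, :] / T1[:, None])
    mm = np.einsum("ij,ij->i", m, m)
    sm = np.einsum("ij,ij->i", S, m)
    A = np.where(mm > 0, sm / mm, 0.0)
    SS = np.einsum("ij,ij->i", S, S)
    return A, SS - A * sm


def fit_t1_map(
    series: ImageSeries,
    min_signal: Optional[float] = None,
    noise: Optional[NoiseEstimate] = None,
    t1_bounds_ms: Tuple[float, float] = (50.0, 10000.0),
    b_bounds: Tuple[float, float] = (0.5, 2.0),
    grid_size: int = 64,
    n_golden: int = 80,
    global_b: bool = False,
) -> ParametricMap:
    """Fit S(t) = A(1 − B·exp(−t/T1)) per voxel of a saturation-recovery series.

    Voxels whose peak signal falls below ``min_signal`` (default 5σ from
    ``noise``) are excluded; non-identifiable or out-of-bounds fits are
    masked out and counted in the diagnostics.

    With ``global_b=True`` a second pass re-fits (A, T1) per voxel with B
    fixed to the robust median of the per-voxel estimates.  B captures
    saturation efficacy and echo-train perturbation — properties of the
    sequence rather than of the tissue — and estimating it per voxel costs
    roughly half again as much T1 variance, so pinning it tightens the map
    considerably while keeping the three-parameter model.
    """
    if series.schedule.kind != KIND_SR_TR:
        raise ValueError("fit_t1_map needs a saturation-recovery series")
    t = series.schedule.times  # seconds
    if t.size < 4:
        raise ValueError("T1 fit needs at least 4 time points (3 parameters + 1)")
    if min_signal is None:
        min_signal = 5.0 * noise.sigma if noise is not None else 0.0

    shape = series.data.shape[:3]
    S_all = series.data.reshape(-1, t.size)
    peak = S_all.max(axis=1)
    fit_sel = peak >= max(min_signal, 1e-300)
    n_below = int(np.sum(~fit_sel))
    if not np.any(fit_sel):
        warnings.warn("all voxels below the signal threshold; empty T1 map",
                      stacklevel=2)

    values = np.full(shape, np.nan).reshape(-1)
    A_map = np.full_like(values, np.nan)
    B_map = np.full_like(values, np.nan)
    resid_map = np.full_like(values, np.nan)
    converged = np.zeros(values.shape, dtype=bool)

    if np.any(fit_sel):
        S = S_all[fit_sel]
        t_s = t * 1000.0  # work in ms
        lo, hi = np.log(t1_bounds_ms[0]), np.log(t1_bounds_ms[1])
        grid = np.exp(np.linspace(lo, hi, grid_size))
        costs = _t1_grid_costs(S, t_s, grid)
        best = np.argmin(costs, axis=1)
        g_lo = np.log(grid[np.maximum(best - 1, 0)])
        g_hi = np.log(grid[np.minimum(best + 1, grid_size - 1)])

        def cost(logT1):
            return _t1_linear(S, t_s, np.exp(logT1))[2]

        logT1 = _golden_minimize(cost, g_lo, g_hi, n_iter=n_golden)
        T1 = np.exp(logT1)
        A, C, resid = _t1_linear(S, t_s, T1)
        with np.errstate(divide="ignore", invalid="ignore"):
            B = C / A

        if global_b:
            prelim_ok = (np.isfinite(B) & (A > 0)
                         & (B >= b_bounds[0]) & (B <= b_bounds[1]))
            if not np.any(prelim_ok):
                raise ValueError("no voxel yields a usable B estimate")
            b_hat = float(np.median(B[prelim_ok]))

            def cost_b(logT1):
                return _t1_fixedb_costs(S, t_s, b_hat, np.exp(logT1))[1]

            costs = np.stack([cost_b(np.full(S.shape[0], np.log(g)))
                              for g in grid], axis=1)
            best = np.argmin(costs, axis=1)
            g_lo = np.log(grid[np.maximum(best - 1, 0)])
            g_hi = np.log(grid[np.minimum(best + 1, grid_size - 1)])
            T1 = np.exp(_golden_minimize(cost_b, g_lo, g_hi, n_iter=n_golden))
            A, resid = _t1_fixedb_costs(S, t_s, b_hat, T1)
            B = np.full_like(A, b_hat)

        ok = (
            np.isfinite(T1) & np.isfinite(A) & np.isfinite(B)
            & (A > 0)
            & (B >= b_bounds[0]) & (B <= b_bounds[1])
            & (T1 > t1_bounds_ms[0] * 1.0000001)
            & (T1 < t1_bounds_ms[1] * 0.9999999)
        )
        idx = np.flatnonzero(fit_sel)
        values[idx[ok]] = T1[ok]
        A_map[idx] = A
        B_map[idx] = B
        resid_map[idx] = np.sqrt(np.maximum(resid, 0.0))
        converged[idx[ok]] = True

    n_nonconv = int(np.sum(fit_sel) - converged.sum())
    log.info("T1 fit: %d below threshold, %d non-converged", n_below, n_nonconv)
    mask = converged.reshape(shape)
    return ParametricMap(
        values=values.reshape(shape),
        mask=mask,
        unit="ms",
        diagnostics={
            "A": A_map.reshape(shape),
            "B": B_map.reshape(shape),
            "residual_norm": resid_map.reshape(shape),
            "converged": converged.reshape(shape),
            "n_below_threshold": n_below,
            "n_nonconverged": n_nonconv,
            "min_signal": float(min_signal),
            "global_b": bool(global_b),
        },
        pixel_um=series.pixel_um,
        slice_mm=series.slice_mm,
    )


# ----------------------------------------------------------------------
# monoexponential T2 / T2* fitting
# ----------------------------------------------------------------------

def _monoexp_linear(S, te, tau):
    e = np.exp(-te[None, :] / tau[:, None])
    ee = (e * e).sum(axis=1)
    se = (S * e).sum(axis=1)
    S0 = np.where(ee > 0, se / ee, 0.0)
    resid = S - S0[:, None] * e
    return S0, np.einsum("ij,ij->i", resid, resid)


def _monoexp_grid_costs(S, te, grid):
    SS = np.einsum("ij,ij->i", S, S)
    costs = np.empty((S.shape[0], grid.size))
    for gi, g in enumerate(grid):
        e = np.exp(-te / g)
        se = S @ e
        S0 = se / (e @ e)
        costs[:, gi] = SS - S0 * se
    return costs


def _fit_monoexp_gaussian(S, te, bounds, grid_size=64, n_golden=70):
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    grid = np.exp(np.linspace(lo, hi, grid_size))
    costs = _monoexp_grid_costs(S, te, grid)
    best = np.argmin(costs, axis=1)
    g_lo = np.log(grid[np.maximum(best - 1, 0)])
    g_hi = np.log(grid[np.minimum(best + 1, grid_size - 1)])

    def cost(logtau):
        return _monoexp_linear(S, te, np.exp(logtau))[1]

    tau = np.exp(_golden_minimize(cost, g_lo, g_hi, n_iter=n_golden))
    S0, resid = _monoexp_linear(S, te, tau)
    return S0, tau, resid


def _fit_monoexp_rician(S, te, sigma, S0_init, tau_init, bounds,
                        max_iter=60, tol=1e-7):
    """Vectorised Levenberg-Marquardt on (log S0, log τ) minimising
    Σ (M − E[M | S0·e^{−TE/τ}, σ])².  Jacobian by central differences on ν."""
    a_full = np.log(np.maximum(S0_init, 1e-12))
    b_full = np.log(np.clip(tau_init, bounds[0], bounds[1]))
    lo_b, hi_b = np.log(bounds[0]), np.log(bounds[1])
    cost_full = np.empty_like(a_full)

    def model_cost(a, b, Ssub):
        nu = np.exp(a)[:, None] * np.exp(-te[None, :] / np.exp(b)[:, None])
        r = Ssub - rician_mean(nu, sigma)
        return nu, r, np.einsum("ij,ij->i", r, r)

    idx = np.arange(a_full.size)  # active voxel indices
    a, b = a_full[idx], b_full[idx]
    Ssub = S
    nu, r, cost = model_cost(a, b, Ssub)
    cost_full[:] = cost
    lam = np.full(a.shape, 1e-3)
    for _ in range(max_iter):
        if idx.size == 0:
            break
        dE = rician_mean_derivative(nu, sigma)
        tau = np.exp(b)
        J1 = -dE * nu  # d r / d log S0
        J2 = J1 * (te[None, :] / tau[:, None])  # d r / d log tau
        g11 = np.einsum("ij,ij->i", J1, J1)
        g12 = np.einsum("ij,ij->i", J1, J2)
        g22 = np.einsum("ij,ij->i", J2, J2)
        r1 = -np.einsum("ij,ij->i", J1, r)
        r2 = -np.einsum("ij,ij->i", J2, r)
        d11 = g11 * (1 + lam) + 1e-300
        d22 = g22 * (1 + lam) + 1e-300
        det = np.where(np.abs(d11 * d22 - g12**2) < 1e-300, 1e-300,
                       d11 * d22 - g12**2)
        da = (d22 * r1 - g12 * r2) / det
        db = (d11 * r2 - g12 * r1) / det
        a_new = np.clip(a + da, -50.0, 50.0)
        b_new = np.clip(b + db, lo_b, hi_b)
        nu_new, r_new, cost_new = model_cost(a_new, b_new, Ssub)
        ok = cost_new <= cost
        a = np.where(ok, a_new, a)
        b = np.where(ok, b_new, b)
        nu = np.where(ok[:, None], nu_new, nu)
        r = np.where(ok[:, None], r_new, r)
        rel_improve = np.where(ok, (cost - cost_new) / np.maximum(cost, 1e-300),
                               0.0)
        cost = np.where(ok, cost_new, cost)
        lam = np.where(ok, np.maximum(lam * 0.3, 1e-9), lam * 10.0)
        a_full[idx], b_full[idx], cost_full[idx] = a, b, cost
        done = (
            (ok & (np.maximum(np.abs(da), np.abs(db)) < tol))
            | (ok & (rel_improve < 1e-12))
            | (lam >= 1e6)
        )
        if np.any(done):  # compress to the still-active subset
            keep = ~done
            idx, a, b, lam, cost = idx[keep], a[keep], b[keep], lam[keep], cost[keep]
            nu, r, Ssub = nu[keep], r[keep], Ssub[keep]
    return np.exp(a_full), np.exp(b_full), cost_full


def fit_monoexp_map(
    series: ImageSeries,
    noise: Optional[NoiseEstimate] = None,
    noise_model: str = "gaussian",
    min_signal: float = 0.0,
    tau_bounds_ms: Tuple[float, float] = (1.0, 5000.0),
    unit: str = "ms",
) -> ParametricMap:
    """Fit S(TE) = S0·exp(−TE/τ) per voxel of a multi-echo series.

    With ``noise_model="rician"`` the fit minimises the misfit of the Rician
    expected magnitude E[M | ν = S0·e^{−TE/τ}, σ] (σ from ``noise``), which
    removes the noise-floor bias of the plain least-squares fit.
    """
    if series.schedule.kind != KIND_ME_TE:
        raise ValueError("fit_monoexp_map needs a multi-echo series")
    te = series.schedule.times
    if te.size < 3:
        raise ValueError("monoexponential fit needs at least 3 echoes")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError("noise_model must be 'gaussian' or 'rician'")
    if noise_model == "rician" and noise is None:
        raise ValueError("rician noise model requires a NoiseEstimate")

    shape = series.data.shape[:3]
    S_all = series.data.reshape(-1, te.size)
    fit_sel = S_all.max(axis=1) >= max(min_signal, 1e-300)
    n_below = int(np.sum(~fit_sel))

    values = np.full(shape, np.nan).reshape(-1)
    S0_map = np.full_like(values, np.nan)
    resid_map = np.full_like(values, np.nan)
    converged = np.zeros(values.shape, dtype=bool)

    if np.any(fit_sel):
        S = S_all[fit_sel]
        S0, tau, resid = _fit_monoexp_gaussian(S, te, tau_bounds_ms)
        if noise_model == "rician" and noise.sigma > 0:
            S0, tau, resid = _fit_monoexp_rician(
                S, te, noise.sigma, S0, tau, tau_bounds_ms)
        ok = (
            np.isfinite(tau) & np.isfinite(S0) & (S0 > 0)
            & (tau > tau_bounds_ms[0] * 1.0000001)
            & (tau < tau_bounds_ms[1] * 0.9999999)
        )
        idx = np.flatnonzero(fit_sel)
        values[idx[ok]] = tau[ok]
        S0_map[idx] = S0
        resid_map[idx] = np.sqrt(np.maximum(resid, 0.0))
        converged[idx[ok]] = True

    n_nonconv = int(np.sum(fit_sel) - converged.sum())
    log.info("monoexp fit (%s): %d below threshold, %d non-converged",
             noise_model, n_below, n_nonconv)
    return ParametricMap(
        values=values.reshape(shape),
        mask=converged.reshape(shape),
        unit=unit,
        diagnostics={
            "S0": S0_map.reshape(shape),
            "residual_norm": resid_map.reshape(shape),
            "converged": converged.reshape(shape),
            "n_below_threshold": n_below,
            "n_nonconverged": n_nonconv,
            "noise_model": noise_model,
        },
        pixel_um=series.pixel_um,
        slice_mm=series.slice_mm,
    )


# ----------------------------------------------------------------------
# background noise estimation
# ----------------------------------------------------------------------

def _auto_background_mask(series: ImageSeries) -> np.ndarray:
    """Lowest-intensity connected region touching the volume border."""
    mean_img = series.data.mean(axis=3)
    thr = 0.1 * mean_img.max()
    low = mean_img < thr
    lab, n = ndimage.label(low)
    if n == 0:
        return np.zeros_like(low)
    border = np.zeros_like(low)
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    border_labels = np.unique(lab[border & low])
    border_labels = border_labels[border_labels > 0]
    return np.isin(lab, border_labels)


def estimate_background_sigma(
    series: ImageSeries,
    background_mask: Optional[np.ndarray] = None,
    method: str = "rayleigh-mean",
    min_voxels: int = 100,
) -> NoiseEstimate:
    """Estimate the Rician scale σ from signal-free background magnitudes.

    Background magnitudes follow a Rayleigh law, so σ = mean/sqrt(π/2)
    (``rayleigh-mean``) or σ = sqrt(E[M²]/2) (``second-moment``).
    """
    if background_mask is None:
        background_mask = _auto_background_mask(series)
    background_mask = np.asarray(background_mask, dtype=bool)
    n_bg = int(background_mask.sum())
    if n_bg < min_voxels:
        raise ValueError(
            f"only {n_bg} background voxels found (need >= {min_voxels})")
    m = series.data[background_mask].ravel()
    if method == "rayleigh-mean":
        sigma = float(m.mean() / _SQRT_HALF_PI)
    elif method == "second-moment":
        sigma = float(np.sqrt(np.mean(m * m) / 2.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    if sigma == 0:
        warnings.warn("degenerate noise estimate: background is exactly zero",
                      stacklevel=2)
    return NoiseEstimate(sigma=sigma, n_background_voxels=n_bg, method=method)
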