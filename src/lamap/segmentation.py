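"""Tissue segmentation of T1 maps by 1-D Gaussian mixture modelling.

The T1 histogram of a fixed left-atrial sample is multi-modal: fat-region
voxels sit lowest, non-fibrotic myocardium around 962 ms, fibrosis around
1131 ms and the PFA fixative bath highest.  A k-component 1-D Gaussian
mixture is fitted by EM and components are assigned tissue roles purely by
their T1 ordering; fibrosis is the class between myocardium and PFA.

Fatty fibrosis is obtained by restricting the T1 map to the Dixon fat region
and clustering that "T1-fat map" into two classes (fat low, fatty fibrosis
high).  Fraction reports aggregate per-slice tissue percentages and average
them over configurable slice counts (3 slices for fibrosis, 5 for fat).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from skimage.filters import threshold_otsu

from .containers import ParametricMap
from .dixon import FatMap

log = logging.getLogger(__name__)

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.354820045...

ROLE_VOCAB = {
    "three-class": ("myocardium", "total_fibrosis", "pfa"),
    "four-class": ("fat_mixture", "myocardium", "interstitial_fibrosis", "pfa"),
    "fat-region": ("fat", "fatty_fibrosis"),
}

# voxel label codes of TissueClassMap volumes
CLASS_CODES = {
    "background": 0,
    "pfa": 1,
    "myocardium": 2,
    "interstitial_fibrosis": 3,
    "fat": 4,
    "fatty_fibrosis": 5,
    "total_fibrosis": 6,
    "fat_mixture": 7,
}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}


# ----------------------------------------------------------------------
# 1-D Gaussian mixture model
# ----------------------------------------------------------------------

@dataclass
class GmmModel1D:
    """EM-fitted k-component 1-D Gaussian mixture over T1 values.

    ``outlier_weight`` is the mixing weight of an optional uniform background
    component fitted alongside the Gaussians (it absorbs partial-volume
    bridge voxels between tissue modes so they cannot hijack a component);
    the stored Gaussian ``weights`` are renormalised to sum to 1, which
    leaves posteriors among the Gaussian classes unchanged.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood_trace: np.ndarray
    seed: int
    n_iter: int
    converged: bool
    outlier_weight: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if np.any(self.weights <= 0) or np.any(self.variances <= 0):
            raise ValueError("weights and variances must be > 0")

    @property
    def k(self) -> int:
        return self.means.size

    @property
    def sigmas(self) -> np.ndarray:
        return np.sqrt(self.variances)

    @property
    def fwhm(self) -> np.ndarray:
        """Full width at half maximum, 2·sqrt(2 ln 2)·σ, per component (ms)."""
        return FWHM_FACTOR * self.sigmas

    def peak_heights(self, n: Optional[int] = None,
                     bin_width: Optional[float] = None) -> np.ndarray:
        """Density amplitude w/(σ√(2π)) per component; if ``n`` and
        ``bin_width`` are given, scaled to histogram counts."""
        amp = self.weights / (self.sigmas * np.sqrt(2 * np.pi))
        if n is not None and bin_width is not None:
            amp = amp * n * bin_width
        return amp

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Per-component log of weight × normal density; shape (n, k)."""
        x = np.asarray(x, dtype=float)[:, None]
        return (
            np.log(self.weights)[None, :]
            - 0.5 * np.log(2 * np.pi * self.variances)[None, :]
            - 0.5 * (x - self.means[None, :]) ** 2 / self.variances[None, :]
        )

    def posterior(self, x: np.ndarray) -> np.ndarray:
        lp = self.log_density(x)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))

    def bic(self, x: np.ndarray) -> float:
        ll = float(logsumexp(self.log_density(x), axis=1).sum())
        n_params = 3 * self.k - 1
        return n_params * np.log(x.size) - 2.0 * ll


def _kmeans_1d(x, means0, n_iter: int = 15):
    """Lloyd refinement of initial means; returns means, variances, weights."""
    means = np.sort(means0.astype(float))
    for _ in range(n_iter):
        edges = 0.5 * (means[1:] + means[:-1])
        assign = np.searchsorted(edges, x)
        new = means.copy()
        for j in range(means.size):
            sel = assign == j
            if np.any(sel):
                new[j] = x[sel].mean()
        if np.allclose(new, means):
            break
        means = np.sort(new)
    edges = 0.5 * (means[1:] + means[:-1])
    assign = np.searchsorted(edges, x)
    variances = np.empty_like(means)
    weights = np.empty_like(means)
    span = np.ptp(x)
    for j in range(means.size):
        sel = assign == j
        weights[j] = max(sel.mean(), 1e-6)
        variances[j] = x[sel].var() if np.sum(sel) > 1 else (span / 20) ** 2
        variances[j] = max(variances[j], (span / 200) ** 2, 1e-12)
    weights = weights / weights.sum()
    return means, variances, weights


def _em_once(x, k, init, max_iter, tol, var_floor, outlier_uniform):
    n = x.size
    means, variances, weights = (a.copy() for a in init)
    if outlier_uniform:
        log_u = -np.log(np.ptp(x))  # fixed uniform density over the data range
        w_u = 0.05
        weights = weights * (1.0 - w_u)
    else:
        w_u = 0.0
    trace = []
    ll_prev = -np.inf
    converged = False
    for it in range(max_iter):
        lp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        )
        if outlier_uniform:
            lp = np.concatenate(
                [lp, np.full((n, 1), np.log(max(w_u, 1e-300)) + log_u)], axis=1)
        norm = logsumexp(lp, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(lp - norm[:, None])
        nk = resp[:, :k].sum(axis=0)
        if np.any(nk < 1e-10):
            return None  # component starved -> collapse
        weights = nk / n
        if outlier_uniform:
            w_u = float(resp[:, k].sum() / n)
        means = (resp[:, :k] * x[:, None]).sum(axis=0) / nk
        variances = (resp[:, :k] * (x[:, None] - means[None, :]) ** 2
                     ).sum(axis=0) / nk
        if np.any(variances < var_floor):
            return None  # variance collapse
        if ll - ll_prev < tol * max(1.0, abs(ll)) and it > 0:
            converged = True
            break
        ll_prev = ll
    return weights, means, variances, np.asarray(trace), converged, w_u


def fit_gmm(
    values: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-8,
    outlier_uniform: bool = False,
) -> GmmModel1D:
    """Fit a k-component 1-D Gaussian mixture by EM with seeded restarts.

    Initial means are quantile-spaced (restart 0) or drawn from the data
    (later restarts), refined by a short 1-D k-means pass that also sets the
    initial variances and weights; the best log-likelihood over restarts is
    kept.  ``outlier_uniform=True`` adds a uniform background component over
    the data range whose weight is learned by EM — a standard robustification
    that keeps stray values (e.g. partial-volume bridges between tissue
    modes) from capturing a Gaussian component.  Collapsed restarts
    (vanishing variance or starved component) are discarded; if every restart
    collapses an error is raised.
    """
    x = np.asarray(values, dtype=float).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} values for k={k}")
    rng_range = float(np.ptp(x))
    if rng_range == 0:
        raise ValueError("degenerate data: all values identical")
    var_floor = max(1e-12 * rng_range**2, 1e-300)
    rng = np.random.default_rng(seed)
    q = np.quantile(x, (np.arange(k) + 0.5) / k)

    best = None
    seen = set()
    for r in range(n_restarts):
        if r == 0:
            means0 = q  # deterministic quantile baseline
        else:
            # k-means++-style seeding: spread initial means over the data
            means0 = np.sort(rng.choice(x, size=k, replace=False))
        init = _kmeans_1d(x, means0)
        # restarts that k-means collapses onto the same start are redundant
        key = tuple(np.round(init[0] / (rng_range / 1e4)).astype(np.int64))
        if key in seen:
            continue
        seen.add(key)
        res = _em_once(x, k, init, max_iter, tol, var_floor, outlier_uniform)
        if res is None:
            continue
        if best is None or res[3][-1] > best[3][-1]:
            best = res
    if best is None:
        raise RuntimeError("all EM restarts collapsed")
    weights, means, variances, trace, converged, w_u = best
    return GmmModel1D(
        weights=weights / weights.sum(),
        means=means,
        variances=variances,
        log_likelihood_trace=trace,
        seed=seed,
        n_iter=trace.size,
        converged=converged,
        outlier_weight=w_u,
    )


def refit_gmm(values: np.ndarray, init_model: GmmModel1D,
              max_iter: int = 300, tol: float = 1e-8,
              outlier_uniform: bool = True) -> GmmModel1D:
    """Re-fit a mixture on new values, warm-started from a previous model.

    EM runs to convergence from the given model's parameters (no random
    restarts), so the components keep their identities while adapting their
    means, widths and weights to the new value distribution — the natural
    way to re-cluster a resolution-degraded map whose histogram is a smeared
    version of the original.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10 * init_model.k:
        raise ValueError(f"need at least {10 * init_model.k} values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all values identical")
    var_floor = max(1e-12 * np.ptp(x) ** 2, 1e-300)
    init = (init_model.means.copy(), init_model.variances.copy(),
            init_model.weights.copy())
    res = _em_once(x, init_model.k, init, max_iter, tol, var_floor,
                   outlier_uniform)
    if res is None:
        raise RuntimeError("warm-started EM collapsed")
    weights, means, variances, trace, converged, w_u = res
    return GmmModel1D(
        weights=weights / weights.sum(), means=means, variances=variances,
        log_likelihood_trace=trace, seed=init_model.seed, n_iter=trace.size,
        converged=converged, outlier_weight=w_u)


# ----------------------------------------------------------------------
# role assignment and per-voxel classification
# ----------------------------------------------------------------------

def assign_roles(model: GmmModel1D, mode: str) -> Dict[int, str]:
    """Map mixture components to tissue roles by ascending mean T1.

    three-class → (myocardium, total fibrosis, PFA); four-class →
    (fat mixture, myocardium, interstitial fibrosis, PFA); fat-region →
    (fat, fatty fibrosis).  Mean ties are broken by smaller variance first,
    with a warning.
    """
    if mode not in ROLE_VOCAB:
        raise ValueError(f"unknown mode {mode!r}")
    vocab = ROLE_VOCAB[mode]
    if model.k != len(vocab):
        raise ValueError(f"mode {mode!r} expects k={len(vocab)}, got {model.k}")
    if np.unique(model.means).size < model.k:
        warnings.warn("tied component means; breaking ties by variance",
                      stacklevel=2)
    order = np.lexsort((model.variances, model.means))
    return {int(comp): vocab[rank] for rank, comp in enumerate(order)}


@dataclass
class TissueClassMap:
    """Per-voxel tissue labels with provenance of the producing model."""

    labels: np.ndarray  # int codes per CLASS_CODES; 0 = background
    provenance: str
    model: Optional[GmmModel1D] = None
    roles: Optional[Dict[int, str]] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels)) - set(CODE_NAMES)
        if bad:
            raise ValueError(f"labels outside the vocabulary: {sorted(bad)}")

    @property
    def legend(self) -> Dict[int, str]:
        return dict(CODE_NAMES)

    def mask_of(self, *names: str) -> np.ndarray:
        codes = [CLASS_CODES[n] for n in names]
        return np.isin(self.labels, codes)


def classify_map(t1_map: ParametricMap, model: GmmModel1D,
                 roles: Dict[int, str],
                 within: Optional[np.ndarray] = None,
                 provenance: str = "gmm") -> TissueClassMap:
    """Hard maximum-posterior assignment of every masked voxel; voxels
    outside the map mask (or outside ``within``) stay background."""
    sel = t1_map.mask if within is None else (t1_map.mask & within)
    labels = np.zeros(t1_map.values.shape, dtype=np.uint8)
    if np.any(sel):
        post = model.posterior(t1_map.values[sel])
        comp = np.argmax(post, axis=1)
        codes = np.array([CLASS_CODES[roles[c]] for c in range(model.k)])
        labels[sel] = codes[comp]
    return TissueClassMap(labels=labels, provenance=provenance, model=model,
                          roles=roles)


# ----------------------------------------------------------------------
# fat-region (fatty fibrosis) clustering
# ----------------------------------------------------------------------

def fat_region_mask(fat_map: FatMap, tissue: np.ndarray,
                    ff_threshold="otsu", ff_floor: float = 0.05) -> Tuple[np.ndarray, float]:
    """Fat region = tissue voxels whose fat fraction exceeds a threshold.

    ``ff_threshold="otsu"`` derives the cut from the FF histogram within
    tissue (never below ``ff_floor``, which guards the zero-fat case where
    Otsu would split noise); a float fixes it explicitly.
    """
    sel = tissue & fat_map.mask
    ff = fat_map.fat_fraction
    if ff_threshold == "otsu":
        vals = ff[sel]
        if vals.size < 2 or np.ptp(vals) < 1e-6:
            thr = ff_floor
        else:
            thr = max(float(threshold_otsu(vals)), ff_floor)
    else:
        thr = float(ff_threshold)
    region = sel & (ff >= thr)
    if ff_threshold == "otsu" and np.any(region):
        # a genuine fat region sits well above the cut; the upper noise
        # tail of a fat-free map does not
        if float(ff[region].mean()) < 1.5 * thr:
            log.info("fat-region candidate rejected (mean FF %.3f < 1.5x "
                     "threshold %.3f)", float(ff[region].mean()), thr)
            region = np.zeros_like(region)
    return region, thr


def fatty_fibrosis_map(
    t1_map: ParametricMap,
    fat_map: FatMap,
    tissue: Optional[np.ndarray] = None,
    ff_threshold="otsu",
    seed: int = 0,
    min_voxels: int = 20,
    bimodality: str = "bic",
    fixed_model: Optional[GmmModel1D] = None,
) -> TissueClassMap:
    """Two-class clustering of the T1-fat map into fat and fatty fibrosis.

    The non-fat region is eliminated by superimposing the fat map on the T1
    map; the remaining T1 values are clustered into two classes, lower T1 →
    fat, higher → fatty fibrosis.  A fat region smaller than ``min_voxels``
    (or, with ``bimodality="bic"``, one whose T1 distribution a single
    Gaussian explains better) yields an all-fat map with 0% fatty fibrosis,
    flagged in the diagnostics.
    """
    if t1_map.values.shape != fat_map.fat_fraction.shape:
        raise ValueError("t1 map and fat map must share geometry")
    if tissue is None:
        tissue = t1_map.mask
    region, thr = fat_region_mask(fat_map, tissue & t1_map.mask, ff_threshold)
    labels = np.zeros(t1_map.values.shape, dtype=np.uint8)
    diag = {"ff_threshold": thr, "n_fat_region": int(region.sum()),
            "degenerate": False}
    if region.sum() < min_voxels:
        warnings.warn("fat region too small; reporting 0% fatty fibrosis",
                      stacklevel=2)
        labels[region] = CLASS_CODES["fat"]
        return TissueClassMap(labels=labels, provenance="fat-region",
                              diagnostics=diag)
    vals = t1_map.values[region]
    if fixed_model is not None:
        roles = assign_roles(fixed_model, "fat-region")
        out = classify_map(t1_map, fixed_model, roles, within=region,
                           provenance="fat-region")
        out.diagnostics.update(diag)
        return out
    try:
        model = fit_gmm(vals, k=2, seed=seed)
    except (ValueError, RuntimeError):
        labels[region] = CLASS_CODES["fat"]
        diag["degenerate"] = True
        return TissueClassMap(labels=labels, provenance="fat-region",
                              diagnostics=diag)
    if bimodality == "bic":
        mu, var = float(vals.mean()), float(vals.var())
        ll1 = -0.5 * vals.size * (np.log(2 * np.pi * var) + 1.0)
        bic1 = 2 * np.log(vals.size) - 2 * ll1
        if bic1 <= model.bic(vals):
            labels[region] = CLASS_CODES["fat"]
            diag["degenerate"] = True
            log.info("fat-region T1 unimodal by BIC; 0%% fatty fibrosis")
            return TissueClassMap(labels=labels, provenance="fat-region",
                                  diagnostics=diag)
    roles = assign_roles(model, "fat-region")
    out = classify_map(t1_map, model, roles, within=region,
                       provenance="fat-region")
    out.diagnostics.update(diag)
    return out


# ----------------------------------------------------------------------
# fraction reporting
# ----------------------------------------------------------------------

COMPONENTS = ("myocardium", "interstitial_fibrosis", "fat", "fatty_fibrosis")


@dataclass
class FractionReport:
    """Per-slice and volumetric tissue percentages.

    ``per_slice`` holds one row per slice with the four-component partition
    percentages plus total fibrosis and the tissue-voxel denominator;
    ``volume`` averages per-slice values over the configured slice windows
    and ``designated_2d`` is the single histology-matched slice.
    """

    per_slice: pd.DataFrame
    volume: Dict[str, float]
    designated_2d: Dict[str, float]
    n_slices_fibrosis: int
    n_slices_fat: int

    def __post_init__(self) -> None:
        comp = self.per_slice[list(COMPONENTS)].to_numpy()
        if np.any(comp < -1e-9) or np.any(comp > 100 + 1e-9):
            raise ValueError("percentages must lie in [0, 100]")
        sums = comp.sum(axis=1)
        if np.any(np.abs(sums - 100.0) > 0.01):
            raise ValueError("per-slice component percentages must sum to 100")


def _central_slices(n_slices: int, n_used: int) -> np.ndarray:
    n_used = min(n_used, n_slices)
    start = (n_slices - n_used) // 2
    return np.arange(start, start + n_used)


def fraction_report(
    partition: TissueClassMap,
    total_fibrosis_map: Optional[TissueClassMap] = None,
    volume_slices_fibrosis: int = 3,
    volume_slices_fat: int = 5,
) -> FractionReport:
    """Tissue fractions from a four-component partition map.

    ``partition`` labels every tissue voxel as exactly one of myocardium,
    interstitial fibrosis, fat or fatty fibrosis (PFA/background excluded
    from the denominator).  Total fibrosis per slice comes from
    ``total_fibrosis_map`` membership when given, else interstitial + fatty.
    Volumetric values average the per-slice values over central slice
    windows (3 for fibrosis quantities, 5 for fat, by default).
    """
    labels = partition.labels
    n_slices = labels.shape[0]
    rows = []
    for s in range(n_slices):
        counts = {c: int(np.sum(labels[s] == CLASS_CODES[c])) for c in COMPONENTS}
        n_tissue = sum(counts.values())
        if n_tissue == 0:
            raise ValueError(f"slice {s} has zero tissue voxels")
        row = {c: 100.0 * counts[c] / n_tissue for c in COMPONENTS}
        if total_fibrosis_map is not None:
            tf = int(np.sum(total_fibrosis_map.mask_of(
                "total_fibrosis", "fatty_fibrosis", "interstitial_fibrosis")[s]))
            row["total_fibrosis"] = 100.0 * tf / n_tissue
        else:
            row["total_fibrosis"] = (
                row["interstitial_fibrosis"] + row["fatty_fibrosis"])
        row["n_tissue_voxels"] = n_tissue
        rows.append(pd.Series(row, name=f"slice_{s}"))
    per_slice = pd.DataFrame(rows)

    fib_cols = ["total_fibrosis", "interstitial_fibrosis", "fatty_fibrosis",
                "myocardium"]
    fat_cols = ["fat"]
    vol = {}
    fib_idx = _central_slices(n_slices, volume_slices_fibrosis)
    fat_idx = _central_slices(n_slices, volume_slices_fat)
    for c in fib_cols:
        vol[c] = float(per_slice[c].iloc[fib_idx].mean())
    for c in fat_cols:
        vol[c] = float(per_slice[c].iloc[fat_idx].mean())
    mid = n_slices // 2
    designated = {c: float(per_slice[c].iloc[mid])
                  for c in fib_cols + fat_cols}
    return FractionReport(
        per_slice=per_slice,
        volume=vol,
        designated_2d=designated,
        n_slices_fibrosis=len(fib_idx),
        n_slices_fat=len(fat_idx),
    )


def reclassification_rate(map_a: TissueClassMap, map_b: TissueClassMap,
                          mode: str = "fibrosis") -> float:
    """Percentage of voxels whose classification differs between two runs.

    ``mode="fibrosis"`` compares fibrosis-class membership (any fibrosis
    label) between e.g. the 3-class total-fibrosis map and the 4-class
    interstitial-fibrosis map; ``mode="any"`` compares full labels.  The
    denominator is the number of voxels labelled in either map.
    """
    if map_a.labels.shape != map_b.labels.shape:
        raise ValueError("geometry mismatch between class maps")
    labelled = (map_a.labels > 0) | (map_b.labels > 0)
    n = int(labelled.sum())
    if n == 0:
        raise ValueError("no labelled voxels")
    if mode == "fibrosis":
        fib = ("total_fibrosis", "interstitial_fibrosis", "fatty_fibrosis")
        diff = map_a.mask_of(*fib) != map_b.mask_of(*fib)
    elif mode == "any":
        diff = map_a.labels != map_b.labels
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * float(np.sum(diff & labelled)) / n


def _adjacent_to(mask: np.ndarray) -> np.ndarray:
    """Voxels 4-adjacent (in plane) to a true voxel of ``mask``."""
    out = np.zeros_like(mask)
    out[:, 1:, :] |= mask[:, :-1, :]
    out[:, :-1, :] |= mask[:, 1:, :]
    out[:, :, 1:] |= mask[:, :, :-1]
    out[:, :, :-1] |= mask[:, :, 1:]
    return out


def interior_mask(pmap: ParametricMap, factor: float = 3.0,
                  within: Optional[np.ndarray] = None) -> np.ndarray:
    """Voxels whose T1 agrees with all in-plane neighbours.

    A voxel is interior when its maximum absolute in-plane neighbour
    difference stays below ``factor`` × the map-wide median of that
    statistic (a self-calibrating noise scale).  Partial-volume voxels on
    strong interfaces (tissue/bath) fail the test; mixture models fitted on
    interior voxels are then free of bridge artefacts while classification
    still covers every voxel.
    """
    base = pmap.mask if within is None else (pmap.mask & within)
    v = np.where(base, pmap.values, np.nan)

    def shifted(ax, sh):
        out = np.full_like(v, np.nan)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        src[ax] = slice(None, -sh) if sh > 0 else slice(-sh, None)
        dst[ax] = slice(sh, None) if sh > 0 else slice(None, sh)
        out[tuple(dst)] = v[tuple(src)]
        return out

    diffs = [np.abs(v - shifted(ax, sh))
             for ax, sh in ((1, 1), (1, -1), (2, 1), (2, -1))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dmax = np.nanmax(np.stack(diffs), axis=0)
    med = np.nanmedian(dmax[base]) if np.any(base) else 0.0
    if not np.isfinite(med) or med == 0:
        return base
    return base & np.where(np.isfinite(dmax), dmax < factor * med, False)


# ----------------------------------------------------------------------
# composite quantification of one sample
# ----------------------------------------------------------------------

@dataclass
class SampleQuantification:
    """All clustering products of one sample."""

    map_three_class: TissueClassMap
    map_four_class: TissueClassMap
    map_fat_region: TissueClassMap
    partition: TissueClassMap
    total_fibrosis_map: TissueClassMap
    report: FractionReport
    models: Dict[str, GmmModel1D]
    tissue_mask: np.ndarray
    fat_region: np.ndarray
    reclassification_pct: float


def quantify_sample(
    t1_map: ParametricMap,
    fat_map: FatMap,
    seed: int = 0,
    ff_threshold="otsu",
    volume_slices_fibrosis: int = 3,
    volume_slices_fat: int = 5,
    gradient_screen: Optional[float] = 3.0,
    exclude_border: bool = True,
    fixed_models: Optional[Dict[str, Optional[GmmModel1D]]] = None,
) -> SampleQuantification:
    """Full tissue quantification of one sample from its T1 and fat maps.

    Steps: (1) four-class GMM over all fitted T1 values delimits PFA and
    yields the interstitial-fibrosis class; (2) the Dixon fat region is
    superimposed; (3) a three-class GMM over the fat-eliminated T1 values
    yields the total-fibrosis class (the three-class model assumes fat
    signal is absent, which fat saturation only approximates on rendered
    data); (4) a two-class GMM inside the fat region separates fat from
    fatty fibrosis; (5) the four-component partition (myocardium,
    interstitial fibrosis, fat, fatty fibrosis) is assembled — interstitial
    fibrosis inside the fat region counts as fatty — and total fibrosis is
    the union of the three-class fibrosis and fatty fibrosis.

    The 3- and 4-class mixtures are fitted on gradient-screened interior
    voxels (see :func:`interior_mask`) so that partial-volume bridge values
    between tissue modes cannot capture a component; every masked voxel is
    then classified under the fitted models.  ``fixed_models`` (keys
    "three-class", "four-class", "fat-region") skips the fitting and
    classifies under previously fitted mixtures — used when re-clustering
    resolution-degraded maps, whose sharp-core/partial-volume-halo histograms
    defeat unsupervised maximum-likelihood fitting.

    With ``exclude_border`` (default), tissue voxels touching the bath
    (PFA class, background or unfitted voxels) are excluded from the
    denominators and numerators — mirroring the usual exclusion of the
    specimen border from quantification — and fatty fibrosis is confined to
    the fat-region interior, since an elevated T1 on the region's rim
    reflects myocardial partial volume rather than septal fibrosis.
    """
    if t1_map.values.shape != fat_map.fat_fraction.shape:
        raise ValueError("t1 map and fat map must share geometry")

    if gradient_screen is not None:
        fit_sel = interior_mask(t1_map, gradient_screen)
    else:
        fit_sel = t1_map.mask
    if fixed_models is not None:
        model4 = fixed_models["four-class"]
    else:
        model4 = fit_gmm(t1_map.values[fit_sel], k=4, seed=seed,
                         outlier_uniform=True)
    roles4 = assign_roles(model4, "four-class")
    map4 = classify_map(t1_map, model4, roles4, provenance="four-class")
    tissue = t1_map.mask & ~map4.mask_of("pfa")
    if exclude_border:
        tissue = tissue & ~_adjacent_to(~tissue)

    region, thr = fat_region_mask(fat_map, tissue, ff_threshold)
    non_fat = t1_map.mask & ~region
    if fixed_models is not None:
        model3 = fixed_models["three-class"]
    else:
        model3 = fit_gmm(t1_map.values[non_fat & fit_sel], k=3, seed=seed,
                         outlier_uniform=True)
    roles3 = assign_roles(model3, "three-class")
    map3 = classify_map(t1_map, model3, roles3, within=non_fat,
                        provenance="three-class")

    fat_region_map = fatty_fibrosis_map(
        t1_map, fat_map, tissue=tissue, ff_threshold=thr, seed=seed,
        fixed_model=(fixed_models or {}).get("fat-region"))

    # four-component partition over tissue voxels
    part = np.zeros(t1_map.values.shape, dtype=np.uint8)
    part[tissue] = CLASS_CODES["myocardium"]
    part[tissue & map4.mask_of("interstitial_fibrosis")] = (
        CLASS_CODES["interstitial_fibrosis"])
    part[region & fat_region_map.mask_of("fat")] = CLASS_CODES["fat"]
    ffib_sel = region & fat_region_map.mask_of("fatty_fibrosis")
    if exclude_border:
        rim = region & _adjacent_to(tissue & ~region)
        part[ffib_sel & rim] = CLASS_CODES["fat"]
        ffib_sel = ffib_sel & ~rim
    part[ffib_sel] = (
        CLASS_CODES["fatty_fibrosis"])
    n_fatmix_outside = int(np.sum(map4.mask_of("fat_mixture") & tissue & ~region))
    if n_fatmix_outside:
        log.info("%d fat-mixture voxels outside the fat region counted as "
                 "myocardium", n_fatmix_outside)
    partition = TissueClassMap(labels=part, provenance="partition",
                               diagnostics={"ff_threshold": thr,
                                            "n_fatmix_outside": n_fatmix_outside})

    # total fibrosis = three-class fibrosis (non-fat region) + fatty fibrosis
    tot = np.zeros(t1_map.values.shape, dtype=np.uint8)
    tot_mask = (map3.mask_of("total_fibrosis") & tissue) | (
        partition.mask_of("fatty_fibrosis"))
    tot[tissue] = CLASS_CODES["myocardium"]
    tot[tot_mask] = CLASS_CODES["total_fibrosis"]
    total_map = TissueClassMap(labels=tot, provenance="total-fibrosis")

    report = fraction_report(
        partition, total_fibrosis_map=total_map,
        volume_slices_fibrosis=volume_slices_fibrosis,
        volume_slices_fat=volume_slices_fat,
    )
    recl = reclassification_rate(total_map, map4, mode="fibrosis")
    return SampleQuantification(
        map_three_class=map3,
        map_four_class=map4,
        map_fat_region=fat_region_map,
        partition=partition,
        total_fibrosis_map=total_map,
        report=report,
        models={"three-class": model3, "four-class": model4,
                "fat-region": fat_region_map.model},
        tissue_mask=tissue,
        fat_region=region,
        reclassification_pct=recl,
    )
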