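"""Two-point Dixon fat-water separation.

Computes per-voxel fat fraction FF = (IP − OP)/(2·IP) from in-phase and
opposed-phase magnitude images, optionally after dividing both magnitudes by
exp(−TE/T2*) voxel-wise (shared-T2* decay correction), and aggregates fat
fractions per slice and per volume.

Magnitude Dixon cannot distinguish water from fat dominance: swapping W and F
leaves the magnitudes unchanged, so the raw fat fraction lives in [0, 0.5].
Fold-over is not resolved by default; an optional dominance flip is provided
for callers that know the fat-dominant voxels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .containers import ImageSeries, NoiseEstimate, ParametricMap, check_same_geometry

log = logging.getLogger(__name__)


@dataclass
class FatMap:
    """Per-voxel fat fraction (dimensionless) and water signal map."""

    fat_fraction: np.ndarray
    water: np.ndarray
    mask: np.ndarray
    t2star_corrected: bool
    diagnostics: dict = field(default_factory=dict)
    pixel_um: Optional[float] = None
    slice_mm: Optional[float] = None

    def __post_init__(self) -> None:
        ff = self.fat_fraction[self.mask]
        if ff.size and (np.any(ff < 0) or np.any(ff > 1)):
            raise ValueError("masked fat fractions must lie in [0, 1]")
        if np.any(self.water[self.mask] < 0):
            raise ValueError("water map must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.fat_fraction.shape


def in_phase_deviation_cycles(te_ms: float, chemical_shift_hz: float) -> float:
    """Distance (in cycles) of the fat-water phase at ``te_ms`` from the
    nearest in-phase condition."""
    cycles = chemical_shift_hz * te_ms * 1e-3
    return float(np.abs(cycles - np.round(cycles)))


def split_echoes(series: ImageSeries) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Pick the first in-phase / opposed-phase echo pair of a multi-echo stack.

    Echoes are classified by the fat-water phase Δf·TE: nearest to an integer
    number of cycles → in-phase, nearest to a half-integer → opposed.
    Returns (ip_image, op_image, te_ip, te_op).
    """
    te = series.schedule.times
    cycles = series.schedule.chemical_shift_hz * te * 1e-3
    frac = np.abs(cycles - np.round(cycles))
    ip_candidates = np.flatnonzero(frac <= 0.25)
    op_candidates = np.flatnonzero(frac > 0.25)
    if ip_candidates.size == 0 or op_candidates.size == 0:
        raise ValueError("series lacks an in-phase/opposed-phase echo pair")
    i, o = int(ip_candidates[0]), int(op_candidates[0])
    return series.data[..., i], series.data[..., o], float(te[i]), float(te[o])


def compute_fat_fraction_map(
    ip: np.ndarray,
    op: np.ndarray,
    te_ip_ms: float,
    te_op_ms: float,
    t2star: Optional[ParametricMap] = None,
    noise: Optional[NoiseEstimate] = None,
    min_ip: Optional[float] = None,
    chemical_shift_hz: float = 600.0,
    in_phase_tol_cycles: float = 0.05,
    pixel_um: Optional[float] = None,
    slice_mm: Optional[float] = None,
) -> FatMap:
    """Fat-fraction map FF = (IP − OP)/(2·IP) with optional T2* correction.

    When ``t2star`` is given, IP and OP are first divided by exp(−TE/T2*)
    voxel-wise (same T2* assumed for fat and water).  Voxels with corrected
    IP below ``min_ip`` (default 5σ) are masked out — the fat fraction
    divides by IP.  Negative fat fractions (noise) are clipped to 0 and
    counted.
    """
    ip = np.asarray(ip, dtype=float)
    op = np.asarray(op, dtype=float)
    if ip.shape != op.shape:
        raise ValueError(f"geometry mismatch: IP {ip.shape} vs OP {op.shape}")
    if te_op_ms <= te_ip_ms:
        raise ValueError("te_op must exceed te_ip")
    dev = in_phase_deviation_cycles(te_ip_ms, chemical_shift_hz)
    if dev > in_phase_tol_cycles:
        warnings.warn(
            f"te_ip={te_ip_ms} ms is {dev:.3f} cycles away from an in-phase "
            "condition for the configured chemical shift", stacklevel=2)

    if min_ip is None:
        min_ip = 5.0 * noise.sigma if noise is not None else 0.0

    if t2star is not None:
        check_same_geometry(t2star.values, ip, "t2star map and IP image")
        decay_ip = np.ones_like(ip)
        decay_op = np.ones_like(op)
        m = t2star.mask
        decay_ip[m] = np.exp(-te_ip_ms / t2star.values[m])
        decay_op[m] = np.exp(-te_op_ms / t2star.values[m])
        ip_c = ip / decay_ip
        op_c = op / decay_op
    else:
        ip_c, op_c = ip, op

    mask = ip_c > max(min_ip, 1e-300)
    ff = np.full(ip.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ff[mask] = (ip_c[mask] - op_c[mask]) / (2.0 * ip_c[mask])
    n_neg = int(np.sum(ff[mask] < 0))
    ff[mask] = np.clip(ff[mask], 0.0, 1.0)
    water = np.where(mask, 0.5 * (ip_c + op_c), np.nan)
    if n_neg:
        log.info("fat-fraction map: clipped %d negative voxels to 0", n_neg)
    return FatMap(
        fat_fraction=ff,
        water=water,
        mask=mask,
        t2star_corrected=t2star is not None,
        diagnostics={
            "n_negative_clipped": n_neg,
            "te_ip_ms": te_ip_ms,
            "te_op_ms": te_op_ms,
            "min_ip": float(min_ip),
            "in_phase_deviation_cycles": dev,
        },
        pixel_um=pixel_um,
        slice_mm=slice_mm,
    )


def fat_volume_fraction(
    fat_map: FatMap,
    tissue_mask: np.ndarray,
    weighted: bool = False,
) -> Tuple[np.ndarray, float]:
    """Per-slice mean fat fraction over tissue voxels (in %) and its
    across-slice average (the fat volume fraction).

    ``weighted=False`` (default) averages the per-slice percentages with
    equal weight; ``weighted=True`` weights by per-slice tissue voxel count.
    Slices without tissue voxels are skipped with a warning.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    check_same_geometry(fat_map.fat_fraction, tissue_mask, "fat map and mask")
    n_slices = fat_map.fat_fraction.shape[0]
    per_slice = np.full(n_slices, np.nan)
    counts = np.zeros(n_slices, dtype=int)
    for s in range(n_slices):
        sel = tissue_mask[s] & fat_map.mask[s]
        counts[s] = sel.sum()
        if counts[s] == 0:
            warnings.warn(f"slice {s} has no tissue voxels; skipped",
                          stacklevel=2)
            continue
        per_slice[s] = 100.0 * float(np.mean(fat_map.fat_fraction[s][sel]))
    ok = np.isfinite(per_slice)
    if not np.any(ok):
        raise ValueError("no slice contains tissue voxels")
    if weighted:
        volume = float(np.average(per_slice[ok], weights=counts[ok]))
    else:
        volume = float(np.mean(per_slice[ok]))
    return per_slice, volume


def resolve_dominance(fat_map: FatMap, fat_dominant: np.ndarray) -> FatMap:
    """Unfold the raw magnitude fat fraction for voxels flagged fat-dominant
    (FF → 1 − FF).  Magnitude Dixon alone cannot provide this flag; it must
    come from outside knowledge (e.g. a low T1)."""
    ff = fat_map.fat_fraction.copy()
    sel = np.asarray(fat_dominant, dtype=bool) & fat_map.mask
    ff[sel] = 1.0 - ff[sel]
    return FatMap(
        fat_fraction=ff,
        water=fat_map.water,
        mask=fat_map.mask,
        t2star_corrected=fat_map.t2star_corrected,
        diagnostics={**fat_map.diagnostics, "dominance_resolved": True},
        pixel_um=fat_map.pixel_um,
        slice_mm=fat_map.slice_mm,
    )
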