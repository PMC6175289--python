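"""Shared data containers for image series and parametric maps.

Arrays follow the internal axis convention ``(slice, row, col[, time])``.
In-plane pixel size is carried in micrometres and slice thickness in
millimetres, matching the acquisition geometry they emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Acquisition kinds understood by the fitting routines.
KIND_SR_TR = "saturation-recovery-TR"
KIND_ME_TE = "multi-echo-TE"


@dataclass
class AcquisitionSchedule:
    """Timing axis of a magnitude image series.

    Parameters
    ----------
    kind:
        ``"saturation-recovery-TR"`` (times are repetition delays in seconds)
        or ``"multi-echo-TE"`` (times are echo times in milliseconds).
    times:
        Strictly increasing delays, at least two of them.
    fat_saturation:
        Whether a fat-suppression pulse is applied (T1 series only).
    chemical_shift_hz:
        Fat-water chemical shift used by gradient-echo (Dixon) rendering.
    """

    kind: str
    times: np.ndarray
    fat_saturation: bool = False
    chemical_shift_hz: float = 600.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.kind not in (KIND_SR_TR, KIND_ME_TE):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("schedule needs at least 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("schedule times must be strictly increasing")
        if self.chemical_shift_hz <= 0:
            raise ValueError("chemical_shift_hz must be > 0")

    @property
    def units(self) -> str:
        return "s" if self.kind == KIND_SR_TR else "ms"

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "times": [float(t) for t in self.times],
            "units": self.units,
            "fat_saturation": bool(self.fat_saturation),
            "chemical_shift_hz": float(self.chemical_shift_hz),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSchedule":
        return cls(
            kind=d["kind"],
            times=np.asarray(d["times"], dtype=float),
            fat_saturation=bool(d.get("fat_saturation", False)),
            chemical_shift_hz=float(d.get("chemical_shift_hz", 600.0)),
        )


@dataclass
class ImageSeries:
    """Magnitude voxel stack with its acquisition schedule and geometry.

    ``data`` has shape ``(n_slices, n_rows, n_cols, n_times)`` and holds
    non-negative magnitudes.
    """

    data: np.ndarray
    schedule: AcquisitionSchedule
    pixel_um: float
    slice_mm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("ImageSeries data must be 4-D (slice,row,col,time)")
        if self.data.shape[-1] != self.schedule.times.size:
            raise ValueError("time axis length must equal schedule length")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class ParametricMap:
    """Per-voxel scalar map (T1, T2, T2*, ...) with mask and fit diagnostics.

    ``values`` and ``mask`` share shape ``(n_slices, n_rows, n_cols)``;
    ``values`` is finite and positive wherever ``mask`` is true and NaN
    elsewhere.  ``diagnostics`` holds per-voxel arrays (nuisance parameters,
    residual norm, convergence flag) plus scalar counters.
    """

    values: np.ndarray
    mask: np.ndarray
    unit: str
    diagnostics: dict = field(default_factory=dict)
    pixel_um: Optional[float] = None
    slice_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share shape")
        masked = self.values[self.mask]
        if masked.size and not (np.all(np.isfinite(masked)) and np.all(masked > 0)):
            raise ValueError("masked values must be finite and > 0")

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class NoiseEstimate:
    """Rician noise scale estimated from background magnitudes."""

    sigma: float
    n_background_voxels: int
    method: str

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def check_same_geometry(a, b, what: str = "inputs") -> None:
    """Raise if two array-bearing objects differ in spatial shape."""
    sa = a.shape[:3] if hasattr(a, "shape") else None
    sb = b.shape[:3] if hasattr(b, "shape") else None
    if sa != sb:
        raise ValueError(f"geometry mismatch between {what}: {sa} vs {sb}")
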