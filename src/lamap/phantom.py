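"""Digital left-atrial tissue phantoms.

Generates ground-truth labelled samples on a supersampled grid and renders
the three magnitude series the pipeline consumes — a fat-saturated
saturation-recovery T1 stack, a multi-echo gradient-echo (Dixon) stack and a
multi-echo spin-echo stack — with in-plane partial volume (block averaging of
supersampled cells onto the acquisition grid) and Rician magnitude noise.

The sample is a myocardial ellipse holding fibrotic patches and strands, fat
lobules crossed by fatty-fibrosis septa, surrounded by a paraformaldehyde
(PFA) rim and immersed in a proton-free fluorinert bath (background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .containers import (
    KIND_ME_TE,
    KIND_SR_TR,
    AcquisitionSchedule,
    ImageSeries,
)

# Fixed, closed tissue vocabulary.
BACKGROUND = 0
PFA = 1
MYOCARDIUM = 2
INTERSTITIAL_FIBROSIS = 3
FAT = 4
FATTY_FIBROSIS = 5

LABEL_NAMES: Dict[int, str] = {
    BACKGROUND: "background",
    PFA: "pfa",
    MYOCARDIUM: "myocardium",
    INTERSTITIAL_FIBROSIS: "interstitial_fibrosis",
    FAT: "fat",
    FATTY_FIBROSIS: "fatty_fibrosis",
}
TISSUE_LABELS = (MYOCARDIUM, INTERSTITIAL_FIBROSIS, FAT, FATTY_FIBROSIS)
ALL_LABELS = tuple(sorted(LABEL_NAMES))


@dataclass
class TissueParams:
    """Relaxation and composition parameters of one tissue.

    ``t1_ms``/``t2_ms``/``t2star_ms`` are longitudinal/transverse/effective
    transverse relaxation times, ``pd`` a proton density in arbitrary units
    and ``fat_fraction`` the intravoxel lipid-proton fraction in [0, 1].
    """

    t1_ms: float
    t2_ms: float
    t2star_ms: float
    pd: float
    fat_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.t1_ms, self.t2_ms, self.t2star_ms) <= 0:
            raise ValueError("relaxation times must be > 0")
        if self.pd < 0:
            raise ValueError("proton density must be >= 0")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError("fat_fraction must be in [0, 1]")


def default_tissue_params() -> Dict[int, TissueParams]:
    """Study-condition tissue parameters.

    Myocardial and fibrotic T1 follow the reported ex vivo values (962 and
    1131 ms).  Fat T1 (350 ms), PFA T1 (2000 ms) and all T2/T2* values are
    explicit assumptions: only the T1 ordering fat < myocardium < fibrosis
    < PFA matters downstream.  The bath T1 is kept within reach of the
    longest repetition delay (6.5 s) so that its per-voxel estimates stay
    tight and near-Gaussian; a much longer bath T1 is so poorly constrained
    by the acquisition that its estimate distribution dominates the T1
    histogram's tails.  Adipose tissue carries a 0.45 intravoxel fat
    fraction and fatty fibrosis 0.30, keeping every voxel water-dominant so
    that two-point magnitude Dixon is single-valued.
    """
    return {
        BACKGROUND: TissueParams(1.0, 1.0, 1.0, 0.0, 0.0),
        PFA: TissueParams(2000.0, 300.0, 150.0, 1000.0, 0.0),
        MYOCARDIUM: TissueParams(962.0, 40.0, 25.0, 1000.0, 0.0),
        INTERSTITIAL_FIBROSIS: TissueParams(1131.0, 50.0, 30.0, 1000.0, 0.0),
        FAT: TissueParams(350.0, 60.0, 35.0, 1000.0, 0.45),
        FATTY_FIBROSIS: TissueParams(1100.0, 50.0, 30.0, 1000.0, 0.30),
    }


@dataclass
class GeometryConfig:
    """Sizes and area targets of the synthetic microstructure.

    Area targets are percentages of the tissue (non-PFA, non-background)
    cross-section.  Structure sizes are physical (µm/mm) so the same
    geometry renders consistently at any grid size.
    """

    bath_margin_mm: float = 1.0  # PFA rim thickness
    target_interstitial_pct: float = 10.0
    target_fat_pct: float = 15.0
    target_fatty_pct: float = 4.0
    n_patches: int = 2  # confluent fibrotic patches (stay resolved at 2 mm)
    patch_area_share: float = 0.6  # share of interstitial target in patches
    patch_axes_mm: tuple = (2.5, 4.5)  # semi-axis range of patches
    strand_width_um: tuple = (400.0, 600.0)
    strand_length_mm: tuple = (3.0, 8.0)
    lobule_radius_um: tuple = (1000.0, 1800.0)
    septum_width_um: float = 500.0


@dataclass
class PhantomSpec:
    """Full description of a digital sample and its acquisition geometry."""

    grid_rows: int = 96
    grid_cols: int = 192
    n_slices: int = 5
    pixel_um: float = 200.0
    slice_mm: float = 1.0
    supersample: int = 10
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    tissue_params: Dict[int, TissueParams] = field(default_factory=default_tissue_params)
    noise_sigma: float = 0.0  # Rician scale relative to the peak clean signal
    fat_sat_residual: float = 0.0  # residual lipid signal under fat saturation
    saturation_b: float = 1.0  # saturation-efficiency factor B of the recovery
    seed: int = 0

    def __post_init__(self) -> None:
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if min(self.grid_rows, self.grid_cols, self.n_slices) < 1:
            raise ValueError("grid dimensions must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class LabelVolume:
    """Integer tissue code per supersampled cell per slice."""

    labels: np.ndarray  # (n_slices, rows*ss, cols*ss) uint8
    supersample: int
    cell_um: float
    slice_mm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D (slice, row, col)")
        bad = set(np.unique(self.labels)) - set(ALL_LABELS)
        if bad:
            raise ValueError(f"unknown tissue codes {sorted(bad)}")

    @property
    def code_table(self) -> Dict[int, str]:
        return dict(LABEL_NAMES)


# ----------------------------------------------------------------------
# label map construction
# ----------------------------------------------------------------------

def _ellipse_mask(rr, cc, center, semi_axes):
    r0, c0 = center
    ar, ac = semi_axes
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def _paint_until(target_cells, paint_candidates, labels, code, allowed):
    """Paint candidate cells (boolean mask) over ``allowed`` labels, stopping
    mid-structure once ``target_cells`` is reached.  Returns cells painted."""
    sel = paint_candidates & np.isin(labels, allowed)
    idx = np.flatnonzero(sel.ravel())
    if idx.size == 0:
        return 0
    take = idx[: max(0, target_cells)] if target_cells < idx.size else idx
    labels.ravel()[take] = code
    return take.size


def build_label_map(spec: PhantomSpec) -> LabelVolume:
    """Generate the supersampled ground-truth label volume.

    The tissue ellipse is surrounded by a PFA rim inside a fluorinert bath.
    Fat lobules (with fatty-fibrosis septa) are painted first, then large
    interstitial patches and thin strands over the remaining myocardium,
    each component painted until its area target is met (±1 cell row).
    """
    g = spec.geometry
    ss = spec.supersample
    cell_um = spec.pixel_um / ss
    nr, nc = spec.grid_rows * ss, spec.grid_cols * ss
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xFA17]))

    rr, cc = np.mgrid[0:nr, 0:nc].astype(float)
    center = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    bath_cells = g.bath_margin_mm * 1000.0 / cell_um

    # Outer (PFA) ellipse nearly fills the grid; tissue ellipse sits inside it.
    outer = (0.5 * nr * 0.94, 0.5 * nc * 0.94)
    tissue_axes = (outer[0] - bath_cells, outer[1] - bath_cells)
    if min(tissue_axes) <= 2:
        raise ValueError("bath margin leaves no room for tissue in this grid")

    slices = []
    for s in range(spec.n_slices):
        jit = 1.0 + 0.03 * rng.uniform(-1, 1, size=2)
        ax = (tissue_axes[0] * jit[0], tissue_axes[1] * jit[1])
        labels = np.zeros((nr, nc), dtype=np.uint8)
        labels[_ellipse_mask(rr, cc, center, outer)] = PFA
        tissue = _ellipse_mask(rr, cc, center, ax)
        labels[tissue] = MYOCARDIUM
        n_tissue = int(tissue.sum())

        # --- fat lobules (sized for fat + the septa carved out of them) ---
        fat_target = int(round(
            (g.target_fat_pct + g.target_fatty_pct) / 100.0 * n_tissue))
        lobules = []
        guard = 0
        while fat_target > 0 and labels[tissue].size and guard < 500:
            guard += 1
            painted = int(np.sum(labels == FAT))
            remaining = fat_target - painted
            if remaining <= 0:
                break
            r_um = rng.uniform(*g.lobule_radius_um)
            r_cells = r_um / cell_um
            if remaining < np.pi * r_cells**2:
                r_cells = max(2.0, np.sqrt(remaining / np.pi))
            if 2 * r_cells > min(ax):
                raise ValueError(
                    "lobule radius exceeds the tissue extent; shrink "
                    "lobule_radius_um or enlarge the grid"
                )
            theta = rng.uniform(0, 2 * np.pi)
            rho = np.sqrt(rng.uniform(0, 1)) * 0.80
            cr = center[0] + rho * (ax[0] - r_cells) * np.sin(theta)
            cx = center[1] + rho * (ax[1] - r_cells) * np.cos(theta)
            disc = (rr - cr) ** 2 + (cc - cx) ** 2 <= r_cells**2
            n = _paint_until(remaining, disc & tissue, labels, FAT, (MYOCARDIUM,))
            if n:
                lobules.append((cr, cx, r_cells))
        # random placement can saturate in crowded tissue: grow the
        # existing lobules outward until the target is met
        guard = 0
        while guard < 200:
            guard += 1
            remaining = fat_target - int(np.sum(labels == FAT))
            if remaining <= 0 or not lobules:
                break
            fat_mask = labels == FAT
            ring = np.zeros_like(fat_mask)
            ring[1:, :] |= fat_mask[:-1, :]
            ring[:-1, :] |= fat_mask[1:, :]
            ring[:, 1:] |= fat_mask[:, :-1]
            ring[:, :-1] |= fat_mask[:, 1:]
            if _paint_until(remaining, ring & tissue, labels, FAT,
                            (MYOCARDIUM,)) == 0:
                break

        # --- fatty-fibrosis septa through lobules -------------------------
        fatty_target = int(round(g.target_fatty_pct / 100.0 * n_tissue))
        w_cells = g.septum_width_um / cell_um
        guard = 0
        while fatty_target > 0 and lobules and guard < 200:
            guard += 1
            painted = int(np.sum(labels == FATTY_FIBROSIS))
            remaining = fatty_target - painted
            if remaining <= 0:
                break
            cr, cx, r_cells = lobules[rng.integers(len(lobules))]
            ang = rng.uniform(0, np.pi)
            off = rng.uniform(-0.5, 0.5) * r_cells
            d = np.abs((rr - cr) * np.sin(ang) - (cc - cx) * np.cos(ang) - off)
            band = d <= w_cells / 2.0
            if _paint_until(remaining, band, labels, FATTY_FIBROSIS, (FAT,)) == 0:
                continue
        if fatty_target > 0 and np.sum(labels == FATTY_FIBROSIS) < 0.8 * fatty_target:
            warnings.warn(
                "fatty-fibrosis target not reachable within the fat lobules",
                stacklevel=2,
            )

        # --- interstitial fibrosis: patches then strands ------------------
        int_target = int(round(g.target_interstitial_pct / 100.0 * n_tissue))
        patch_target = int(round(int_target * g.patch_area_share))
        guard = 0
        for _ in range(g.n_patches * 4):
            painted = int(np.sum(labels == INTERSTITIAL_FIBROSIS))
            if painted >= patch_target:
                break
            a = rng.uniform(*g.patch_axes_mm) * 1000.0 / cell_um
            b = rng.uniform(*g.patch_axes_mm) * 1000.0 / cell_um
            theta = rng.uniform(0, 2 * np.pi)
            rho = np.sqrt(rng.uniform(0, 1)) * 0.7
            cr = center[0] + rho * ax[0] * np.sin(theta)
            cx = center[1] + rho * ax[1] * np.cos(theta)
            patch = _ellipse_mask(rr, cc, (cr, cx), (a, b))
            _paint_until(
                patch_target - painted, patch, labels, INTERSTITIAL_FIBROSIS,
                (MYOCARDIUM,),
            )
        guard = 0
        while guard < 300:
            guard += 1
            painted = int(np.sum(labels == INTERSTITIAL_FIBROSIS))
            remaining = int_target - painted
            if remaining <= 0:
                break
            w = rng.uniform(*g.strand_width_um) / cell_um
            length = rng.uniform(*g.strand_length_mm) * 1000.0 / cell_um
            ang = rng.uniform(0, np.pi)
            theta = rng.uniform(0, 2 * np.pi)
            rho = np.sqrt(rng.uniform(0, 1)) * 0.85
            cr = center[0] + rho * ax[0] * np.sin(theta)
            cx = center[1] + rho * ax[1] * np.cos(theta)
            d_perp = np.abs((rr - cr) * np.sin(ang) - (cc - cx) * np.cos(ang))
            d_par = np.abs((rr - cr) * np.cos(ang) + (cc - cx) * np.sin(ang))
            strand = (d_perp <= w / 2.0) & (d_par <= length / 2.0)
            _paint_until(remaining, strand, labels, INTERSTITIAL_FIBROSIS,
                         (MYOCARDIUM,))

        slices.append(labels)

    return LabelVolume(
        labels=np.stack(slices),
        supersample=ss,
        cell_um=cell_um,
        slice_mm=spec.slice_mm,
    )


# ----------------------------------------------------------------------
# ground-truth fractions
# ----------------------------------------------------------------------

def ground_truth_fractions(labels: LabelVolume) -> pd.DataFrame:
    """Per-slice and whole-volume tissue percentages from label counts.

    Percentages are relative to tissue cells (background and PFA excluded);
    total fibrosis = interstitial + fatty.  The returned frame has one row
    per slice plus a ``volume`` row (mean of the per-slice values).
    """
    rows = []
    for s in range(labels.labels.shape[0]):
        counts = np.bincount(labels.labels[s].ravel(), minlength=6)
        n_tissue = counts[list(TISSUE_LABELS)].sum()
        if n_tissue == 0:
            raise ValueError(f"slice {s} contains zero tissue cells")
        pct = {LABEL_NAMES[l]: 100.0 * counts[l] / n_tissue for l in TISSUE_LABELS}
        pct["total_fibrosis"] = (
            pct["interstitial_fibrosis"] + pct["fatty_fibrosis"]
        )
        pct["n_tissue_cells"] = n_tissue
        rows.append(pd.Series(pct, name=f"slice_{s}"))
    frame = pd.DataFrame(rows)
    vol = frame.mean(axis=0)
    vol["n_tissue_cells"] = frame["n_tissue_cells"].sum()
    frame.loc["volume"] = vol
    return frame


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def label_fractions(labels: LabelVolume) -> np.ndarray:
    """Per-acquisition-voxel composition: shape (S, R, C, n_labels)."""
    ss = labels.supersample
    S, nr, nc = labels.labels.shape
    R, C = nr // ss, nc // ss
    lab = labels.labels.reshape(S, R, ss, C, ss)
    return np.stack(
        [(lab == code).mean(axis=(2, 4)) for code in ALL_LABELS], axis=-1
    )


def _require_params(spec: PhantomSpec, labels: LabelVolume) -> None:
    present = np.unique(labels.labels)
    for code in present:
        if int(code) not in spec.tissue_params:
            raise ValueError(
                f"missing tissue parameters for label "
                f"{LABEL_NAMES.get(int(code), code)!r}"
            )


def _apply_rician_noise(clean: np.ndarray, spec: PhantomSpec,
                        stream: int) -> np.ndarray:
    """Add Rician noise: two independent Gaussian channels on the complex
    signal (real part = clean magnitude), applied after block averaging."""
    mag = np.abs(clean)
    if spec.noise_sigma == 0:
        return mag
    sigma = spec.noise_sigma * mag.max()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))
    g1 = rng.standard_normal(mag.shape)
    g2 = rng.standard_normal(mag.shape)
    if np.iscomplexobj(clean):
        return np.hypot(clean.real + sigma * g1, clean.imag + sigma * g2)
    return np.hypot(mag + sigma * g1, sigma * g2)


def _render(labels, spec, table, stream, schedule, note) -> ImageSeries:
    frac = label_fractions(labels)  # (S,R,C,L)
    clean = frac @ table  # block average in (complex) signal domain
    noisy = _apply_rician_noise(clean, spec, stream)
    return ImageSeries(
        data=noisy,
        schedule=schedule,
        pixel_um=spec.pixel_um,
        slice_mm=labels.slice_mm,
        provenance=note,
    )


def render_t1_series(labels: LabelVolume, spec: PhantomSpec,
                     schedule: AcquisitionSchedule) -> ImageSeries:
    """Saturation-recovery series S(t) = PD·f_sat·(1 − B·exp(−t/T1)).

    Under fat saturation each cell's intravoxel lipid fraction is scaled by
    ``spec.fat_sat_residual`` (default 0), so adipose cells keep only their
    residual-water signal.  Cells are block-averaged onto the acquisition
    grid before Rician noise is applied.
    """
    if schedule.kind != KIND_SR_TR:
        raise ValueError("render_t1_series needs a saturation-recovery schedule")
    _require_params(spec, labels)
    t = schedule.times[None, :]  # s
    rows = []
    for code in ALL_LABELS:
        p = spec.tissue_params[code]
        f_sat = 1.0
        if schedule.fat_saturation:
            f_sat = (1.0 - p.fat_fraction) + p.fat_fraction * spec.fat_sat_residual
        rows.append(
            p.pd * f_sat * (1.0 - spec.saturation_b * np.exp(-t * 1000.0 / p.t1_ms))
        )
    table = np.vstack(rows)
    return _render(labels, spec, table, 0x71, schedule, "saturation-recovery T1")


def render_dixon_series(labels: LabelVolume, spec: PhantomSpec,
                        schedule: AcquisitionSchedule) -> ImageSeries:
    """Multi-echo gradient-echo series with fat-water chemical shift.

    Per cell the complex signal is (W + F·e^{i·2π·Δf·TE})·e^{−TE/T2*} with
    W, F from proton density and intravoxel fat fraction; cells are averaged
    in the complex domain, then magnitude and Rician noise.
    """
    if schedule.kind != KIND_ME_TE:
        raise ValueError("render_dixon_series needs a multi-echo schedule")
    _require_params(spec, labels)
    te_ms = schedule.times[None, :]
    phase = np.exp(2j * np.pi * schedule.chemical_shift_hz * te_ms * 1e-3)
    rows = []
    for code in ALL_LABELS:
        p = spec.tissue_params[code]
        w, f = p.pd * (1.0 - p.fat_fraction), p.pd * p.fat_fraction
        rows.append((w + f * phase) * np.exp(-te_ms / p.t2star_ms))
    table = np.vstack(rows)
    return _render(labels, spec, table, 0xD1, schedule, "multi-echo gradient echo")


def render_msme_series(labels: LabelVolume, spec: PhantomSpec,
                       schedule: AcquisitionSchedule) -> ImageSeries:
    """Multi-slice multi-echo spin-echo series S(TE) = PD·exp(−TE/T2)."""
    if schedule.kind != KIND_ME_TE:
        raise ValueError("render_msme_series needs a multi-echo schedule")
    _require_params(spec, labels)
    te_ms = schedule.times[None, :]
    rows = []
    for code in ALL_LABELS:
        p = spec.tissue_params[code]
        rows.append(p.pd * np.exp(-te_ms / p.t2_ms))
    table = np.vstack(rows)
    return _render(labels, spec, table, 0x52, schedule, "multi-echo spin echo")


# canonical acquisition schedules ---------------------------------------

#: Repetition-delay array of the saturation-recovery acquisition (s).
T1_TR_ARRAY_S = np.array([0.15, 0.25, 0.4, 0.65, 1.0, 1.5, 2.5, 4.0, 6.5])
#: Echo times of the dual/tri-echo gradient-echo acquisition (ms).
DIXON_TE_MS = np.array([3.356, 4.194, 5.033])


def default_t1_schedule(fat_saturation: bool = True) -> AcquisitionSchedule:
    return AcquisitionSchedule(KIND_SR_TR, T1_TR_ARRAY_S.copy(),
                               fat_saturation=fat_saturation)


def default_dixon_schedule(chemical_shift_hz: float = 600.0) -> AcquisitionSchedule:
    return AcquisitionSchedule(KIND_ME_TE, DIXON_TE_MS.copy(),
                               chemical_shift_hz=chemical_shift_hz)


def default_msme_schedule(n_echoes: int = 48,
                          spacing_ms: float = 5.0) -> AcquisitionSchedule:
    te = spacing_ms * np.arange(1, n_echoes + 1)
    return AcquisitionSchedule(KIND_ME_TE, te)
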