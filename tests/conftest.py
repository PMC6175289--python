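"""Shared fixtures: small, quickly rendered phantoms."""

import numpy as np
import pytest

from lamap import phantom as ph
from lamap import pipeline as pl


def small_geometry(**overrides) -> ph.GeometryConfig:
    """Microstructure scaled down to fit a 32×64 test grid."""
    kwargs = dict(
        bath_margin_mm=0.6,
        target_interstitial_pct=10.0,
        target_fat_pct=12.0,
        target_fatty_pct=3.0,
        n_patches=1,
        patch_axes_mm=(0.7, 1.2),
        strand_width_um=(300.0, 400.0),
        strand_length_mm=(1.5, 3.0),
        lobule_radius_um=(500.0, 800.0),
        septum_width_um=300.0,
    )
    kwargs.update(overrides)
    return ph.GeometryConfig(**kwargs)


def small_spec(**overrides) -> ph.PhantomSpec:
    kwargs = dict(
        grid_rows=32,
        grid_cols=64,
        n_slices=2,
        supersample=4,
        geometry=small_geometry(),
        noise_sigma=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return ph.PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_labels():
    return ph.build_label_map(small_spec())


@pytest.fixture(scope="session")
def noisy_small_sample():
    """Rendered small phantom at SNR 40 with all three series."""
    spec = small_spec(noise_sigma=1.0 / 40.0, n_slices=3, seed=3)
    return pl.render_sample(
        spec,
        msme_schedule=ph.default_msme_schedule(16, 8.0),
    )
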