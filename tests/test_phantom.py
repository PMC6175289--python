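"""Phantom generation: label maps, ground truth and forward rendering."""

import numpy as np
import pytest

from lamap import phantom as ph
from lamap.containers import AcquisitionSchedule

from conftest import small_geometry, small_spec


# ----------------------------------------------------------------------
# label map construction
# ----------------------------------------------------------------------

def test_empty_geometry_yields_only_bath_and_myocardium():
    spec = small_spec(geometry=small_geometry(
        target_interstitial_pct=0, target_fat_pct=0, target_fatty_pct=0,
        n_patches=0))
    labels = ph.build_label_map(spec)
    present = set(np.unique(labels.labels))
    assert present == {ph.BACKGROUND, ph.PFA, ph.MYOCARDIUM}


def test_area_targets_met_within_one_percent():
    spec = small_spec(geometry=small_geometry(
        target_interstitial_pct=15.0, target_fat_pct=20.0,
        target_fatty_pct=4.0))
    truth = ph.ground_truth_fractions(ph.build_label_map(spec))
    vol = truth.loc["volume"]
    assert vol["interstitial_fibrosis"] == pytest.approx(15.0, abs=1.0)
    assert vol["fat"] == pytest.approx(20.0, abs=1.0)
    assert vol["fatty_fibrosis"] == pytest.approx(4.0, abs=1.0)


def test_label_map_deterministic_for_same_seed():
    a = ph.build_label_map(small_spec(seed=7))
    b = ph.build_label_map(small_spec(seed=7))
    assert np.array_equal(a.labels, b.labels)
    c = ph.build_label_map(small_spec(seed=8))
    assert not np.array_equal(a.labels, c.labels)


def test_oversized_lobule_raises():
    spec = small_spec(geometry=small_geometry(
        lobule_radius_um=(20000.0, 30000.0), target_fat_pct=30.0))
    with pytest.raises(ValueError, match="lobule"):
        ph.build_label_map(spec)


# ----------------------------------------------------------------------
# ground-truth fractions
# ----------------------------------------------------------------------

def _slab(codes_per_col, n_rows=4):
    """1-slice label volume with given label per column."""
    arr = np.tile(np.asarray(codes_per_col, dtype=np.uint8),
                  (1, n_rows, 1))
    return ph.LabelVolume(labels=arr, supersample=1, cell_um=200.0,
                          slice_mm=1.0)


def test_fraction_trivial_cases():
    all_myo = _slab([ph.MYOCARDIUM] * 8)
    f = ph.ground_truth_fractions(all_myo)
    assert f.loc["slice_0", "myocardium"] == 100.0
    assert f.loc["slice_0", "total_fibrosis"] == 0.0

    half = _slab([ph.MYOCARDIUM] * 4 + [ph.FAT] * 4)
    f = ph.ground_truth_fractions(half)
    assert f.loc["slice_0", "fat"] == 50.0


def test_fractions_match_bincount_oracle_and_sum_to_100():
    rng = np.random.default_rng(0)
    arr = rng.choice([ph.PFA, ph.MYOCARDIUM, ph.INTERSTITIAL_FIBROSIS,
                      ph.FAT, ph.FATTY_FIBROSIS], size=(3, 10, 12)).astype(np.uint8)
    vol = ph.LabelVolume(labels=arr, supersample=1, cell_um=200.0, slice_mm=1.0)
    frame = ph.ground_truth_fractions(vol)
    for s in range(3):
        sl = arr[s]
        n_tissue = np.sum(sl != ph.PFA)
        for code, name in [(ph.MYOCARDIUM, "myocardium"), (ph.FAT, "fat"),
                           (ph.INTERSTITIAL_FIBROSIS, "interstitial_fibrosis"),
                           (ph.FATTY_FIBROSIS, "fatty_fibrosis")]:
            expected = 100.0 * np.sum(sl == code) / n_tissue
            assert frame.loc[f"slice_{s}", name] == pytest.approx(expected)
        comp_sum = frame.loc[f"slice_{s}",
                             ["myocardium", "interstitial_fibrosis",
                              "fat", "fatty_fibrosis"]].sum()
        assert comp_sum == pytest.approx(100.0, abs=1e-9)


def test_all_bath_volume_raises():
    vol = _slab([ph.PFA] * 6)
    with pytest.raises(ValueError, match="zero tissue"):
        ph.ground_truth_fractions(vol)


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

def _uniform_volume(code, shape=(1, 4, 4), ss=1):
    arr = np.full((shape[0], shape[1] * ss, shape[2] * ss), code,
                  dtype=np.uint8)
    return ph.LabelVolume(labels=arr, supersample=ss, cell_um=200.0 / ss,
                          slice_mm=1.0)


def test_t1_signal_closed_form():
    # S = PD (1 - exp(-t/T1)): 1000*(1-e^-1) at t = 1 s, T1 = 1000 ms
    spec = small_spec()
    spec.tissue_params[ph.MYOCARDIUM] = ph.TissueParams(1000.0, 40.0, 25.0,
                                                        1000.0, 0.0)
    sched = AcquisitionSchedule("saturation-recovery-TR", [0.5, 1.0, 2.0],
                                fat_saturation=True)
    series = ph.render_t1_series(_uniform_volume(ph.MYOCARDIUM), spec, sched)
    assert series.data[0, 0, 0, 1] == pytest.approx(1000.0 * (1 - np.exp(-1)),
                                                    rel=1e-12)


def test_pure_lipid_voxel_silent_under_fat_saturation():
    spec = small_spec()
    spec.tissue_params[ph.FAT] = ph.TissueParams(350.0, 60.0, 35.0, 1000.0,
                                                 1.0)  # pure lipid
    sched = AcquisitionSchedule("saturation-recovery-TR", [0.5, 1.0, 2.0],
                                fat_saturation=True)
    series = ph.render_t1_series(_uniform_volume(ph.FAT), spec, sched)
    assert np.all(series.data == 0.0)
    # without fat saturation the voxel recovers normally
    sched2 = AcquisitionSchedule("saturation-recovery-TR", [0.5, 1.0, 2.0],
                                 fat_saturation=False)
    series2 = ph.render_t1_series(_uniform_volume(ph.FAT), spec, sched2)
    assert np.all(series2.data > 0)


def test_block_average_equals_mean_of_pure_tissue_signals():
    # 50/50 myocardium-PFA boundary voxel: signal = mean of the two pure rows
    ss = 4
    arr = np.full((1, ss, 2 * ss), ph.MYOCARDIUM, dtype=np.uint8)
    arr[:, :, : ss // 2] = ph.PFA  # half of first acquisition voxel is PFA
    vol = ph.LabelVolume(labels=arr, supersample=ss, cell_um=50.0, slice_mm=1.0)
    spec = small_spec()
    sched = ph.default_t1_schedule()
    series = ph.render_t1_series(vol, spec, sched)
    pure_m = ph.render_t1_series(_uniform_volume(ph.MYOCARDIUM), spec, sched)
    pure_p = ph.render_t1_series(_uniform_volume(ph.PFA), spec, sched)
    expected = 0.5 * (pure_m.data[0, 0, 0] + pure_p.data[0, 0, 0])
    np.testing.assert_allclose(series.data[0, 0, 0], expected, rtol=1e-9)
    # the second voxel is pure myocardium
    np.testing.assert_allclose(series.data[0, 0, 1], pure_m.data[0, 0, 0],
                               rtol=1e-12)


def test_missing_tissue_parameter_names_the_label():
    spec = small_spec()
    del spec.tissue_params[ph.FAT]
    vol = _uniform_volume(ph.FAT)
    with pytest.raises(ValueError, match="fat"):
        ph.render_t1_series(vol, spec, ph.default_t1_schedule())


def test_dixon_pure_water_constant_across_echoes():
    spec = small_spec()
    spec.tissue_params[ph.MYOCARDIUM] = ph.TissueParams(962.0, 40.0, np.inf,
                                                        100.0, 0.0)
    sched = AcquisitionSchedule("multi-echo-TE", [1.0, 2.5, 4.0],
                                chemical_shift_hz=500.0)
    series = ph.render_dixon_series(_uniform_volume(ph.MYOCARDIUM), spec, sched)
    np.testing.assert_allclose(series.data, 100.0, rtol=1e-9)


def test_dixon_opposed_phase_cancels_equal_water_fat():
    spec = small_spec()
    spec.tissue_params[ph.FAT] = ph.TissueParams(350.0, 60.0, np.inf, 100.0, 0.5)
    # chemical shift 500 Hz: TE 1 ms -> half cycle (opposed), 2 ms -> full
    sched = AcquisitionSchedule("multi-echo-TE", [1.0, 2.0],
                                chemical_shift_hz=500.0)
    series = ph.render_dixon_series(_uniform_volume(ph.FAT), spec, sched)
    assert series.data[0, 0, 0, 0] == pytest.approx(0.0, abs=1e-9)
    assert series.data[0, 0, 0, 1] == pytest.approx(100.0, rel=1e-9)


def test_dixon_matches_hand_computed_complex_sum():
    # W=70, F=30, T2*=20 ms at the acquisition TEs
    spec = small_spec()
    spec.tissue_params[ph.FAT] = ph.TissueParams(350.0, 60.0, 20.0, 100.0, 0.3)
    sched = ph.default_dixon_schedule(600.0)
    series = ph.render_dixon_series(_uniform_volume(ph.FAT), spec, sched)
    for i, te in enumerate(sched.times):
        z = (70.0 + 30.0 * np.exp(2j * np.pi * 600.0 * te * 1e-3))
        expected = abs(z) * np.exp(-te / 20.0)
        assert series.data[0, 0, 0, i] == pytest.approx(expected, rel=1e-12)


def test_msme_closed_form_and_monotone_decay():
    spec = small_spec()
    spec.tissue_params[ph.MYOCARDIUM] = ph.TissueParams(962.0, 50.0, 25.0,
                                                        100.0, 0.0)
    sched = AcquisitionSchedule("multi-echo-TE", [25.0, 50.0, 75.0, 100.0])
    series = ph.render_msme_series(_uniform_volume(ph.MYOCARDIUM), spec, sched)
    assert series.data[0, 0, 0, 1] == pytest.approx(100.0 / np.e, rel=1e-12)
    assert np.all(np.diff(series.data[0, 0, 0]) < 0)


def test_background_noise_is_rayleigh_with_expected_mean():
    # PD = 0 voxels keep only the two noise channels: mean = sigma*sqrt(pi/2)
    spec = small_spec(noise_sigma=0.05, seed=11)
    arr = np.full((1, 120, 120), ph.BACKGROUND, dtype=np.uint8)
    arr[0, :2, :2] = ph.MYOCARDIUM  # one tissue corner sets the peak signal
    vol = ph.LabelVolume(labels=arr, supersample=1, cell_um=200.0, slice_mm=1.0)
    series = ph.render_msme_series(vol, spec,
                                   ph.default_msme_schedule(4, 10.0))
    clean_peak = 1000.0 * np.exp(-10.0 / 40.0)
    sigma = 0.05 * clean_peak
    bg = series.data[0, 4:, 4:, :].ravel()
    assert bg.size >= 1e4
    assert bg.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)


def test_rendering_deterministic_given_seed():
    spec = small_spec(noise_sigma=0.02, seed=5)
    vol = ph.build_label_map(spec)
    a = ph.render_t1_series(vol, spec, ph.default_t1_schedule())
    b = ph.render_t1_series(vol, spec, ph.default_t1_schedule())
    assert np.array_equal(a.data, b.data)


def test_schedule_validation():
    with pytest.raises(ValueError):
        AcquisitionSchedule("multi-echo-TE", [2.0, 1.0])
    with pytest.raises(ValueError):
        AcquisitionSchedule("multi-echo-TE", [1.0])
    with pytest.raises(ValueError):
        ph.render_t1_series(_uniform_volume(ph.MYOCARDIUM), small_spec(),
                            AcquisitionSchedule("multi-echo-TE", [1.0, 2.0]))
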