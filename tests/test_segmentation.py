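"""GMM tissue clustering, role assignment and fraction reporting."""

import numpy as np
import pandas as pd
import pytest

from lamap import segmentation as sg
from lamap.containers import ParametricMap
from lamap.dixon import FatMap


def _pmap(values, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values) & (values > 0)
    return ParametricMap(values=values, mask=mask, unit="ms")


def _fatmap(ff):
    ff = np.asarray(ff, dtype=float)
    return FatMap(fat_fraction=ff, water=np.ones_like(ff),
                  mask=np.isfinite(ff), t2star_corrected=False)


# ----------------------------------------------------------------------
# EM fitting
# ----------------------------------------------------------------------

def test_two_component_recovery():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0.0, 1.0, 1000),
                        rng.normal(10.0, 1.0, 1000)])
    model = sg.fit_gmm(x, k=2, seed=0)
    order = np.argsort(model.means)
    assert model.means[order] == pytest.approx([0.0, 10.0], abs=0.1)
    assert model.weights[order] == pytest.approx([0.5, 0.5], abs=0.02)


def test_loglik_trace_nondecreasing():
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(0, 1, 400), rng.normal(4, 2, 600)])
    for k in (2, 3):
        model = sg.fit_gmm(x, k=k, seed=1)
        assert np.all(np.diff(model.log_likelihood_trace) >= -1e-7)


def test_fit_deterministic_given_seed():
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(0, 1, 500), rng.normal(6, 1, 500)])
    a = sg.fit_gmm(x, k=2, seed=5)
    b = sg.fit_gmm(x, k=2, seed=5)
    assert np.array_equal(a.means, b.means)
    assert np.array_equal(a.weights, b.weights)
    assert np.array_equal(a.log_likelihood_trace, b.log_likelihood_trace)


def test_single_gaussian_with_k2_stays_in_data_range():
    rng = np.random.default_rng(3)
    x = rng.normal(5.0, 1.0, 5000)
    model = sg.fit_gmm(x, k=2, seed=0)
    assert np.all(model.means > x.min()) and np.all(model.means < x.max())


def test_degenerate_inputs_raise():
    with pytest.raises(ValueError, match="identical"):
        sg.fit_gmm(np.full(100, 3.0), k=2)
    with pytest.raises(ValueError, match="at least"):
        sg.fit_gmm(np.arange(15.0), k=2)
    with pytest.raises(ValueError):
        sg.fit_gmm(np.arange(100.0), k=1)


def test_against_sklearn_reference():
    sklearn = pytest.importorskip("sklearn.mixture")
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(0, 1, 800), rng.normal(7, 1.5, 1200)])
    ours = sg.fit_gmm(x, k=2, seed=0)
    ref = sklearn.GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
    ref_means = np.sort(ref.means_.ravel())
    ref_w = ref.weights_[np.argsort(ref.means_.ravel())]
    order = np.argsort(ours.means)
    assert ours.means[order] == pytest.approx(ref_means, abs=0.15)
    assert ours.weights[order] == pytest.approx(ref_w, abs=0.02)


def test_fwhm_and_peak_height_closed_forms():
    model = sg.GmmModel1D(weights=np.array([0.4, 0.6]),
                          means=np.array([0.0, 10.0]),
                          variances=np.array([4.0, 9.0]),
                          log_likelihood_trace=np.array([-1.0]),
                          seed=0, n_iter=1, converged=True)
    assert model.fwhm == pytest.approx(2.354820045 * np.array([2.0, 3.0]),
                                       rel=1e-9)
    assert model.peak_heights() == pytest.approx(
        [0.4 / (2 * np.sqrt(2 * np.pi)), 0.6 / (3 * np.sqrt(2 * np.pi))])


def test_refit_tracks_shifted_modes_and_keeps_identities():
    rng = np.random.default_rng(5)
    x = np.concatenate([rng.normal(0, 1, 800), rng.normal(8, 1, 200)])
    base = sg.fit_gmm(x, k=2, seed=0)
    # same structure, modes shifted and reweighted
    y = np.concatenate([rng.normal(1, 1, 600), rng.normal(9, 1, 400)])
    refit = sg.refit_gmm(y, base, outlier_uniform=False)
    order = np.argsort(refit.means)
    assert refit.means[order] == pytest.approx([1.0, 9.0], abs=0.2)
    assert refit.weights[order] == pytest.approx([0.6, 0.4], abs=0.05)
    assert np.all(np.diff(refit.log_likelihood_trace) >= -1e-7)


def test_interior_mask_drops_interface_voxels():
    rng = np.random.default_rng(0)
    vals = 960.0 + rng.normal(0, 1.0, (1, 12, 12))
    vals[0, :, 6:] += 1000.0  # sharp interface at column 6
    pm = _pmap(vals)
    interior = sg.interior_mask(pm, factor=4.0)
    assert not interior[0, :, 5].any() and not interior[0, :, 6].any()
    assert interior[0, :, 2].mean() > 0.8 and interior[0, :, 9].mean() > 0.8


# ----------------------------------------------------------------------
# role assignment
# ----------------------------------------------------------------------

def _model(means, variances=None, weights=None):
    means = np.asarray(means, dtype=float)
    k = means.size
    return sg.GmmModel1D(
        weights=np.asarray(weights if weights is not None
                           else np.full(k, 1.0 / k)),
        means=means,
        variances=np.asarray(variances if variances is not None
                             else np.full(k, 100.0)),
        log_likelihood_trace=np.array([-1.0]),
        seed=0, n_iter=1, converged=True)


def test_four_class_roles_by_t1_ordering():
    model = _model([962.0, 2800.0, 350.0, 1131.0])
    roles = sg.assign_roles(model, "four-class")
    assert roles == {0: "myocardium", 1: "pfa", 2: "fat_mixture",
                     3: "interstitial_fibrosis"}


def test_three_class_roles_and_permutation_invariance():
    roles = sg.assign_roles(_model([900.0, 1100.0, 2800.0]), "three-class")
    assert [roles[i] for i in range(3)] == ["myocardium", "total_fibrosis",
                                            "pfa"]
    perm = sg.assign_roles(_model([2800.0, 900.0, 1100.0]), "three-class")
    assert perm == {1: "myocardium", 2: "total_fibrosis", 0: "pfa"}


def test_tied_means_break_by_variance_with_warning():
    model = _model([500.0, 500.0], variances=[400.0, 100.0])
    with pytest.warns(UserWarning, match="tie"):
        roles = sg.assign_roles(model, "fat-region")
    assert roles == {1: "fat", 0: "fatty_fibrosis"}


def test_mode_k_mismatch_raises():
    with pytest.raises(ValueError, match="expects k"):
        sg.assign_roles(_model([1.0, 2.0]), "three-class")


# ----------------------------------------------------------------------
# per-voxel classification
# ----------------------------------------------------------------------

def test_classification_at_component_means_and_midpoint_boundary():
    model = _model([300.0, 900.0], variances=[100.0, 100.0])
    roles = sg.assign_roles(model, "fat-region")
    vals = np.array([[[300.0, 900.0, 599.0, 601.0]]])
    cm = sg.classify_map(_pmap(vals), model, roles)
    names = [cm.legend[c] for c in cm.labels[0, 0]]
    # equal weights/variances: decision boundary at the midpoint of means
    assert names == ["fat", "fatty_fibrosis", "fat", "fatty_fibrosis"]


def test_classification_matches_bruteforce_posterior_argmax():
    rng = np.random.default_rng(6)
    model = _model([300.0, 960.0, 1130.0, 2000.0],
                   variances=[900.0, 2500.0, 3600.0, 10000.0],
                   weights=[0.1, 0.6, 0.15, 0.15])
    roles = sg.assign_roles(model, "four-class")
    vals = rng.uniform(200.0, 2500.0, size=(2, 8, 9))
    pm = _pmap(vals)
    cm = sg.classify_map(pm, model, roles)
    # brute force: evaluate weighted normal densities per voxel
    for idx in np.ndindex(vals.shape):
        dens = [model.weights[j] / np.sqrt(2 * np.pi * model.variances[j])
                * np.exp(-0.5 * (vals[idx] - model.means[j]) ** 2
                         / model.variances[j])
                for j in range(4)]
        expected = sg.CLASS_CODES[roles[int(np.argmax(dens))]]
        assert cm.labels[idx] == expected
    # unmasked voxels stay background
    pm2 = _pmap(vals, mask=np.zeros(vals.shape, bool))
    assert np.all(sg.classify_map(pm2, model, roles).labels == 0)


# ----------------------------------------------------------------------
# fatty fibrosis from the T1-fat map
# ----------------------------------------------------------------------

def test_fatty_fibrosis_recovers_septa():
    rng = np.random.default_rng(7)
    t1 = np.full((1, 20, 20), 960.0) + rng.normal(0, 20, (1, 20, 20))
    ff = np.zeros((1, 20, 20))
    ff[0, 4:16, 4:16] = 0.45  # lobule
    t1[0, 4:16, 4:16] = 350.0 + rng.normal(0, 30, (12, 12))
    ff[0, 9:11, 4:16] = 0.30  # septum
    t1[0, 9:11, 4:16] = 1100.0 + rng.normal(0, 40, (2, 12))
    cm = sg.fatty_fibrosis_map(_pmap(t1), _fatmap(ff), seed=0)
    septum = cm.labels[0, 9:11, 4:16]
    assert np.mean(septum == sg.CLASS_CODES["fatty_fibrosis"]) > 0.9
    cores = cm.labels[0, 12:16, 4:16]
    assert np.mean(cores == sg.CLASS_CODES["fat"]) > 0.9


def test_empty_fat_region_warns_and_reports_none():
    t1 = np.full((1, 10, 10), 960.0)
    ff = np.full((1, 10, 10), 0.01)
    with pytest.warns(UserWarning, match="too small"):
        cm = sg.fatty_fibrosis_map(_pmap(t1), _fatmap(ff), ff_threshold=1.0,
                                   seed=0)
    assert not np.any(cm.labels == sg.CLASS_CODES["fatty_fibrosis"])


def test_unimodal_fat_region_flagged_degenerate():
    rng = np.random.default_rng(8)
    t1 = 400.0 + rng.normal(0, 25, (1, 30, 30))
    ff = np.full((1, 30, 30), 0.45)
    cm = sg.fatty_fibrosis_map(_pmap(t1), _fatmap(ff), ff_threshold=0.2,
                               seed=0)
    assert cm.diagnostics["degenerate"]
    assert not np.any(cm.labels == sg.CLASS_CODES["fatty_fibrosis"])


# ----------------------------------------------------------------------
# fraction report
# ----------------------------------------------------------------------

def _partition_map(labels):
    return sg.TissueClassMap(labels=np.asarray(labels, dtype=np.uint8),
                             provenance="test")


def test_fraction_report_three_slice_average():
    # per-slice interstitial fibrosis 10/20/30% -> 3-slice volume 20%
    maps = np.zeros((3, 10, 10), dtype=np.uint8)
    maps[:, :, :] = sg.CLASS_CODES["myocardium"]
    for s, n in enumerate([10, 20, 30]):
        maps[s].ravel()[:n] = sg.CLASS_CODES["interstitial_fibrosis"]
    rep = sg.fraction_report(_partition_map(maps), volume_slices_fibrosis=3)
    assert rep.volume["interstitial_fibrosis"] == pytest.approx(20.0)
    assert rep.per_slice["interstitial_fibrosis"].tolist() == [10.0, 20.0,
                                                               30.0]


def test_all_myocardium_reports_zero_everywhere_else():
    maps = np.full((2, 5, 5), sg.CLASS_CODES["myocardium"], dtype=np.uint8)
    rep = sg.fraction_report(_partition_map(maps))
    assert rep.volume["myocardium"] == 100.0
    for c in ("interstitial_fibrosis", "fat", "fatty_fibrosis",
              "total_fibrosis"):
        assert rep.volume[c] == 0.0


def test_fraction_report_components_sum_to_100():
    rng = np.random.default_rng(9)
    codes = [sg.CLASS_CODES[c] for c in sg.COMPONENTS]
    maps = rng.choice(codes, size=(4, 8, 8)).astype(np.uint8)
    rep = sg.fraction_report(_partition_map(maps))
    sums = rep.per_slice[list(sg.COMPONENTS)].sum(axis=1)
    assert np.allclose(sums, 100.0, atol=1e-9)


# ----------------------------------------------------------------------
# reclassification rate
# ----------------------------------------------------------------------

def test_reclassification_rate_oracle():
    rng = np.random.default_rng(10)
    a = rng.choice([sg.CLASS_CODES["myocardium"],
                    sg.CLASS_CODES["total_fibrosis"]], size=(2, 10, 10))
    b = rng.choice([sg.CLASS_CODES["myocardium"],
                    sg.CLASS_CODES["interstitial_fibrosis"]], size=(2, 10, 10))
    rate = sg.reclassification_rate(_partition_map(a), _partition_map(b))
    fib_a = a == sg.CLASS_CODES["total_fibrosis"]
    fib_b = b == sg.CLASS_CODES["interstitial_fibrosis"]
    expected = 100.0 * np.mean(fib_a != fib_b)
    assert rate == pytest.approx(expected, abs=1e-12)
    assert sg.reclassification_rate(_partition_map(a), _partition_map(a)) == 0.0


def test_reclassification_half_and_geometry_check():
    a = np.full((1, 2, 4), sg.CLASS_CODES["myocardium"], dtype=np.uint8)
    b = a.copy()
    b[0, 0, :] = sg.CLASS_CODES["interstitial_fibrosis"]
    assert sg.reclassification_rate(_partition_map(a),
                                    _partition_map(b)) == 50.0
    with pytest.raises(ValueError, match="geometry"):
        sg.reclassification_rate(_partition_map(a),
                                 _partition_map(np.zeros((1, 3, 3),
                                                         dtype=np.uint8)))
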