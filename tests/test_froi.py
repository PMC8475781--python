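"""Sphere ROIs, cross-run voxel selection, signal-change extraction, and the
ROI-level permutation statistics."""

import numpy as np
import pandas as pd
import pytest

from demandmri import design as dsg
from demandmri import froi
from demandmri import glm as glm_mod
from demandmri import synthetic as syn
from _oracles import (brute_force_topk, region_swap_p_enumeration,
                      rm_anova_oneway_gg, sign_flip_p_enumeration)


def _affine(voxel_mm, dims):
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.array(dims) - 1) / 2.0 * voxel_mm
    return aff


# --------------------------------------------------------------------------
# Sphere masks
# --------------------------------------------------------------------------

def test_sphere_count_matches_exhaustive_scan():
    dims = (20, 20, 20)
    aff = _affine(2.0, dims)
    spec = froi.SphereSpec("s", center_mm=(0.0, 0.0, 0.0), radius_mm=8.0)
    mask = froi.make_sphere_roi(spec, dims, aff)
    count = 0
    for v in np.ndindex(dims):
        mm = aff[:3, :3] @ v + aff[:3, 3]
        if (mm ** 2).sum() <= 64.0:
            count += 1
    assert mask.sum() == count
    assert count > 0


def test_sphere_tiny_radius_single_voxel():
    dims = (9, 9, 9)
    aff = _affine(3.0, dims)
    spec = froi.SphereSpec("s", center_mm=(0.0, 0.0, 0.0), radius_mm=0.1)
    assert froi.make_sphere_roi(spec, dims, aff).sum() == 1


def test_sphere_clipped_at_edge_is_smaller():
    dims = (20, 20, 20)
    aff = _affine(2.0, dims)
    interior = froi.make_sphere_roi(
        froi.SphereSpec("a", (0.0, 0.0, 0.0), 8.0), dims, aff).sum()
    edge = froi.make_sphere_roi(
        froi.SphereSpec("b", (-19.0, 0.0, 0.0), 8.0), dims, aff).sum()
    assert edge < interior


def test_sphere_outside_grid_rejected():
    dims = (10, 10, 10)
    aff = _affine(2.0, dims)
    with pytest.raises(ValueError, match="outside"):
        froi.make_sphere_roi(froi.SphereSpec("x", (500.0, 0, 0), 8.0),
                             dims, aff)


# --------------------------------------------------------------------------
# Top-10% selection
# --------------------------------------------------------------------------

def _selection_setup(rng, dims=(12, 12, 12)):
    aff = _affine(2.0, dims)
    mask = froi.make_sphere_roi(
        froi.SphereSpec("s", (0.0, 0.0, 0.0), 8.0), dims, aff)
    loc = rng.normal(size=dims)
    exc = rng.normal(size=dims)
    return mask, loc, exc


def test_select_all_eligible_takes_top_tenth(rng):
    mask, loc, _ = _selection_setup(rng)
    cfg = froi.FROIConfig()
    sel, n_elig = froi.select_froi(mask, loc, np.zeros_like(loc), 224, cfg)
    assert n_elig == mask.sum()
    assert len(sel) == round(0.10 * mask.sum())


def test_selection_matches_brute_force_sort(rng):
    from scipy import stats as st
    mask, loc, exc = _selection_setup(rng)
    exc = exc * 2.0
    cfg = froi.FROIConfig()
    df = 224
    sel, _ = froi.select_froi(mask, loc, exc, df, cfg)
    vox = np.argwhere(mask)
    loc_in = loc[mask]
    cut = st.t.ppf(1 - cfg.exclusion_p / 2, df)
    eligible = np.abs(exc[mask]) < cut
    k = round(cfg.select_fraction * len(vox))
    oracle_idx = brute_force_topk(loc_in, eligible, min(k, eligible.sum()))
    np.testing.assert_array_equal(sel, vox[oracle_idx])


def test_selection_all_excluded_flagged(rng):
    mask, loc, _ = _selection_setup(rng)
    sel, n_elig = froi.select_froi(mask, loc, np.full(mask.shape, 50.0),
                                   224, froi.FROIConfig())
    assert len(sel) == 0 and n_elig == 0


def test_selection_tie_break_by_index(rng):
    mask = np.zeros((4, 4, 4), bool)
    mask[:2, :2, :2] = True          # 8 voxels
    loc = np.zeros((4, 4, 4))        # all tied
    cfg = froi.FROIConfig(select_fraction=0.25)
    sel, _ = froi.select_froi(mask, loc, np.zeros_like(loc), 100, cfg)
    np.testing.assert_array_equal(sel, np.argwhere(mask)[:2])


# --------------------------------------------------------------------------
# Peak finding after extra smoothing
# --------------------------------------------------------------------------

def test_impulse_single_peak():
    v = np.zeros((15, 15, 15))
    v[7, 7, 7] = 1.0
    _, peaks = froi.smooth_for_peaks(v, voxel_mm=3.0, threshold=1e-6)
    assert peaks == [(7.0, 7.0, 7.0)]


def test_two_impulses_40mm_apart_two_peaks():
    v = np.zeros((21, 9, 9))
    v[2, 4, 4] = 1.0
    v[16, 4, 4] = 1.0                # 14 voxels ~ 42 mm apart at 3 mm
    _, peaks = froi.smooth_for_peaks(v, voxel_mm=3.0, threshold=1e-6)
    assert sorted(p[0] for p in peaks) == [2.0, 16.0]


def test_phantom_language_peak_near_truth(clean_phantom, hrf):
    """The smoothed language-contrast peak lies within one voxel of a
    language region's center."""
    sched = dsg.generate_run_schedule(6)
    run = syn.simulate_run(clean_phantom, sched, hrf, 0)
    dm = glm_mod.build_design_matrix(list(sched.blocks), run.nuisance, hrf,
                                     run.tr_ms)
    fit = glm_mod.fit_glm(run.data, dm)
    eff = glm_mod.estimate_contrast(fit, "language").effect.reshape(
        clean_phantom.grid_dims)
    _, peaks = froi.smooth_for_peaks(eff, clean_phantom.voxel_mm,
                                     threshold=0.5 * eff.max())
    lang_centers = [r.center_vox for r in clean_phantom.regions
                    if r.family == "language"]
    for peak in peaks:
        d = min(np.linalg.norm(np.array(peak) - np.array(c))
                for c in lang_centers)
        assert d <= 1.0


# --------------------------------------------------------------------------
# Signal-change extraction
# --------------------------------------------------------------------------

def _clean_fits(clean_phantom, hrf, seeds=(31, 32)):
    fits = {}
    for label, seed in zip(("run-1", "run-2"), seeds):
        sched = dsg.generate_run_schedule(seed)
        run = syn.simulate_run(clean_phantom, sched, hrf, seed)
        dm = glm_mod.build_design_matrix(list(sched.blocks), run.nuisance,
                                         hrf, run.tr_ms)
        fits[label] = glm_mod.fit_glm(run.data, dm)
    return fits


def test_signal_change_recovers_percent_of_baseline(clean_phantom, hrf):
    fits = _clean_fits(clean_phantom, hrf)
    region = next(r for r in clean_phantom.regions if r.family == "md")
    vox = np.argwhere(clean_phantom.region_mask(region))
    sel = {"run-1": vox, "run-2": vox}
    out = froi.extract_signal_change(fits, sel, clean_phantom.grid_dims)
    for cond in dsg.ACTIVE_CONDITIONS:
        expected = 100.0 * region.amplitudes[cond] / clean_phantom.baseline
        # the baseline estimate (intercept) also absorbs the mean of the
        # simulated global WM/CSF coupling, so recovery is near-exact only
        assert out[cond] == pytest.approx(expected, abs=5e-3)
    raw = froi.extract_signal_change(fits, sel, clean_phantom.grid_dims,
                                     percent=False)
    assert raw["semantic_difficult"] == pytest.approx(
        region.amplitudes["semantic_difficult"], abs=1e-8)


def test_signal_change_zero_amplitude_region_is_zero(clean_phantom, hrf):
    fits = _clean_fits(clean_phantom, hrf)
    dmn = next(r for r in clean_phantom.regions if r.family == "dmn")
    vox = np.argwhere(clean_phantom.region_mask(dmn))
    out = froi.extract_signal_change(fits, {"run-1": vox, "run-2": vox},
                                     clean_phantom.grid_dims)
    assert out["semantic_easy"] == pytest.approx(0.0, abs=1e-8)


def test_signal_change_identical_runs_equal_single_run(clean_phantom, hrf):
    """Cross-run averaging is symmetric: identical fits give the single-run
    value."""
    fits = _clean_fits(clean_phantom, hrf, seeds=(41, 41))
    region = clean_phantom.regions[0]
    vox = np.argwhere(clean_phantom.region_mask(region))
    out = froi.extract_signal_change(fits, {"run-1": vox, "run-2": vox},
                                     clean_phantom.grid_dims)
    one = froi.extract_signal_change(
        {"run-1": fits["run-1"], "run-2": fits["run-1"]},
        {"run-1": vox, "run-2": vox}, clean_phantom.grid_dims)
    for cond in dsg.ACTIVE_CONDITIONS:
        assert out[cond] == pytest.approx(one[cond])


# --------------------------------------------------------------------------
# Effect size and sign-flip tests
# --------------------------------------------------------------------------

def test_dz_hand_computation():
    """{2,1,3,2}: mean 2, sample SD sqrt(2/3) -> d_z = 2.449."""
    assert froi.cohens_dz(np.array([2.0, 1.0, 3.0, 2.0])) \
        == pytest.approx(2.0 / np.sqrt(2.0 / 3.0), abs=1e-12)
    assert froi.cohens_dz(np.array([2.0, 1.0, 3.0, 2.0])) \
        == pytest.approx(2.449, abs=5e-4)


def test_dz_zero_sd_undefined():
    assert np.isnan(froi.cohens_dz(np.array([1.0, 1.0, 1.0])))


def test_sign_flip_symmetric_values_not_significant():
    vals = np.array([-3.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 3.0])
    out = froi.roi_sign_flip_test(vals, n_permutations=256)
    assert out["exact"]
    assert out["p_unc"] >= 0.5


def test_sign_flip_all_equal_minimum_p():
    vals = np.full(8, 2.5)
    out = froi.roi_sign_flip_test(vals, n_permutations=256)
    assert out["exact"]
    assert out["p_unc"] == pytest.approx(2.0 / 256.0)


def test_sign_flip_matches_enumeration_oracle(rng):
    vals = rng.normal(0.7, 1.0, 8)
    exact = sign_flip_p_enumeration(vals)
    out = froi.roi_sign_flip_test(vals, n_permutations=256)
    assert out["p_unc"] == pytest.approx(exact, abs=1e-12)
    mc = froi.roi_sign_flip_test(vals, n_permutations=255, seed=5)
    se = np.sqrt(exact * (1 - exact) / 255)
    assert abs(mc["p_unc"] - exact) <= 2.5 * se + 1 / 255


def test_family_correction_bounds(rng):
    effects = pd.DataFrame(rng.normal(0.5, 1.0, (10, 6)),
                           columns=[f"r{i}" for i in range(6)])
    out = froi.roi_family_tests(effects, n_permutations=1024)
    assert (out["p_corrected"] >= out["p_unc"] - 1e-12).all()
    assert (out["p_corrected"] <= 1.0).all()


# --------------------------------------------------------------------------
# Region comparison and omnibus ANOVA
# --------------------------------------------------------------------------

def test_region_comparison_identical_columns():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5]})
    out = froi.region_comparison_test(X, n_permutations=200, seed=0)
    assert out["pairwise"][("a", "b")]["difference"] == 0.0
    assert out["pairwise"][("a", "b")]["p"] == 1.0


def test_region_comparison_matches_enumeration(rng):
    X = rng.normal(0, 1, (5, 2))
    X[:, 0] += 1.2
    exact = region_swap_p_enumeration(X)
    out = froi.region_comparison_test(
        pd.DataFrame(X, columns=["a", "b"]), n_permutations=4000, seed=2)
    p = out["pairwise"][("a", "b")]["p"]
    se = np.sqrt(exact * (1 - exact) / 4000)
    assert abs(p - exact) <= 2.5 * se + 1 / 4000


def test_omnibus_identical_columns_F_zero():
    X = pd.DataFrame(np.tile(np.arange(5.0)[:, None], (1, 4)),
                     columns=list("abcd"))
    out = froi.omnibus_rm_anova(X)
    assert out["F"] == pytest.approx(0.0, abs=1e-20)


def test_omnibus_matches_first_principles_oracle(rng):
    X = rng.normal(0, 1, (20, 12)) + rng.normal(0, 0.5, (20, 1))
    out = froi.omnibus_rm_anova(pd.DataFrame(X))
    oracle = rm_anova_oneway_gg(X)
    assert out["F"] == pytest.approx(oracle["F"], rel=1e-8)
    assert out["epsilon"] == pytest.approx(oracle["epsilon"], rel=1e-8)


def test_omnibus_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    X = pd.DataFrame(rng.normal(0, 1, (15, 5)), columns=list("abcde"))
    long = X.reset_index().melt(id_vars="index", var_name="region")
    ref = pg.rm_anova(data=long, dv="value", within="region",
                      subject="index", correction=True)
    out = froi.omnibus_rm_anova(X)
    assert out["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
    assert out["epsilon"] == pytest.approx(float(ref["eps"].iloc[0]),
                                           rel=1e-6)
    assert out["p"] == pytest.approx(float(ref["p_GG_corr"].iloc[0]),
                                     rel=1e-4)


def test_omnibus_compound_symmetry_epsilon_near_one(rng):
    """Compound-symmetric data satisfy sphericity, so epsilon-hat ~ 1."""
    n, k = 400, 6
    subject = rng.normal(0, 1.0, (n, 1))
    X = subject + rng.normal(0, 1.0, (n, k))
    out = froi.omnibus_rm_anova(pd.DataFrame(X))
    assert out["epsilon"] >= 0.95


def test_omnibus_requires_three_regions():
    with pytest.raises(ValueError):
        froi.omnibus_rm_anova(pd.DataFrame(np.ones((5, 2))))
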