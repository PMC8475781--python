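"""Functional ROI definition and ROI-level permutation statistics.

Anatomical constraints are 8-mm spheres around network peaks (12
multiple-demand spheres, 10 language-network spheres by default).  Within
each sphere and for each run, the individual fROI is the top 10% of voxels
with the highest localizer t statistics *in the other run*, excluding voxels
modulated by the orthogonal network contrast (uncorrected p > 0.1 keeps a
voxel).  Condition effects are then read out cross-run — voxels selected
from run A are measured in run B and vice versa — as percent signal change
relative to the voxel baseline.

ROI statistics follow the permutation logic of the voxelwise analysis:
within-subject effect sizes d_z with sign-flip permutation p values,
single-step max-statistic correction across each ROI family, permutation
tests of between-region differences, and a Greenhouse-Geisser-corrected
omnibus repeated-measures ANOVA over regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import ACTIVE_CONDITIONS
from .glm import GLMFit
from .synthetic import gaussian_smooth


@dataclass(frozen=True)
class SphereSpec:
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 8.0
    network: str = ""               # "md" | "language"
    hemisphere: str = ""


@dataclass
class FROIConfig:
    select_fraction: float = 0.10
    exclusion_p: float = 0.10       # two-sided, uncorrected
    localizer: str = "nonlinguistic_demand"
    exclusion: str = "language"
    n_permutations: int = 10000
    seed: int = 0


@dataclass
class FROISelection:
    sphere: SphereSpec
    selected: dict[str, np.ndarray]   # localizer run label -> (k, 3) voxel idx
    eligible_count: dict[str, int]
    dropped: bool = False


def make_sphere_roi(spec: SphereSpec, grid_dims, affine) -> np.ndarray:
    """Boolean mask of voxels whose center lies within the sphere."""
    idx = np.indices(grid_dims).reshape(3, -1).T
    mm = (affine[:3, :3] @ idx.T).T + affine[:3, 3]
    d2 = ((mm - np.asarray(spec.center_mm)) ** 2).sum(axis=1)
    mask = (d2 <= spec.radius_mm ** 2).reshape(grid_dims)
    if not mask.any():
        raise ValueError(f"sphere {spec.name} lies entirely outside the grid")
    return mask


def select_froi(sphere_mask: np.ndarray, localizer_t: np.ndarray,
                exclusion_t: np.ndarray, df: int,
                config: FROIConfig) -> tuple[np.ndarray, int]:
    """Top-fraction voxel selection with orthogonal-contrast exclusion.

    Eligible voxels have |exclusion t| below the two-sided uncorrected
    p > ``exclusion_p`` cut.  k = round(fraction x sphere size) voxels with
    the highest localizer t are taken from the eligible set (fewer if the
    eligible set is smaller); ties break by voxel index order.  Returns the
    (k, 3) selected indices and the eligible count.
    """
    t_cut = float(stats.t.ppf(1.0 - config.exclusion_p / 2.0, df))
    vox = np.argwhere(sphere_mask)
    loc = localizer_t[sphere_mask]
    exc = exclusion_t[sphere_mask]
    eligible = np.abs(exc) < t_cut
    k = int(round(config.select_fraction * len(vox)))
    k = min(k, int(eligible.sum()))
    if k == 0:
        return np.empty((0, 3), dtype=int), int(eligible.sum())
    order = np.lexsort((np.arange(len(vox)), -loc))
    order = order[eligible[order]]
    return vox[order[:k]], int(eligible.sum())


def smooth_for_peaks(contrast_map: np.ndarray, voxel_mm: float,
                     fwhm_mm: float = 8.0, threshold: float = 0.0,
                     affine: np.ndarray | None = None):
    """Extra smoothing before peak finding (maximally general peaks).

    Returns (smoothed map, list of peak locations).  Peaks are strict local
    maxima over the 26-neighborhood exceeding ``threshold``; locations are mm
    coordinates when an affine is given, else voxel indices.
    """
    sm = gaussian_smooth(contrast_map, fwhm_mm, voxel_mm)
    footprint = np.ones((3, 3, 3), bool)
    local_max = (sm == ndimage.maximum_filter(sm, footprint=footprint,
                                              mode="reflect"))
    peaks = np.argwhere(local_max & (sm > threshold))
    if affine is not None:
        peaks = [(affine[:3, :3] @ p + affine[:3, 3]) for p in peaks]
    return sm, [tuple(map(float, p)) for p in peaks]


def extract_signal_change(run_fits: dict[str, GLMFit],
                          selections: dict[str, np.ndarray],
                          grid_dims, *, percent: bool = True) -> dict[str, float]:
    """Cross-run per-condition effects for one participant and one ROI.

    ``selections`` maps a localizer run label to voxels chosen from that
    run's statistics; those voxels are measured in the *other* run, and the
    two measurements averaged.  Effects are versus the implicit rest baseline
    and, when ``percent`` is true, scaled to percent of the voxel's baseline
    (intercept) signal.
    """
    run_labels = sorted(run_fits)
    if sorted(selections) != run_labels or len(run_labels) != 2:
        raise ValueError("need selections from exactly the two fitted runs")
    per_run_vals = []
    for loc_run in run_labels:
        measure_run = [r for r in run_labels if r != loc_run][0]
        fit = run_fits[measure_run]
        vox = selections[loc_run]
        if len(vox) == 0:
            raise ValueError("empty selection")
        flat = np.ravel_multi_index(vox.T, grid_dims)
        icept = fit.design.columns.index("intercept")
        baseline = fit.beta[icept, flat]
        ok = baseline != 0
        if not ok.all():
            warnings.warn("zero-baseline voxels excluded from signal change")
        vals = {}
        for j, cond in enumerate(ACTIVE_CONDITIONS):
            ci = fit.design.columns.index(cond)
            eff = fit.beta[ci, flat][ok]
            if percent:
                eff = 100.0 * eff / baseline[ok]
            vals[cond] = float(eff.mean())
        per_run_vals.append(vals)
    return {c: 0.5 * (per_run_vals[0][c] + per_run_vals[1][c])
            for c in ACTIVE_CONDITIONS}


# --------------------------------------------------------------------------
# Permutation statistics on per-participant ROI effects
# --------------------------------------------------------------------------

def _sign_flips(n: int, n_permutations: int, seed: int):
    if n <= 12 and 2 ** n <= n_permutations:
        bits = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :] & 1
        return 1.0 - 2.0 * bits, True
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    signs[0] = 1.0
    return signs, False


def cohens_dz(values: np.ndarray) -> float:
    """Within-subject effect size: mean / sample SD (n-1 denominator)."""
    values = np.asarray(values, float)
    sd = values.std(ddof=1)
    if sd == 0:
        return np.nan
    return float(values.mean() / sd)


def roi_sign_flip_test(values: np.ndarray, n_permutations: int = 10000,
                       seed: int = 0) -> dict:
    """Two-sided sign-flip permutation test of a zero mean for one ROI.

    The observed statistic is the mean; the null re-signs each participant's
    value.  Exhaustive enumeration is used for n <= 12 when the requested
    permutation count covers it.
    """
    values = np.asarray(values, float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least two participants")
    signs, exact = _sign_flips(n, n_permutations, seed)
    null_means = (signs @ values) / n
    obs = values.mean()
    count = int((np.abs(null_means) >= abs(obs) - 1e-12).sum())
    # the identity assignment sits in the null set in both modes, so the
    # Monte Carlo p equals (1 + #{|null| >= |obs| among draws}) / (1 + draws)
    p = count / len(null_means)
    return dict(mean=float(obs), d_z=cohens_dz(values), p_unc=float(p),
                n=n, exact=exact)


def roi_family_tests(effects: pd.DataFrame, n_permutations: int = 10000,
                     seed: int = 0) -> pd.DataFrame:
    """Sign-flip tests for every ROI column with max-statistic correction.

    ``effects`` is participants x ROIs of one contrast's per-participant
    effects.  Uncorrected p values use each ROI's own permutation null of
    the mean; the family-corrected p compares each ROI's observed |t| with
    the permutation distribution of the maximum |t| across the family
    (single-step max-statistic), which is scale-free across ROIs.
    """
    X = effects.to_numpy(float)
    n, k = X.shape
    signs, exact = _sign_flips(n, n_permutations, seed)
    sums = signs @ X                     # (perm, k)
    means = sums / n
    sumsq = (X ** 2).sum(axis=0)
    var = (sumsq[None, :] - n * means ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstats = means / np.sqrt(var / n)
    max_abs_t = np.abs(tstats).max(axis=1)
    rows = []
    for j, roi in enumerate(effects.columns):
        obs_mean = X[:, j].mean()
        obs_t = obs_mean / (X[:, j].std(ddof=1) / np.sqrt(n))
        p_unc = float((np.abs(means[:, j]) >= abs(obs_mean) - 1e-12).mean())
        p_corr = float((max_abs_t >= abs(obs_t) - 1e-12).mean())
        rows.append(dict(roi=roi, d_z=cohens_dz(X[:, j]), mean=obs_mean,
                         p_unc=p_unc, p_corrected=p_corr))
    return pd.DataFrame(rows)


def region_comparison_test(effects: pd.DataFrame, n_permutations: int = 10000,
                           seed: int = 0) -> dict:
    """Permutation tests of between-region differences.

    ``effects`` is participants x regions.  The null independently permutes
    each participant's vector of region values (preserving every
    participant's multiset).  Pairwise statistics are differences of region
    means; the omnibus statistic is the one-way repeated-measures F over
    regions.
    """
    X = effects.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("missing cells are not allowed")
    n, k = X.shape
    rng = np.random.default_rng(seed)
    obs_F = _rm_f_statistic(X)
    obs_pair = {}
    for i in range(k):
        for j in range(i + 1, k):
            obs_pair[(i, j)] = X[:, i].mean() - X[:, j].mean()
    count_F = 1
    count_pair = {key: 1 for key in obs_pair}
    for _ in range(n_permutations - 1):
        perm = X.copy()
        for r in range(n):
            rng.shuffle(perm[r])
        if _rm_f_statistic(perm) >= obs_F - 1e-12:
            count_F += 1
        for (i, j), obs in obs_pair.items():
            d = perm[:, i].mean() - perm[:, j].mean()
            if abs(d) >= abs(obs) - 1e-12:
                count_pair[(i, j)] += 1
    cols = list(effects.columns)
    pairwise = {(cols[i], cols[j]): dict(difference=obs,
                                         p=count_pair[(i, j)] / n_permutations)
                for (i, j), obs in obs_pair.items()}
    return dict(omnibus_F=obs_F, omnibus_p=count_F / n_permutations,
                pairwise=pairwise)


def _rm_f_statistic(X: np.ndarray) -> float:
    """Uncorrected one-way repeated-measures F over columns."""
    n, k = X.shape
    grand = X.mean()
    col_means = X.mean(axis=0)
    row_means = X.mean(axis=1)
    ss_effect = n * ((col_means - grand) ** 2).sum()
    resid = X - col_means[None, :] - row_means[:, None] + grand
    ss_error = (resid ** 2).sum()
    if ss_error == 0:
        return 0.0 if ss_effect == 0 else np.inf
    return float((ss_effect / (k - 1)) / (ss_error / ((k - 1) * (n - 1))))


def greenhouse_geisser_epsilon(X: np.ndarray) -> float:
    """GG epsilon from the double-centered sample covariance of the columns."""
    n, k = X.shape
    S = np.cov(X, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) \
        + S.mean()
    denom = (k - 1) * (Sc ** 2).sum()
    if denom <= 0:
        return 1.0 / (k - 1)
    eps = np.trace(Sc) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def omnibus_rm_anova(effects: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA over regions with GG-corrected dfs."""
    X = effects.to_numpy(float)
    n, k = X.shape
    if k < 3:
        raise ValueError("need at least three regions for the omnibus test")
    F = _rm_f_statistic(X)
    eps = greenhouse_geisser_epsilon(X)
    df1 = eps * (k - 1)
    df2 = eps * (k - 1) * (n - 1)
    p = float(stats.f.sf(F, df1, df2))
    return dict(F=F, df1=df1, df2=df2, epsilon=eps, p=p)


# --------------------------------------------------------------------------
# Default sphere configuration
# --------------------------------------------------------------------------

def default_spheres(phantom) -> list[SphereSpec]:
    """Twelve MD and ten language spheres at the phantom's truth centers.

    In a real study the MD centers come from an external group image and the
    language centers from smoothed language-contrast peaks; the shipped
    defaults place them at the simulation's ground-truth region centers.
    Midline pre-SMA/AC style regions keep their lattice centers (the x = +/-6
    convention for midline peaks becomes relevant only with real coordinates).
    """
    out = []
    for r in phantom.regions:
        if r.family not in ("md", "language"):
            continue
        out.append(SphereSpec(
            name=r.name, center_mm=tuple(map(float, phantom.center_mm(r))),
            radius_mm=8.0, network=r.family, hemisphere=r.name.split()[0]))
    return out
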