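"""First-level GLM: HRF construction, design matrices, per-voxel fits, contrasts.

The hemodynamic response function is a difference of two gamma densities
parameterized by peak time and FWHM (first peak 5.4 s, FWHM 5.2 s; second
peak 15 s, FWHM 10 s; second-gamma coefficient 0.09).  Condition regressors
are unit-height boxcars over 16-s blocks convolved with this kernel; rest is
the implicit baseline.  The full design holds 16 columns: 4 condition
regressors, 6 motion parameters, white-matter and CSF series, 3 cubic-spline
temporal trends, and an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import ACTIVE_CONDITIONS, BLOCK_S, Block


# --------------------------------------------------------------------------
# HRF
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Difference-of-gammas HRF parameters (times in seconds)."""

    peak1_s: float = 5.4
    fwhm1_s: float = 5.2
    peak2_s: float = 15.0
    fwhm2_s: float = 10.0
    c2: float = 0.09


@dataclass(frozen=True)
class HRFKernel:
    samples: np.ndarray
    dt_s: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_s


def _gamma_fwhm_unit_scale(shape: float) -> float:
    """FWHM of a gamma density with the given shape and unit scale."""
    if shape <= 1:
        raise ValueError("shape must exceed 1 for an interior mode")
    mode = shape - 1.0
    dist = stats.gamma(shape)
    half = dist.pdf(mode) / 2.0
    f = lambda x: dist.pdf(x) - half
    # for shapes near 1 the density never drops below half-max left of the
    # mode; the width is then measured from zero
    left = 0.0 if f(1e-12) > 0 else optimize.brentq(f, 1e-12, mode)
    hi = mode + 1.0
    while f(hi) > 0:
        hi *= 2.0
    right = optimize.brentq(f, mode, hi)
    return right - left


def gamma_from_peak_fwhm(peak_s: float, fwhm_s: float):
    """Gamma density with the requested mode and FWHM.

    The mode of a gamma(shape a, scale s) density is (a-1)s and its FWHM
    scales linearly with s at fixed a, so the dimensionless ratio
    FWHM/mode pins down the shape; the scale then follows from the mode.
    Returns a frozen ``scipy.stats.gamma`` distribution.
    """
    if peak_s <= 0 or fwhm_s <= 0:
        raise ValueError("peak and FWHM must be positive")
    target = fwhm_s / peak_s

    def ratio_err(a: float) -> float:
        return _gamma_fwhm_unit_scale(a) / (a - 1.0) - target

    try:
        shape = optimize.brentq(ratio_err, 1.0 + 1e-6, 5000.0, xtol=1e-12)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"gamma solve failed for peak={peak_s}, fwhm={fwhm_s}: {exc}"
        )
    scale = peak_s / (shape - 1.0)
    return stats.gamma(shape, scale=scale)


def build_hrf(params: HRFParams = HRFParams(), dt_s: float = 0.1,
              span_s: float = 32.0) -> HRFKernel:
    """Sample gamma1 - c2*gamma2 on [0, span], normalized to unit integral.

    Unit integral makes the steady-state response to a sustained unit boxcar
    equal one, so condition coefficients are read directly in signal units of
    sustained block response.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    g1 = gamma_from_peak_fwhm(params.peak1_s, params.fwhm1_s)
    g2 = gamma_from_peak_fwhm(params.peak2_s, params.fwhm2_s)
    t = np.arange(0.0, span_s + dt_s / 2, dt_s)
    k = g1.pdf(t) - params.c2 * g2.pdf(t)
    k = k / (k.sum() * dt_s)
    return HRFKernel(samples=k, dt_s=dt_s)


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------

CONTRASTS: dict[str, np.ndarray] = {
    "semantic_easy_vs_rest": np.array([1.0, 0, 0, 0]),
    "semantic_difficult_vs_rest": np.array([0, 1.0, 0, 0]),
    "perceptual_easy_vs_rest": np.array([0, 0, 1.0, 0]),
    "perceptual_difficult_vs_rest": np.array([0, 0, 0, 1.0]),
    # Semantic Difficult - Semantic Easy
    "linguistic_demand": np.array([-1.0, 1.0, 0, 0]),
    # Perceptual Difficult - Perceptual Easy
    "nonlinguistic_demand": np.array([0, 0, -1.0, 1.0]),
    # (SE + SD) - (PE + PD)
    "language": np.array([1.0, 1.0, -1.0, -1.0]),
    # (SD - SE) - (PD - PE)
    "interaction": np.array([-1.0, 1.0, 1.0, -1.0]),
}


def spline_trend_basis(n_volumes: int, tr_s: float) -> np.ndarray:
    """Three natural-cubic-spline temporal trend columns over the run.

    Knots sit at the run start, 1/3, 2/3, and end, which yields exactly three
    basis functions beyond the constant (the constant lives in the intercept
    column).  Columns are centered and scaled to unit SD for conditioning.
    """
    t = np.arange(n_volumes) * tr_s
    knots = np.linspace(t[0], t[-1], 4)

    def d(k):
        return (np.maximum(t - knots[k], 0) ** 3
                - np.maximum(t - knots[-1], 0) ** 3) / (knots[-1] - knots[k])

    cols = np.column_stack([t, d(0) - d(2), d(1) - d(2)])
    cols = cols - cols.mean(axis=0)
    cols = cols / cols.std(axis=0)
    return cols


def condition_regressors(blocks: list[Block], hrf: HRFKernel, tr_ms: float,
                         n_volumes: int, onset_shift_s: float = 0.0) -> np.ndarray:
    """Boxcar-convolved condition regressors sampled at volume times.

    Convolution runs on the kernel's internal grid (0.1 s by default) and the
    result is sampled at acquisition times k*TR + onset_shift.
    """
    tr_s = tr_ms / 1000.0
    dt = hrf.dt_s
    total_s = n_volumes * tr_s + onset_shift_s + BLOCK_S
    n_fine = int(np.ceil(total_s / dt)) + 1
    fine_t = np.arange(n_fine) * dt
    out = np.zeros((n_volumes, len(ACTIVE_CONDITIONS)))
    vol_t = np.arange(n_volumes) * tr_s + onset_shift_s
    for j, cond in enumerate(ACTIVE_CONDITIONS):
        box = np.zeros(n_fine)
        for b in blocks:
            if b.condition == cond:
                i0 = int(round(b.onset_s / dt))
                i1 = int(round((b.onset_s + b.duration_s) / dt))
                box[i0:i1] = 1.0
        conv = np.convolve(box, hrf.samples)[:n_fine] * dt
        out[:, j] = np.interp(vol_t, fine_t, conv)
    return out


@dataclass
class DesignMatrix:
    X: np.ndarray
    columns: list[str]

    def __post_init__(self):
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def condition_index(self) -> np.ndarray:
        return np.array([self.columns.index(c) for c in ACTIVE_CONDITIONS])


def build_design_matrix(blocks: list[Block], nuisance: pd.DataFrame,
                        hrf: HRFKernel, tr_ms: float) -> DesignMatrix:
    """Assemble the 16-column first-level design.

    ``nuisance`` must carry the 6 motion columns (trans_x..rot_z) plus ``wm``
    and ``csf``; its row count fixes the number of volumes.  Nuisance and
    trend columns are centered so the intercept estimates the rest baseline.
    """
    n_volumes = len(nuisance)
    motion_cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    needed = motion_cols + ["wm", "csf"]
    missing = [c for c in needed if c not in nuisance.columns]
    if missing:
        raise ValueError(f"nuisance table missing columns: {missing}")
    tr_s = tr_ms / 1000.0
    if max(b.onset_s + b.duration_s for b in blocks) > n_volumes * tr_s + 1e-6:
        raise ValueError("schedule extends beyond the acquired volumes")

    cond = condition_regressors(blocks, hrf, tr_ms, n_volumes)
    nuis = nuisance[needed].to_numpy(float)
    nuis = nuis - nuis.mean(axis=0)
    trends = spline_trend_basis(n_volumes, tr_s)
    intercept = np.ones((n_volumes, 1))
    X = np.hstack([cond, nuis, trends, intercept])
    columns = (list(ACTIVE_CONDITIONS) + needed
               + ["spline_1", "spline_2", "spline_3", "intercept"])
    return DesignMatrix(X=X, columns=columns)


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass
class GLMFit:
    beta: np.ndarray          # (n_columns, n_voxels)
    sigma2: np.ndarray        # (n_voxels,)
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray
    shape3d: tuple[int, int, int] | None = None


def legendre_trends(n_volumes: int, degree: int) -> np.ndarray:
    """Legendre polynomial trend columns P1..P_degree on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    return np.column_stack([np.polynomial.legendre.Legendre.basis(d)(x)
                            for d in range(1, degree + 1)])


def fit_glm(data: np.ndarray, design: DesignMatrix, *,
            ar1_prewhiten: bool = False,
            legendre_degree: int | None = None) -> GLMFit:
    """Ordinary least squares per voxel.

    ``data`` is (x, y, z, time) or (time, n_voxels).  With
    ``ar1_prewhiten=True`` a lag-1 autocorrelation coefficient is estimated
    per voxel from the OLS residuals and the model refit once on the
    quasi-differenced data (voxels grouped into 0.01-wide rho bins so the
    refit stays vectorized).

    ``legendre_degree`` emulates polynomial detrending as a preprocessing
    step: Legendre trend columns up to that degree are appended to the model
    for estimation (the consistent form of detrending both data and design),
    reducing the residual df accordingly; reported coefficients cover only
    the nominal design columns.
    """
    shape3d = None
    if data.ndim == 4:
        shape3d = data.shape[:3]
        Y = data.reshape(-1, data.shape[3]).T
    elif data.ndim == 2:
        Y = data
    else:
        raise ValueError("data must be 4D (x,y,z,t) or 2D (t, voxels)")
    if not np.all(np.isfinite(Y)):
        bad = np.where(~np.all(np.isfinite(Y), axis=0))[0]
        raise ValueError(f"non-finite data at voxel indices {bad[:10]}")
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("design rows must match the number of volumes")
    if legendre_degree:
        T = legendre_trends(n, legendre_degree)
        # residualize against the design: components already in the model
        # span (constant, the linear spline term) drop out, and the retained
        # orthogonal columns leave the nominal coefficients identified
        T = T - X @ np.linalg.lstsq(X, T, rcond=None)[0]
        norms = np.linalg.norm(T, axis=0)
        keep = norms > 1e-8 * np.sqrt(n)
        if keep.any():
            X = np.hstack([X, T[:, keep] / norms[keep]])
    p_full = X.shape[1]
    xtx_inv_full = np.linalg.inv(X.T @ X)
    beta = xtx_inv_full @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p_full
    sigma2 = (resid ** 2).sum(axis=0) / df
    beta = beta[:p]
    xtx_inv = xtx_inv_full[:p, :p]

    if ar1_prewhiten:
        num = (resid[1:] * resid[:-1]).sum(axis=0)
        den = (resid ** 2).sum(axis=0)
        rho = np.where(den > 0, num / den, 0.0)
        rho = np.clip(rho, -0.95, 0.95)
        bins = np.round(rho, 2)
        beta = np.empty((p, Y.shape[1]))
        sigma2 = np.empty(Y.shape[1])
        xtx_inv_by_bin = {}
        for r in np.unique(bins):
            idx = bins == r
            Xw = np.vstack([X[:1] * np.sqrt(1 - r ** 2), X[1:] - r * X[:-1]])
            Yv = Y[:, idx]
            Yw = np.vstack([Yv[:1] * np.sqrt(1 - r ** 2), Yv[1:] - r * Yv[:-1]])
            inv = np.linalg.inv(Xw.T @ Xw)
            b = inv @ (Xw.T @ Yw)
            rw = Yw - Xw @ b
            beta[:, idx] = b[:p]
            sigma2[idx] = (rw ** 2).sum(axis=0) / df
            xtx_inv_by_bin[float(r)] = inv[:p, :p]
        # report the modal bin's covariance factor for contrast SEs
        counts = {float(r): int((bins == r).sum()) for r in np.unique(bins)}
        xtx_inv = xtx_inv_by_bin[max(counts, key=counts.get)]

    return GLMFit(beta=beta, sigma2=sigma2, df=df, design=design,
                  xtx_inv=xtx_inv, shape3d=shape3d)


@dataclass
class ContrastResult:
    name: str
    effect: np.ndarray
    t: np.ndarray
    variance: np.ndarray      # sampling variance of the effect estimate
    df: int
    shape3d: tuple[int, int, int] | None = None

    def effect_map(self) -> np.ndarray:
        return self.effect.reshape(self.shape3d) if self.shape3d else self.effect

    def t_map(self) -> np.ndarray:
        return self.t.reshape(self.shape3d) if self.shape3d else self.t


def contrast_weights(name: str, design: DesignMatrix) -> np.ndarray:
    if name not in CONTRASTS:
        raise KeyError(f"unknown contrast {name!r}; known: {sorted(CONTRASTS)}")
    w = np.zeros(len(design.columns))
    w[design.condition_index] = CONTRASTS[name]
    return w


def estimate_contrast(fit: GLMFit, name: str) -> ContrastResult:
    """Effect w'beta and its t statistic for a named contrast."""
    w = contrast_weights(name, fit.design)
    effect = w @ fit.beta
    var = fit.sigma2 * float(w @ fit.xtx_inv @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    return ContrastResult(name=name, effect=effect, t=t, variance=var,
                          df=fit.df, shape3d=fit.shape3d)


def combine_runs(a: ContrastResult, b: ContrastResult) -> ContrastResult:
    """Participant-level contrast: unweighted mean of the two run effects."""
    if a.shape3d != b.shape3d or a.effect.shape != b.effect.shape:
        raise ValueError("run results are on different grids")
    effect = 0.5 * (a.effect + b.effect)
    var = 0.25 * (a.variance + b.variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    return ContrastResult(name=a.name, effect=effect, t=t, variance=var,
                          df=a.df + b.df, shape3d=a.shape3d)
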