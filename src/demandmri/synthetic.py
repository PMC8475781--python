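"""Ground-truth phantoms, simulated BOLD runs, and behavioral trial outcomes.

The phantom stands in for the study cohort's brains: disjoint truth regions
carry known sustained-response amplitudes for the four active conditions, on
top of a constant baseline, a slow quadratic drift, and AR(1)-colored
Gaussian noise.  Three region families mirror the qualitative functional
profiles the analysis is meant to recover:

* ``md`` (multiple-demand-like): positive modulation by both kinds of demand,
  larger for non-linguistic demand (negative domain-by-difficulty
  interaction);
* ``language``-like: positive modulation by linguistic demand, none (or
  slightly negative) by non-linguistic demand (positive interaction);
* ``dmn`` (default-mode-like): deactivated by difficulty in both domains.

The behavioral simulator draws go/no-go responses and lognormal reaction
times so that difficulty lowers accuracy and slows responses identically in
both domains in expectation, while errors in the semantic-difficult
condition are mostly misses and errors in the perceptual-difficult condition
mostly false alarms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from . import design as dsg
from . import glm as glm_mod

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

MD_NAMES = [f"{h} {r}" for r in ("IFJ", "aIns", "SMA/AC", "PMd", "IPS", "OT")
            for h in ("L", "R")]
LANGUAGE_NAMES = [f"L {r}" for r in
                  ("IFGpop", "IFGpt", "SMA/AC-lang", "Fus", "pSTS", "aSTS", "Hipp")] \
                 + [f"R {r}" for r in ("IFGpt", "pSTS", "aSTS")]
DMN_NAMES = ["L Precuneus", "R Precuneus"]

DEFAULT_AMPLITUDES = {
    # sustained block response in signal units (baseline 100)
    "md": {"semantic_easy": 0.5, "semantic_difficult": 1.0,
           "perceptual_easy": 0.5, "perceptual_difficult": 1.6},
    "language": {"semantic_easy": 1.0, "semantic_difficult": 1.8,
                 "perceptual_easy": 0.1, "perceptual_difficult": 0.0},
    "dmn": {"semantic_easy": 0.0, "semantic_difficult": -0.8,
            "perceptual_easy": 0.0, "perceptual_difficult": -1.2},
}


@dataclass(frozen=True)
class Region:
    name: str
    family: str                    # md | language | dmn
    center_vox: tuple[int, int, int]
    radius_vox: float
    amplitudes: dict[str, float]


@dataclass
class PhantomSpec:
    grid_dims: tuple[int, int, int] = (24, 24, 18)
    voxel_mm: float = 3.0
    regions: list[Region] = field(default_factory=list)
    baseline: float = 100.0
    noise_sd: float = 0.75
    drift: tuple[float, float] = (1.0, -0.5)   # linear, quadratic (signal units)
    ar1: float = 0.3
    participant_scale_sd: float = 0.15

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        aff[:3, 3] = -(np.array(self.grid_dims) - 1) / 2.0 * self.voxel_mm
        return aff

    def region_mask(self, region: Region) -> np.ndarray:
        idx = np.indices(self.grid_dims)
        c = np.array(region.center_vox).reshape(3, 1, 1, 1)
        return ((idx - c) ** 2).sum(axis=0) <= region.radius_vox ** 2

    def center_mm(self, region: Region) -> np.ndarray:
        v = np.array(region.center_vox + (1,), float)
        return (self.affine @ v)[:3]

    def truth_table(self) -> dict:
        out = {}
        for r in self.regions:
            amps = dict(r.amplitudes)
            out[r.name] = dict(
                family=r.family,
                amplitudes=amps,
                linguistic_demand=amps["semantic_difficult"] - amps["semantic_easy"],
                nonlinguistic_demand=(amps["perceptual_difficult"]
                                      - amps["perceptual_easy"]),
                interaction=(amps["semantic_difficult"] - amps["semantic_easy"])
                            - (amps["perceptual_difficult"] - amps["perceptual_easy"]),
                center_mm=list(map(float, self.center_mm(r))),
            )
        return out


def _lattice_positions(grid_dims, hemisphere):
    """Fixed lattice of candidate region centers for one hemisphere."""
    nx, ny, nz = grid_dims
    xs = [nx // 6, nx // 2 - nx // 6] if hemisphere == "L" \
        else [nx // 2 + nx // 6, nx - 1 - nx // 6]
    ys = [round(q * (ny - 1)) for q in (0.18, 0.4, 0.62, 0.84)]
    zs = [round(q * (nz - 1)) for q in (0.22, 0.5, 0.78)]
    return [(x, y, z) for z in zs for y in ys for x in xs]


def make_phantom(grid_dims=(24, 24, 18), voxel_mm=3.0, *, baseline=100.0,
                 noise_sd=0.75, ar1=0.3, drift=(1.0, -0.5),
                 amplitudes: dict | None = None, radius_vox=1.8,
                 participant_scale_sd=0.15, null=False) -> PhantomSpec:
    """Default phantom: 12 MD-like, 10 language-like, 2 default-mode regions.

    Region centers sit on a fixed per-hemisphere lattice so all masks are
    pairwise disjoint.  ``null=True`` zeroes every amplitude (global-null
    phantom for calibration work).
    """
    amps = amplitudes or DEFAULT_AMPLITUDES
    if null:
        amps = {fam: {c: 0.0 for c in a} for fam, a in amps.items()}
    pos = {h: _lattice_positions(grid_dims, h) for h in ("L", "R")}
    cursor = {"L": 0, "R": 0}

    def take(h):
        p = pos[h][cursor[h]]
        cursor[h] += 1
        return p

    regions = []
    for name in MD_NAMES:
        h = name.split()[0]
        regions.append(Region(name, "md", take(h), radius_vox, dict(amps["md"])))
    for name in LANGUAGE_NAMES:
        h = name.split()[0]
        regions.append(Region(name, "language", take(h), radius_vox,
                              dict(amps["language"])))
    for name in DMN_NAMES:
        h = name.split()[0]
        regions.append(Region(name, "dmn", take(h), radius_vox, dict(amps["dmn"])))

    spec = PhantomSpec(grid_dims=tuple(grid_dims), voxel_mm=voxel_mm,
                       regions=regions, baseline=baseline, noise_sd=noise_sd,
                       drift=tuple(drift), ar1=ar1,
                       participant_scale_sd=participant_scale_sd)
    _check_disjoint(spec)
    return spec


def _check_disjoint(spec: PhantomSpec) -> None:
    total = np.zeros(spec.grid_dims, dtype=int)
    for r in spec.regions:
        m = spec.region_mask(r)
        if not m.any():
            raise ValueError(f"region {r.name} is empty")
        total += m
    if (total > 1).any():
        raise ValueError("region masks overlap")


@dataclass
class BOLDRun:
    data: np.ndarray               # (x, y, z, time), dummy volumes removed
    tr_ms: float
    nuisance: pd.DataFrame
    affine: np.ndarray
    schedule: dsg.BlockSchedule | None = None

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def _ar1_noise(rng, shape_spatial, n_t, sd, rho):
    """Stationary AR(1) series with marginal SD ``sd`` along the last axis."""
    n_vox = int(np.prod(shape_spatial))
    eps = rng.standard_normal((n_vox, n_t))
    if rho == 0:
        return (sd * eps).reshape(*shape_spatial, n_t)
    innov_sd = np.sqrt(1.0 - rho ** 2)
    eps[:, 1:] *= innov_sd
    out = signal.lfilter([1.0], [1.0, -rho], eps, axis=1)
    return (sd * out).reshape(*shape_spatial, n_t)


def simulate_nuisance(rng, n_volumes: int) -> pd.DataFrame:
    """Six motion parameters plus WM/CSF series as smooth random walks."""
    cols = {}
    scales = dict(trans_x=0.02, trans_y=0.02, trans_z=0.02,
                  rot_x=0.0004, rot_y=0.0004, rot_z=0.0004, wm=0.05, csf=0.05)
    for name, s in scales.items():
        walk = np.cumsum(rng.normal(0.0, s, n_volumes))
        cols[name] = ndimage.gaussian_filter1d(walk, sigma=2.0)
    return pd.DataFrame(cols)


def simulate_run(phantom: PhantomSpec, schedule: dsg.BlockSchedule,
                 hrf: glm_mod.HRFKernel, seed: int, *, tr_ms: float = 2000.0,
                 n_dummy: int = 4, amplitude_scale: float = 1.0,
                 nuisance_coupling: float = 0.2) -> BOLDRun:
    """One simulated 4D run for the given block schedule.

    ``n_dummy + run/TR`` volumes of noise are generated and the first
    ``n_dummy`` discarded, emulating discarded initial volumes; the retained
    grid is exactly the acquisition grid the first-level model sees.  Signal
    per voxel is baseline + sum of region amplitude x (boxcar convolved with
    the HRF), plus quadratic drift, a small coupling to the simulated WM/CSF
    series, and AR(1) Gaussian noise.  ``amplitude_scale`` multiplies every
    region amplitude (per-participant responsiveness).
    """
    tr_s = tr_ms / 1000.0
    n_ret = int(round(schedule.run_duration_s / tr_s))
    if abs(n_ret * tr_s - schedule.run_duration_s) > 1e-6:
        raise ValueError("run duration is not a whole number of volumes")
    rng = np.random.default_rng(seed)

    reg = glm_mod.condition_regressors(list(schedule.blocks), hrf, tr_ms, n_ret)
    data = np.empty(phantom.grid_dims + (n_dummy + n_ret,))
    data[:] = phantom.baseline
    noise = _ar1_noise(rng, phantom.grid_dims, n_dummy + n_ret,
                       phantom.noise_sd, phantom.ar1)
    x = np.linspace(-1.0, 1.0, n_dummy + n_ret)
    drift = phantom.drift[0] * x + phantom.drift[1] * (1.5 * x ** 2 - 0.5)
    data += noise + drift

    nuisance = simulate_nuisance(rng, n_ret)
    data = data[..., n_dummy:]
    glob = nuisance_coupling * (nuisance["wm"] + nuisance["csf"]).to_numpy()
    data += glob

    for r in phantom.regions:
        mask = phantom.region_mask(r)
        ts = sum(amplitude_scale * r.amplitudes[c] * reg[:, j]
                 for j, c in enumerate(dsg.ACTIVE_CONDITIONS))
        data[mask] += ts

    return BOLDRun(data=data, tr_ms=tr_ms, nuisance=nuisance,
                   affine=phantom.affine, schedule=schedule)


# --------------------------------------------------------------------------
# Smoothing
# --------------------------------------------------------------------------

def gaussian_smooth(volume: np.ndarray, fwhm_mm: float,
                    voxel_mm: float) -> np.ndarray:
    """3D Gaussian smoothing with reflective boundaries.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted from mm to voxels.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return volume.copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    return ndimage.gaussian_filter(volume, sigma=sigma, mode="reflect")


# --------------------------------------------------------------------------
# Behavior
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionBehavior:
    hit_p: float
    fa_p: float
    rt_log_mean: float
    rt_log_sd: float


DEFAULT_BEHAVIOR = {
    # hit/false-alarm probabilities conditional on trial type; with the mean
    # match proportion of 1/2 these yield ~14.4% misses + 3.6% false alarms
    # (semantic difficult) and ~3.5% + 15.2% (perceptual difficult) over all
    # trials, and a difficulty effect on RT with no domain effect.
    "semantic_easy": ConditionBehavior(0.97, 0.02, np.log(700.0), 0.22),
    "semantic_difficult": ConditionBehavior(0.712, 0.072, np.log(1000.0), 0.25),
    "perceptual_easy": ConditionBehavior(0.97, 0.02, np.log(700.0), 0.22),
    "perceptual_difficult": ConditionBehavior(0.93, 0.304, np.log(1000.0), 0.25),
}


@dataclass
class BehavioralParams:
    conditions: dict[str, ConditionBehavior] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR))
    participant_logit_sd: float = 0.35
    participant_rt_log_sd: float = 0.08
    sublevel_logit_step: float = 0.25   # harder sub-level -> lower accuracy
    adaptive_update: str = "block"      # "block" or "trial"


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_behavior(schedule: dsg.BlockSchedule, trials: dsg.TrialSchedule,
                      params: BehavioralParams, seed: int, *,
                      state: dsg.AdaptiveState | None = None,
                      skill: float = 0.0, rt_shift: float = 0.0) -> pd.DataFrame:
    """Trial-level responses and reaction times for one run.

    ``skill`` (logit units) and ``rt_shift`` (log-ms units) are the
    participant's random offsets; ``state`` carries the adaptive
    semantic-difficult sub-level tracker across runs.
    """
    rng = np.random.default_rng(seed)
    state = state if state is not None else dsg.AdaptiveState()
    rows = []
    for block, block_trials in zip(schedule.blocks, trials.trials):
        if block.condition == dsg.REST:
            rows.append(dict(onset=block.onset_s, duration=block.duration_s,
                             trial_type=dsg.REST, is_match=np.nan,
                             sub_level="n/a", response_time_ms=np.nan))
            continue
        cb = params.conditions[block.condition]
        sub = (dsg.select_sublevel(state)
               if block.condition == "semantic_difficult" else None)
        for tr in block_trials:
            if (block.condition == "semantic_difficult"
                    and params.adaptive_update == "trial"):
                sub = dsg.select_sublevel(state)
            shift = skill - params.sublevel_logit_step * ((sub or 2) - 2)
            hit_p = _expit(_logit(cb.hit_p) + shift)
            fa_p = _expit(_logit(cb.fa_p) - shift)
            responded = (rng.random() < hit_p) if tr.is_match \
                else (rng.random() < fa_p)
            rt = float(rng.lognormal(cb.rt_log_mean + rt_shift, cb.rt_log_sd)) \
                if responded else np.nan
            correct = responded == tr.is_match
            state.record(block.condition, correct)
            rows.append(dict(
                onset=block.onset_s + tr.onset_in_block_s,
                duration=trials.soa_s,
                trial_type=block.condition,
                is_match=int(tr.is_match),
                sub_level=sub if sub is not None else "n/a",
                response_time_ms=rt,
            ))
    return pd.DataFrame(rows)


def draw_participant_offsets(params: BehavioralParams, rng) -> tuple[float, float]:
    return (float(rng.normal(0.0, params.participant_logit_sd)),
            float(rng.normal(0.0, params.participant_rt_log_sd)))


def save_truth_table(path, phantom: PhantomSpec) -> None:
    with open(path, "w") as fh:
        json.dump(phantom.truth_table(), fh, indent=1)
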