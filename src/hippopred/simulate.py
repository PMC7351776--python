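"""Synthetic per-ROI BOLD generation with known ground truth.

Each ROI is a list of voxels.  Every room has a fixed multivoxel template
per ROI (unit-variance Gaussian components).  On each trial the cue event
carries the room template (reinstatement) and the image event carries a
partially corrupted copy of it, with a fraction of components resampled
per unit change.  Trial amplitudes ("gains") of the image events are
latent variables whose across-trial correlation between ROI pairs is set
per total-changes level — this is exactly the estimand of beta-series
connectivity, so recovery can be checked against stored ground truth.
Timeseries are baseline + polynomial drift + HRF-convolved event signal +
AR(1) Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as spsig

from .design import DesignSpec, TrialSchedule
from .glm import HRFParams, convolve_events_batch

ROI_CA1 = "CA1"
ROI_CA3 = "CA23DG"   # CA2/CA3/dentate gyrus combined, as segmented
ROI_ERC = "ERC"      # entorhinal cortex

PAIR_ERC = (ROI_CA1, ROI_ERC)
PAIR_CA3 = (ROI_CA1, ROI_CA3)

#: default coupling profiles: a match<mismatch-shaped increase for
#: CA1-entorhinal, a linear-shaped decrease for CA1-CA3
DEFAULT_COUPLING: dict[tuple[str, str], dict[int, float]] = {
    PAIR_ERC: {0: 0.05, 1: 0.28, 2: 0.28, 3: 0.34, 4: 0.34},
    PAIR_CA3: {0: 0.40, 1: 0.30, 2: 0.25, 3: 0.15, 4: 0.10},
}

FLAT_COUPLING: dict[tuple[str, str], dict[int, float]] = {
    PAIR_ERC: {c: 0.25 for c in range(5)},
    PAIR_CA3: {c: 0.25 for c in range(5)},
}


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters for one participant's synthetic data."""

    roi_specs: tuple[tuple[str, int], ...] = (
        (ROI_CA1, 24), (ROI_CA3, 20), (ROI_ERC, 20))
    hrf_params: HRFParams = field(default_factory=HRFParams)
    pattern_strength_cue: float = 0.7
    pattern_strength_image: float = 0.7
    change_corruption_fraction: float = 0.15
    coupling_by_changes: dict[tuple[str, str], dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COUPLING.items()})
    gain_mean: float = 1.0
    gain_sd: float = 0.6
    cue_gain_sd: float | None = None    # None: same as gain_sd
    gain_by_changes: dict[int, float] = field(
        default_factory=lambda: {c: 1.0 for c in range(5)})
    baseline_amp: float = 100.0
    noise_sd: float = 0.7
    ar1_coef: float = 0.3
    drift_order: int = 1
    drift_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.roi_specs or any(n < 1 for _, n in self.roi_specs):
            raise ValueError("every ROI must have at least one voxel")
        for name in ("pattern_strength_cue", "pattern_strength_image",
                     "gain_mean", "gain_sd", "baseline_amp", "noise_sd",
                     "drift_amp"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.change_corruption_fraction <= 1.0:
            raise ValueError("change_corruption_fraction must be in [0, 1]")
        if 4 * self.change_corruption_fraction > 1.0 + 1e-12:
            raise ValueError("corruption budget exceeded: "
                             "4 * change_corruption_fraction must be <= 1")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must be in [0, 1)")
        for pair, prof in self.coupling_by_changes.items():
            for c, rho in prof.items():
                if not 0.0 <= rho < 1.0:
                    raise ValueError(
                        f"coupling for {pair} at {c} changes must be in [0, 1)")

    @property
    def roi_names(self) -> list[str]:
        return [name for name, _ in self.roi_specs]

    def n_voxels(self, roi: str) -> int:
        return dict(self.roi_specs)[roi]


@dataclass
class ROIRunData:
    """Voxels x timepoints BOLD matrix for one ROI in one scan."""

    roi_name: str
    scan_index: int
    data: np.ndarray
    tr_s: float
    spec: DesignSpec

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in simulated timeseries")


@dataclass
class GroundTruth:
    """Latent quantities the downstream analyses try to recover."""

    room_templates: dict[str, dict[str, np.ndarray]]   # roi -> room -> pattern
    trial_gains: dict[str, np.ndarray]                 # roi -> (n_trials,) image gains
    cue_gains: dict[str, np.ndarray]                   # roi -> (n_trials,)
    image_patterns: dict[str, np.ndarray]              # roi -> trials x voxels (corrupted)

    def pair_gain_correlation(self, pair: tuple[str, str],
                              trial_mask: np.ndarray) -> float:
        """Direct correlation of stored image gains over selected trials."""
        a = self.trial_gains[pair[0]][trial_mask]
        b = self.trial_gains[pair[1]][trial_mask]
        return float(np.corrcoef(a, b)[0, 1])


def corrupt_pattern(template: np.ndarray, total_changes: int,
                    fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Resample ``total_changes * fraction`` of the template's components.

    Replaced components are fresh draws from the template distribution
    (standard normal); the rest are untouched.  With unit-variance
    independent components the expected correlation with the template is
    ``1 - total_changes * fraction``.
    """
    budget = total_changes * fraction
    if budget > 1.0 + 1e-12:
        raise ValueError("corruption budget exceeded: "
                         f"{total_changes} changes x fraction {fraction} > 1")
    out = template.copy()
    n_replace = int(round(budget * template.size))
    if n_replace:
        idx = rng.choice(template.size, size=n_replace, replace=False)
        out[idx] = rng.standard_normal(n_replace)
    return out


def _draw_image_gains(schedule: TrialSchedule, params: SimulationParams,
                      rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Latent image amplitudes with the requested per-condition coupling.

    A shared factor drives CA1; the other ROI of each pair loads on it
    with weight rho(c), giving across-trial corr(CA1, other) = rho(c) per
    total-changes level by construction (in expectation).
    """
    n = len(schedule)
    changes = np.array([t.total_changes for t in schedule.trials])
    latent = {roi: np.empty(n) for roi in params.roi_names}
    shared = rng.standard_normal(n)
    indep = {roi: rng.standard_normal(n) for roi in params.roi_names}
    for roi in params.roi_names:
        if roi == ROI_CA1:
            latent[roi] = shared
            continue
        pair = (ROI_CA1, roi)
        prof = params.coupling_by_changes.get(pair)
        if prof is None:
            latent[roi] = indep[roi]
            continue
        rho = np.array([prof[c] for c in changes])
        latent[roi] = rho * shared + np.sqrt(1.0 - rho ** 2) * indep[roi]
    mean = np.array([params.gain_mean * params.gain_by_changes[c]
                     for c in changes])
    return {roi: mean + params.gain_sd * z for roi, z in latent.items()}


def _ar1_noise(shape: tuple[int, int], sd: float, phi: float,
               rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(shape) * sd * np.sqrt(max(1.0 - phi ** 2, 1e-12))
    if phi == 0.0:
        return w
    return spsig.lfilter([1.0], [1.0, -phi], w, axis=-1)


def simulate_participant(schedule: TrialSchedule, params: SimulationParams,
                         event_regressors_by_scan: dict[int, tuple] | None = None
                         ) -> tuple[list[ROIRunData], GroundTruth]:
    """Generate all scans of all ROIs for one participant.

    Deterministic in ``params.seed``: two calls with equal arguments give
    bit-identical output.  ``event_regressors_by_scan`` optionally
    supplies precomputed per-scan (cue, image) convolved regressors,
    which are also what the GLM stage uses.
    """
    spec = schedule.spec
    rng = np.random.default_rng(params.seed)
    n_trials = len(schedule)
    rooms = sorted({t.room_id for t in schedule.trials})

    templates = {
        roi: {room: rng.standard_normal(params.n_voxels(roi))
              for room in rooms}
        for roi in params.roi_names
    }
    image_gains = _draw_image_gains(schedule, params, rng)
    cue_sd = params.gain_sd if params.cue_gain_sd is None else params.cue_gain_sd
    cue_gains = {roi: params.gain_mean
                 + cue_sd * rng.standard_normal(n_trials)
                 for roi in params.roi_names}
    image_patterns = {
        roi: np.stack([
            corrupt_pattern(templates[roi][t.room_id], t.total_changes,
                            params.change_corruption_fraction, rng)
            for t in schedule.trials])
        for roi in params.roi_names
    }

    runs: list[ROIRunData] = []
    for scan in range(spec.n_scans):
        trials = schedule.scan_trials(scan)
        T = schedule.scan_timepoints(scan)
        if event_regressors_by_scan is not None:
            cue_reg, img_reg = event_regressors_by_scan[scan]
        else:
            cue_reg = convolve_events_batch(
                [t.cue_onset_s for t in trials],
                [spec.cue_duration_s] * len(trials), T, spec.tr_s,
                params.hrf_params)
            img_reg = convolve_events_batch(
                [t.image_onset_s for t in trials],
                [spec.image_duration_s] * len(trials), T, spec.tr_s,
                params.hrf_params)
        idx = [t.trial_index for t in trials]
        for roi in params.roi_names:
            nv = params.n_voxels(roi)
            # voxel amplitude of each event: gain * (1 + strength * pattern)
            amp_img = (image_gains[roi][idx, None]
                       * (1.0 + params.pattern_strength_image
                          * image_patterns[roi][idx]))
            tmpl = np.stack([templates[roi][t.room_id] for t in trials])
            amp_cue = (cue_gains[roi][idx, None]
                       * (1.0 + params.pattern_strength_cue * tmpl))
            signal = amp_img.T @ img_reg + amp_cue.T @ cue_reg
            tgrid = np.linspace(-1.0, 1.0, T)
            drift = np.zeros((nv, T))
            for k in range(1, params.drift_order + 1):
                coef = rng.standard_normal(nv) * params.drift_amp
                drift += coef[:, None] * tgrid[None, :] ** k
            noise = _ar1_noise((nv, T), params.noise_sd, params.ar1_coef, rng)
            data = params.baseline_amp + drift + signal + noise
            runs.append(ROIRunData(roi_name=roi, scan_index=scan, data=data,
                                   tr_s=spec.tr_s, spec=spec))
    truth = GroundTruth(room_templates=templates, trial_gains=image_gains,
                        cue_gains=cue_gains, image_patterns=image_patterns)
    return runs, truth


# ---------------------------------------------------------------------------
# optional NIfTI export (voxels laid out on a synthetic 1-D grid)


def write_roi_nifti(runs: list[ROIRunData], out_dir) -> list[str]:
    """Write each run as a 4D NIfTI plus a matching binary ROI mask."""
    import pathlib

    import nibabel as nib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    masks_done = set()
    for run in runs:
        nv, T = run.data.shape
        vol = run.data.reshape(nv, 1, 1, T).astype(np.float32)
        affine = np.diag([1.5, 1.5, 2.0, 1.0])
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((1.5, 1.5, 2.0, run.tr_s))
        path = out / f"{run.roi_name}_scan{run.scan_index:02d}_bold.nii.gz"
        nib.save(img, path)
        written.append(str(path))
        if run.roi_name not in masks_done:
            mask = nib.Nifti1Image(np.ones((nv, 1, 1), dtype=np.uint8),
                                   affine[:4, :4])
            mpath = out / f"{run.roi_name}_mask.nii.gz"
            nib.save(mask, mpath)
            written.append(str(mpath))
            masks_done.add(run.roi_name)
    return written
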