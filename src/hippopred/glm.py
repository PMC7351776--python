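"""Design matrices and trial-level GLM estimation.

Implements the canonical double-gamma HRF, boxcar-by-HRF regressor
construction with 0.1 s super-sampling (trial onsets fall on a 0.5 s grid
that is not TR-aligned, so regressors are built on a fine grid and
bin-averaged down to TR resolution), ordinary least squares with voxelwise
t-statistics, the least-squares-separate (LSS) single-trial models for
images and cues, and the per-trial-type condition GLM used for voxel
selection and univariate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as spsig
from scipy import stats as sps

from .design import TRIAL_TYPES, Trial


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response parameters.

    The kernel is the difference of two gamma densities; each gamma is
    parameterized so that its mode equals the stated delay (shape =
    1 + delay/dispersion, scale = dispersion), i.e. ``peak_delay_s`` is
    literally the time of the response peak.  The undershoot is scaled by
    ``1/peak_undershoot_ratio`` and the kernel is normalized to peak 1.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay_s", "undershoot_delay_s", "peak_dispersion_s",
                     "undershoot_dispersion_s", "peak_undershoot_ratio",
                     "length_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def hrf(params: HRFParams = HRFParams(), dt_s: float = 0.1) -> np.ndarray:
    """Sample the double-gamma kernel on a grid of spacing ``dt_s``.

    Returns values at t = 0, dt, 2*dt, ..., length_s, normalized so the
    positive peak equals 1.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    t = np.arange(0.0, params.length_s + dt_s / 2, dt_s)
    peak = sps.gamma.pdf(t, 1.0 + params.peak_delay_s / params.peak_dispersion_s,
                         scale=params.peak_dispersion_s)
    under = sps.gamma.pdf(
        t, 1.0 + params.undershoot_delay_s / params.undershoot_dispersion_s,
        scale=params.undershoot_dispersion_s)
    h = peak - under / params.peak_undershoot_ratio
    return h / h.max()


@lru_cache(maxsize=8)
def _cached_hrf(params: HRFParams, dt_s: float) -> np.ndarray:
    out = hrf(params, dt_s)
    out.setflags(write=False)
    return out


@dataclass
class DesignMatrix:
    """Ordered named columns sampled at TR resolution."""

    names: list[str]
    X: np.ndarray  # timepoints x columns
    tr_s: float

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("column names do not match matrix shape")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite entries")

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]


_OVERSAMPLE_DT = 0.1


def convolve_event(onset_s: float, duration_s: float, timepoints: int,
                   tr_s: float, hrf_params: HRFParams,
                   dt_s: float = _OVERSAMPLE_DT) -> np.ndarray:
    """HRF-convolved boxcar for one event, bin-averaged to TR samples.

    The boxcar is laid out on a ``dt_s`` grid (value = fraction of each
    fine bin covered by the event), convolved with the kernel, scaled by
    ``dt_s`` to approximate the continuous convolution, and averaged
    within each TR bin.
    """
    return convolve_events_batch([onset_s], [duration_s], timepoints, tr_s,
                                 hrf_params, dt_s)[0]


def convolve_events_batch(onsets_s, durations_s, timepoints: int, tr_s: float,
                          hrf_params: HRFParams,
                          dt_s: float = _OVERSAMPLE_DT) -> np.ndarray:
    """Vectorized :func:`convolve_event` over many events.

    Returns an (n_events, timepoints) array; convolution runs on the fine
    grid for all events at once.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    durations = np.asarray(durations_s, dtype=float)
    run_len_s = timepoints * tr_s
    if (onsets < 0).any() or (onsets + durations > run_len_s).any():
        j = int(np.argmax((onsets < 0) | (onsets + durations > run_len_s)))
        raise ValueError(
            f"event [{onsets[j]}, {onsets[j] + durations[j]}] s exceeds run "
            f"of {run_len_s} s")
    n_fine = int(round(run_len_s / dt_s))
    fine_t = np.arange(n_fine) * dt_s
    # coverage fraction of each fine bin [t, t+dt)
    box = np.clip((np.minimum(fine_t[None, :] + dt_s,
                              (onsets + durations)[:, None])
                   - np.maximum(fine_t[None, :], onsets[:, None])) / dt_s,
                  0.0, 1.0)
    kern = _cached_hrf(hrf_params, dt_s)
    conv = spsig.fftconvolve(box, kern[None, :], axes=-1)[:, :n_fine] * dt_s
    per_tr = int(round(tr_s / dt_s))
    if per_tr * timepoints == n_fine:
        return conv.reshape(len(onsets), timepoints, per_tr).mean(axis=2)
    edges = np.round(np.arange(timepoints) * tr_s / dt_s).astype(int)
    widths = np.diff(np.append(edges, n_fine))
    return np.add.reduceat(conv, edges, axis=-1) / widths


def _drift_columns(timepoints: int, drift_order: int) -> tuple[list[str], list[np.ndarray]]:
    names, cols = ["intercept"], [np.ones(timepoints)]
    t = np.linspace(-1.0, 1.0, timepoints)
    for k in range(1, drift_order + 1):
        names.append(f"drift{k}")
        cols.append(t ** k)
    return names, cols


def build_design_matrix(events, timepoints: int, tr_s: float,
                        hrf_params: HRFParams = HRFParams(),
                        add_derivatives: bool = True,
                        drift_order: int = 1) -> DesignMatrix:
    """Build a design matrix from ``(onset_s, duration_s, name)`` events.

    Events sharing a regressor name are merged (their boxcars summed
    before convolution).  Each regressor is followed by its temporal
    derivative column (finite difference of the convolved regressor) when
    ``add_derivatives`` is set; intercept and polynomial drift columns are
    appended last.
    """
    merged: dict[str, np.ndarray] = {}
    for onset, duration, name in events:
        if not name:
            raise ValueError("regressor name must be non-empty")
        col = convolve_event(onset, duration, timepoints, tr_s, hrf_params)
        merged[name] = merged.get(name, 0.0) + col
    names: list[str] = []
    cols: list[np.ndarray] = []
    for name, col in merged.items():
        names.append(name)
        cols.append(col)
        if add_derivatives:
            names.append(name + "_derivative")
            cols.append(np.gradient(col))
    dnames, dcols = _drift_columns(timepoints, drift_order)
    return DesignMatrix(names=names + dnames,
                        X=np.column_stack(cols + dcols) if cols or dcols else
                        np.empty((timepoints, 0)),
                        tr_s=tr_s)


class RankDeficientError(np.linalg.LinAlgError):
    pass


@dataclass
class GLMFit:
    """OLS results for one design matrix over many voxels."""

    names: list[str]
    betas: np.ndarray      # columns x voxels
    t_stats: np.ndarray    # columns x voxels (NaN where residual var is 0)
    residual_variance: np.ndarray  # voxels
    df_resid: int

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]

    def t(self, name: str) -> np.ndarray:
        return self.t_stats[self.names.index(name)]


def fit_glm(Y: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Voxelwise ordinary least squares.

    ``Y`` is voxels x timepoints.  t_j = beta_j / sqrt(sigma2 *
    [(X'X)^-1]_jj) with sigma2 = RSS/(n - p).  Voxels with zero residual
    variance get NaN t-statistics rather than infinities.
    """
    X = design.X
    n, p = X.shape
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape[1] != n:
        raise ValueError("Y timepoints do not match design matrix")
    if p == 0:
        raise ValueError("empty design matrix")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the columns implicated in the deficiency via pivoted QR diag
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.names[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise RankDeficientError(
            f"design matrix rank {rank} < {p}; collinear column(s): "
            f"{bad or 'unidentified'}")
    if n <= p:
        raise RankDeficientError(f"{n} timepoints <= {p} columns")
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ X.T @ Y.T           # p x voxels
    resid = Y.T - X @ betas
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / (n - p)
    # residual variance indistinguishable from rounding noise -> NaN t,
    # not a silently huge value
    yvar = Y.var(axis=1)
    degenerate = sigma2 <= 1e-12 * np.maximum(yvar, 1e-300)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((se > 0) & ~degenerate[None, :], betas / se, np.nan)
    return GLMFit(names=list(design.names), betas=betas, t_stats=t,
                  residual_variance=sigma2, df_resid=n - p)


# ---------------------------------------------------------------------------
# single-trial (LSS) and condition-level models


@dataclass
class TrialEstimates:
    """Per-trial voxelwise estimates for one ROI and one scan."""

    roi_name: str
    scan_index: int
    event_kind: str                  # "cue" | "image"
    trials: list[Trial]
    betas: np.ndarray                # trials x voxels
    t_stats: np.ndarray              # trials x voxels

    @property
    def trial_indices(self) -> np.ndarray:
        return np.array([t.trial_index for t in self.trials])


def _event_columns(run_trials: list[Trial], spec, timepoints: int,
                   hrf_params: HRFParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-event convolved regressors: (cues, images), each trials x T."""
    tr = spec.tr_s
    cues = convolve_events_batch(
        [t.cue_onset_s for t in run_trials],
        [spec.cue_duration_s] * len(run_trials), timepoints, tr, hrf_params)
    images = convolve_events_batch(
        [t.image_onset_s for t in run_trials],
        [spec.image_duration_s] * len(run_trials), timepoints, tr, hrf_params)
    return cues, images


def _assemble(names_cols: list[tuple[str, np.ndarray]], timepoints: int,
              tr_s: float, add_derivatives: bool,
              drift_order: int) -> DesignMatrix:
    names, cols = [], []
    for name, col in names_cols:
        if not np.any(np.abs(col) > 1e-12):
            continue  # empty bin (e.g. no remaining images of a type)
        names.append(name)
        cols.append(col)
        if add_derivatives:
            names.append(name + "_derivative")
            cols.append(np.gradient(col))
    dnames, dcols = _drift_columns(timepoints, drift_order)
    return DesignMatrix(names=names + dnames,
                        X=np.column_stack(cols + dcols), tr_s=tr_s)


def _batch_ols_target(Xs: np.ndarray, Y: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """OLS of Y (voxels x T) on a stack of designs (m x T x p).

    Returns (betas, t) for the FIRST column of each design.  Raises
    :class:`RankDeficientError` if any stacked design is singular.
    """
    m, T, p = Xs.shape
    if T <= p:
        raise RankDeficientError(f"{T} timepoints <= {p} columns")
    Xt = Xs.transpose(0, 2, 1)
    xtx = Xt @ Xs
    try:
        np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError:
        raise RankDeficientError("singular LSS design matrix") from None
    inv = np.linalg.inv(xtx)
    xty = Xt @ Y.T                      # m x p x voxels
    betas = inv @ xty
    # RSS via the quadratic form y'y - b'X'y (b solves the normal equations)
    yty = np.einsum("vt,vt->v", Y, Y)
    rss = np.maximum(yty[None, :] - np.einsum("mpv,mpv->mv", xty, betas), 0.0)
    sigma2 = rss / (T - p)
    se = np.sqrt(inv[:, 0, 0][:, None] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas[:, 0, :] / se, np.nan)
    return betas[:, 0, :], t


def lss_estimate(run_data, run_trials: list[Trial],
                 hrf_params: HRFParams = HRFParams(),
                 target_kind: str = "image",
                 add_derivatives: bool = True,
                 drift_order: int = 1,
                 event_regressors: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> TrialEstimates:
    """Least-squares-separate single-trial estimation.

    One GLM per target event, with that event as the sole regressor of
    interest.  For image targets the nuisance structure is: all cues
    pooled into one regressor plus the remaining images binned by trial
    type (up to nine regressors).  For cue targets: all other cues pooled
    into one regressor plus nine trial-type image regressors.  Every
    regressor carries a temporal-derivative column; intercept and
    polynomial drift columns close the model.

    ``event_regressors`` optionally supplies the precomputed per-event
    (cue, image) convolved regressors to avoid recomputing them across
    the image, cue and condition models of the same scan.  Targets with
    identical column structure are solved in one batched OLS.
    """
    if target_kind not in ("cue", "image"):
        raise ValueError("target_kind must be 'cue' or 'image'")
    if 2 * len(run_trials) < 2:
        raise ValueError("LSS estimation refused: fewer than 2 events in run")
    if any(t.scan_index != run_data.scan_index for t in run_trials):
        raise ValueError("run_trials do not belong to this scan")
    spec = run_data.spec
    T = run_data.data.shape[1]
    if event_regressors is None:
        cues, images = _event_columns(run_trials, spec, T, hrf_params)
    else:
        cues, images = event_regressors
    dcues = np.gradient(cues, axis=1)
    dimages = np.gradient(images, axis=1)
    all_cues, d_all_cues = cues.sum(axis=0), dcues.sum(axis=0)
    type_of = [t.trial_type for t in run_trials]
    type_idx = {tt: [i for i, x in enumerate(type_of) if x == tt]
                for tt in TRIAL_TYPES if tt in type_of}
    type_sums = {tt: images[idx].sum(axis=0) for tt, idx in type_idx.items()}
    dtype_sums = {tt: dimages[idx].sum(axis=0) for tt, idx in type_idx.items()}
    dnames, dcols = _drift_columns(T, drift_order)

    def with_deriv(col, dcol):
        return [col, dcol] if add_derivatives else [col]

    grouped: dict[tuple, list[tuple[int, np.ndarray]]] = {}
    for j, trial in enumerate(run_trials):
        if target_kind == "image":
            cols = with_deriv(images[j], dimages[j]) \
                + with_deriv(all_cues, d_all_cues)
            key: list = ["image"]
            for tt, s in type_sums.items():
                if tt == trial.trial_type:
                    rest, drest = s - images[j], dtype_sums[tt] - dimages[j]
                else:
                    rest, drest = s, dtype_sums[tt]
                if np.any(np.abs(rest) > 1e-12):
                    cols += with_deriv(rest, drest)
                    key.append(tt)
        else:
            cols = with_deriv(cues[j], dcues[j])
            other, dother = all_cues - cues[j], d_all_cues - dcues[j]
            key = ["cue"]
            if np.any(np.abs(other) > 1e-12):
                cols += with_deriv(other, dother)
                key.append("other_cues")
            for tt, s in type_sums.items():
                cols += with_deriv(s, dtype_sums[tt])
                key.append(tt)
        cols += dcols
        grouped.setdefault(tuple(key), []).append((j, np.column_stack(cols)))

    betas = np.empty((len(run_trials), run_data.data.shape[0]))
    tstats = np.empty_like(betas)
    for members in grouped.values():
        idx = [j for j, _ in members]
        Xs = np.stack([X for _, X in members])
        b, t = _batch_ols_target(Xs, run_data.data)
        betas[idx] = b
        tstats[idx] = t
    return TrialEstimates(roi_name=run_data.roi_name,
                          scan_index=run_data.scan_index,
                          event_kind=target_kind, trials=list(run_trials),
                          betas=betas, t_stats=tstats)


def write_trial_estimates(estimates: list[TrialEstimates], path) -> None:
    """Serialize per-scan estimates of one ROI/event kind as one TSV.

    Wide layout: trial metadata columns followed by per-voxel beta and t
    columns (``b0..bN``, ``t0..tN``).
    """
    import pandas as pd

    rows = []
    for est in sorted(estimates, key=lambda e: e.scan_index):
        for j, trial in enumerate(est.trials):
            row = {"trial_index": trial.trial_index,
                   "scan_index": est.scan_index,
                   "roi": est.roi_name, "event_kind": est.event_kind}
            row.update({f"b{v}": est.betas[j, v]
                        for v in range(est.betas.shape[1])})
            row.update({f"t{v}": est.t_stats[j, v]
                        for v in range(est.t_stats.shape[1])})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")


def read_trial_estimates(path, schedule) -> list[TrialEstimates]:
    """Read back a table written by :func:`write_trial_estimates`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    n_vox = sum(c.startswith("t") and c[1:].isdigit() for c in df.columns)
    bcols = [f"b{v}" for v in range(n_vox)]
    tcols = [f"t{v}" for v in range(n_vox)]
    trial_by_index = {t.trial_index: t for t in schedule.trials}
    out = []
    for scan, sub in df.groupby("scan_index"):
        sub = sub.sort_values("trial_index")
        out.append(TrialEstimates(
            roi_name=str(sub["roi"].iloc[0]), scan_index=int(scan),
            event_kind=str(sub["event_kind"].iloc[0]),
            trials=[trial_by_index[i] for i in sub["trial_index"]],
            betas=sub[bcols].to_numpy(dtype=float),
            t_stats=sub[tcols].to_numpy(dtype=float)))
    return out


@dataclass
class ConditionActivation:
    """Per-trial-type voxelwise estimates for one ROI and one scan."""

    roi_name: str
    scan_index: int
    task: str
    type_labels: list[tuple[int, int]]   # trial types present in the run
    missing_types: list[tuple[int, int]]
    n_trials: dict[tuple[int, int], int]
    betas: np.ndarray                    # types x voxels
    t_stats: np.ndarray

    def changes_level_means(self) -> dict[int, float]:
        """ROI-mean activation per total-changes level (0-4).

        Each level's value is the trial-count-weighted mean of its
        constituent trial types' ROI-mean betas.
        """
        out: dict[int, float] = {}
        roi_mean = self.betas.mean(axis=1)
        for c in range(5):
            idx = [i for i, tt in enumerate(self.type_labels)
                   if tt[0] + tt[1] == c]
            if not idx:
                continue
            w = np.array([self.n_trials[self.type_labels[i]] for i in idx],
                         dtype=float)
            out[c] = float(np.average(roi_mean[idx], weights=w))
        return out

    def voxel_task_mean(self) -> np.ndarray:
        """Per-voxel beta averaged over changes levels (types weighted by
        trial count within level, levels weighted equally)."""
        levels = []
        for c in range(5):
            idx = [i for i, tt in enumerate(self.type_labels)
                   if tt[0] + tt[1] == c]
            if not idx:
                continue
            w = np.array([self.n_trials[self.type_labels[i]] for i in idx],
                         dtype=float)
            levels.append(np.average(self.betas[idx], axis=0, weights=w))
        return np.mean(levels, axis=0)


def condition_glm(run_data, run_trials: list[Trial],
                  hrf_params: HRFParams = HRFParams(),
                  add_derivatives: bool = True,
                  drift_order: int = 1,
                  event_regressors: tuple[np.ndarray, np.ndarray] | None = None
                  ) -> ConditionActivation:
    """One regressor per trial type for images, plus one for all cues."""
    if 2 * len(run_trials) < 2:
        raise ValueError("condition GLM refused: fewer than 2 events in run")
    if any(t.scan_index != run_data.scan_index for t in run_trials):
        raise ValueError("run_trials do not belong to this scan")
    spec = run_data.spec
    T = run_data.data.shape[1]
    if event_regressors is None:
        cues, images = _event_columns(run_trials, spec, T, hrf_params)
    else:
        cues, images = event_regressors
    type_of = [t.trial_type for t in run_trials]
    cols = [("all_cues", cues.sum(axis=0))]
    present, missing, counts = [], [], {}
    for tt in TRIAL_TYPES:
        idx = [i for i, x in enumerate(type_of) if x == tt]
        if not idx:
            missing.append(tt)
            continue
        present.append(tt)
        counts[tt] = len(idx)
        cols.append((f"images_f{tt[0]}l{tt[1]}", images[idx].sum(axis=0)))
    dm = _assemble(cols, T, spec.tr_s, add_derivatives, drift_order)
    fit = fit_glm(run_data.data, dm)
    betas = np.stack([fit.beta(f"images_f{tt[0]}l{tt[1]}") for tt in present])
    tstats = np.stack([fit.t(f"images_f{tt[0]}l{tt[1]}") for tt in present])
    return ConditionActivation(
        roi_name=run_data.roi_name, scan_index=run_data.scan_index,
        task=run_trials[0].task, type_labels=present, missing_types=missing,
        n_trials=counts, betas=betas, t_stats=tstats)
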