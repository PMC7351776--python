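"""End-to-end orchestration: simulate -> GLM -> connectivity -> RSA -> stats.

A cohort run simulates ``n_participants`` independent participants (each
with their own counterbalanced schedule and noise realization), estimates
single-trial responses by LSS, computes beta-series connectivity for the
CA1-CA3 and CA1-entorhinal pairs, the two CA1 pattern statistics, and the
group-level statistics.  Seed propagation is deterministic: participant i
of replicate r uses seeds derived from the master seed by a fixed scheme,
so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import glm, rsa, stats
from .design import DesignSpec, TrialSchedule, generate_schedule, write_events
from .simulate import (PAIR_CA3, PAIR_ERC, ROI_CA1, GroundTruth, ROIRunData,
                       SimulationParams, simulate_participant)

PAIRS = [PAIR_CA3, PAIR_ERC]
PAIR_CA3_NAME = f"{PAIR_CA3[0]}-{PAIR_CA3[1]}"
PAIR_ERC_NAME = f"{PAIR_ERC[0]}-{PAIR_ERC[1]}"

#: match > mismatch (0-changes above pooled 1-4), used for the
#: prediction-error similarity which *decreases* with changes
MATCH_GT_MISMATCH = stats.ContrastSpec(
    "match_gt_mismatch", {0: 1.0, 1: -0.25, 2: -0.25, 3: -0.25, 4: -0.25})


@dataclass(frozen=True)
class PipelineConfig:
    design: DesignSpec = field(default_factory=DesignSpec)
    sim: SimulationParams = field(default_factory=SimulationParams)
    n_participants: int = 19
    seed: int = 0
    drop_fraction: float = 1.0 / 3.0
    drift_order: int = 1
    add_derivatives: bool = True
    include_connectivity: bool = True
    include_rsa: bool = True
    include_mixed_models: bool = True
    restrict_others: bool = True

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def participant_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic (n, 2) array of (design, simulation) seeds < 2**31."""
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2 ** 31 - 1, size=(n, 2))


@dataclass
class ParticipantResult:
    participant: int
    schedule: TrialSchedule
    connectivity: pd.DataFrame | None
    prediction_strength: rsa.PredictionStrengthResult | None
    prediction_error: dict[int, float] | None
    activation_by_changes: dict[int, float] | None
    truth: GroundTruth
    image_estimates: dict[str, list[glm.TrialEstimates]] | None = None
    cue_estimates: list[glm.TrialEstimates] | None = None
    voxel_activation: np.ndarray | None = None   # CA1 ranking statistic


def _stack_runs(runs: list[ROIRunData], rois: list[str],
                scan: int) -> tuple[ROIRunData, list[tuple[str, int]]]:
    """Stack the selected ROIs' voxels of one scan into a single block."""
    blocks, sizes = [], []
    by_key = {(r.roi_name, r.scan_index): r for r in runs}
    for roi in rois:
        r = by_key[(roi, scan)]
        blocks.append(r.data)
        sizes.append((roi, r.data.shape[0]))
    first = by_key[(rois[0], scan)]
    return ROIRunData(roi_name="stacked", scan_index=scan,
                      data=np.vstack(blocks), tr_s=first.tr_s,
                      spec=first.spec), sizes


def _split_estimates(est: glm.TrialEstimates,
                     sizes: list[tuple[str, int]]) -> dict[str, glm.TrialEstimates]:
    out, start = {}, 0
    for roi, nv in sizes:
        out[roi] = glm.TrialEstimates(
            roi_name=roi, scan_index=est.scan_index,
            event_kind=est.event_kind, trials=est.trials,
            betas=est.betas[:, start:start + nv],
            t_stats=est.t_stats[:, start:start + nv])
        start += nv
    return out


def analyze_participant(config: PipelineConfig, participant: int,
                        design_seed: int, sim_seed: int) -> ParticipantResult:
    """Run all single-participant stages for one synthetic participant."""
    schedule = generate_schedule(replace(config.design, seed=int(design_seed)))
    params = replace(config.sim, seed=int(sim_seed))
    regs_by_scan = {
        scan: glm._event_columns(schedule.scan_trials(scan), schedule.spec,
                                 schedule.scan_timepoints(scan),
                                 params.hrf_params)
        for scan in range(schedule.spec.n_scans)}
    runs, truth = simulate_participant(schedule, params, regs_by_scan)

    rois = params.roi_names if config.include_connectivity else [ROI_CA1]
    image_by_roi: dict[str, list[glm.TrialEstimates]] = {r: [] for r in rois}
    cue_ca1: list[glm.TrialEstimates] = []
    activations: list[glm.ConditionActivation] = []
    ca1_runs = [r for r in runs if r.roi_name == ROI_CA1]

    for scan in range(schedule.spec.n_scans):
        trials = schedule.scan_trials(scan)
        stacked, sizes = _stack_runs(runs, rois, scan)
        regs = regs_by_scan[scan]
        est = glm.lss_estimate(stacked, trials, params.hrf_params,
                               target_kind="image",
                               add_derivatives=config.add_derivatives,
                               drift_order=config.drift_order,
                               event_regressors=regs)
        for roi, part in _split_estimates(est, sizes).items():
            image_by_roi[roi].append(part)
        if config.include_rsa:
            ca1_run = next(r for r in ca1_runs if r.scan_index == scan)
            cue_ca1.append(glm.lss_estimate(
                ca1_run, trials, params.hrf_params, target_kind="cue",
                add_derivatives=config.add_derivatives,
                drift_order=config.drift_order, event_regressors=regs))
            activations.append(glm.condition_glm(
                ca1_run, trials, params.hrf_params,
                add_derivatives=config.add_derivatives,
                drift_order=config.drift_order, event_regressors=regs))

    conn_table = None
    if config.include_connectivity:
        conn_table = conn.pair_connectivity(image_by_roi, schedule, PAIRS,
                                            participant=participant)

    ps = pes = act = None
    activation_vec = None
    if config.include_rsa:
        activation_vec = rsa.participant_task_mean_activation(activations)
        selection = rsa.select_active_voxels(activation_vec,
                                             config.drop_fraction, ROI_CA1)
        n_trials = len(schedule)
        nv = params.n_voxels(ROI_CA1)
        cue_patterns = np.full((n_trials, nv), np.nan)
        image_patterns = np.full((n_trials, nv), np.nan)
        for est in cue_ca1:
            cue_patterns[est.trial_indices] = est.t_stats
        for est in image_by_roi[ROI_CA1]:
            image_patterns[est.trial_indices] = est.t_stats
        ps = rsa.prediction_strength(cue_patterns, image_patterns, selection,
                                     schedule, config.restrict_others)
        pes = rsa.prediction_error_similarity(cue_patterns, image_patterns,
                                              selection, schedule)
        # univariate CA1 activation per changes level: runs averaged
        # within task, then tasks averaged
        by_task: dict[str, list[dict[int, float]]] = {}
        for a in activations:
            by_task.setdefault(a.task, []).append(a.changes_level_means())
        act = {}
        for c in range(5):
            task_means = [np.mean([m[c] for m in ms if c in m])
                          for ms in by_task.values()]
            act[c] = float(np.mean(task_means))
    return ParticipantResult(participant=participant, schedule=schedule,
                             connectivity=conn_table,
                             prediction_strength=ps, prediction_error=pes,
                             activation_by_changes=act, truth=truth,
                             image_estimates=image_by_roi,
                             cue_estimates=cue_ca1 or None,
                             voxel_activation=activation_vec)


@dataclass
class CohortResult:
    config: PipelineConfig
    participants: list[ParticipantResult]
    connectivity: pd.DataFrame | None      # per-task tidy table
    connectivity_collapsed: pd.DataFrame | None
    similarity: pd.DataFrame | None        # tidy RSA table
    activation: pd.DataFrame | None        # CA1 univariate means
    group: dict


def analyze_cohort(config: PipelineConfig) -> CohortResult:
    """Simulate and analyze a full cohort, returning tables and stats."""
    seeds = participant_seeds(config.seed, config.n_participants)
    parts = [analyze_participant(config, i, seeds[i, 0], seeds[i, 1])
             for i in range(config.n_participants)]

    conn_table = collapsed = similarity = activation = None
    if config.include_connectivity:
        conn_table = pd.concat([p.connectivity for p in parts],
                               ignore_index=True)
        collapsed = conn.collapse_tasks(conn_table)
    if config.include_rsa:
        rows = []
        for p in parts:
            rows.append(dict(participant=p.participant,
                             statistic="prediction_strength",
                             total_changes=None,
                             value_z=p.prediction_strength.index_z,
                             n_pairs=p.prediction_strength.n_pairs))
            for c, z in p.prediction_error.items():
                rows.append(dict(participant=p.participant,
                                 statistic="prediction_error_similarity",
                                 total_changes=c, value_z=z, n_pairs=None))
        similarity = pd.DataFrame(rows)
        activation = pd.DataFrame([
            dict(participant=p.participant, total_changes=c, value=v)
            for p in parts for c, v in p.activation_by_changes.items()])
    group = group_stats(config, collapsed, similarity, activation)
    return CohortResult(config=config, participants=parts,
                        connectivity=conn_table,
                        connectivity_collapsed=collapsed,
                        similarity=similarity, activation=activation,
                        group=group)


def _pair_contrasts(collapsed: pd.DataFrame, pair: str,
                    spec: stats.ContrastSpec) -> list[float]:
    sub = collapsed[collapsed["pair"] == pair]
    scores = []
    for _, rows in sub.groupby("participant"):
        values = dict(zip(rows["total_changes"], rows["z"]))
        scores.append(stats.contrast_score(values, spec))
    return scores


def group_stats(config: PipelineConfig, collapsed: pd.DataFrame | None,
                similarity: pd.DataFrame | None,
                activation: pd.DataFrame | None) -> dict:
    """Group-level inference on the cohort tables."""
    if (collapsed is not None and collapsed["participant"].nunique() < 2) or \
       (similarity is not None and similarity["participant"].nunique() < 2):
        raise ValueError("group statistics need at least 2 participants "
                         f"(got {config.n_participants})")
    out: dict = {}
    if collapsed is not None:
        out["anova_changes_by_roi"] = stats.rm_anova(
            collapsed, dv="z", subject="participant",
            within=["total_changes", "pair"])
        for pair in (PAIR_CA3_NAME, PAIR_ERC_NAME):
            sub = collapsed[collapsed["pair"] == pair]
            out[f"anova_changes[{pair}]"] = stats.rm_anova(
                sub, dv="z", subject="participant", within=["total_changes"])
            for spec in (stats.LINEAR_CONTRAST,
                         stats.MATCH_MISMATCH_CONTRAST):
                scores = _pair_contrasts(collapsed, pair, spec)
                out[f"contrast[{pair}][{spec.name}]"] = \
                    stats.group_contrast_test(scores)
            if config.include_mixed_models:
                sub = sub.reset_index(drop=True)
                full = stats.fit_mixed_model(
                    sub, "z", [stats.LINEAR_CONTRAST,
                               stats.MATCH_MISMATCH_CONTRAST])
                lin = stats.fit_mixed_model(sub, "z", [stats.LINEAR_CONTRAST])
                mm = stats.fit_mixed_model(
                    sub, "z", [stats.MATCH_MISMATCH_CONTRAST])
                out[f"lrt[{pair}][full_vs_linear]"] = \
                    stats.compare_models(full, lin)
                out[f"lrt[{pair}][full_vs_match]"] = \
                    stats.compare_models(full, mm)
    if similarity is not None:
        ps = similarity[similarity["statistic"] == "prediction_strength"]
        out["prediction_strength_t"] = stats.one_sample_t(ps["value_z"])
        pes = similarity[
            similarity["statistic"] == "prediction_error_similarity"]
        scores, lin_scores = [], []
        for _, rows in pes.groupby("participant"):
            values = dict(zip(rows["total_changes"], rows["value_z"]))
            scores.append(stats.contrast_score(values, MATCH_GT_MISMATCH))
            lin_scores.append(
                stats.contrast_score(values, stats.LINEAR_CONTRAST))
        out["prediction_error_match_gt_mismatch"] = \
            stats.group_contrast_test(scores)
        out["prediction_error_linear"] = stats.group_contrast_test(lin_scores)
        out["prediction_error_group_means"] = {
            int(c): float(v) for c, v in
            pes.groupby("total_changes")["value_z"].mean().items()}
    if activation is not None:
        out["univariate_trend_CA1"] = stats.univariate_trend(activation)
    if collapsed is not None and similarity is not None:
        erc_match = _pair_contrasts(collapsed, PAIR_ERC_NAME,
                                    stats.MATCH_MISMATCH_CONTRAST)
        ps_vals = similarity[
            similarity["statistic"] == "prediction_strength"][
            "value_z"].to_numpy()
        r, p = stats.across_participant_correlation(ps_vals, erc_match)
        out["prediction_strength_vs_erc_connectivity"] = {"r": r, "p": p}
    return out


# ---------------------------------------------------------------------------
# serialization / manifest


def _serialize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialize(v)
                for k, v in dataclasses.asdict(obj).items() if k != "result"}
    if isinstance(obj, dict):
        return {str(k): _serialize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir,
                 retain_estimates: bool = False) -> CohortResult:
    """Run a cohort and write all tables plus a run manifest.

    Outputs: per-participant events TSVs, the per-task and collapsed
    connectivity tables, the RSA similarity table, the CA1 activation
    table, group statistics as JSON, and ``manifest.json`` with the
    config, seeds, stage wall times and output checksums.  Rerunning with
    the same config is bit-identical on all tables.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    result = analyze_cohort(config)
    timings["analyze_cohort_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    written: list[pathlib.Path] = []
    for p in result.participants:
        path = out / f"events_p{p.participant:02d}.tsv"
        write_events(p.schedule, path)
        written.append(path)
        if retain_estimates:
            pdir = out / f"p{p.participant:02d}"
            pdir.mkdir(exist_ok=True)
            write_events(p.schedule, pdir / "events.tsv")
            written.append(pdir / "events.tsv")
            for roi, est in (p.image_estimates or {}).items():
                epath = pdir / f"estimates_image_{roi}.tsv"
                glm.write_trial_estimates(est, epath)
                written.append(epath)
            if p.cue_estimates:
                epath = pdir / "estimates_cue_CA1.tsv"
                glm.write_trial_estimates(p.cue_estimates, epath)
                written.append(epath)
            if p.voxel_activation is not None:
                apath = pdir / "activation_rank_CA1.tsv"
                pd.DataFrame({"voxel": np.arange(len(p.voxel_activation)),
                              "activation": p.voxel_activation}
                             ).to_csv(apath, sep="\t", index=False,
                                      float_format="%.10g")
                written.append(apath)
    tables = {
        "connectivity.tsv": result.connectivity,
        "connectivity_collapsed.tsv": result.connectivity_collapsed,
        "similarity.tsv": result.similarity,
        "activation_ca1.tsv": result.activation,
    }
    for name, df in tables.items():
        if df is None:
            continue
        path = out / name
        df.to_csv(path, sep="\t", index=False, na_rep=".",
                  float_format="%.10g")
        written.append(path)
    stats_path = out / "group_stats.json"
    stats_path.write_text(
        json.dumps(_serialize(result.group), indent=2, sort_keys=True))
    written.append(stats_path)
    timings["write_outputs_s"] = time.perf_counter() - t0

    config_json = json.dumps(_serialize(config), sort_keys=True)
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "master_seed": config.seed,
        "participant_seeds": participant_seeds(
            config.seed, config.n_participants).tolist(),
        "stage_wall_times": timings,
        "outputs": {p.name: _sha256(p) for p in written},
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return result


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__
    return {"hippopred": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__}


# ---------------------------------------------------------------------------
# parameter-recovery experiment

ALPHA = 0.05   # two-tailed, matching the reporting convention

DETECTION_FLAGS = [
    "interaction_detected",
    "erc_match_detected",
    "ca3_linear_detected",
    "prediction_strength_detected",
    "prediction_error_detected",
]


@dataclass
class RecoveryReport:
    """Per-replicate detection flags and aggregate rates per setting."""

    table: pd.DataFrame
    rates: dict[str, dict[str, float]]


def cohort_detection_flags(group: dict) -> dict[str, bool]:
    """Apply the five detection criteria to one cohort's group stats."""
    flags: dict[str, bool] = {}
    if "anova_changes_by_roi" in group:
        inter = group["anova_changes_by_roi"]["total_changes:pair"]
        flags["interaction_detected"] = inter.p < ALPHA
        erc = group[f"contrast[{PAIR_ERC_NAME}][match_lt_mismatch]"]
        flags["erc_match_detected"] = erc.mean > 0 and erc.p < ALPHA
        ca3 = group[f"contrast[{PAIR_CA3_NAME}][linear]"]
        flags["ca3_linear_detected"] = ca3.mean < 0 and ca3.p < ALPHA
    if "prediction_strength_t" in group:
        ps = group["prediction_strength_t"]
        flags["prediction_strength_detected"] = ps.t > 0 and ps.p < ALPHA
        pe = group["prediction_error_match_gt_mismatch"]
        flags["prediction_error_detected"] = pe.mean > 0 and pe.p < ALPHA
    return flags


def replicate_cohorts(config: PipelineConfig, n_replicates: int):
    """Yield (replicate_index, group-stats dict) over seeded cohorts.

    Replicate seeds are derived deterministically from ``config.seed``.
    """
    rep_seeds = np.random.default_rng(config.seed).integers(
        0, 2 ** 31 - 1, size=n_replicates)
    for rep in range(n_replicates):
        cfg = replace(config, seed=int(rep_seeds[rep]))
        yield rep, analyze_cohort(cfg).group


def recovery_experiment(config: PipelineConfig, n_replicates: int,
                        effect_settings: dict[str, dict] | None = None
                        ) -> RecoveryReport:
    """Repeatedly simulate and analyze cohorts, recording detection rates.

    ``effect_settings`` maps a setting name to simulation-parameter
    overrides (fields of :class:`SimulationParams`); ``None`` runs the
    config's own parameters under the setting name ``"default"``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if effect_settings is None:
        effect_settings = {"default": {}}
    rep_seeds = np.random.default_rng(config.seed).integers(
        0, 2 ** 31 - 1, size=n_replicates)
    rows = []
    for setting, overrides in effect_settings.items():
        sim = replace(config.sim, **overrides) if overrides else config.sim
        for rep in range(n_replicates):
            cfg = replace(config, sim=sim, seed=int(rep_seeds[rep]))
            result = analyze_cohort(cfg)
            row = dict(setting=setting, replicate=rep,
                       seed=int(rep_seeds[rep]))
            row.update(cohort_detection_flags(result.group))
            rows.append(row)
    table = pd.DataFrame(rows)
    rates = {
        setting: {flag: float(sub[flag].mean())
                  for flag in DETECTION_FLAGS if flag in sub.columns}
        for setting, sub in table.groupby("setting")
    }
    return RecoveryReport(table=table, rates=rates)
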