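"""Replicated recovery and calibration experiments.

Each function simulates many independent cohorts under a named condition
and summarizes how often the group-level analyses recover (or, under a
null, falsely detect) the generative effects.  These are the package's
standing validation experiments; both the test suite and the
reproduction script run them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import glm, pipeline as pl
from .design import DesignSpec, generate_schedule
from .simulate import (FLAT_COUPLING, ROI_CA1, SimulationParams,
                       simulate_participant)

ALPHA = pl.ALPHA


def _conn_config(seed: int) -> pl.PipelineConfig:
    return pl.PipelineConfig(seed=seed, include_rsa=False,
                             include_mixed_models=False)


def _rsa_config(seed: int, **sim_kw) -> pl.PipelineConfig:
    return pl.PipelineConfig(seed=seed, include_connectivity=False,
                             include_mixed_models=False,
                             sim=SimulationParams(**sim_kw))


def connectivity_recovery(seed: int, n_replicates: int = 50) -> dict:
    """Recovery of the condition-dependent coupling profiles.

    Per replicate cohort records whether (a) the group-mean contrast
    signs match the generative ordering (CA1-entorhinal: match<mismatch
    contrast positive; CA1-CA3: linear contrast negative), (b) the
    Changes x ROI interaction is detected at p < .05, and (c) each
    pair's directed contrast is individually detected.
    """
    ordering = interaction = erc = ca3 = 0
    for _, group in pl.replicate_cohorts(_conn_config(seed), n_replicates):
        e = group[f"contrast[{pl.PAIR_ERC_NAME}][match_lt_mismatch]"]
        c = group[f"contrast[{pl.PAIR_CA3_NAME}][linear]"]
        ordering += (e.mean > 0) and (c.mean < 0)
        interaction += group["anova_changes_by_roi"][
            "total_changes:pair"].p < ALPHA
        erc += (e.mean > 0) and (e.p < ALPHA)
        ca3 += (c.mean < 0) and (c.p < ALPHA)
    n = n_replicates
    return {"ordering_rate": ordering / n, "interaction_rate": interaction / n,
            "erc_match_rate": erc / n, "ca3_linear_rate": ca3 / n,
            "n_replicates": n}


def connectivity_type1(seed: int, n_replicates: int = 200) -> dict:
    """False-detection rate of the Changes x ROI interaction when the
    coupling profile is flat across change levels (no true interaction).

    Runs at the default ROI sizes: shrinking the ROIs inflates the CA1
    estimation noise that both pairs share, which violates sphericity
    enough to make the uncorrected F visibly liberal.
    """
    sim = SimulationParams(
        coupling_by_changes={k: dict(v) for k, v in FLAT_COUPLING.items()},
        pattern_strength_cue=0.0, pattern_strength_image=0.0)
    config = replace(_conn_config(seed), sim=sim)
    hits = sum(group["anova_changes_by_roi"]["total_changes:pair"].p < ALPHA
               for _, group in pl.replicate_cohorts(config, n_replicates))
    return {"type1_rate": hits / n_replicates, "n_replicates": n_replicates}


def rsa_recovery(seed: int, n_replicates: int = 50) -> dict:
    """Detection of reinstatement and of the graded prediction-error
    decrease under the default generative parameters."""
    ps = decreasing = strict = 0
    for _, group in pl.replicate_cohorts(_rsa_config(seed), n_replicates):
        t = group["prediction_strength_t"]
        ps += (t.t > 0) and (t.p < ALPHA)
        m = [group["prediction_error_group_means"][c] for c in range(5)]
        trend = sum(w * v for w, v in zip((-2, -1, 0, 1, 2), m))
        decreasing += (trend < 0) and (m[0] > m[4])
        strict += all(m[i] > m[i + 1] for i in range(4))
    n = n_replicates
    return {"prediction_strength_rate": ps / n,
            "prediction_error_decreasing_rate": decreasing / n,
            "prediction_error_strict_monotone_rate": strict / n,
            "n_replicates": n}


def rsa_null(seed: int, n_replicates: int = 100) -> dict:
    """False-detection rate of prediction strength with no room-specific
    patterns in the signal (the no-reinstatement null)."""
    config = _rsa_config(seed, pattern_strength_cue=0.0,
                         pattern_strength_image=0.0)
    hits = sum(group["prediction_strength_t"].p < ALPHA
               for _, group in pl.replicate_cohorts(config, n_replicates))
    return {"null_rate": hits / n_replicates, "n_replicates": n_replicates}


def single_trial_oracle_disagreement(seed: int) -> dict:
    """Largest |difference| between LSS estimates and independently
    assembled per-trial GLM fits on one simulated 27-trial run, plus the
    OLS-vs-normal-equations disagreement on a small random instance."""
    spec = DesignSpec(n_rooms=6, n_scans=2, seed=seed)
    schedule = generate_schedule(spec)
    params = SimulationParams(seed=seed + 1)
    runs, _ = simulate_participant(schedule, params)
    run = next(r for r in runs if r.roi_name == ROI_CA1 and r.scan_index == 0)
    trials = schedule.scan_trials(0)
    est = glm.lss_estimate(run, trials, params.hrf_params, "image")
    lss_diff = 0.0
    for j, target in enumerate(trials):
        events = [(target.image_onset_s, spec.image_duration_s,
                   "target_image")]
        events += [(t.cue_onset_s, spec.cue_duration_s, "all_cues")
                   for t in trials]
        events += [(t.image_onset_s, spec.image_duration_s,
                    f"images_{t.trial_type_label}")
                   for t in trials if t is not target]
        dm = glm.build_design_matrix(events, run.data.shape[1], spec.tr_s,
                                     params.hrf_params)
        fit = glm.fit_glm(run.data, dm)
        lss_diff = max(lss_diff,
                       float(np.max(np.abs(est.betas[j]
                                           - fit.beta("target_image")))),
                       float(np.max(np.abs(est.t_stats[j]
                                           - fit.t("target_image")))))

    rng = np.random.default_rng(seed + 2)
    X = rng.standard_normal((40, 4))
    Y = rng.standard_normal((5, 40))
    dm = glm.DesignMatrix(names=list("abcd"), X=X, tr_s=2.5)
    fit = glm.fit_glm(Y, dm)
    xtx_inv = np.linalg.inv(X.T @ X)
    glm_diff = 0.0
    for v in range(Y.shape[0]):
        b = xtx_inv @ X.T @ Y[v]
        resid = Y[v] - X @ b
        s2 = resid @ resid / (40 - 4)
        t = b / np.sqrt(s2 * np.diag(xtx_inv))
        glm_diff = max(glm_diff,
                       float(np.max(np.abs(fit.betas[:, v] - b))),
                       float(np.max(np.abs(fit.t_stats[:, v] - t))))
    return {"lss_oracle_max_abs_diff": lss_diff,
            "glm_oracle_max_abs_diff": glm_diff,
            "n_trials": len(trials)}
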