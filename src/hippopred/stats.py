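"""Group-level inference: repeated-measures ANOVA, planned contrasts,
t-tests with effect sizes, and random-intercept mixed models with
likelihood-ratio comparison.

The rm-ANOVA is the classical balanced within-subject decomposition
(1-3 within factors, one observation per cell): each effect is tested
against its own subject-by-effect interaction stratum, with partial eta
squared SS_effect / (SS_effect + SS_error).  No sphericity correction is
applied by default (Greenhouse-Geisser is available behind a flag).
Mixed models are Gaussian with a per-participant random intercept, fit
by maximum likelihood (not REML) so that likelihood-ratio comparisons of
fixed effects are valid; AIC/BIC are computed from the ML log-likelihood.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as spopt
from scipy import stats as sps


# ---------------------------------------------------------------------------
# contrasts


@dataclass(frozen=True)
class ContrastSpec:
    """Named within-condition contrast; weights must sum to zero."""

    name: str
    weights: dict[int, float]

    def __post_init__(self) -> None:
        if abs(sum(self.weights.values())) > 1e-10:
            raise ValueError(f"contrast '{self.name}' weights must sum to 0")

    def vector(self, levels) -> np.ndarray:
        return np.array([self.weights[l] for l in levels], dtype=float)


#: linear trend over the five change levels
LINEAR_CONTRAST = ContrastSpec("linear", {0: -2, 1: -1, 2: 0, 3: 1, 4: 2})
#: no-change vs. pooled 1-4 changes
MATCH_MISMATCH_CONTRAST = ContrastSpec(
    "match_lt_mismatch", {0: -1.0, 1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25})


def contrast_score(values: dict[int, float], spec: ContrastSpec) -> float:
    """Sum of weight x value over condition levels for one participant."""
    missing = [l for l in spec.weights if l not in values]
    if missing:
        raise ValueError(f"missing level(s) {missing} for contrast '{spec.name}'")
    return float(sum(w * values[l] for l, w in spec.weights.items()))


# ---------------------------------------------------------------------------
# t-tests


@dataclass
class TTestResult:
    mean: float
    sd: float
    t: float
    df: int
    p: float
    cohens_d: float
    ci95: tuple[float, float]


def one_sample_t(scores, popmean: float = 0.0) -> TTestResult:
    """One-sample two-tailed t-test with Cohen's d and 95% CI of the mean."""
    x = np.asarray(scores, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance: t-test undefined")
    mean = float(x.mean())
    se = sd / math.sqrt(n)
    t = (mean - popmean) / se
    df = n - 1
    p = 2 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    return TTestResult(mean=mean, sd=sd, t=float(t), df=df, p=float(p),
                       cohens_d=(mean - popmean) / sd,
                       ci95=(mean - tcrit * se, mean + tcrit * se))


def group_contrast_test(scores) -> TTestResult:
    """Per-participant contrast scores tested against zero."""
    return one_sample_t(scores, 0.0)


def paired_t(a, b) -> TTestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    eta_p_sq: float
    ss_effect: float
    ss_error: float
    gg_epsilon: float | None = None
    p_gg: float | None = None


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]

    def __getitem__(self, key: str) -> EffectResult:
        return self.effects[key]


def _center(a: np.ndarray, axis: int) -> np.ndarray:
    return a - a.mean(axis=axis, keepdims=True)


def rm_anova(data: pd.DataFrame, dv: str, subject: str,
             within: list[str], gg_correction: bool = False) -> AnovaResult:
    """Balanced within-subject ANOVA for 1-3 within factors.

    ``data`` is long format with one value per subject x cell.  Each
    effect's F uses the subject-by-effect interaction as its error term.
    """
    if not 1 <= len(within) <= 3:
        raise ValueError("supports 1 to 3 within factors")
    subjects = sorted(data[subject].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 participants")
    levels = [sorted(data[w].unique()) for w in within]
    shape = (len(subjects),) + tuple(len(l) for l in levels)
    # pivot to dense array; detect missing/duplicate cells
    counts = data.groupby([subject] + within, observed=True)[dv].count()
    expected = np.prod([len(l) for l in levels])
    for s in subjects:
        got = counts.loc[s]
        if got.size != expected or (got != 1).any():
            cells = got[got != 1] if got.size else got
            raise ValueError(
                f"design not balanced for subject {s}: expected one value "
                f"per cell; offending cells: {list(cells.index)[:5]}")
    idx = {w: {l: i for i, l in enumerate(lv)} for w, lv in zip(within, levels)}
    sidx = {s: i for i, s in enumerate(subjects)}
    arr = np.full(shape, np.nan)
    for _, row in data.iterrows():
        pos = (sidx[row[subject]],) + tuple(
            idx[w][row[w]] for w in within)
        arr[pos] = row[dv]
    if np.isnan(arr).any():
        raise ValueError("missing cell(s) after pivot")

    n_subj = len(subjects)
    results: dict[str, EffectResult] = {}
    factor_axes = {w: i + 1 for i, w in enumerate(within)}
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(within, k):
            axes = [factor_axes[w] for w in combo]
            other = [factor_axes[w] for w in within if w not in combo]
            eff = arr.mean(axis=tuple(other), keepdims=False) if other else arr
            # eff: subjects x levels(combo...), in order of combo
            n_avg = np.prod([len(levels[factor_axes[w] - 1]) for w in within
                             if w not in combo]) if other else 1
            cell = eff.mean(axis=0)
            for ax in range(cell.ndim):
                cell = _center(cell, ax)
            ss_eff = n_subj * n_avg * float((cell ** 2).sum())
            err = eff
            for ax in range(err.ndim):
                err = _center(err, ax)
            ss_err = n_avg * float((err ** 2).sum())
            df1 = int(np.prod([len(levels[factor_axes[w] - 1]) - 1
                               for w in combo]))
            df2 = df1 * (n_subj - 1)
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            F = ms_eff / ms_err if ms_err > 0 else 0.0
            p = float(sps.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
            eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            res = EffectResult(F=float(F), df_num=df1, df_den=df2, p=p,
                               eta_p_sq=float(eta), ss_effect=ss_eff,
                               ss_error=ss_err)
            if gg_correction and len(combo) == 1:
                res.gg_epsilon, res.p_gg = _greenhouse_geisser(
                    eff, F, df1, df2)
            results[":".join(combo)] = res
    return AnovaResult(effects=results)


def _greenhouse_geisser(eff: np.ndarray, F: float, df1: int, df2: int
                        ) -> tuple[float, float]:
    """Greenhouse-Geisser epsilon from the sample covariance of levels."""
    S = np.cov(eff.T)
    k = S.shape[0]
    d = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) \
        + S.mean()
    eps = (np.trace(d) ** 2) / ((k - 1) * np.sum(d * d))
    eps = float(min(max(eps, 1.0 / (k - 1)), 1.0))
    p = float(sps.f.sf(F, df1 * eps, df2 * eps))
    return eps, p


def univariate_trend(activation: pd.DataFrame, dv: str = "value",
                     subject: str = "participant",
                     level: str = "total_changes",
                     spec: ContrastSpec = LINEAR_CONTRAST) -> TTestResult:
    """Linear-trend analysis of per-participant activation means.

    Computes the contrast score per participant and tests the scores
    against zero with a one-sample two-tailed t-test.
    """
    scores = []
    for _, sub in activation.groupby(subject):
        values = dict(zip(sub[level], sub[dv]))
        scores.append(contrast_score(values, spec))
    if len(scores) < 2:
        raise ValueError("need at least 2 participants for a group test")
    return group_contrast_test(scores)


# ---------------------------------------------------------------------------
# mixed models


@dataclass
class MixedModelFit:
    """ML fit of a Gaussian random-intercept model."""

    fixed_names: list[str]
    params: dict[str, float]
    loglik: float
    n_params: int          # fixed effects + random-intercept var + residual var
    n_obs: int
    aic: float
    bic: float
    random_intercept_var: float
    residual_var: float
    data_hash: int


def _profiled_ml(lam: float, Xg: list[np.ndarray], yg: list[np.ndarray]
                 ) -> tuple[float, np.ndarray, float]:
    """ML log-likelihood profiled over beta and sigma2 at variance ratio lam.

    lam = tau^2 / sigma^2.  Per group, V = I + lam J, with closed-form
    inverse V^-1 = I - c J, c = lam / (1 + lam n), and log|V| =
    log(1 + lam n); beta is the GLS solution and sigma2 the ML residual
    quadratic form / N.
    """
    p = Xg[0].shape[1]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for X, y in zip(Xg, yg):
        n_i = len(y)
        c = lam / (1.0 + lam * n_i)
        xs, ys = X.sum(axis=0), y.sum()
        A += X.T @ X - c * np.outer(xs, xs)
        b += X.T @ y - c * xs * ys
    beta = np.linalg.solve(A, b)
    N = sum(len(y) for y in yg)
    q = 0.0
    logdet = 0.0
    for X, y in zip(Xg, yg):
        n_i = len(y)
        c = lam / (1.0 + lam * n_i)
        r = y - X @ beta
        q += r @ r - c * r.sum() ** 2
        logdet += math.log(1.0 + lam * n_i)
    sigma2 = q / N
    ll = -0.5 * (N * (math.log(2 * math.pi * sigma2) + 1.0) + logdet)
    return ll, beta, sigma2


def fit_mixed_model(table: pd.DataFrame, response: str,
                    fixed: list[str | ContrastSpec],
                    group: str = "participant",
                    level: str = "total_changes") -> MixedModelFit:
    """Random-intercept Gaussian mixed model fit by maximum likelihood.

    ``fixed`` entries are either numeric column names or
    :class:`ContrastSpec` objects applied to the ``level`` column.  A
    :class:`ContrastSpec` with exactly two distinct weights is entered as
    a two-level factor (indicator), others as a numeric covariate.

    The likelihood is maximized exactly: beta and sigma2 have closed
    forms given the variance ratio tau^2/sigma^2, which is optimized by
    bounded scalar search (the zero boundary is evaluated explicitly, so
    a vanishing random-intercept variance is handled cleanly).
    """
    if table[group].nunique() < 2:
        raise ValueError("need at least 2 participants")
    cols, names = [], []
    for term in fixed:
        if isinstance(term, ContrastSpec):
            w = table[level].map(term.weights).to_numpy(dtype=float)
            if len(set(term.weights.values())) == 2:
                # two-level factor: indicator of the higher-weight group
                w = (w == max(term.weights.values())).astype(float)
            cols.append(w)
            names.append(term.name)
        else:
            cols.append(table[term].to_numpy(dtype=float))
            names.append(term)
    exog = np.column_stack([np.ones(len(table))] + cols)
    exog_names = ["intercept"] + names
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError(f"confounded fixed terms: {exog_names} not full rank")
    endog = table[response].to_numpy(dtype=float)
    groups = table[group].to_numpy()
    Xg, yg = [], []
    for g in pd.unique(groups):
        m = groups == g
        Xg.append(exog[m])
        yg.append(endog[m])

    def nll(lam: float) -> float:
        return -_profiled_ml(lam, Xg, yg)[0]

    opt = spopt.minimize_scalar(nll, bounds=(0.0, 1e4), method="bounded",
                                options={"xatol": 1e-10})
    if not opt.success:
        raise RuntimeError(
            f"mixed-model variance-ratio search failed: {opt.message} "
            f"(fixed terms {exog_names})")
    lam = float(opt.x) if opt.fun <= nll(0.0) else 0.0
    llf, beta, sigma2 = _profiled_ml(lam, Xg, yg)
    k = exog.shape[1] + 2   # fixed + random-intercept var + residual var
    n = len(endog)
    params = dict(zip(exog_names, map(float, beta)))
    return MixedModelFit(
        fixed_names=exog_names, params=params, loglik=float(llf),
        n_params=k, n_obs=n, aic=2 * k - 2 * llf,
        bic=k * math.log(n) - 2 * llf,
        random_intercept_var=float(lam * sigma2),
        residual_var=float(sigma2),
        data_hash=hash((n, round(float(endog.sum()), 10))))


@dataclass
class ModelComparison:
    chi2: float
    df: int
    p: float
    loglik_full: float
    loglik_reduced: float
    aic_full: float
    aic_reduced: float
    bic_full: float
    bic_reduced: float


def compare_models(full: MixedModelFit, reduced: MixedModelFit
                   ) -> ModelComparison:
    """Likelihood-ratio test of nested ML fits on the same data."""
    if full.n_obs != reduced.n_obs or full.data_hash != reduced.data_hash:
        raise ValueError("models were fit on different data")
    if not set(reduced.fixed_names) <= set(full.fixed_names):
        raise ValueError(
            f"models not nested: {reduced.fixed_names} not a subset of "
            f"{full.fixed_names}")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -1e-6:
        raise RuntimeError(
            "log-likelihood of the full model is below the reduced model's: "
            "optimizer failure")
    chi2 = max(chi2, 0.0)
    df = full.n_params - reduced.n_params
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return ModelComparison(chi2=float(chi2), df=df, p=p,
                           loglik_full=full.loglik,
                           loglik_reduced=reduced.loglik,
                           aic_full=full.aic, aic_reduced=reduced.aic,
                           bic_full=full.bic, bic_reduced=reduced.bic)


def across_participant_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation of two per-participant scalars, two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
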