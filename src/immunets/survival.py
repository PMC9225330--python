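"""Survival-based biomarker evaluation.

Two layers of analysis over per-patient (time, event, age, stage, gene
expression) cohorts:

* univariate: per gene, patients are grouped by a 1-D Gaussian mixture
  with the number of components chosen by BIC (K = 1..5, multi-start
  EM); groups are compared with a (K-1)-df log-rank test and p-values are
  BH-corrected across the gene panel. Genes for which the mixture
  collapses to one component are unstratifiable and enter the BH family
  with p = 1, keeping panel-level q-values conservative.

* multivariate: Cox proportional hazards (Efron tie handling) over
  age, numerically coded AJCC stage and panel genes, reduced by
  backwards stepwise elimination under AIC; the proportional-hazards
  assumption is checked with the Grambsch-Therneau test on scaled
  Schoenfeld residuals; risk groups in held-out data are defined by the
  median linear-predictor threshold of the training set.

Stage coding follows the ordinal TNM convention: I/Ia/Ib/Ic -> 1,
II/IIa/IIb/IIc -> 2, III/IIIa/IIIb/IIIc -> 3, IV -> 4.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .stats import bh_adjust

_STAGE_RE = re.compile(r"^(?:stage\s*)?(i{1,3}v?|iv)\s*([a-c]?)$")
_STAGE_VALUE = {"i": 1, "ii": 2, "iii": 3, "iv": 4}


def encode_stage(ajcc_label: str) -> int:
    """Numeric code for an AJCC stage label (case-insensitive).

    I/Ia/Ib/Ic -> 1, II* -> 2, III* -> 3, IV -> 4. Any other label is an
    error naming the offending value.
    """
    if not isinstance(ajcc_label, str) or not ajcc_label.strip():
        raise ValueError(f"unmapped AJCC stage label: {ajcc_label!r}")
    m = _STAGE_RE.match(ajcc_label.strip().lower())
    if not m or m.group(1) not in _STAGE_VALUE:
        raise ValueError(f"unmapped AJCC stage label: {ajcc_label!r}")
    if m.group(1) == "iv" and m.group(2):
        raise ValueError(f"unmapped AJCC stage label: {ajcc_label!r}")
    return _STAGE_VALUE[m.group(1)]


# --------------------------------------------------------------------------
# GMM risk groups
# --------------------------------------------------------------------------


@dataclass
class GMMFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    labels: np.ndarray
    bic: dict  # K -> BIC
    stratifiable: bool


def gmm_risk_groups(values, k_max: int = 5, seed: int = 0) -> GMMFit:
    """1-D Gaussian mixture risk groups with BIC-selected cardinality.

    EM is run with 10 seeded restarts for each K in 1..k_max and the K
    minimising BIC is selected; each patient is assigned to its
    maximum-responsibility component. K = 1 (or zero-variance input)
    marks the gene unstratifiable.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 10:
        raise ValueError("GMM stratification needs at least 10 values")
    if np.std(x) == 0:
        return GMMFit(
            1,
            np.array([1.0]),
            np.array([float(x[0, 0])]),
            np.array([0.0]),
            np.zeros(x.shape[0], dtype=int),
            {1: np.nan},
            False,
        )
    bics: dict = {}
    fits: dict = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            n_init=10,
            random_state=seed,
            covariance_type="full",
            reg_covar=1e-6,
        ).fit(x)
        bics[k] = float(gm.bic(x))
        fits[k] = gm
    best_k = min(bics, key=bics.get)
    gm = fits[best_k]
    return GMMFit(
        best_k,
        gm.weights_.ravel().copy(),
        gm.means_.ravel().copy(),
        gm.covariances_.ravel().copy(),
        gm.predict(x),
        bics,
        best_k > 1,
    )


# --------------------------------------------------------------------------
# log-rank
# --------------------------------------------------------------------------


def logrank_test(groups, time, event):
    """(K-1)-df log-rank chi-square across groups; returns (statistic, p).

    An all-censored input leaves the test undefined; it is reported as
    statistic 0, p = 1 with a warning.
    """
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if len(np.unique(groups)) < 2:
        raise ValueError("log-rank needs at least 2 nonempty groups")
    if not event.any():
        warnings.warn("no events observed; log-rank undefined, reporting p = 1")
        return 0.0, 1.0
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


def univariate_screen(
    cohort: pd.DataFrame, panel, k_max: int = 5, seed: int = 0
) -> pd.DataFrame:
    """GMM-stratify each panel gene, log-rank test, BH across the panel."""
    missing = [g for g in panel if g not in cohort.columns]
    if missing:
        raise ValueError(f"panel genes absent from cohort: {missing[:5]}")
    rows = []
    for i, gene in enumerate(panel):
        fit = gmm_risk_groups(cohort[gene].to_numpy(), k_max=k_max, seed=seed + i)
        if not fit.stratifiable:
            rows.append({"gene": gene, "k": fit.k, "statistic": 0.0, "p": 1.0})
            continue
        stat, p = logrank_test(fit.labels, cohort["time"], cohort["event"])
        rows.append({"gene": gene, "k": fit.k, "statistic": stat, "p": p})
    df = pd.DataFrame(rows).set_index("gene")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------


def stratified_split(
    cohort: pd.DataFrame,
    fraction: float = 255 / 390,
    key: str = "stage_code",
    seed: int = 0,
):
    """Random train/validation split holding per-stratum proportions constant.

    Each stratum contributes ``round(fraction * stratum size)`` patients
    to the training set (size-1 strata go to training with a warning).
    Returns (train, valid) as disjoint, exhaustive row subsets.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx, valid_idx = [], []
    for _, block in cohort.groupby(key, sort=True):
        ids = block.index.to_numpy()
        if ids.size == 1:
            warnings.warn(f"stratum of size 1 assigned to training: {ids[0]!r}")
            train_idx.extend(ids)
            continue
        perm = rng.permutation(ids)
        n_train = int(round(fraction * ids.size))
        n_train = min(max(n_train, 1), ids.size - 1)  # both sides nonempty
        train_idx.extend(perm[:n_train])
        valid_idx.extend(perm[n_train:])
    if not valid_idx:
        raise ValueError("validation split is empty")
    return cohort.loc[train_idx], cohort.loc[valid_idx]


# --------------------------------------------------------------------------
# Cox modelling
# --------------------------------------------------------------------------


@dataclass
class CoxModel:
    """A fitted Cox proportional-hazards model summary.

    ``summary`` has one row per covariate with columns coef, hr,
    ci_lower, ci_upper, p (Wald); ``aic = 2k - 2 logPL``; ``lr_p`` is the
    likelihood-ratio p against the null (no-covariate) model.
    """

    covariates: list
    summary: pd.DataFrame
    log_likelihood: float
    aic: float
    lr_p: float
    n: int
    n_events: int
    fitter: CoxPHFitter = field(repr=False, default=None)

    def linear_predictor(self, data: pd.DataFrame) -> pd.Series:
        x = data[self.covariates].to_numpy(dtype=float)
        beta = self.summary["coef"].to_numpy()
        return pd.Series(x @ beta, index=data.index, name="score")


def fit_cox(
    cohort: pd.DataFrame,
    covariates,
    time_col: str = "time",
    event_col: str = "event",
    penalizer: float = 0.0,
) -> CoxModel:
    """Fit a Cox PH model by partial-likelihood maximisation (Efron ties).

    Monotone likelihood (perfect separation) is flagged: the fit is
    retried with a small ridge penalty, which caps the runaway
    coefficient, and a warning is emitted. Constant covariates are an
    error.
    """
    covariates = list(covariates)
    if not covariates:
        raise ValueError("need at least one covariate")
    df = cohort[[time_col, event_col] + covariates].copy()
    df[event_col] = df[event_col].astype(bool)
    if not df[event_col].any():
        raise ValueError("no events in cohort")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"constant covariate: {c!r}")

    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col=time_col,
                event_col=event_col,
                fit_options={"precision": 1e-9},
            )
    except ConvergenceError:
        warnings.warn(
            "monotone partial likelihood suspected; refitting with ridge "
            "penalty to cap coefficients"
        )
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(df, duration_col=time_col, event_col=event_col)

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": np.exp(s["coef"]),
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    summary.index.name = "covariate"
    log_pl = float(cph.log_likelihood_)
    aic = 2.0 * len(covariates) - 2.0 * log_pl
    lr_stat = 2.0 * (log_pl - _null_log_likelihood(cph))
    lr_p = float(sps.chi2.sf(max(lr_stat, 0.0), len(covariates)))
    return CoxModel(
        covariates,
        summary,
        log_pl,
        aic,
        lr_p,
        n=len(df),
        n_events=int(df[event_col].sum()),
        fitter=cph,
    )


def _null_log_likelihood(cph: CoxPHFitter) -> float:
    try:
        return float(cph._log_likelihood_null)
    except AttributeError:  # lifelines version drift
        return float(cph.log_likelihood_ - cph.log_likelihood_ratio_test().test_statistic / 2.0)


def stepwise_aic(
    cohort: pd.DataFrame,
    candidate_covariates,
    never_drop=(),
    time_col: str = "time",
    event_col: str = "event",
):
    """Backwards stepwise elimination under AIC.

    From the full model, repeatedly remove the (droppable) covariate
    whose removal lowers AIC the most; stop when no removal lowers AIC.
    Returns (CoxModel, trace) where trace records every step's AIC. The
    returned model's AIC is never above the full model's.
    """
    never_drop = set(never_drop)
    current = list(candidate_covariates)
    unknown = never_drop - set(current)
    if unknown:
        raise ValueError(f"never_drop covariates not in candidates: {sorted(unknown)}")
    model = fit_cox(cohort, current, time_col=time_col, event_col=event_col)
    trace = [{"step": 0, "dropped": None, "aic": model.aic, "covariates": tuple(current)}]
    step = 0
    while True:
        droppable = [c for c in current if c not in never_drop]
        if not droppable or len(current) == 1:
            break
        best = None
        for c in droppable:
            reduced = [x for x in current if x != c]
            try:
                cand = fit_cox(cohort, reduced, time_col=time_col, event_col=event_col)
            except ValueError:
                continue
            if best is None or cand.aic < best[1].aic:
                best = (c, cand)
        if best is None or best[1].aic >= model.aic:
            break
        step += 1
        current = [x for x in current if x != best[0]]
        model = best[1]
        trace.append(
            {"step": step, "dropped": best[0], "aic": model.aic, "covariates": tuple(current)}
        )
    return model, trace


# --------------------------------------------------------------------------
# proportional hazards diagnostics (Grambsch-Therneau)
# --------------------------------------------------------------------------


def ph_check(model: CoxModel, cohort: pd.DataFrame, time_col: str = "time",
             event_col: str = "event") -> pd.DataFrame:
    """Grambsch-Therneau test on scaled Schoenfeld residuals.

    Correlates scaled Schoenfeld residuals with a Kaplan-Meier transform
    of event time. Per covariate j, with Schoenfeld residuals r_k at the
    d event times, centred transform g_k, average-information variance
    V = Var(beta_hat):

        u = sum_k g_k r_k,  T_j = d (V u)_j^2 / (V_jj sum g^2),

    chi-square on 1 df, and the global statistic is
    T = d u' V u / sum g^2 on p df. For a single-covariate model the
    global test equals the per-covariate test. The returned frame has one
    row per covariate plus a ``GLOBAL`` row; ``rho`` is the correlation
    of the transform with the scaled residuals.
    """
    df = cohort[[time_col, event_col] + model.covariates].copy()
    df[event_col] = df[event_col].astype(bool)
    d = int(df[event_col].sum())
    if d < 3:
        warnings.warn("fewer than 3 events; proportional-hazards test undefined")
        rows = [{"covariate": c, "rho": np.nan, "statistic": np.nan, "p": np.nan}
                for c in model.covariates + ["GLOBAL"]]
        return pd.DataFrame(rows).set_index("covariate")

    cph = model.fitter
    resid = cph.compute_residuals(df, kind="schoenfeld")
    resid = resid[model.covariates]
    event_rows = df[df[event_col]]
    times = event_rows.loc[resid.index, time_col].to_numpy(dtype=float)

    # KM transform of time, left-continuous at event times
    km = KaplanMeierFitter().fit(df[time_col], df[event_col])
    surv = km.survival_function_["KM_estimate"]
    g = np.array([1.0 - _km_left(surv, t) for t in times])
    order = np.argsort(times, kind="mergesort")
    g = g[order]
    r = resid.to_numpy(dtype=float)[order]
    g_c = g - g.mean()
    denom = float((g_c**2).sum())

    v = model.fitter.variance_matrix_.loc[model.covariates, model.covariates].to_numpy()
    u = r.T @ g_c  # p-vector
    vu = v @ u
    per_stat = d * vu**2 / (np.diag(v) * denom)
    per_p = sps.chi2.sf(per_stat, 1)
    global_stat = float(d * u @ vu / denom)
    global_p = float(sps.chi2.sf(global_stat, len(model.covariates)))

    # rho: correlation of the transform with scaled Schoenfeld residuals
    scaled = d * (r @ v)
    rho = [float(np.corrcoef(g_c, scaled[:, j])[0, 1]) if np.std(scaled[:, j]) > 0 else np.nan
           for j in range(scaled.shape[1])]

    rows = [
        {"covariate": c, "rho": rho[j], "statistic": float(per_stat[j]), "p": float(per_p[j])}
        for j, c in enumerate(model.covariates)
    ]
    rows.append({"covariate": "GLOBAL", "rho": np.nan, "statistic": global_stat, "p": global_p})
    return pd.DataFrame(rows).set_index("covariate")


def _km_left(surv: pd.Series, t: float) -> float:
    """Left-continuous Kaplan-Meier estimate S(t-)."""
    prior = surv[surv.index < t]
    return float(prior.iloc[-1]) if len(prior) else 1.0


# --------------------------------------------------------------------------
# risk groups from a fitted model
# --------------------------------------------------------------------------


@dataclass
class RiskStratification:
    labels: pd.Series  # 'high' / 'low' per patient of apply_to
    threshold: float
    train_sizes: tuple  # (n_high, n_low) in the training cohort
    statistic: float
    p: float


def risk_split(model: CoxModel, train: pd.DataFrame, apply_to: pd.DataFrame,
               time_col: str = "time", event_col: str = "event") -> RiskStratification:
    """Median-score risk grouping transported from train to a target cohort.

    The threshold is the median linear predictor of the training cohort;
    scores at or above the threshold are high-risk (ties at the boundary
    go to the high-risk side), which partitions an odd-sized training
    set into two nearly equal groups (e.g. 255 -> 128 high / 127 low). A
    log-rank test compares the groups in ``apply_to``.
    """
    train_scores = model.linear_predictor(train)
    if train_scores.nunique() == 1:
        raise ValueError("all training scores equal; no threshold exists")
    threshold = float(train_scores.median())
    train_high = int((train_scores >= threshold).sum())
    scores = model.linear_predictor(apply_to)
    labels = pd.Series(
        np.where(scores >= threshold, "high", "low"), index=apply_to.index
    )
    stat, p = logrank_test(labels.to_numpy(), apply_to[time_col], apply_to[event_col])
    return RiskStratification(
        labels, threshold, (train_high, len(train) - train_high), stat, p
    )
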