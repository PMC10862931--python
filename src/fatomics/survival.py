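"""Survival-model construction and the evaluation battery.

Thin functional wrappers over the estimators plus the metrics used to judge
a risk model: Harrell's C-index, AIC of an unpenalized refit, inverse-
probability-of-censoring-weighted time-dependent AUC, likelihood-ratio
tests between nested models, categorical net reclassification improvement
(NRI) with Kaplan–Meier-adjusted event proportions, and median-split
Kaplan–Meier stratification.

Conventions: risk scores are linear predictors (higher = higher hazard);
survival tables are DataFrames with ``time`` (> 0) and ``event`` ({0,1})
columns aligned with the feature rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from lifelines.utils import restricted_mean_survival_time
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc

from .estimators import CoxElasticNet, MRMRSelector, as_sksurv_y, breslow_partial_loglik

__all__ = [
    "mrmr_select",
    "fit_cox_elasticnet",
    "concordance_index",
    "cox_aic",
    "auc_at_time",
    "likelihood_ratio_test",
    "nri_categorical",
    "km_stratify",
    "train_test_split_stratified",
    "NRIResult",
    "KMStratification",
]


def _time_event(surv: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return surv["time"].to_numpy(dtype=float), surv["event"].to_numpy(dtype=int)


def mrmr_select(features: pd.DataFrame, events: np.ndarray, k: int = 50) -> list[str]:
    """Greedy mRMR (FCQ) selection of k feature names against the event indicator."""
    sel = MRMRSelector(k=k).fit(features, np.asarray(events))
    return sel.selected_features_[:k]


def fit_cox_elasticnet(
    features: pd.DataFrame,
    surv: pd.DataFrame,
    l1_ratio: float = 0.8,
    n_folds: int = 10,
    seed: int = 0,
    target_support: int | None = None,
) -> CoxElasticNet:
    """Fit the elastic-net Cox model with CV-chosen penalty (see CoxElasticNet)."""
    model = CoxElasticNet(
        l1_ratio=l1_ratio, n_folds=n_folds, random_state=seed, target_support=target_support
    )
    return model.fit(features, surv[["time", "event"]])


def concordance_index(risk: np.ndarray, surv: pd.DataFrame) -> float:
    """Harrell's C over usable (event-anchored) pairs; score ties count 0.5."""
    risk = np.asarray(risk, dtype=float)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores must be finite")
    time, event = _time_event(surv)
    if event.sum() == 0:
        raise ValueError("no events: concordance undefined")
    # lifelines scores 'predicted survival time'-like quantities, so negate risk
    return float(_lifelines_cindex(time, -risk, event))


def _null_loglik(time: np.ndarray, event: np.ndarray) -> float:
    return breslow_partial_loglik(np.zeros(len(time)), time, event)


def fit_cph(df: pd.DataFrame, duration_col: str = "time", event_col: str = "event") -> CoxPHFitter:
    """Cox refit with a numerical-stabilization ladder.

    Tries the plain Newton fit first; on collinearity-driven failures
    retries with a vanishingly small, then a small, ridge stabilizer. The
    reported ``log_likelihood_`` is the unpenalized partial likelihood at
    the fitted coefficients in every case. Covariates that are constant in
    the given table are dropped first: their coefficients are
    unidentifiable and leave the partial likelihood unchanged. Raises with
    diagnostics if the whole ladder fails.
    """
    covariates = [c for c in df.columns if c not in (duration_col, event_col)]
    constant = [c for c in covariates if df[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant covariates from Cox refit: {constant[:5]}",
            stacklevel=2,
        )
        df = df.drop(columns=constant)
    last_exc: Exception | None = None
    for penalizer in (0.0, 1e-6, 1e-3, 1e-1):
        try:
            cph = CoxPHFitter(penalizer=penalizer)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col=duration_col, event_col=event_col)
            return cph
        except Exception as exc:  # ConvergenceError / LinAlgError
            last_exc = exc
    raise RuntimeError(
        f"Cox refit failed on {df.shape[1] - 2} features even with ridge stabilization"
    ) from last_exc


def _refit_loglik(features: pd.DataFrame, surv: pd.DataFrame, names: list[str]) -> float:
    """Unpenalized Cox partial log-likelihood on the named features."""
    time, event = _time_event(surv)
    if not names:
        return _null_loglik(time, event)
    df = features[list(names)].copy()
    df["time"] = time
    df["event"] = event
    return float(fit_cph(df).log_likelihood_)


def cox_aic(features: pd.DataFrame, surv: pd.DataFrame, selected: list[str]) -> float:
    """AIC = -2 log PL + 2 k on an unpenalized refit of the selected support.

    The penalized partial likelihood has no defensible AIC, so the selected
    features are refit without penalty first. An empty support gives the
    null-model AIC, -2 log PL(0).
    """
    ll = _refit_loglik(features, surv, selected)
    return -2.0 * ll + 2.0 * len(selected)


def auc_at_time(risk: np.ndarray, surv: pd.DataFrame, t: float,
                surv_train: pd.DataFrame | None = None) -> float:
    """Cumulative/dynamic time-dependent AUC at horizon t with IPCW.

    Censoring weights come from a Kaplan–Meier estimate of the censoring
    distribution on ``surv_train`` (defaults to the evaluation table
    itself).
    """
    time, event = _time_event(surv)
    if event[time <= t].sum() == 0:
        raise ValueError(f"no events by t={t}: time-dependent AUC undefined")
    if (time > t).sum() == 0:
        raise ValueError(f"no subjects at risk beyond t={t}")
    if surv_train is None:
        surv_train = surv
    tr_t, tr_e = _time_event(surv_train)
    auc, _ = cumulative_dynamic_auc(
        as_sksurv_y(tr_t, tr_e), as_sksurv_y(time, event), np.asarray(risk, dtype=float), [t]
    )
    return float(auc[0])


def likelihood_ratio_test(
    features: pd.DataFrame,
    surv: pd.DataFrame,
    model_a: list[str],
    model_b: list[str],
) -> dict:
    """Compare two Cox models by likelihood ratio.

    For nested models (A ⊆ B) returns 2·ΔlogPL against chi-square with
    df = |B| − |A|. Non-nested models with equal feature counts get only
    the ΔlogPL (no p-value); unequal-df non-nested comparisons refuse the
    chi-square with a warning.
    """
    a, b = set(model_a), set(model_b)
    if b < a:  # ensure B is the larger model
        model_a, model_b = model_b, model_a
        a, b = b, a
    ll_a = _refit_loglik(features, surv, list(model_a))
    ll_b = _refit_loglik(features, surv, list(model_b))
    delta = ll_b - ll_a
    out = {"loglik_a": ll_a, "loglik_b": ll_b, "delta_loglik": delta}
    if a <= b:
        df = len(b) - len(a)
        statistic = 2.0 * delta
        out["df"] = df
        out["statistic"] = statistic
        out["p"] = 1.0 if df == 0 else float(stats.chi2.sf(max(statistic, 0.0), df))
    else:
        warnings.warn("models are not nested; reporting delta log-likelihood only", stacklevel=2)
        out["df"] = None
        out["p"] = None
    return out


# ---------------------------------------------------------------------------
# NRI


@dataclass(frozen=True)
class NRIResult:
    nri: float
    nri_event: float
    nri_nonevent: float
    ci_low: float
    ci_high: float
    p: float
    table: pd.DataFrame  # reclassification table (old category x new category)
    horizon: float
    n_bootstrap: int


def _km_event_prob(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """KM estimate of P(event by t) for a subject subset; 0 for empty subsets."""
    if len(time) == 0:
        return 0.0
    km = KaplanMeierFitter()
    km.fit(time, event)
    return float(1.0 - km.predict(t))


def _nri_point(risk_old, risk_new, time, event, t) -> tuple[float, float, float]:
    cat_old = risk_old > np.median(risk_old)
    cat_new = risk_new > np.median(risk_new)
    up = cat_new & ~cat_old
    down = ~cat_new & cat_old
    n = len(time)
    p_all = _km_event_prob(time, event, t)
    p_up = _km_event_prob(time[up], event[up], t)
    p_down = _km_event_prob(time[down], event[down], t)
    f_up, f_down = up.sum() / n, down.sum() / n
    nri_event = (f_up * p_up - f_down * p_down) / p_all if p_all > 0 else 0.0
    nri_nonevent = (
        (f_down * (1 - p_down) - f_up * (1 - p_up)) / (1 - p_all) if p_all < 1 else 0.0
    )
    return nri_event + nri_nonevent, nri_event, nri_nonevent


def nri_categorical(
    risk_old: np.ndarray,
    risk_new: np.ndarray,
    surv: pd.DataFrame,
    t: float,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> NRIResult:
    """Two-category NRI at horizon t, split at each model's own median.

    NRI_event = P(up | event) − P(down | event) and NRI_nonevent =
    P(down | nonevent) − P(up | nonevent); event status at the horizon is
    estimated by Kaplan–Meier within each reclassification cell, so
    subjects censored before t contribute through the product-limit
    weights rather than being dropped. The confidence interval is a seeded
    percentile bootstrap (category medians recomputed per resample) and
    the p-value is a normal approximation from the bootstrap spread.
    """
    risk_old = np.asarray(risk_old, dtype=float)
    risk_new = np.asarray(risk_new, dtype=float)
    time, event = _time_event(surv)
    if len(risk_old) != len(risk_new) or len(risk_old) != len(time):
        raise ValueError("risk vectors and survival table must cover the same subjects")
    if t > time.max():
        raise ValueError(f"horizon t={t} lies beyond the longest follow-up {time.max():.3g}")

    nri, nri_e, nri_ne = _nri_point(risk_old, risk_new, time, event, t)

    cat_old = np.where(risk_old > np.median(risk_old), "high", "low")
    cat_new = np.where(risk_new > np.median(risk_new), "high", "low")
    table = pd.crosstab(
        pd.Series(cat_old, name="old"), pd.Series(cat_new, name="new")
    ).reindex(index=["low", "high"], columns=["low", "high"], fill_value=0)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    n = len(time)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            boots[i], _, _ = _nri_point(risk_old[idx], risk_new[idx], time[idx], event[idx], t)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    se = boots.std(ddof=1)
    p = float(2 * stats.norm.sf(abs(nri) / se)) if se > 0 else (0.0 if nri != 0 else 1.0)
    return NRIResult(
        nri=float(nri),
        nri_event=float(nri_e),
        nri_nonevent=float(nri_ne),
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        table=table,
        horizon=float(t),
        n_bootstrap=n_bootstrap,
    )


# ---------------------------------------------------------------------------
# KM stratification


@dataclass(frozen=True)
class KMStratification:
    logrank_p: float
    hazard_ratio: float  # high-risk vs low-risk
    hr_ci: tuple[float, float]
    mean_survival: dict  # stratum -> restricted mean survival time
    curves: dict  # stratum -> DataFrame(time, survival)
    n_per_stratum: dict
    events_per_stratum: dict


def km_stratify(risk: np.ndarray, surv: pd.DataFrame, split: float | None = None) -> KMStratification:
    """Median-split Kaplan–Meier stratification of a risk score.

    Subjects above the split (default: the score median) form the
    high-risk stratum. Reports per-stratum KM curves and restricted mean
    survival, the log-rank p-value, and the between-group hazard ratio
    from a univariate Cox fit on the group indicator. A stratum with zero
    events yields an unstable HR; it is reported with a warning.
    """
    risk = np.asarray(risk, dtype=float)
    time, event = _time_event(surv)
    thr = float(np.median(risk)) if split is None else float(split)
    high = risk > thr
    if high.all() or (~high).all():
        raise ValueError("median split produced an empty stratum")

    curves, means, ns, evs = {}, {}, {}, {}
    tmax = time.max()
    for name, m in (("low", ~high), ("high", high)):
        km = KaplanMeierFitter()
        km.fit(time[m], event[m], label=name)
        curves[name] = km.survival_function_.reset_index().rename(
            columns={"timeline": "time", name: "survival"}
        )
        means[name] = float(restricted_mean_survival_time(km, t=tmax))
        ns[name] = int(m.sum())
        evs[name] = int(event[m].sum())

    lr = logrank_test(time[high], time[~high], event[high], event[~high])

    if evs["high"] == 0 or evs["low"] == 0:
        warnings.warn("a stratum has zero events; hazard ratio is a bound, not an estimate",
                      stacklevel=2)
    df = pd.DataFrame({"time": time, "event": event, "high": high.astype(int)})
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["high"]))
        ci = cph.confidence_intervals_.loc["high"]
        hr_ci = (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1])))
    except Exception:  # zero-event stratum: monotone likelihood
        hr = np.inf if evs["low"] == 0 else 0.0
        hr_ci = (np.nan, np.nan)
    return KMStratification(
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci=hr_ci,
        mean_survival=means,
        curves=curves,
        n_per_stratum=ns,
        events_per_stratum=evs,
    )


def train_test_split_stratified(
    features: pd.DataFrame, surv: pd.DataFrame, test_size: float = 0.2, seed: int = 0
):
    """80/20 split stratified by event status, preserving the event ratio."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(surv))
    tr, te = train_test_split(
        idx, test_size=test_size, random_state=seed, stratify=surv["event"].to_numpy()
    )
    return (
        features.iloc[tr],
        features.iloc[te],
        surv.iloc[tr].reset_index(drop=True),
        surv.iloc[te].reset_index(drop=True),
    )
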