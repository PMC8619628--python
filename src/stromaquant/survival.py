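"""Survival screen for per-patient collagen features.

Implements the statistical stage of the workflow: per-patient aggregation
of core-level features, two-group comparisons, a Spearman collinearity
screen, univariable and multivariable Cox proportional-hazards models
(Efron tie handling), Kaplan-Meier curves with the mean of each continuous
feature as the High/Low cutoff, the two-group log-rank test, AIC /
likelihood-ratio model comparison, and a check of the proportional-hazards
assumption via scaled Schoenfeld residuals.

Model fitting is delegated to lifelines; this module fixes the
conventions (tie handling, cutoff rule, complete-case handling per model,
reporting order) and the result containers. Raw p-values are reported
with no multiple-testing correction — the screen is a hypothesis
generator, not a prediction model — so expect about one false flag per
twenty null features at the 0.05 level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test
from scipy import stats


@dataclass
class PatientRecord:
    """Per-patient data: core-level features, outcome, clinical covariates."""

    patient_id: str
    core_features: list        # list[FeatureVector]
    mean_features: object      # FeatureVector
    time_months: float
    event: int
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError("time_months must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(frozen=True)
class CoxResult:
    """One covariate's row of a Cox model plus the model-level fit stats."""

    covariate: str
    coefficient: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    log_likelihood: float      # model partial log-likelihood at the optimum
    aic: float                 # -2 log L + 2 k
    n: int
    n_events: int


@dataclass
class KMResult:
    """Kaplan-Meier curves per group with the two-group log-rank test."""

    times: dict[str, np.ndarray]
    survival: dict[str, np.ndarray]
    groups: list[str]
    logrank_chi2: float
    logrank_p: float


def aggregate_patient(core_features: list) -> object:
    """Across-core, field-wise mean feature vector (NaNs ignored)."""
    from .content import FeatureVector

    if not core_features:
        raise ValueError("no cores to aggregate")
    return FeatureVector.mean(core_features)


def compare_groups(x, y, test: str = "t") -> tuple[float, float]:
    """Unpaired two-sided two-group comparison.

    ``test`` is ``"t"`` (pooled-variance Student's t) or ``"mannwhitney"``
    (exact when sample sizes permit, normal approximation otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    if test == "t":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ValueError("zero variance in both groups")
        stat, p = stats.ttest_ind(x, y, equal_var=True)
    elif test == "mannwhitney":
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    fit_options = {"precision": 1e-9}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            cph.fit(df[["time_months", "event", *covariates]],
                    duration_col="time_months", event_col="event",
                    fit_options=fit_options)
    except ConvergenceError as exc:
        raise RuntimeError(
            f"Cox fit failed to converge for covariates {covariates}: {exc}"
        ) from exc
    except ConvergenceWarning as exc:
        # lifelines warns on near-monotone likelihoods / collinearity; treat a
        # wildly diverging coefficient (per covariate SD) as separation
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df[["time_months", "event", *covariates]],
                    duration_col="time_months", event_col="event",
                    fit_options=fit_options)
        scale = df[covariates].std(ddof=0).replace(0, 1.0)
        blown = (cph.params_.abs() * scale) > 5
        if blown.any():
            bad = list(cph.params_.index[blown])
            raise RuntimeError(
                f"monotone partial likelihood (perfect separation) for {bad}"
            ) from exc
    return cph


def cox_fit(time, event, X: pd.DataFrame) -> list[CoxResult]:
    """Cox proportional-hazards fit (Efron ties, Newton-Raphson).

    Returns one :class:`CoxResult` per covariate; the model-level
    log-likelihood and AIC are repeated on each row.
    """
    X = pd.DataFrame(X).copy()
    df = X.assign(time_months=np.asarray(time, dtype=float),
                  event=np.asarray(event, dtype=int))
    if df["event"].sum() < 1:
        raise ValueError("no events")
    const = [c for c in X.columns if df[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    cph = _fit_cox(df, list(X.columns))
    ll = float(cph.log_likelihood_)
    aic = float(cph.AIC_partial_)
    out = []
    summ = cph.summary
    for cov in X.columns:
        row = summ.loc[cov]
        out.append(CoxResult(
            covariate=str(cov),
            coefficient=float(row["coef"]),
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
            log_likelihood=ll, aic=aic,
            n=len(df), n_events=int(df["event"].sum())))
    return out


def lr_test(model_small: list[CoxResult],
            model_large: list[CoxResult]) -> tuple[float, int, float]:
    """Likelihood-ratio test between nested Cox models."""
    ll_s, ll_l = model_small[0].log_likelihood, model_large[0].log_likelihood
    df = len(model_large) - len(model_small)
    if df <= 0:
        df = max(df, 0)
    chi2 = 2.0 * (ll_l - ll_s)
    if chi2 < -1e-6:
        raise ValueError("models not nested or fit failed (log-likelihood decreased)")
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), p


def ph_check(time, event, X: pd.DataFrame) -> pd.DataFrame:
    """Proportional-hazards check via scaled Schoenfeld residuals.

    For each covariate, the scaled Schoenfeld residuals are correlated
    (Pearson) with the rank of the event times; a small two-sided p flags
    a time-varying effect. Returns a frame indexed by covariate with
    columns ``correlation`` and ``p``.
    """
    X = pd.DataFrame(X)
    df = X.assign(time_months=np.asarray(time, dtype=float),
                  event=np.asarray(event, dtype=int))
    if df["event"].sum() < 2:
        raise ValueError("need >= 2 events to check proportional hazards")
    cph = _fit_cox(df, list(X.columns))
    resid = cph.compute_residuals(df, kind="scaled_schoenfeld")
    event_times = df.loc[resid.index, "time_months"]
    ranks = stats.rankdata(event_times)
    rows = {}
    for cov in X.columns:
        r, p = stats.pearsonr(resid[cov].to_numpy(), ranks)
        rows[cov] = {"correlation": float(r), "p": float(p)}
    return pd.DataFrame.from_dict(rows, orient="index")


def dichotomize_at_mean(x) -> np.ndarray:
    """Label values High/Low at the mean cutoff; ties at the mean are Low."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    return np.where(x > x.mean(), "High", "Low")


def km_estimate(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate; returns (event-time grid, S(t))."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def km_logrank(time, event, groups) -> KMResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    times, survival = {}, {}
    for lab in labels:
        sel = groups == lab
        if sel.sum() == 0:
            raise ValueError(f"group {lab!r} has no subjects")
        times[lab], survival[lab] = km_estimate(time[sel], event[sel])
    a, b = labels
    res = logrank_test(time[groups == a], time[groups == b],
                       event_observed_A=event[groups == a],
                       event_observed_B=event[groups == b])
    return KMResult(times=times, survival=survival, groups=labels,
                    logrank_chi2=float(res.test_statistic),
                    logrank_p=float(res.p_value))


# ---------------------------------------------------------------------------
# The univariable screen
# ---------------------------------------------------------------------------

#: Fraction-valued features are entered into Cox models per percentage
#: point (x100), matching how area fractions and intensity ratios are
#: reported in clinical tables; p-values and flags are scale-invariant.
PERCENT_SCALED_FEATURES: tuple[str, ...] = ("af", "norm_intensity")


def covariate_scale(feature: str) -> float:
    return 100.0 if feature in PERCENT_SCALED_FEATURES else 1.0


@dataclass
class ScreenResult:
    """Outcome of the univariable feature screen.

    ``table`` has one row per feature (reporting order fixed) with HR,
    95% CI, p; ``flagged`` are the features with p < alpha and HR > 1 is
    *not* required for candidacy — the flag mirrors the univariable
    p-value rule; ``model_groups`` partitions the flagged features into
    collinearity groups (|Spearman rho| > 0.7 cannot share a model).
    """

    table: pd.DataFrame
    flagged: list[str]
    model_groups: list[list[str]]
    spearman_matrix: pd.DataFrame


def univariable_screen(patients: list[PatientRecord],
                       features: list[str] | None = None,
                       alpha: float = 0.05,
                       collinearity_rho: float = 0.7) -> ScreenResult:
    """Screen each collagen feature for association with recurrence.

    One univariable Cox model per continuous feature (complete cases for
    that feature only), a flag at p < alpha, and a Spearman collinearity
    partition among the flagged features: features correlated above
    ``collinearity_rho`` in absolute value go to separate multivariable
    models, so each group lists mutually compatible features.
    """
    from .content import SCREEN_FEATURES

    features = list(features) if features is not None else list(SCREEN_FEATURES)
    data = pd.DataFrame([{
        "patient_id": p.patient_id, "time_months": p.time_months,
        "event": p.event,
        **{f: getattr(p.mean_features, f) * covariate_scale(f)
           for f in features}} for p in patients])
    if data["event"].sum() < 2:
        raise ValueError("need >= 2 events")

    rows = []
    for f in features:
        sub = data.dropna(subset=[f])
        try:
            res = cox_fit(sub["time_months"], sub["event"], sub[[f]])[0]
            rows.append({"variable": f, "hr": res.hr, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p": res.p, "n": res.n,
                         "n_events": res.n_events})
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"univariable fit failed for {f}: {exc}",
                          RuntimeWarning, stacklevel=2)
            rows.append({"variable": f, "hr": math.nan, "ci_low": math.nan,
                         "ci_high": math.nan, "p": math.nan,
                         "n": len(sub), "n_events": int(sub["event"].sum())})
    table = pd.DataFrame(rows).set_index("variable").loc[features].reset_index()
    flagged = [r["variable"] for _, r in table.iterrows()
               if not math.isnan(r["p"]) and r["p"] < alpha]

    # Spearman collinearity partition among flagged features
    rho = pd.DataFrame(np.eye(len(flagged)), index=flagged, columns=flagged)
    for i, fi in enumerate(flagged):
        for fj in flagged[i + 1:]:
            sub = data.dropna(subset=[fi, fj])
            r, _ = spearman(sub[fi], sub[fj])
            rho.loc[fi, fj] = rho.loc[fj, fi] = r
    groups: list[list[str]] = []
    for f in flagged:
        placed = False
        for g in groups:
            if all(abs(rho.loc[f, other]) <= collinearity_rho for other in g):
                g.append(f)
                placed = True
                break
        if not placed:
            groups.append([f])
    return ScreenResult(table=table, flagged=flagged, model_groups=groups,
                        spearman_matrix=rho)
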