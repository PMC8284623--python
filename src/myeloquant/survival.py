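"""Median-split survival analysis: Kaplan-Meier, log-rank and Cox models.

The outcome analysis downstream of gating: per-case metrics (myeloid /
microglia / TAM density, microglia:TAM ratio) are dichotomised at their
cohort median into high/low groups, compared with Kaplan-Meier curves and
the log-rank test, screened with univariate Cox proportional-hazards
models, reduced by AIC-guided variable selection, and fitted jointly in a
multivariate Cox model.  Estimation is delegated to lifelines (Efron tie
handling); this module owns the cohort bookkeeping, the split and
selection logic, and the result contracts.

Survival times are in months throughout.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ConfigError, DegenerateSplitError, InsufficientDataError, ValidationError

__all__ = [
    "KMCurve",
    "CoxResult",
    "exclude_cases",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "cox_multivariate",
    "aic_select",
    "SelectionResult",
    "plot_km",
]

TIME_COL = "time_months"
EVENT_COL = "event"


def _check_cohort(records: pd.DataFrame) -> None:
    for c in (TIME_COL, EVENT_COL):
        if c not in records.columns:
            raise ValidationError(f"cohort table missing column {c!r}")
    t = records[TIME_COL]
    if not np.isfinite(t).all() or (t <= 0).any():
        raise ValidationError("survival times must be finite and > 0")
    if not records[EVENT_COL].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0/1")


def exclude_cases(
    records: pd.DataFrame, rules: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records matching any exclusion rule; log what was dropped and why.

    Each rule is a pandas query expression selecting records to EXCLUDE,
    e.g. ``"idh1_mutant == 1"`` (the standard exclusion of IDH1-mutant
    glioblastoma cases from survival analysis).  Returns (kept, log) where
    log has one row per excluded record with the rule that fired first.
    """
    kept = records.copy()
    log_rows = []
    for rule in rules:
        try:
            hit = kept.eval(rule)
        except Exception as exc:  # unknown column / bad syntax
            raise ConfigError(f"exclusion rule {rule!r} failed: {exc}") from exc
        hit = np.asarray(hit, dtype=bool)
        for _, row in kept.loc[hit].iterrows():
            log_rows.append({"case_id": row.get("case_id", "?"), "rule": rule})
        kept = kept.loc[~hit]
    if len(kept) == 0 and len(records):
        warnings.warn("exclusion rules removed every record")
    log = pd.DataFrame(log_rows, columns=["case_id", "rule"])
    return kept.reset_index(drop=True), log


def median_split(records: pd.DataFrame, metric: str, ties: str = "low") -> pd.DataFrame:
    """Dichotomise a per-case metric at its median into high/low groups.

    Values strictly above the median are "high", strictly below "low";
    values exactly at the median go to "low" by default (``ties="high"``
    flips the convention).  The split depends only on ranks, so any strictly
    monotone transform of the metric yields the same groups.  A new column
    ``<metric>_group`` is added.
    """
    if metric not in records.columns:
        raise ValidationError(f"metric {metric!r} not in cohort table")
    vals = pd.to_numeric(records[metric], errors="raise").to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError(f"metric {metric!r} has missing values")
    if np.ptp(vals) == 0:
        raise DegenerateSplitError(f"all values of {metric!r} are identical; cannot split")
    if ties not in ("low", "high"):
        raise ValidationError("ties must be 'low' or 'high'")
    med = float(np.median(vals))
    if ties == "low":
        high = vals > med
    else:
        high = vals >= med
    out = records.copy()
    out[f"{metric}_group"] = np.where(high, "high", "low")
    return out


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group.

    ``median`` is the earliest observed time with S(t) <= 0.5, or None if
    the curve never reaches 0.5.
    """

    group: str
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    median: float | None
    censor_times: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: pd.DataFrame, group_col: str | None = None) -> dict[str, KMCurve]:
    """Kaplan-Meier estimate per group (single group "all" when group_col=None)."""
    _check_cohort(records)
    if group_col is None:
        groups = {"all": records}
    else:
        if group_col not in records.columns:
            raise ValidationError(f"group column {group_col!r} missing")
        groups = {str(k): g for k, g in records.groupby(group_col, sort=True)}
    out: dict[str, KMCurve] = {}
    for name, g in groups.items():
        if len(g) < 1:
            raise InsufficientDataError(f"group {name!r} has no records")
        kmf = KaplanMeierFitter()
        kmf.fit(g[TIME_COL], g[EVENT_COL])
        tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
        times = tbl.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.loc[times].to_numpy().ravel()
        med = float(kmf.median_survival_time_)
        out[name] = KMCurve(
            group=name,
            times=times,
            at_risk=tbl["at_risk"].to_numpy(dtype=int),
            survival=surv,
            median=None if math.isinf(med) else med,
            censor_times=g.loc[g[EVENT_COL] == 0, TIME_COL].to_numpy(dtype=float),
            n=len(g),
            n_events=int(g[EVENT_COL].sum()),
        )
    return out


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p_value: float
    groups: tuple[str, str]
    n: tuple[int, int]


def logrank_test(records: pd.DataFrame, group_col: str) -> LogrankResult:
    """Two-group log-rank comparison of survival curves (df = 1)."""
    _check_cohort(records)
    levels = sorted(map(str, records[group_col].astype(str).unique()))
    if len(levels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {levels}")
    if records[EVENT_COL].sum() < 1:
        raise InsufficientDataError("log-rank needs at least one event")
    a = records[records[group_col].astype(str) == levels[0]]
    b = records[records[group_col].astype(str) == levels[1]]
    res = _ll_logrank(a[TIME_COL], b[TIME_COL], a[EVENT_COL], b[EVENT_COL])
    return LogrankResult(
        chi2=float(res.test_statistic),
        df=1,
        p_value=float(res.p_value),
        groups=(levels[0], levels[1]),
        n=(len(a), len(b)),
    )


@dataclass
class CoxResult:
    """Proportional-hazards fit: per-covariate HR with 95% CI and p, plus
    the partial log-likelihood, AIC (= 2k - 2 loglik) and a convergence flag.
    """

    covariates: pd.DataFrame  # index: covariate; columns: hr, ci_lower, ci_upper, p
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    converged: bool
    notes: list[str] = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.covariates.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.covariates.loc[covariate, "p"])


def _encode(records: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric design frame; high/low group labels become 1/0 indicators."""
    X = pd.DataFrame(index=records.index)
    for c in covariates:
        if c not in records.columns:
            raise ValidationError(f"covariate {c!r} missing from cohort table")
        col = records[c]
        if col.dtype == object or str(col.dtype) == "category":
            vals = set(map(str, col.unique()))
            if vals <= {"high", "low"}:
                X[c] = (col.astype(str) == "high").astype(float)
            else:
                raise ValidationError(
                    f"covariate {c!r} is non-numeric with levels {sorted(vals)}; "
                    "encode it before fitting"
                )
        else:
            X[c] = pd.to_numeric(col).astype(float)
    return X


def _null_partial_loglik(records: pd.DataFrame) -> float:
    """Efron partial log-likelihood of the null (no-covariate) Cox model.

    At beta = 0 every relative hazard is 1, so each of the d tied events at a
    time with risk-set size n contributes -log(n - j), j = 0..d-1.
    """
    t = records[TIME_COL].to_numpy(dtype=float)
    e = records[EVENT_COL].to_numpy(dtype=int)
    order = np.argsort(t)
    t, e = t[order], e[order]
    ll = 0.0
    n_total = len(t)
    for ut in np.unique(t[e == 1]):
        n_risk = int((t >= ut).sum())
        d = int(((t == ut) & (e == 1)).sum())
        ll -= sum(math.log(n_risk - j) for j in range(d))
    _ = n_total
    return ll


def _fit_cox(records: pd.DataFrame, covariates: Sequence[str]) -> CoxResult:
    X = _encode(records, covariates)
    notes: list[str] = []
    n_events = int(records[EVENT_COL].sum())
    if n_events < 1:
        raise InsufficientDataError("Cox model needs at least one event")
    if len(records) <= len(covariates):
        raise ValidationError("more covariates than records")
    if n_events < 10 * len(covariates):
        notes.append(f"events-per-variable below 10 ({n_events} events, {len(covariates)} covariates)")
    degenerate = [c for c in X.columns if X[c].nunique() <= 1]
    if degenerate:
        # constant covariate: no information; report HR 1 and flag
        cov = pd.DataFrame(
            {
                "hr": 1.0,
                "ci_lower": np.nan,
                "ci_upper": np.nan,
                "p": np.nan,
            },
            index=list(covariates),
        )
        ll = _null_partial_loglik(records)
        return CoxResult(
            covariates=cov,
            log_likelihood=ll,
            aic=2 * len(covariates) - 2 * ll,
            n=len(records),
            n_events=n_events,
            converged=False,
            notes=notes + [f"constant covariate(s) {degenerate}: degenerate fit flagged"],
        )
    data = pd.concat(
        [records[[TIME_COL, EVENT_COL]].reset_index(drop=True), X.reset_index(drop=True)], axis=1
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=TIME_COL, event_col=EVENT_COL)
    except Exception as exc:
        cov = pd.DataFrame(
            {"hr": np.nan, "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan},
            index=list(covariates),
        )
        ll = _null_partial_loglik(records)
        return CoxResult(
            covariates=cov,
            log_likelihood=ll,
            aic=math.inf,
            n=len(records),
            n_events=n_events,
            converged=False,
            notes=notes + [f"fit failed: {exc}"],
        )
    s = cph.summary
    cov = pd.DataFrame(
        {
            "hr": s["exp(coef)"].to_numpy(),
            "ci_lower": s["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        },
        index=list(s.index),
    )
    ll = float(cph.log_likelihood_)
    return CoxResult(
        covariates=cov,
        log_likelihood=ll,
        aic=2 * len(covariates) - 2 * ll,
        n=len(records),
        n_events=n_events,
        converged=True,
        notes=notes,
    )


def cox_univariate(records: pd.DataFrame, covariate: str) -> CoxResult:
    """Exploratory single-covariate Cox proportional-hazards fit (Efron ties)."""
    _check_cohort(records)
    return _fit_cox(records, [covariate])


def cox_multivariate(records: pd.DataFrame, covariates: Sequence[str]) -> CoxResult:
    """Joint Cox fit of several covariates (typically the AIC-selected set)."""
    _check_cohort(records)
    if not covariates:
        raise ValidationError("cox_multivariate needs at least one covariate")
    return _fit_cox(records, list(covariates))


@dataclass
class SelectionResult:
    """AIC-guided covariate selection with the full audit trail."""

    selected: tuple[str, ...]
    best_aic: float
    null_aic: float
    trace: list[dict]
    dropped_collinear: list[str] = field(default_factory=list)
    strategy: str = "exhaustive"


def aic_select(
    records: pd.DataFrame, candidates: Sequence[str], exhaustive_limit: int = 10
) -> SelectionResult:
    """Select the covariate subset minimising AIC.

    Exhaustive search over all subsets (including the null model) when the
    candidate list has at most ``exhaustive_limit`` entries, backward
    stepwise otherwise.  Perfectly collinear duplicates are dropped up front
    with a warning; every model evaluated is logged in the trace.
    """
    _check_cohort(records)
    candidates = list(dict.fromkeys(candidates))
    if not candidates:
        raise ValidationError("aic_select needs at least one candidate")
    X = _encode(records, candidates)
    keep: list[str] = []
    dropped: list[str] = []
    for c in candidates:
        collinear = False
        for k in keep:
            xa, xb = X[c].to_numpy(), X[k].to_numpy()
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue
            if abs(np.corrcoef(xa, xb)[0, 1]) > 0.9999:
                collinear = True
                break
        if collinear:
            dropped.append(c)
            warnings.warn(f"candidate {c!r} is collinear with {k!r}; dropped from selection")
        else:
            keep.append(c)
    null_aic = -2.0 * _null_partial_loglik(records)
    trace: list[dict] = [{"subset": (), "aic": null_aic}]
    best: tuple[str, ...] = ()
    best_aic = null_aic
    if len(keep) <= exhaustive_limit:
        strategy = "exhaustive"
        for r in range(1, len(keep) + 1):
            for subset in itertools.combinations(keep, r):
                res = _fit_cox(records, list(subset))
                trace.append({"subset": subset, "aic": res.aic, "converged": res.converged})
                if res.converged and res.aic < best_aic:
                    best, best_aic = subset, res.aic
    else:
        strategy = "backward"
        current = tuple(keep)
        res = _fit_cox(records, list(current))
        trace.append({"subset": current, "aic": res.aic, "converged": res.converged})
        best, best_aic = (current, res.aic) if res.converged else ((), null_aic)
        improved = True
        while improved and current:
            improved = False
            for c in current:
                subset = tuple(x for x in current if x != c)
                aic = (
                    -2.0 * _null_partial_loglik(records)
                    if not subset
                    else _fit_cox(records, list(subset)).aic
                )
                trace.append({"subset": subset, "aic": aic})
                if aic < best_aic:
                    best, best_aic, current, improved = subset, aic, subset, True
    return SelectionResult(
        selected=best,
        best_aic=best_aic,
        null_aic=null_aic,
        trace=trace,
        dropped_collinear=dropped,
        strategy=strategy,
    )


def plot_km(curves: dict[str, KMCurve], path=None, title: str | None = None):
    """Step plot of one or more KM curves; writes to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, c in curves.items():
        t = np.concatenate([[0.0], c.times])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=f"{name} (n={c.n})")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
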