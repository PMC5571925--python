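"""Prognostic screening: Cox proportional-hazards models, Spearman
correlation of feature deltas against histologic regression, and
detection-performance summaries.

Univariate Cox fits screen each candidate feature or clinical covariate
against PFS or OS; candidates with univariate Wald p at or below an inclusion
level (default 0.10, "significant or nearly significant") enter a joint
multivariate fit, and the rest are reported as not retained in the model.

The partial likelihood is maximized with the Efron correction for tied event
times (Newton-Raphson, via lifelines). Monotone-likelihood separation is
surfaced as a warning flag on the fit instead of silent divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats

ENDPOINTS = {"PFS": ("pfs_days", "pfs_event"), "OS": ("os_days", "os_event")}


@dataclass
class CoxFit:
    """Per-covariate estimates from one proportional-hazards fit."""

    covariates: list[str]
    coef: dict[str, float]
    hazard_ratio: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p_value: dict[str, float]
    log_likelihood: float
    n: int
    n_events: int
    endpoint: str
    warnings: list[str] = field(default_factory=list)
    not_retained: list[str] = field(default_factory=list)

    def ci(self, covariate: str, level: float = 0.95) -> tuple[float, float]:
        """Wald confidence interval for the hazard ratio."""
        zcrit = stats.norm.ppf(0.5 + level / 2.0)
        b, s = self.coef[covariate], self.se[covariate]
        return float(np.exp(b - zcrit * s)), float(np.exp(b + zcrit * s))


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    from .cohort import records_to_frame

    return records_to_frame(records)


def _prepare(df: pd.DataFrame, covariates: list[str], endpoint: str) -> pd.DataFrame:
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {sorted(ENDPOINTS)}")
    dur, ev = ENDPOINTS[endpoint]
    cols = [dur, ev, *covariates]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    data = df[cols].dropna().astype(float)
    if data[ev].sum() < 2:
        raise ValueError(">= 2 events required for a Cox fit")
    for c in covariates:
        if np.ptp(data[c].to_numpy()) == 0:
            raise ValueError(f"covariate {c!r} is constant")
    return data


def _fit(data: pd.DataFrame, covariates: list[str], endpoint: str) -> CoxFit:
    dur, ev = ENDPOINTS[endpoint]
    cph = CoxPHFitter()  # Efron tie handling is lifelines' default
    flagged: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(data, duration_col=dur, event_col=ev)
        except ConvergenceError as exc:
            raise ValueError(f"Cox fit failed to converge: {exc}") from exc
        for w in wlist:
            if issubclass(w.category, ConvergenceWarning):
                flagged.append(str(w.message))
    summ = cph.summary
    return CoxFit(
        covariates=list(covariates),
        coef={c: float(summ.loc[c, "coef"]) for c in covariates},
        hazard_ratio={c: float(np.exp(summ.loc[c, "coef"])) for c in covariates},
        se={c: float(summ.loc[c, "se(coef)"]) for c in covariates},
        z={c: float(summ.loc[c, "z"]) for c in covariates},
        p_value={c: float(summ.loc[c, "p"]) for c in covariates},
        log_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=int(data[ev].sum()),
        endpoint=endpoint,
        warnings=flagged,
    )


def cox_univariate(records, covariate: str, endpoint: str = "PFS") -> CoxFit:
    """Single-covariate proportional-hazards fit."""
    df = _as_frame(records)
    data = _prepare(df, [covariate], endpoint)
    return _fit(data, [covariate], endpoint)


def cox_multivariate(
    records,
    candidates: list[str],
    endpoint: str = "PFS",
    inclusion_alpha: float = 0.10,
) -> CoxFit:
    """Joint fit over candidates passing the univariate screen.

    Candidates with univariate p > ``inclusion_alpha`` are excluded and listed
    in ``not_retained`` (mirroring "not retained in model"). If no candidate
    passes, an empty-model CoxFit with explicit status is returned.
    """
    df = _as_frame(records)
    retained, dropped = [], []
    for c in candidates:
        fit = cox_univariate(df, c, endpoint)
        (retained if fit.p_value[c] <= inclusion_alpha else dropped).append(c)
    if not retained:
        dur, ev = ENDPOINTS[endpoint]
        return CoxFit(
            covariates=[],
            coef={},
            hazard_ratio={},
            se={},
            z={},
            p_value={},
            log_likelihood=float("nan"),
            n=len(df),
            n_events=int(df[ev].sum()),
            endpoint=endpoint,
            warnings=["no candidate passed the univariate screen; empty model"],
            not_retained=dropped,
        )
    data = _prepare(df, retained, endpoint)
    out = _fit(data, retained, endpoint)
    out.not_retained = dropped
    return out


def spearman_delta_vs_grade(records, delta_feature: str) -> tuple[float, float]:
    """Spearman rank correlation of a feature delta with the regression grade.

    Mid-ranks handle ties; the p-value uses the t approximation. Requires at
    least 4 complete pairs; constant ranks on either side make rho undefined.
    """
    df = _as_frame(records)
    col = delta_feature if delta_feature in df.columns else f"delta_{delta_feature}"
    if col not in df.columns:
        raise KeyError(f"no delta column for {delta_feature!r}")
    data = df[[col, "salzer_kuntschik_grade"]].dropna()
    if len(data) < 4:
        raise ValueError(">= 4 paired observations required")
    x = data[col].to_numpy(float)
    y = data["salzer_kuntschik_grade"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant ranks: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class DetectionTable:
    """Per (modality, lesion class) confusion counts for staging detection."""

    counts: pd.DataFrame  # columns: modality, lesion_class, tp, fn, tn, fp

    def __post_init__(self) -> None:
        req = {"modality", "lesion_class", "tp", "fn", "tn", "fp"}
        if not req.issubset(self.counts.columns):
            raise ValueError(f"detection table needs columns {sorted(req)}")
        if (self.counts[["tp", "fn", "tn", "fp"]] < 0).any().any():
            raise ValueError("counts must be non-negative")


def _exact_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a binomial proportion."""
    a = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a / 2, k + 1, n - k))
    return lo, hi


def detection_performance(table: DetectionTable, level: float = 0.95) -> pd.DataFrame:
    """Sensitivity and specificity (%) with exact binomial CIs.

    A metric with a zero denominator is reported as NaN with status
    'undefined'.
    """
    rows = []
    for _, r in table.counts.iterrows():
        tp, fn, tn, fp = int(r.tp), int(r.fn), int(r.tn), int(r.fp)
        for metric, k, n in (("sensitivity", tp, tp + fn), ("specificity", tn, tn + fp)):
            if n == 0:
                rows.append(
                    dict(modality=r.modality, lesion_class=r.lesion_class, metric=metric,
                         value=np.nan, ci_low=np.nan, ci_high=np.nan, status="undefined")
                )
            else:
                lo, hi = _exact_ci(k, n, level)
                rows.append(
                    dict(modality=r.modality, lesion_class=r.lesion_class, metric=metric,
                         value=100.0 * k / n, ci_low=100.0 * lo, ci_high=100.0 * hi,
                         status="ok")
                )
    return pd.DataFrame(rows)
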