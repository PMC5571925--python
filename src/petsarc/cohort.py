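"""Simulated patient cohorts with survival outcomes of known structure.

Event times follow a Weibull proportional-hazards model: with baseline scale
``lambda``, shape ``k`` and linear predictor ``eta = beta . x``, the survival
function is ``S(t | x) = exp(-(t / lambda)^k * exp(eta))`` and event times are
drawn by inversion as ``T = lambda * (-log U / exp(eta))^(1/k)``.

Censoring is independent Uniform(0, t_max); ``t_max`` is calibrated by
bisection so the expected censored fraction matches the requested target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# covariate distributions understood by CohortSpec.covariate_model:
#   ("binary", p)            Bernoulli(p), 0/1
#   ("normal", mu, sd)       Gaussian
#   ("lognormal", mu, sd)    exp(Normal(mu, sd)) — strictly positive features
#   ("uniform", lo, hi)
_DISTS = ("binary", "normal", "lognormal", "uniform")

#: Default covariate model: prevalences follow a typical pediatric bone-sarcoma
#: presentation (roughly one in five to one in four with lung lesions, one in
#: seven with bone lesions) and a right-skewed shape feature around 1.5.
DEFAULT_COVARIATE_MODEL: dict[str, tuple] = {
    "lung_metastasis": ("binary", 0.23),
    "bone_metastasis": ("binary", 0.15),
    "elongation": ("lognormal", 0.4, 0.3),
}


@dataclass
class CohortSpec:
    """Parameters of one simulated survival cohort."""

    n_patients: int = 60
    true_log_hr: dict[str, float] = field(
        default_factory=lambda: {"lung_metastasis": np.log(6.4), "elongation": np.log(1.8)}
    )
    baseline_hazard: tuple[float, float] = (1500.0, 1.2)  # Weibull (scale days, shape)
    censoring_fraction: float = 0.3
    covariate_model: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring_fraction must be in [0, 1)")
        scale, shape = self.baseline_hazard
        if scale <= 0 or shape <= 0:
            raise ValueError("Weibull scale and shape must be > 0")
        for name, dist in self.covariate_model.items():
            if dist[0] not in _DISTS:
                raise ValueError(f"unknown covariate distribution {dist[0]!r} for {name!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["baseline_hazard"] = list(self.baseline_hazard)
        d["covariate_model"] = {k: list(v) for k, v in self.covariate_model.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        d["baseline_hazard"] = tuple(d["baseline_hazard"])
        d["covariate_model"] = {k: tuple(v) for k, v in d["covariate_model"].items()}
        return cls(**d)


@dataclass
class PatientRecord:
    """Features, covariates and endpoints for one simulated subject."""

    id: str
    subgroup: str  # EWS or OST
    bone_metastasis: bool
    lung_metastasis: bool
    histologic_subtype: str
    salzer_kuntschik_grade: int
    features_baseline: dict[str, float]
    features_post: dict[str, float] | None
    deltas: dict[str, float] | None
    pfs_days: float
    os_days: float
    pfs_event: bool
    os_event: bool

    def __post_init__(self) -> None:
        if not (1 <= self.salzer_kuntschik_grade <= 6):
            raise ValueError("Salzer-Kuntschik grade must be in 1..6 (I-VI)")
        if self.pfs_days <= 0 or self.os_days <= 0:
            raise ValueError("durations must be > 0")


def _draw_covariates(
    model: dict[str, tuple], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    for name, dist in model.items():
        kind = dist[0]
        if kind == "binary":
            cols[name] = (rng.random(n) < dist[1]).astype(float)
        elif kind == "normal":
            cols[name] = rng.normal(dist[1], dist[2], n)
        elif kind == "lognormal":
            cols[name] = np.exp(rng.normal(dist[1], dist[2], n))
        elif kind == "uniform":
            cols[name] = rng.uniform(dist[1], dist[2], n)
    df = pd.DataFrame(cols)
    if all(np.ptp(df[c].to_numpy()) == 0 for c in df.columns):
        raise ValueError("degenerate covariate_model: zero variance in every covariate")
    return df


def _weibull_times(
    eta: np.ndarray, scale: float, shape: float, rng: np.random.Generator
) -> np.ndarray:
    u = rng.uniform(1e-12, 1.0, len(eta))
    return scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)


def _calibrate_tmax(times: np.ndarray, target: float) -> float:
    """Bisection for t_max of Uniform(0, t_max) censoring.

    With C ~ U(0, t_max), P(censored | T=t) = min(t / t_max, 1); the expected
    censored fraction over the drawn times is monotone decreasing in t_max.
    """
    f = lambda tm: float(np.mean(np.minimum(times / tm, 1.0)))
    lo, hi = times.min() * 1e-3, times.max() * 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival(
    eta: np.ndarray,
    baseline_hazard: tuple[float, float],
    censoring_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed times and event flags under the Weibull PH model."""
    scale, shape = baseline_hazard
    t = _weibull_times(np.asarray(eta, float), scale, shape, rng)
    if censoring_fraction == 0:
        return t, np.ones(len(t), dtype=bool)
    tmax = _calibrate_tmax(t, censoring_fraction)
    c = rng.uniform(0.0, tmax, len(t))
    observed = np.minimum(t, c)
    event = t <= c
    return observed, event


def generate_cohort(cspec: CohortSpec) -> list[PatientRecord]:
    """Draw a full simulated cohort of :class:`PatientRecord`.

    Covariates enter the linear predictor through ``true_log_hr`` (names absent
    from the covariate model are ignored with a KeyError instead — a typo
    guard). PFS and OS share the linear predictor; OS uses a 1.5x longer
    baseline scale so deaths lag progressions, and grades are drawn more
    favourable for low-hazard subjects.
    """
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_patients
    cov = _draw_covariates(cspec.covariate_model, n, rng)
    for name in cspec.true_log_hr:
        if name not in cov.columns:
            raise KeyError(f"true_log_hr names unknown covariate {name!r}")
    # the linear predictor uses raw covariate values so the fitted Cox
    # coefficient estimates exactly true_log_hr per covariate unit
    eta = np.zeros(n)
    for name, b in cspec.true_log_hr.items():
        eta += b * cov[name].to_numpy(float)
    eta -= eta.mean()  # centering only shifts the baseline hazard

    scale, shape = cspec.baseline_hazard
    pfs_t, pfs_e = simulate_survival(eta, (scale, shape), cspec.censoring_fraction, rng)
    os_t, os_e = simulate_survival(eta, (scale * 1.5, shape), cspec.censoring_fraction, rng)

    # histology: higher hazard -> stochastically worse regression grade
    p_bad = 1.0 / (1.0 + np.exp(-(eta - np.median(eta))))
    grades = np.where(
        rng.random(n) < 0.2 + 0.6 * p_bad, rng.integers(4, 7, n), rng.integers(1, 4, n)
    )
    subgroup = np.where(rng.random(n) < 0.5, "EWS", "OST")
    subtypes = {"EWS": ["classic"], "OST": ["osteoblastic", "chondroblastic", "telangiectatic"]}

    records = []
    for i in range(n):
        feats = {c: float(cov.iloc[i][c]) for c in cov.columns}
        sg = str(subgroup[i])
        records.append(
            PatientRecord(
                id=f"P{i:04d}",
                subgroup=sg,
                bone_metastasis=bool(cov.iloc[i].get("bone_metastasis", 0.0) > 0.5),
                lung_metastasis=bool(cov.iloc[i].get("lung_metastasis", 0.0) > 0.5),
                histologic_subtype=str(rng.choice(subtypes[sg])),
                salzer_kuntschik_grade=int(grades[i]),
                features_baseline=feats,
                features_post=None,
                deltas=None,
                pfs_days=float(max(pfs_t[i], 1e-3)),
                os_days=float(max(os_t[i], 1e-3)),
                pfs_event=bool(pfs_e[i]),
                os_event=bool(os_e[i]),
            )
        )
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten records to one row per patient (features prefixed by timepoint)."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "subgroup": r.subgroup,
            "bone_metastasis": int(r.bone_metastasis),
            "lung_metastasis": int(r.lung_metastasis),
            "histologic_subtype": r.histologic_subtype,
            "salzer_kuntschik_grade": r.salzer_kuntschik_grade,
            "pfs_days": r.pfs_days,
            "os_days": r.os_days,
            "pfs_event": int(r.pfs_event),
            "os_event": int(r.os_event),
        }
        for k, v in (r.features_baseline or {}).items():
            row[k] = v
        for k, v in (r.features_post or {}).items():
            row[f"post_{k}"] = v
        for k, v in (r.deltas or {}).items():
            row[f"delta_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort_csv(records: list[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
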