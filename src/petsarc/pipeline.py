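"""End-to-end orchestration: images -> masks -> features -> deltas ->
response -> prognostic report.

A study is described by a :class:`RunConfig` (YAML): an image manifest (one
row per patient: baseline/post NIfTI paths, optional mask paths, seed voxel,
background SUV), a clinical table (survival endpoints, metastasis flags,
histology), and the feature/segmentation/statistics settings.

Missing-data policy: a patient without a post-chemotherapy study participates
in baseline prognostic models only and is excluded from delta analyses, with
the reason logged. A post-therapy lesion that cannot be delineated falls back
to the translated baseline VOI for SUV statistics, and MTV/TLG are recorded
as 0 (complete metabolic disappearance) with a flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .intensity import delta_percent, mtv_tlg, suv_basic, suv_peak
from .prognostics import cox_multivariate, cox_univariate, spearman_delta_vs_grade
from .response import percist_classify
from .segmentation import (
    LesionNotDelineableError,
    SegmentationParams,
    adaptive_segment,
    fallback_voi,
)
from .shape import shape_features
from .texture import texture_features
from .volumes import LesionMask, SuvVolume, load_mask, load_suv_volume

log = logging.getLogger("petsarc")


@dataclass
class FeatureSettings:
    n_levels: int = 64
    suvpeak_mode: str = "max_mean"
    shape_mode: str = "box3d"


@dataclass
class StatsSettings:
    endpoints: list[str] = field(default_factory=lambda: ["PFS", "OS"])
    candidates: list[str] = field(default_factory=list)
    inclusion_alpha: float = 0.10
    dichotomize: bool = False


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    manifest: str
    clinical: str
    output_dir: str
    features: FeatureSettings = field(default_factory=FeatureSettings)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    statistics: StatsSettings = field(default_factory=StatsSettings)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            manifest=d["manifest"],
            clinical=d["clinical"],
            output_dir=d["output_dir"],
            features=FeatureSettings(**d.get("features", {})),
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            statistics=StatsSettings(**d.get("statistics", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))


def _features_one_timepoint(
    vol: SuvVolume, mask: LesionMask, cfg: FeatureSettings
) -> dict[str, float]:
    smax, smean = suv_basic(vol, mask)
    speak = suv_peak(vol, mask, mode=cfg.suvpeak_mode)
    mtv, tlg = mtv_tlg(vol, mask)
    out = {"suv_max": smax, "suv_peak": speak, "suv_mean": smean, "mtv": mtv, "tlg": tlg}
    # texture needs voxel pairs and shape needs a meshable mask; a lesion
    # shrunk to a handful of voxels keeps its SUV metrics with the rest NaN
    try:
        out.update(texture_features(vol, mask, cfg.n_levels))
    except ValueError as exc:
        log.warning("texture features undefined (%s)", exc)
        out.update(dict.fromkeys(
            ("homogeneity", "entropy", "dissimilarity", "hgre", "zlnu", "szhge"), float("nan")
        ))
    try:
        out.update(shape_features(mask, mode=cfg.shape_mode))
    except ValueError as exc:
        log.warning("shape features undefined (%s)", exc)
        out.update(dict.fromkeys(("elongation", "sphericity", "compactness"), float("nan")))
    return out


def _path_or_none(value) -> str | None:
    """Manifest cells may be empty strings or NaN after CSV round-trip."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _get_mask(
    vol: SuvVolume,
    mask_path: str | None,
    seed_voxel: tuple[int, int, int],
    background: float,
    params: SegmentationParams,
) -> LesionMask:
    if mask_path:
        mask = load_mask(mask_path)
        mask.check_companion(vol)
        return mask
    return adaptive_segment(vol, seed_voxel, background, params).mask


def extract_features(config: RunConfig, patient: dict) -> dict:
    """Features at each available timepoint plus deltas for one patient.

    ``patient`` is one manifest row as a dict: id, baseline_image,
    post_image (optional), baseline_mask / post_mask (optional),
    seed_i/seed_j/seed_k, background_suv, new_lesion (optional).
    """
    pid = patient["id"]
    seed_voxel = (int(patient["seed_i"]), int(patient["seed_j"]), int(patient["seed_k"]))
    background = float(patient["background_suv"])
    fcfg, scfg = config.features, config.segmentation

    vol0 = load_suv_volume(patient["baseline_image"], "baseline")
    mask0 = _get_mask(
        vol0, _path_or_none(patient.get("baseline_mask")), seed_voxel, background, scfg
    )
    baseline = _features_one_timepoint(vol0, mask0, fcfg)

    result = {
        "id": pid,
        "baseline": baseline,
        "post": None,
        "deltas": None,
        "percist": None,
        "flags": [],
    }

    post_path = _path_or_none(patient.get("post_image"))
    if not post_path:
        log.info("%s: no post-CHT study; baseline-only analyses", pid)
        result["flags"].append("no_post_study")
        return result

    vol1 = load_suv_volume(post_path, "post_cht")
    disappeared = False
    post_mask_path = _path_or_none(patient.get("post_mask"))
    if post_mask_path:
        mask1 = load_mask(post_mask_path)
        mask1.check_companion(vol1)
    else:
        try:
            mask1 = adaptive_segment(vol1, seed_voxel, background, scfg).mask
        except LesionNotDelineableError:
            log.info("%s: post-CHT lesion not delineable; baseline VOI reproduced", pid)
            mask1 = fallback_voi(mask0, vol1, offset=(0, 0, 0))
            disappeared = True
            result["flags"].append("fallback_voi")
            result["flags"].append("metabolic_disappearance")

    post = _features_one_timepoint(vol1, mask1, fcfg)
    if disappeared:
        # no metabolically active volume remains; SUV statistics keep the
        # fallback-VOI values, the volumetric burden is zero
        post["mtv"] = 0.0
        post["tlg"] = 0.0
    result["post"] = post
    result["deltas"] = delta_percent(baseline, post)
    result["percist"] = percist_classify(
        baseline["suv_peak"],
        post["suv_peak"],
        background_ref=background,
        new_lesion=bool(patient.get("new_lesion", False)),
    )
    return result


def _flatten(results: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    feat_rows, delta_rows, resp_rows = [], [], []
    for r in results:
        base = {"id": r["id"], "timepoint": "baseline", **r["baseline"]}
        feat_rows.append(base)
        if r["post"] is not None:
            feat_rows.append({"id": r["id"], "timepoint": "post_cht", **r["post"]})
        if r["deltas"] is not None:
            delta_rows.append({"id": r["id"], **{f"delta_{k}": v for k, v in r["deltas"].items()}})
        resp_rows.append(
            {"id": r["id"], "percist": r["percist"], "flags": ";".join(r["flags"])}
        )
    return pd.DataFrame(feat_rows), pd.DataFrame(delta_rows), pd.DataFrame(resp_rows)


def _prognostic_table(df: pd.DataFrame, stats_cfg: StatsSettings) -> pd.DataFrame:
    rows = []
    for endpoint in stats_cfg.endpoints:
        usable = []
        for cov in stats_cfg.candidates:
            if cov not in df.columns:
                log.warning("covariate %s missing; skipped", cov)
                continue
            x = df[cov].dropna()
            if len(x) < 2 or np.ptp(x.to_numpy(float)) == 0:
                log.warning("covariate %s constant or empty; skipped", cov)
                continue
            usable.append(cov)
        work = df.copy()
        if stats_cfg.dichotomize:
            for cov in usable:
                x = work[cov].astype(float)
                if set(x.dropna().unique()) - {0.0, 1.0}:
                    work[cov] = (x > x.median()).astype(float)
        fits = {c: cox_univariate(work, c, endpoint) for c in usable}
        multi = cox_multivariate(
            work, usable, endpoint, inclusion_alpha=stats_cfg.inclusion_alpha
        )
        for cov in usable:
            uf = fits[cov]
            lo, hi = uf.ci(cov)
            retained = cov in multi.covariates
            row = {
                "endpoint": endpoint,
                "covariate": cov,
                "hr_univariate": uf.hazard_ratio[cov],
                "ci_low": lo,
                "ci_high": hi,
                "p_univariate": uf.p_value[cov],
                "retained_multivariate": retained,
                "hr_multivariate": multi.hazard_ratio.get(cov, np.nan),
                "p_multivariate": multi.p_value.get(cov, np.nan),
            }
            rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: RunConfig) -> dict:
    """Run the full analysis and write the report files.

    Writes features.csv, deltas.csv, response.csv, prognostics.csv and a JSON
    run manifest (settings + version + seed) to ``config.output_dir``. Any
    per-patient stage error is recorded and the run continues.
    """
    manifest = pd.read_csv(config.manifest)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    clinical = pd.read_csv(config.clinical)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    results, errors = [], []
    for _, row in manifest.iterrows():
        patient = row.to_dict()
        try:
            results.append(extract_features(config, patient))
        except Exception as exc:  # keep going for the remaining patients
            log.error("%s: %s", patient.get("id"), exc)
            errors.append({"id": patient.get("id"), "error": str(exc)})
    if not results:
        raise RuntimeError("no patient could be processed")

    features, deltas, response = _flatten(results)
    baseline_feats = features[features.timepoint == "baseline"].drop(columns="timepoint")
    table = clinical.merge(baseline_feats, on="id", how="inner")
    if not deltas.empty:
        table = table.merge(deltas, on="id", how="left")

    prog = _prognostic_table(table, config.statistics)

    spearman_rows = []
    for col in [c for c in table.columns if c.startswith("delta_")]:
        sub = table[[col, "salzer_kuntschik_grade"]].dropna()
        if len(sub) >= 4 and np.ptp(sub[col].to_numpy(float)) > 0:
            rho, p = spearman_delta_vs_grade(table, col)
            spearman_rows.append({"delta_feature": col, "rho": rho, "p_value": p})
    if spearman_rows:
        prog = pd.concat(
            [prog, pd.DataFrame(spearman_rows)], axis=0, ignore_index=True
        )

    features.to_csv(outdir / "features.csv", index=False)
    deltas.to_csv(outdir / "deltas.csv", index=False)
    response.to_csv(outdir / "response.csv", index=False)
    prog.to_csv(outdir / "prognostics.csv", index=False)
    run_manifest = {
        "petsarc_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_patients": int(len(manifest)),
        "n_processed": len(results),
        "errors": errors,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    return run_manifest
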