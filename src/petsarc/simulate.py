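"""Generate a complete synthetic study on disk: paired PET phantoms, a
clinical table, and the run configuration for the analysis pipeline.

Each simulated patient gets an ellipsoidal lesion whose true elongation is
controlled, a post-chemotherapy study with uptake/volume scaled according to
a latent histologic response, and survival endpoints drawn from a Weibull
proportional-hazards model in which true lesion elongation and lung
metastasis carry the prognostic signal. A configurable fraction of patients
(default 30%, as is typical when follow-up imaging is incomplete) has no
post-chemotherapy study and participates in baseline analyses only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import simulate_survival
from .phantoms import PhantomSpec, Texture, generate_phantom, generate_response_pair
from .pipeline import RunConfig, StatsSettings
from .volumes import save_volume

_TEXTURES = (
    Texture("uniform"),
    Texture("gradient"),
    Texture("checkerboard", period=2),
    Texture("blobs", count=4),
)


def simulate_study(
    outdir: str | Path,
    n_patients: int = 60,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (36, 36, 36),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    post_fraction: float = 0.7,
    log_hr_elongation: float = np.log(1.8),
    log_hr_lung: float = np.log(6.0),
    censoring_fraction: float = 0.3,
) -> RunConfig:
    """Write images + tables under ``outdir`` and return the run config."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n = int(n_patients)
    if n < 2:
        raise ValueError("need at least 2 patients")

    background = 1.0
    center_vox = tuple((g - 1) / 2.0 for g in grid_shape)

    # lesion geometry: base radius and a true elongation factor
    radius = rng.uniform(9.0, 16.0, n)
    elong_true = np.clip(np.exp(rng.normal(0.35, 0.25, n)), 1.0, 2.6)
    lesion_suv = rng.uniform(4.0, 14.0, n)
    lung = rng.random(n) < 0.23
    bone = rng.random(n) < 0.15
    subgroup = np.where(rng.random(n) < 0.5, "EWS", "OST")

    # latent response drives grade and post-therapy scaling
    latent = rng.random(n)
    grades = np.clip((latent * 6).astype(int) + 1, 1, 6)
    uptake_scale = np.clip(0.1 + 0.85 * latent + rng.normal(0, 0.05, n), 0.0, 1.2)
    uptake_scale[(grades == 1) & (rng.random(n) < 0.5)] = 0.0  # complete disappearance
    volume_scale = np.clip(0.2 + 0.8 * latent + rng.normal(0, 0.05, n), 0.05, 1.5)

    eta = log_hr_elongation * (elong_true - elong_true.mean()) + log_hr_lung * lung
    pfs_t, pfs_e = simulate_survival(eta, (1500.0, 1.2), censoring_fraction, rng)
    os_t, os_e = simulate_survival(eta, (2200.0, 1.2), censoring_fraction, rng)

    has_post = rng.random(n) < post_fraction

    manifest_rows, clinical_rows = [], []
    for i in range(n):
        pid = f"P{i:04d}"
        spec = PhantomSpec(
            grid_shape=grid_shape,
            spacing=spacing,
            background_suv=background,
            background_noise_sd=0.05,
            lesion_center=center_vox,
            semi_axes=(radius[i] * elong_true[i], radius[i], radius[i]),
            lesion_suv=float(lesion_suv[i]),
            texture=_TEXTURES[int(rng.integers(0, len(_TEXTURES)))],
            noise_sd=0.1,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        b_img = outdir / "images" / f"{pid}_baseline.nii.gz"
        p_img = outdir / "images" / f"{pid}_post.nii.gz"
        if has_post[i]:
            (vol0, _), (vol1, _) = generate_response_pair(
                spec, float(uptake_scale[i]), float(volume_scale[i])
            )
            save_volume(vol0, b_img)
            save_volume(vol1, p_img)
        else:
            vol0, _ = generate_phantom(spec)
            save_volume(vol0, b_img)
        manifest_rows.append(
            {
                "id": pid,
                "baseline_image": str(b_img),
                "post_image": str(p_img) if has_post[i] else "",
                "baseline_mask": "",
                "post_mask": "",
                "seed_i": int(round(center_vox[0])),
                "seed_j": int(round(center_vox[1])),
                "seed_k": int(round(center_vox[2])),
                "background_suv": background,
                "new_lesion": False,
            }
        )
        clinical_rows.append(
            {
                "id": pid,
                "subgroup": subgroup[i],
                "bone_metastasis": int(bone[i]),
                "lung_metastasis": int(lung[i]),
                "histologic_subtype": "osteoblastic" if subgroup[i] == "OST" else "classic",
                "salzer_kuntschik_grade": int(grades[i]),
                "pfs_days": float(pfs_t[i]),
                "pfs_event": int(pfs_e[i]),
                "os_days": float(os_t[i]),
                "os_event": int(os_e[i]),
                "true_elongation": float(elong_true[i]),
            }
        )

    manifest_path = outdir / "manifest.csv"
    clinical_path = outdir / "clinical.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(clinical_rows).to_csv(clinical_path, index=False)

    config = RunConfig(
        manifest=str(manifest_path),
        clinical=str(clinical_path),
        output_dir=str(outdir / "results"),
        statistics=StatsSettings(
            candidates=["elongation", "lung_metastasis", "bone_metastasis", "suv_max", "mtv"],
        ),
        seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return config
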