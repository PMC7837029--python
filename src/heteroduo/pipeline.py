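"""End-to-end orchestration: per-patient feature extraction to prognosis.

A cohort is defined by a manifest CSV (columns ``id``, ``slide``, ``roi``,
``pet``, ``mask``; paths relative to the manifest) plus a clinical CSV
keyed by ``id``. ``run_all`` extracts slide and PET features for every
patient, merges them with the clinical table, runs the statistical chain,
and writes a JSON report plus CSV tables, every artifact stamped with the
configuration hash and seed. Per-patient failures are collected, not
fatal, unless they exceed a configurable fraction of the cohort.

``simulate_cohort_inputs`` materializes a fully synthetic cohort in the
same on-disk layout, so the orchestrator can be exercised end to end
without any external data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .config import RunConfig, config_hash
from .ihc import RoiMask, ihc_feature_vector
from .pet import pet_feature_vector
from .simulate import (
    CohortSimParams,
    IhcSimParams,
    PetSimParams,
    gen_cohort,
    gen_pet_lesion,
    gen_ratio_field,
    render_slide,
)
from .stats import cohort_summary, run_paper_pipeline

logger = logging.getLogger("heteroduo")

__all__ = ["extract_cohort_features", "run_all", "simulate_cohort_inputs"]


def _nan_to_none(obj):
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_nan_to_none(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def simulate_cohort_inputs(
    out_dir: str | Path,
    n: int = 40,
    seed: int = 0,
    ihc_template: IhcSimParams = IhcSimParams(),
    pet_template: PetSimParams = PetSimParams(),
    cohort_params: CohortSimParams | None = None,
) -> Path:
    """Write a synthetic cohort (slides, volumes, masks, CSVs) to disk.

    Each patient's slide skewness target follows their planted
    ``skewness_er`` value by skewing the Beta marginal, so the image-level
    and table-level truths are coupled the way the analysis assumes.
    Returns the manifest path.
    """
    import dataclasses

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cohort_params or CohortSimParams(n=n, seed=seed)
    clinical, _ = gen_cohort(params)
    rows = []
    for i, pid in enumerate(clinical["id"]):
        # right-skewed marginal for high planted skewness, and vice versa
        skew_target = clinical["skewness_er"].iloc[i]
        a, b = (2.0, 8.0) if skew_target >= 0 else (8.0, 2.0)
        ip = dataclasses.replace(ihc_template, beta_a=a, beta_b=b, seed=seed + 17 * i)
        field = gen_ratio_field(ip)
        slide, truth = render_slide(field, ip)
        slide_path = out / f"{pid}_slide.tiff"
        hio.write_slide(slide_path, slide)
        pp = dataclasses.replace(pet_template, seed=seed + 31 * i)
        vol, voi, _ = gen_pet_lesion(pp)
        vol_path, mask_path = out / f"{pid}_pet.nii.gz", out / f"{pid}_mask.nii.gz"
        hio.write_volume_mask(vol_path, mask_path, vol, voi)
        rows.append(
            {
                "id": pid,
                "slide": slide_path.name,
                "roi": "",
                "pet": vol_path.name,
                "mask": mask_path.name,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    clinical.to_csv(out / "clinical.csv", index=False)
    return manifest


def extract_cohort_features(
    manifest_path: str | Path, cfg: RunConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Slide + PET features for every patient in a manifest.

    Returns the feature table (one row per successful patient) and a list
    of per-patient failure records.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    base = manifest_path.parent
    rows, failures = [], []
    for _, rec in manifest.iterrows():
        pid = rec["id"]
        try:
            slide = hio.read_slide(base / rec["slide"], cfg.microns_per_pixel)
            roi = (
                hio.read_mask_2d(base / rec["roi"], slide.shape)
                if rec.get("roi")
                else RoiMask.full(slide)
            )
            ihc = ihc_feature_vector(slide, roi, cfg.ihc)
            vol, voi = hio.read_volume_mask(base / rec["pet"], base / rec["mask"])
            pet = pet_feature_vector(vol, voi, cfg.pet)
            row = {"id": pid}
            row.update({f"{k}_er": v for k, v in ihc.as_dict().items()
                        if k != "n_tiles_used"})
            row["n_tiles_used"] = ihc.n_tiles_used
            row.update(pet.as_dict())
            rows.append(row)
        except Exception as exc:  # per-patient isolation is the point here
            logger.warning("patient %s failed: %s", pid, exc)
            failures.append({"id": pid, "error": str(exc)})
    return pd.DataFrame(rows), failures


def run_all(
    manifest_path: str | Path, clinical_path: str | Path, cfg: RunConfig
) -> dict:
    """Extract features, merge with clinical data, run the full chain.

    Writes ``report.json``, ``features.csv`` and ``cohort.csv`` under
    ``cfg.out_dir``; raises if more than
    ``cfg.max_patient_failure_fraction`` of patients fail extraction.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)

    features, failures = extract_cohort_features(manifest_path, cfg)
    n_total = len(features) + len(failures)
    if n_total == 0:
        raise ValueError("empty manifest")
    if len(failures) > cfg.max_patient_failure_fraction * n_total:
        raise RuntimeError(
            f"{len(failures)}/{n_total} patients failed feature extraction"
        )

    clinical = pd.read_csv(clinical_path)
    drop = [c for c in clinical.columns
            if c in features.columns and c != "id"]
    cohort = features.merge(clinical.drop(columns=drop), on="id", how="inner")
    cohort = cohort.drop(columns=["n_tiles_used"])

    report = {
        "config_hash": chash,
        "seed": cfg.seed,
        "n_patients": int(len(cohort)),
        "failures": failures,
        "cohort_summary": cohort_summary(cohort, horizon=cfg.stats.horizon),
    }
    report.update(run_paper_pipeline(cohort, cfg.stats))

    features.insert(1, "config_hash", chash)
    features.to_csv(out / "features.csv", index=False)
    cohort.to_csv(out / "cohort.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(_nan_to_none(report), indent=2, sort_keys=True, default=str)
    )
    return report
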