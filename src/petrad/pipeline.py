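"""End-to-end orchestration: simulate -> segment -> extract -> evaluate -> sham.

A run is driven by one :class:`RunConfig`; every stage seeds its randomness
from the recorded seeds, so re-running a config reproduces all CSV/JSON
payload values exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from petrad.classify import CvResult, run_cv, sham_experiment
from petrad.dimred import DimredConfig
from petrad.imaging_io import write_lesion_table, write_mask, write_volume
from petrad.models import BIOCHEM_COLS, ModelSpec, model_menu
from petrad.radiomics import PreprocessConfig, extract_lesion
from petrad.segmentation import segment_lesion
from petrad.synthetic_cohort import ClusterSimParams, SyntheticLesion, default_params, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "cohort_features", "segment_cohort", "default_config_yaml"]


@dataclass
class RunConfig:
    n_cluster1: int = 13
    n_cluster2: int = 18
    n_sporadic: int = 9
    sim_seed: int = 0
    cv_seed: int = 0
    sham_seed: int = 0
    k_folds: int = 5
    sham_iterations: int = 100
    isocontour_fraction: float = 0.41
    min_voxels: int = 64
    sim_params: ClusterSimParams = field(default_factory=default_params)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    dimred: DimredConfig = field(default_factory=DimredConfig)
    specs: list[ModelSpec] = field(default_factory=model_menu)
    write_volumes: bool = True

    def validate(self) -> None:
        if self.n_cluster1 + self.n_cluster2 + self.n_sporadic == 0:
            raise ValueError("cohort is empty")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def segment_cohort(
    lesions: list[SyntheticLesion],
    fraction: float = 0.41,
    min_voxels: int = 64,
):
    """Delineate every PET lesion; returns (segmentations, qc_pass flags)."""
    segs, passed = [], []
    for les in lesions:
        seg = segment_lesion(les.pet, fraction=fraction, min_voxels=min_voxels)
        segs.append(seg)
        passed.append(seg.passed_size_filter)
        if not seg.passed_size_filter:
            logger.warning("lesion %s failed the %d-voxel size filter", les.lesion_id, min_voxels)
    return segs, passed


def cohort_features(
    lesions: list[SyntheticLesion],
    config: PreprocessConfig | None = None,
    fraction: float = 0.41,
    min_voxels: int = 64,
) -> pd.DataFrame:
    """Segment and extract every lesion into one table.

    PET VOIs come from the adaptive isocontour; CT VOIs are the externally
    supplied (here: truth) masks on the CT grid. Lesions failing the size
    filter are flagged (`qc_pass` False) but kept in the table.
    """
    config = config or PreprocessConfig()
    segs, passed = segment_cohort(lesions, fraction, min_voxels)
    rows = []
    for les, seg, ok in zip(lesions, segs, passed):
        feats, _flags = extract_lesion(les.pet, seg.mask, les.ct, les.ct_truth_mask, config)
        row = {"cluster": les.cluster}
        row.update(dict(zip(BIOCHEM_COLS, [int(b) for b in les.biochemistry])))
        row.update(feats)
        row["qc_pass"] = bool(ok)
        rows.append((les.lesion_id, row))
    df = pd.DataFrame([r for _, r in rows], index=[i for i, _ in rows])
    df.index.name = "lesion_id"
    return df


def _auc_result_to_dict(res) -> dict:
    return {
        "multiclass": res.multiclass,
        **{f"{a}_vs_{b}": v for (a, b), v in res.pairwise.items()},
    }


def cv_result_to_dict(res: CvResult) -> dict:
    return {
        "model": res.spec.name,
        "train": _auc_result_to_dict(res.mean_train),
        "test": _auc_result_to_dict(res.mean_test),
        "folds": [
            {
                "fold": f.fold,
                "train": _auc_result_to_dict(f.train),
                "test": _auc_result_to_dict(f.test),
            }
            for f in res.folds
        ],
    }


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline into `out_dir`; returns the run directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("petrad")
    root.addHandler(handler)
    try:
        logger.info(
            "seeds: sim=%d cv=%d sham=%d", config.sim_seed, config.cv_seed, config.sham_seed
        )
        stage = "simulate"
        lesions = simulate_cohort(
            config.n_cluster1, config.n_cluster2, config.n_sporadic,
            config.sim_params, config.sim_seed,
        )
        if config.write_volumes:
            vol_dir = out / "volumes"
            for les in lesions:
                write_volume(les.pet, vol_dir / f"{les.lesion_id}_pet.nii.gz")
                write_volume(les.ct, vol_dir / f"{les.lesion_id}_ct.nii.gz")
                write_mask(les.truth_mask, vol_dir / f"{les.lesion_id}_truth.nii.gz")
                write_mask(les.ct_truth_mask, vol_dir / f"{les.lesion_id}_ct_mask.nii.gz")

        stage = "segment+extract"
        features = cohort_features(
            lesions, config.preprocess, config.isocontour_fraction, config.min_voxels
        )
        write_lesion_table(features, out / "features.csv")

        stage = "evaluate"
        modelled = features[features["qc_pass"]]
        if len(modelled) < len(features):
            logger.warning(
                "excluding %d lesion(s) failing the size filter from modelling",
                len(features) - len(modelled),
            )
        labels = modelled["cluster"].to_numpy()
        feature_block = modelled.drop(columns=["cluster", "qc_pass"])
        results = {}
        fold_models = {}
        for spec in config.specs:
            res = run_cv(
                feature_block, labels, spec, config.dimred,
                k=config.k_folds, seed=config.cv_seed,
            )
            results[spec.name] = cv_result_to_dict(res)
            fold_models[spec.name] = res
        (out / "results.json").write_text(json.dumps(results, indent=2))
        _write_fold_models(fold_models, out / "fold_models")

        stage = "sham"
        sham = {}
        for spec in config.specs:
            sr = sham_experiment(
                feature_block, labels, spec,
                iterations=config.sham_iterations,
                seed=config.sham_seed, k=config.k_folds,
                dimred_config=config.dimred,
            )
            sham[spec.name] = {"mean": sr.mean, "per_iteration": sr.per_iteration}
        (out / "sham.json").write_text(json.dumps(sham, indent=2))
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline aborted in stage {stage}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _write_fold_models(fold_models: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, res in fold_models.items():
        payload = []
        for f in res.folds:
            fm = f.artifacts.get("factor_model")
            entry: dict = {"fold": f.fold}
            if fm is not None:
                entry.update(
                    {
                        "retained": fm.retained,
                        "loadings": fm.loadings.tolist(),
                        "kmo": None if not fm.kmo.defined else fm.kmo.value,
                        "factor_labels": fm.factor_labels,
                        "scaler_mean": fm.scaler.mean.tolist(),
                        "scaler_sd": fm.scaler.sd.tolist(),
                        "ridge_gamma": fm.ridge_gamma,
                    }
                )
            payload.append(entry)
        (out_dir / f"{name}.json").write_text(json.dumps(payload, indent=2))


def default_config_yaml() -> str:
    """Documented default configuration (paper-matching settings)."""
    cfg = RunConfig()
    doc = {
        "cohort": {
            "n_cluster1": cfg.n_cluster1,
            "n_cluster2": cfg.n_cluster2,
            "n_sporadic": cfg.n_sporadic,
        },
        "seeds": {"sim": cfg.sim_seed, "cv": cfg.cv_seed, "sham": cfg.sham_seed},
        "segmentation": {
            "isocontour_fraction": cfg.isocontour_fraction,
            "min_voxels": cfg.min_voxels,
        },
        "radiomics": dataclasses.asdict(cfg.preprocess),
        "dimred": dataclasses.asdict(cfg.dimred),
        "cv": {"k_folds": cfg.k_folds, "sham_iterations": cfg.sham_iterations},
        "models": [s.name for s in cfg.specs],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def config_from_yaml(text: str) -> RunConfig:
    """Build a RunConfig from the YAML layout of :func:`default_config_yaml`."""
    doc = yaml.safe_load(text) or {}
    cfg = RunConfig()
    cohort = doc.get("cohort", {})
    cfg.n_cluster1 = int(cohort.get("n_cluster1", cfg.n_cluster1))
    cfg.n_cluster2 = int(cohort.get("n_cluster2", cfg.n_cluster2))
    cfg.n_sporadic = int(cohort.get("n_sporadic", cfg.n_sporadic))
    seeds = doc.get("seeds", {})
    cfg.sim_seed = int(seeds.get("sim", cfg.sim_seed))
    cfg.cv_seed = int(seeds.get("cv", cfg.cv_seed))
    cfg.sham_seed = int(seeds.get("sham", cfg.sham_seed))
    seg = doc.get("segmentation", {})
    cfg.isocontour_fraction = float(seg.get("isocontour_fraction", cfg.isocontour_fraction))
    cfg.min_voxels = int(seg.get("min_voxels", cfg.min_voxels))
    rad = doc.get("radiomics", {})
    cfg.preprocess = PreprocessConfig(
        ct_iso_spacing=float(rad.get("ct_iso_spacing", 1.5)),
        pet_interpolate=bool(rad.get("pet_interpolate", False)),
        pet_bin_width=float(rad.get("pet_bin_width", 0.5)),
        ct_bin_width=float(rad.get("ct_bin_width", 25.0)),
    )
    dim = doc.get("dimred", {})
    cfg.dimred = DimredConfig(
        spearman_threshold=float(dim.get("spearman_threshold", 0.95)),
        subjects_per_factor=int(dim.get("subjects_per_factor", 10)),
        kmo_min=float(dim.get("kmo_min", 0.9)),
        rotation=str(dim.get("rotation", "varimax")),
        method=str(dim.get("method", "ml")),
    )
    cv = doc.get("cv", {})
    cfg.k_folds = int(cv.get("k_folds", cfg.k_folds))
    cfg.sham_iterations = int(cv.get("sham_iterations", cfg.sham_iterations))
    if "models" in doc:
        specs = []
        for name in doc["models"]:
            base, _, suffix = str(name).partition("+")
            specs.append(ModelSpec(base, add_biochem=suffix == "biochem"))
        cfg.specs = specs
    return cfg
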