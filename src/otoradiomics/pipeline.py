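"""Experiment orchestration: config, staging, provenance.

``run_experiment`` executes simulate (optional) -> preprocess -> extract ->
reduce -> train -> evaluate and writes the feature table, contribution
report, metrics JSON, ROC points and a provenance manifest.  All randomness
derives from one master seed: stage seeds are fixed offsets of it, so a
single integer reproduces every output bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import ExtractionConfig, extract_all, feature_roster
from .model import CrossValidationResults, RadiomicsClassifier, RadiomicsResults
from .mlp import MLPConfig
from .evaluation import make_split
from .preprocess import resample_isotropic, znormalize
from .synthetic import ClassEffect, CohortSpec, iter_cohort, table1_cohort_spec
from .volume import ImageVolume, SegMask, load_mask, load_volume

log = logging.getLogger("otoradiomics")

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "build_feature_table"]

# stage-seed offsets from the master seed
_SEED_SPLIT = 1
_SEED_MLP = 2
_SEED_CV = 4


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    # cohort: either a CSV of an existing cohort, or a synthetic recipe
    cohort_csv: str | None = None
    synthetic: dict | None = None  # kwargs understood by table1_cohort_spec/CohortSpec

    target_mm: float = 0.5
    znorm_scope: str = "volume"
    bin_width: float = 0.5
    wavelet: str = "coif1"

    n_components: int = 10
    mlp: dict = field(default_factory=dict)  # MLPConfig overrides

    test_center: str = "D"
    test_fraction: float = 0.26
    crossval_k: int = 0  # 0 = skip cross-validation
    bootstrap_reps: int = 2000

    seed: int = 0
    out_dir: str = "results"
    write_volumes: bool = False  # also save synthetic NIfTIs

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def validate(self) -> None:
        if self.cohort_csv is None and self.synthetic is None:
            raise ValueError("config needs either cohort_csv or a synthetic recipe")
        if self.target_mm <= 0 or self.bin_width <= 0:
            raise ValueError("target_mm and bin_width must be > 0")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.znorm_scope not in ("volume", "roi"):
            raise ValueError("znorm_scope must be 'volume' or 'roi'")


@dataclass
class ExperimentReport:
    """Outputs of one experiment run."""

    config: ExperimentConfig
    feature_table: pd.DataFrame
    results: RadiomicsResults
    cv_results: CrossValidationResults | None
    out_dir: Path


def preprocess_ear(
    img: ImageVolume, mask: SegMask, target_mm: float = 0.5, znorm_scope: str = "volume"
) -> tuple[ImageVolume, SegMask]:
    """Resample to isotropic voxels and Z-score normalize one ear."""
    rimg, rmsk = resample_isotropic(img, mask, target_mm)
    return znormalize(rimg, rmsk, scope=znorm_scope), rmsk


def build_feature_table(
    ears,
    target_mm: float = 0.5,
    znorm_scope: str = "volume",
    extraction: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Preprocess and extract features for an iterable of
    ``(id, label, center, ImageVolume, SegMask)`` ears.
    """
    extraction = extraction or ExtractionConfig()
    rows = []
    t0 = time.time()
    for n, (ear_id, label, center, img, mask) in enumerate(ears, start=1):
        pimg, pmsk = preprocess_ear(img, mask, target_mm, znorm_scope)
        feats = extract_all(pimg, pmsk, extraction)
        rows.append({"id": ear_id, "label": label, "center": center, **feats})
        if n % 50 == 0:
            log.info("extracted %d ears (%.1f s)", n, time.time() - t0)
    table = pd.DataFrame(rows, columns=["id", "label", "center"] + feature_roster())
    if table["id"].duplicated().any():
        raise ValueError("duplicate ear ids in cohort")
    return table


def _ears_from_csv(path):
    cohort = pd.read_csv(path)
    base = Path(path).parent
    for _, row in cohort.iterrows():

        def _p(p):
            q = Path(p)
            return q if q.is_absolute() else base / q

        yield (
            row["id"],
            row["label"],
            row["center"],
            load_volume(_p(row["image_path"])),
            load_mask(_p(row["mask_path"])),
        )


def _synthetic_spec(config: ExperimentConfig) -> CohortSpec:
    raw = dict(config.synthetic or {})
    effect = raw.pop("effect", None)
    counts = {}
    for key in ("n_patients", "n_controls"):
        if key in raw:
            counts[key] = raw.pop(key)
    kwargs = {}
    if effect is not None:
        kwargs["effect"] = ClassEffect(**effect) if isinstance(effect, dict) else effect
    if raw:
        raise ValueError(f"unknown synthetic keys: {sorted(raw)}")
    spec = table1_cohort_spec(seed=config.seed, **kwargs)
    if counts:
        from dataclasses import replace

        spec = replace(spec, **counts)
    return spec


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full pipeline per ``config`` and write all outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if config.synthetic is not None:
        spec = _synthetic_spec(config)
        if config.write_volumes:
            from .synthetic import generate_cohort

            generate_cohort(spec, out / "cohort")
        ears = iter_cohort(spec)
        log.info("simulate: %d ears, seed %d", spec.total, spec.seed)
    else:
        ears = _ears_from_csv(config.cohort_csv)

    extraction = ExtractionConfig(bin_width=config.bin_width, wavelet=config.wavelet)
    table = build_feature_table(ears, config.target_mm, config.znorm_scope, extraction)
    log.info("extract: %d x %d features (%.1f s)", len(table), len(table.columns) - 3, time.time() - t0)
    table.to_csv(out / "features.csv", index=False)

    split = make_split(table, config.test_center, config.test_fraction, config.seed + _SEED_SPLIT)
    clf = RadiomicsClassifier(
        table, n_components=config.n_components, mlp_config=MLPConfig(**config.mlp)
    )
    results = clf.fit(
        split, seed=config.seed + _SEED_MLP, bootstrap_reps=config.bootstrap_reps
    )
    cv_results = None
    if config.crossval_k:
        cv_results = clf.cross_validate(k=config.crossval_k, seed=config.seed + _SEED_CV)

    _write_outputs(out, config, table, results, cv_results)
    log.info("experiment done in %.1f s -> %s", time.time() - t0, out)
    return ExperimentReport(config, table, results, cv_results, out)


def _roc_points(y, proba) -> pd.DataFrame:
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, proba)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _write_outputs(out: Path, config, table, results, cv_results) -> None:
    results.contributions.to_frame().to_csv(out / "contributions.csv", index=False)
    results.contributions.plot(out / "contributions.png")
    results.predictions.to_csv(out / "predictions.csv", index=False)

    metrics = {"train": results.train_metrics.as_dict()}
    if results.test_metrics is not None:
        metrics["test"] = results.test_metrics.as_dict()
    if cv_results is not None:
        metrics["crossval_mean"] = cv_results.mean_metrics()
        cv_results.to_frame().to_json(out / "crossval_folds.json", orient="records", indent=1)
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1)

    test_rows = results.predictions["partition"] == "test"
    if test_rows.any():
        _roc_points(
            results.predictions.loc[test_rows, "label"],
            results.predictions.loc[test_rows, "proba_patient"],
        ).to_csv(out / "roc_test.csv", index=False)

    np.save(out / "pca_loadings.npy", results.pca.loadings)
    with open(out / "pca_model.json", "w") as fh:
        json.dump(
            {
                "k": results.pca.k,
                "n_train": results.pca.n_train,
                "explained_variance": results.pca.explained_variance.tolist(),
                "loadings_file": "pca_loadings.npy",
            },
            fh,
            indent=1,
        )

    cfg = asdict(config)
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "master_seed": config.seed,
        "stage_seeds": {
            "cohort": config.seed,
            "split": config.seed + _SEED_SPLIT,
            "mlp": config.seed + _SEED_MLP,
            "crossval": config.seed + _SEED_CV,
        },
        "n_samples": len(table),
        "n_features": len(table.columns) - 3,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    with open(out / "summary.txt", "w") as fh:
        fh.write(results.summary())
        if cv_results is not None:
            fh.write("\n" + cv_results.summary() + "\n")
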