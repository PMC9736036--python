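"""End-to-end orchestration: simulate → preprocess → model → cross-validate
→ learning curve → univariate → annotate, with machine-readable reports.

Every run writes a fixed bundle of artifacts to the output directory and a
run manifest listing each file with a SHA-256 content hash, so a rerun with
the same seed and configuration is verifiably identical. All randomness
flows from the single ``seed`` in :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lipid_annotation import annotate_peak, default_panel, read_panel_csv
from .multivariate import cross_validate_lopo, fit_pclda, learning_curve
from .preprocessing import FeatureMatrix, PreprocessConfig, preprocess_cohort
from .spectra_io import read_manifest, read_spectrum_table
from .synthetic_data import SimulationConfig, build_reference_panel, simulate_cohort
from .univariate_stats import (
    FC_THRESHOLD_DEFAULT,
    Q_THRESHOLD_DEFAULT,
    select_discriminant_bins,
    univariate_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_full_pipeline", "load_config"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "reimsdx_out"
    #: directory of project-CSV spectra + manifest CSV; None ⇒ simulate
    spectra_dir: str | None = None
    manifest_path: str | None = None
    seed: int = 1
    n_normal_patients: int = 85
    n_cancer_patients: int = 59
    discriminant_effect: float = 1.0
    poor_quality_fraction: float = 0.15
    n_pcs: int | str = "auto"
    priors: str = "equal"
    lc_start_per_class: int = 5
    lc_max_per_class: int = 32
    lc_iterations: int = 20
    run_learning_curve: bool = True
    q_threshold: float = Q_THRESHOLD_DEFAULT
    fc_threshold: float = FC_THRESHOLD_DEFAULT
    annotation_tolerance: float = 0.1
    panel_csv: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)


def load_config(path) -> PipelineConfig:
    """Load a flat YAML key/value config file; unknown keys are rejected."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    pp_fields = {f.name for f in dataclasses.fields(PreprocessConfig)}
    cfg_fields = {f.name for f in dataclasses.fields(PipelineConfig)} - {"preprocess"}
    pp_kwargs = {k: v for k, v in raw.items() if k in pp_fields}
    cfg_kwargs = {k: v for k, v in raw.items() if k in cfg_fields}
    unknown = set(raw) - pp_fields - cfg_fields
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**cfg_kwargs, preprocess=PreprocessConfig(**pp_kwargs))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_spectra_dir(spectra_dir: Path):
    files = sorted(f for f in spectra_dir.glob("*.csv") if f.name != "manifest.csv")
    return [read_spectrum_table(f) for f in files]


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the run manifest.

    Artifacts: feature_matrix.csv, qc_report.csv, model_report.json,
    learning_curve.csv, univariate.csv, annotations.csv and
    run_manifest.json (content hashes + seed + version).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # --- inputs -----------------------------------------------------------
    try:
        if cfg.spectra_dir is not None or cfg.manifest_path is not None:
            if cfg.manifest_path is None or not Path(cfg.manifest_path).exists():
                raise FileNotFoundError(f"manifest not found: {cfg.manifest_path}")
            manifest = read_manifest(cfg.manifest_path)
            if cfg.spectra_dir is None or not Path(cfg.spectra_dir).is_dir():
                raise FileNotFoundError(f"spectra directory not found: {cfg.spectra_dir}")
            spectra = _load_spectra_dir(Path(cfg.spectra_dir))
            logger.info("loaded %d spectra / %d samples", len(spectra), len(manifest))
        else:
            sim = SimulationConfig(
                n_normal_patients=cfg.n_normal_patients,
                n_cancer_patients=cfg.n_cancer_patients,
                discriminant_effect=cfg.discriminant_effect,
                poor_quality_fraction=cfg.poor_quality_fraction,
                seed=cfg.seed,
            )
            spectra, manifest = simulate_cohort(sim)
            logger.info("simulated %d spectra / %d samples (seed=%d)",
                        len(spectra), len(manifest), cfg.seed)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("manifest" if "manifest" in str(exc).lower() else "input",
                                 str(exc)) from exc

    # --- preprocessing ----------------------------------------------------
    try:
        features, qc_reports, drifts = preprocess_cohort(spectra, manifest, cfg.preprocess)
        qc_df = pd.DataFrame([
            {"spectrum_id": r.spectrum_id, "tic": r.tic, "snr_estimate": r.snr_estimate,
             "passed": r.passed, "reason": r.reason,
             "drift": drifts.get(r.spectrum_id)}
            for r in qc_reports
        ])
        features.to_csv(out / "feature_matrix.csv")
        qc_df.to_csv(out / "qc_report.csv", index=False)
        artifacts["feature_matrix"] = "feature_matrix.csv"
        artifacts["qc_report"] = "qc_report.csv"
        logger.info("preprocess: %d/%d spectra passed QC, %d samples in matrix",
                    int(qc_df["passed"].sum()), len(qc_df), features.n_samples)
    except Exception as exc:
        raise PipelineStageError("preprocess", str(exc)) from exc

    # --- modelling + LOPO cross-validation --------------------------------
    try:
        binary = features.binary()
        model = fit_pclda(binary, n_pcs=cfg.n_pcs, priors=cfg.priors)
        confusion, metrics, preds = cross_validate_lopo(binary, n_pcs=cfg.n_pcs, priors=cfg.priors)
        report = {
            "seed": cfg.seed,
            "version": __version__,
            "n_samples_modelled": binary.n_samples,
            "n_pcs_used": model.n_pcs_used,
            "explained_variance_pct": [round(float(v), 4)
                                       for v in model.pca.explained_variance_pct[:10]],
            "ridge_used": model.ridge_used,
            "priors": cfg.priors,
            "confusion": {"tp": confusion.tp, "fn": confusion.fn,
                          "fp": confusion.fp, "tn": confusion.tn},
            "metrics": {k: (None if np.isnan(v) else round(float(v), 2))
                        for k, v in dataclasses.asdict(metrics).items()},
        }
        with open(out / "model_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        preds.to_csv(out / "lopo_predictions.csv", index=False)
        artifacts["model_report"] = "model_report.json"
        artifacts["lopo_predictions"] = "lopo_predictions.csv"
        logger.info("LOPO: accuracy %.1f%% on %d samples",
                    metrics.accuracy, confusion.total)
    except Exception as exc:
        raise PipelineStageError("crossval", str(exc)) from exc

    # --- learning curve ---------------------------------------------------
    try:
        if cfg.run_learning_curve:
            n_per_class = min(
                sum(1 for l in binary.labels if l == "normal"),
                sum(1 for l in binary.labels if l == "cancer"),
            )
            max_k = min(cfg.lc_max_per_class, n_per_class - 1)
            lc = learning_curve(
                binary, start_per_class=cfg.lc_start_per_class,
                max_per_class=max_k, n_iterations=cfg.lc_iterations,
                seed=cfg.seed, n_pcs=cfg.n_pcs,
            )
            lc.to_csv(out / "learning_curve.csv", index=False)
            artifacts["learning_curve"] = "learning_curve.csv"
            logger.info("learning curve: %d training sizes × %d iterations",
                        len(lc), cfg.lc_iterations)
    except Exception as exc:
        raise PipelineStageError("learning-curve", str(exc)) from exc

    # --- univariate -------------------------------------------------------
    try:
        table = univariate_table(binary, cfg.q_threshold, cfg.fc_threshold)
        table.to_csv(out / "univariate.csv", index=False)
        selected = select_discriminant_bins(table, cfg.q_threshold, cfg.fc_threshold)
        artifacts["univariate"] = "univariate.csv"
        logger.info("univariate: %d of %d bins selected", len(selected), len(table))
    except Exception as exc:
        raise PipelineStageError("univariate", str(exc)) from exc

    # --- annotation of selected bins --------------------------------------
    try:
        panel = read_panel_csv(cfg.panel_csv) if cfg.panel_csv else default_panel()
        ann_rows = []
        for _, row in selected.iterrows():
            centre = float(row["bin_mz"]) + features.bin_width / 2.0
            for cand in annotate_peak(centre, panel, tolerance=cfg.annotation_tolerance):
                ann_rows.append({
                    "bin_mz": row["bin_mz"],
                    "query_mz": centre,
                    "name": cand.lipid.name,
                    "adduct": cand.adduct.value,
                    "theoretical_mz": round(cand.theoretical_mz, 4),
                    "mass_error": round(cand.mass_error, 4),
                    "fragment_support": cand.fragment_support,
                })
        pd.DataFrame(
            ann_rows,
            columns=["bin_mz", "query_mz", "name", "adduct",
                     "theoretical_mz", "mass_error", "fragment_support"],
        ).to_csv(out / "annotations.csv", index=False)
        artifacts["annotations"] = "annotations.csv"
        logger.info("annotation: %d candidate assignments for %d selected bins",
                    len(ann_rows), len(selected))
    except Exception as exc:
        raise PipelineStageError("annotate", str(exc)) from exc

    run_manifest = {
        "seed": cfg.seed,
        "version": __version__,
        "artifacts": {name: {"path": rel, "sha256": _sha256(out / rel)}
                      for name, rel in artifacts.items()},
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(run_manifest, fh, indent=2)
    return run_manifest
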