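"""Orchestration of the full calibration experiment.

``run_experiment`` runs every (preprocessing variant, concentration
basis) combination through the same protocol: replicate averaging →
preprocessing → stratified train/test split → leave-one-out CV on the
training set for one-sigma component selection → refit on the full
training set → calibration statistics (R²cal, RMSEC) on training and
validation statistics (R²CV, RMSEP, RPD) on the held-out test set. The
result is one metrics row per combination — eight rows for the standard
four variants on two bases — and is a pure function of (inputs, config,
seed).

Leave-one-out CV serves component selection only; the reported R²CV and
RMSEP come from the separate held-out partition, reconciling "leave-one-
out cross-validation" with a dedicated validation set. A failed
combination is logged and skipped rather than aborting the experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ModelMetrics, SplitResult, r_squared, rmse, rpd, stratified_split
from .plsr import PLSModel, fit_plsr, get_loadings, loo_cv, predict, save_model
from .preprocess import STANDARD_VARIANTS, PreprocessSpec, apply_pipeline
from .spectra_io import (
    ReferenceTable,
    SpectrumSet,
    average_replicates,
    read_reference,
    read_spectra,
)
from .synthetic_data import SyntheticConfig, generate_dataset

__all__ = ["ExperimentConfig", "ExperimentRow", "run_experiment",
           "calibrate_and_save", "report"]

logger = logging.getLogger("glucospec")


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one full calibration experiment."""

    spectra_path: str | Path | None = None
    reference_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    variants: tuple[str, ...] = ("raw", "snv_detrend", "deriv1", "deriv1_snv_detrend")
    bases: tuple[str, ...] = ("fresh", "dry")
    n_test: int = 24
    n_bins: int = 4
    seed: int = 0
    max_ncomp: int = 20
    scale: bool = True
    sd_source: str = "full"  # {full, test}: population for RPD's reference sd

    def __post_init__(self) -> None:
        if not self.variants or not self.bases:
            raise ValueError("need at least one variant and one basis")
        if self.synthetic is None and (
            self.spectra_path is None or self.reference_path is None
        ):
            raise ValueError("provide spectra/reference paths or a synthetic block")
        if self.sd_source not in ("full", "test"):
            raise ValueError("sd_source must be 'full' or 'test'")

    def resolve_variant(self, label: str) -> PreprocessSpec:
        if label in STANDARD_VARIANTS:
            return STANDARD_VARIANTS[label]
        return PreprocessSpec.parse(label)


@dataclass
class ExperimentRow:
    """Metrics plus the per-sample predictions and loadings behind them."""

    metrics: ModelMetrics
    split: SplitResult
    model: PLSModel
    y_test: np.ndarray
    y_test_pred: np.ndarray
    y_train: np.ndarray
    y_train_pred: np.ndarray
    loadings: np.ndarray  # (p, ncomp)
    wavelengths: np.ndarray


def _load_inputs(config: ExperimentConfig) -> tuple[SpectrumSet, ReferenceTable]:
    if config.synthetic is not None:
        scans, reference = generate_dataset(config.synthetic)
    else:
        scans = read_spectra(config.spectra_path)
        reference = read_reference(config.reference_path)
        # instrument exports suffix replicate scans: S001_r1, S001_r2, ...
        mapping = {sid: sid.rsplit("_r", 1)[0] if "_r" in sid else sid
                   for sid in scans.ids}
        scans = SpectrumSet(scans.grid, [mapping[s] for s in scans.ids], scans.matrix)
    averaged = average_replicates(scans)
    missing = set(averaged.ids) - set(reference.ids)
    if missing:
        raise ValueError(f"spectra without reference chemistry: {sorted(missing)}")
    # align reference row order to the spectra
    pos = {sid: k for k, sid in enumerate(reference.ids)}
    take = [pos[sid] for sid in averaged.ids]
    reference = ReferenceTable(
        [reference.ids[k] for k in take],
        reference.gbs_fresh[take],
        reference.gbs_dry[take],
        reference.dry_matter_fraction[take],
    )
    return averaged, reference


def _fit_one(
    processed: SpectrumSet,
    reference: ReferenceTable,
    basis: str,
    label: str,
    config: ExperimentConfig,
) -> ExperimentRow:
    y_all = reference.values(basis)
    split = stratified_split(reference, basis=basis, n_test=config.n_test,
                             n_bins=config.n_bins, seed=config.seed)
    index = {sid: k for k, sid in enumerate(processed.ids)}
    tr = [index[s] for s in split.train_ids]
    te = [index[s] for s in split.test_ids]
    X_train, y_train = processed.matrix[tr], y_all[tr]
    X_test, y_test = processed.matrix[te], y_all[te]

    max_ncomp = min(config.max_ncomp, len(tr) - 2, processed.p)
    cv = loo_cv(X_train, y_train, max_ncomp=max_ncomp, scale=config.scale)
    model = fit_plsr(X_train, y_train, ncomp=cv.chosen_ncomp, scale=config.scale)

    y_train_pred = predict(model, X_train)
    y_test_pred = predict(model, X_test)
    rmsep = rmse(y_test, y_test_pred)
    sd_ref = float(np.std(y_all if config.sd_source == "full" else y_test, ddof=1))
    metrics = ModelMetrics(
        basis=basis,
        preprocessing=label,
        r2_cal=r_squared(y_train, y_train_pred),
        rmsec=rmse(y_train, y_train_pred),
        r2_cv=r_squared(y_test, y_test_pred),
        rmsep=rmsep,
        rpd=rpd(sd_ref, rmsep),
        terms=model.ncomp,
    )
    logger.info(
        "variant=%s basis=%s scale=%s sd_source=%s ncomp=%d rmsep=%.4g rpd=%.3g",
        label, basis, config.scale, config.sd_source, model.ncomp, rmsep, metrics.rpd,
    )
    return ExperimentRow(
        metrics=metrics,
        split=split,
        model=model,
        y_test=y_test,
        y_test_pred=y_test_pred,
        y_train=y_train,
        y_train_pred=y_train_pred,
        loadings=model.x_loadings.copy(),
        wavelengths=processed.grid.points,
    )


def run_experiment(
    config: ExperimentConfig, return_rows: bool = False
) -> list[ModelMetrics] | list[ExperimentRow]:
    """Run every (variant, basis) combination; one metrics row each.

    A combination that raises is logged with its reason and skipped so the
    remaining rows still run. With ``return_rows=True`` the full
    per-combination detail (split, model, predictions, loadings) is
    returned instead of the bare metrics.
    """
    averaged, reference = _load_inputs(config)
    rows: list[ExperimentRow] = []
    for label in config.variants:
        spec = config.resolve_variant(label)
        try:
            processed = apply_pipeline(averaged, spec)
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("variant %s failed in preprocessing: %s", label, exc)
            continue
        for basis in config.bases:
            try:
                rows.append(_fit_one(processed, reference, basis, label, config))
            except Exception as exc:
                logger.error("variant %s basis %s failed: %s", label, basis, exc)
    return rows if return_rows else [r.metrics for r in rows]


def metrics_frame(metrics: list[ModelMetrics]) -> pd.DataFrame:
    """Results table in the conventional column order."""
    return pd.DataFrame(
        [
            {
                "preprocessing": m.preprocessing,
                "basis": m.basis,
                "r2_cal": m.r2_cal,
                "rmsec": m.rmsec,
                "r2_cv": m.r2_cv,
                "rmsep": m.rmsep,
                "rpd": m.rpd,
                "terms": m.terms,
            }
            for m in metrics
        ]
    )


def calibrate_and_save(
    config: ExperimentConfig, variant: str, basis: str, out_path: str | Path
) -> Path:
    """Fit one (variant, basis) calibration on the training partition and save it.

    The serialized file carries the coefficients, centring/scaling, grid
    and preprocessing label, so re-applying it to the same preprocessed
    test partition reproduces the experiment's RMSEP bit-exactly.
    """
    sub = replace(config, variants=(variant,), bases=(basis,))
    rows = run_experiment(sub, return_rows=True)
    if not rows:
        raise ValueError(f"calibration failed for variant={variant} basis={basis}")
    row = rows[0]
    return save_model(row.model, out_path, wavelengths=row.wavelengths,
                      preprocess=config.resolve_variant(variant).serialize())


def report(
    metrics: list[ModelMetrics],
    out_dir: str | Path,
    rows: list[ExperimentRow] | None = None,
) -> dict[str, Path]:
    """Write the metrics CSV and, when detail rows are given, scatter and
    loading traces.

    Outputs: ``metrics.csv`` always; ``predictions.csv`` (measured vs
    predicted on the held-out set, per variant/basis) and ``loadings.csv``
    (per-wavelength loading of each selected component) when ``rows`` is
    supplied.
    """
    if not metrics:
        raise ValueError("no metrics to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    path = out_dir / "metrics.csv"
    metrics_frame(metrics).to_csv(path, index=False, float_format="%.6g")
    written["metrics"] = path
    if rows:
        pred_records = []
        load_records = []
        for row in rows:
            m = row.metrics
            for sid, yt, yp in zip(row.split.test_ids, row.y_test, row.y_test_pred):
                pred_records.append(
                    {"preprocessing": m.preprocessing, "basis": m.basis,
                     "sample_id": sid, "measured": yt, "predicted": yp}
                )
            for a in range(row.model.ncomp):
                for wl, val in zip(row.wavelengths, row.loadings[:, a]):
                    load_records.append(
                        {"preprocessing": m.preprocessing, "basis": m.basis,
                         "component": a + 1, "wavelength": wl, "loading": val}
                    )
        path = out_dir / "predictions.csv"
        pd.DataFrame(pred_records).to_csv(path, index=False, float_format="%.8g")
        written["predictions"] = path
        if load_records:
            path = out_dir / "loadings.csv"
            pd.DataFrame(load_records).to_csv(path, index=False, float_format="%.8g")
            written["loadings"] = path
    return written
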