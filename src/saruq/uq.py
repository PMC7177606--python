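"""End-to-end uncertainty quantification through the trained surrogate.

The pipeline: build a dataset of (configuration, SAR field) pairs with the
forward model → min–max normalize → train the autoencoder → encode the
fields → train the index→code regressor → push a Monte-Carlo ensemble of
configurations through regressor + decoder → per-voxel mean, standard
deviation and coefficient of variation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import forward as fwd
from .doe import Configuration, ElectrodeLayout, sample_configurations
from .forward import Dataset, ForwardModelParams, SarField, TissueModel, VoxelGrid
from .nets import (
    AutoencoderModel,
    MinMaxNormalizer,
    NetworkSpec,
    SurrogateRegressor,
    TrainingReport,
    mse,
    train_autoencoder,
    train_surrogate,
)

__all__ = [
    "UqSummary",
    "SurrogatePair",
    "normalize_indices",
    "predict_sar",
    "ensemble_statistics",
    "evaluate_surrogate",
    "run_uq",
    "UqResult",
]


def normalize_indices(configs: np.ndarray) -> np.ndarray:
    """Ordinal encoding of position indices 1–9 onto [0, 1]: (i − 1)/8."""
    configs = np.asarray(configs)
    if np.any(configs < 1) or np.any(configs > 9):
        raise ValueError("configuration indices must lie in 1..9")
    return (configs - 1) / 8.0


@dataclass(frozen=True)
class UqSummary:
    """Per-voxel ensemble statistics of the SAR field.

    ``cv_ratio`` is 100·std/mean (percent), masked (NaN) exactly where the
    mean is zero; ``normalized`` flags whether values are on the min–max
    normalized scale or in W/kg.
    """

    mean: np.ndarray
    std: np.ndarray
    cv_ratio: np.ndarray
    n_ensemble: int
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.n_ensemble < 2:
            raise ValueError("ensemble statistics need at least 2 fields")
        if np.any(self.std < 0):
            raise ValueError("standard deviations must be non-negative")

    @property
    def mask(self) -> np.ndarray:
        """True where cv_ratio is defined (mean nonzero)."""
        return ~np.isnan(self.cv_ratio)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel": np.arange(self.mean.size),
                "mean": self.mean,
                "std": self.std,
                "cv_ratio_pct": self.cv_ratio,
            }
        )


def ensemble_statistics(fields: np.ndarray, normalized: bool = False) -> UqSummary:
    """Voxelwise sample mean, sample std (n−1 denominator) and 100·std/mean.

    ``fields`` is an (n, D) stack of flattened SAR vectors; n ≥ 2.
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim != 2 or fields.shape[0] < 2:
        raise ValueError("need at least 2 fields of equal length")
    mean = fields.mean(axis=0)
    std = fields.std(axis=0, ddof=1)
    cv = np.full_like(mean, np.nan)
    nz = mean != 0
    cv[nz] = 100.0 * std[nz] / mean[nz]
    return UqSummary(
        mean=mean, std=std, cv_ratio=cv, n_ensemble=fields.shape[0], normalized=normalized
    )


@dataclass
class SurrogatePair:
    """The trained surrogate: index→code regressor plus the decoder half of
    the autoencoder, with the normalization states needed at both ends."""

    regressor: SurrogateRegressor
    autoencoder: AutoencoderModel
    sar_normalizer: MinMaxNormalizer
    grid: VoxelGrid | None = None
    brain_radius_mm: float | None = None

    def predict_normalized(self, configs: np.ndarray) -> np.ndarray:
        """Normalized SAR predictions for an (n, L) configuration array."""
        z = normalize_indices(np.atleast_2d(configs))
        codes = self.regressor.predict_codes(z)
        out = self.autoencoder.decode(codes)
        return self._enforce_support(np.maximum(out, 0.0))

    def predict(self, configs: np.ndarray) -> np.ndarray:
        """SAR predictions in W/kg (denormalized, clipped at zero)."""
        phys = self.sar_normalizer.inverse_transform(self.predict_normalized(configs))
        return self._enforce_support(np.maximum(phys, 0.0))

    def _enforce_support(self, fields: np.ndarray) -> np.ndarray:
        # predictions are only physical inside the brain sphere; the decoder
        # output there is near but not exactly zero
        if self.grid is not None and self.brain_radius_mm is not None:
            outside = self.grid.radii() > self.brain_radius_mm
            fields[:, outside] = 0.0
        return fields


def predict_sar(
    config: Configuration | np.ndarray,
    surrogate: SurrogateRegressor,
    autoencoder: AutoencoderModel,
    sar_normalizer: MinMaxNormalizer | None = None,
    denormalize: bool = False,
) -> np.ndarray:
    """Surrogate prediction for one configuration (decoder∘regressor)."""
    indices = config.indices if isinstance(config, Configuration) else np.asarray(config)
    z = normalize_indices(indices[None, :])
    out = autoencoder.decode(surrogate.predict_codes(z))[0]
    if denormalize:
        if sar_normalizer is None or not sar_normalizer.fitted:
            raise RuntimeError("denormalization requires a fitted SAR normalizer")
        out = sar_normalizer.inverse_transform(out[None, :])[0]
    return np.maximum(out, 0.0)


def evaluate_surrogate(
    pair: SurrogatePair,
    test_configs: np.ndarray,
    test_fields_normalized: np.ndarray,
    train_configs: np.ndarray | None = None,
) -> dict:
    """Held-out MSEs: reconstructed-field error and predicted-code error.

    Both are on the normalized scale.  If the training configurations are
    supplied, any overlap with the test set is rejected.
    """
    test_configs = np.atleast_2d(test_configs)
    if train_configs is not None:
        tr = {tuple(int(v) for v in row) for row in np.atleast_2d(train_configs)}
        for row in test_configs:
            if tuple(int(v) for v in row) in tr:
                raise ValueError("test configurations overlap the training set")
    z = normalize_indices(test_configs)
    codes_true = pair.autoencoder.encode(test_fields_normalized)
    codes_pred = pair.regressor.predict_codes(z)
    recon = pair.autoencoder.decode(codes_true)
    predicted = pair.autoencoder.decode(codes_pred)
    return {
        "autoencoder_test_mse": mse(test_fields_normalized, recon),
        "code_test_mse": mse(codes_true, codes_pred),
        "end_to_end_test_mse": mse(test_fields_normalized, predicted),
    }


@dataclass
class PipelineConfig:
    """Everything one UQ run needs; defaults follow the shipped protocol."""

    layout: ElectrodeLayout
    tissue: TissueModel
    grid: VoxelGrid
    forward_params: ForwardModelParams
    ae_spec: NetworkSpec
    reg_spec: NetworkSpec
    n_ae_train: int = 100
    n_ae_test: int = 400
    n_reg_train: int = 200
    n_reg_test: int = 200
    val_fraction: float = 0.30
    n_ensemble: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ae_train", "n_ae_test", "n_reg_train", "n_reg_test"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.n_ensemble < 2:
            raise ValueError("n_ensemble must be >= 2")


@dataclass
class UqResult:
    surrogate_summary: UqSummary
    surrogate_summary_normalized: UqSummary
    pair: SurrogatePair
    ae_report: TrainingReport
    reg_report: TrainingReport
    test_metrics: dict
    manifest: dict


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_uq(cfg: PipelineConfig) -> UqResult:
    """Execute the full surrogate-UQ pipeline and return all artifacts.

    Stage seeds are derived deterministically from ``cfg.seed`` so every
    random draw (datasets, splits, weights, Monte-Carlo ensemble) is
    reproducible from the single configuration.
    """
    stage = "build_dataset"
    try:
        n_total = cfg.n_ae_train + cfg.n_ae_test + cfg.n_reg_train + cfg.n_reg_test
        ds = fwd.build_dataset(
            cfg.layout, cfg.tissue, cfg.grid, cfg.forward_params, n_total, seed=cfg.seed
        )
        n1 = cfg.n_ae_train
        n2 = n1 + cfg.n_ae_test
        n3 = n2 + cfg.n_reg_train
        ae_train, ae_test = ds.fields[:n1], ds.fields[n1:n2]
        reg_train_cfg, reg_test_cfg = ds.configs[n2:n3], ds.configs[n3:]
        reg_train_f, reg_test_f = ds.fields[n2:n3], ds.fields[n3:]

        stage = "normalize"
        sar_norm = MinMaxNormalizer(mode="global").fit(ae_train)
        ae_train_n = sar_norm.transform(ae_train)
        ae_test_n = sar_norm.transform(ae_test)
        reg_train_n = sar_norm.transform(reg_train_f)
        reg_test_n = sar_norm.transform(reg_test_f)

        stage = "train_autoencoder"
        ae_spec = dataclasses.replace(cfg.ae_spec, seed=cfg.seed + 1)
        ae, ae_report = train_autoencoder(ae_train_n, ae_spec, cfg.val_fraction)
        ae.normalizer = sar_norm
        ae_report.test_mse = mse(ae_test_n, ae.reconstruct(ae_test_n))

        stage = "train_surrogate"
        codes_train = ae.encode(reg_train_n)
        reg_spec = dataclasses.replace(cfg.reg_spec, seed=cfg.seed + 2)
        reg, reg_report = train_surrogate(
            normalize_indices(reg_train_cfg), codes_train, reg_spec, cfg.val_fraction
        )
        codes_test = ae.encode(reg_test_n)
        reg_report.test_mse = mse(
            codes_test, reg.predict_codes(normalize_indices(reg_test_cfg))
        )

        pair = SurrogatePair(
            regressor=reg,
            autoencoder=ae,
            sar_normalizer=sar_norm,
            grid=cfg.grid,
            brain_radius_mm=cfg.tissue.brain.outer_radius_mm,
        )

        stage = "evaluate"
        test_metrics = evaluate_surrogate(pair, reg_test_cfg, reg_test_n)

        stage = "monte_carlo"
        mc_configs = sample_configurations(cfg.layout.L, cfg.n_ensemble, cfg.seed + 3)
        pred_phys = pair.predict(mc_configs)
        pred_norm = pair.predict_normalized(mc_configs)
        summary = ensemble_statistics(pred_phys, normalized=False)
        summary_norm = ensemble_statistics(pred_norm, normalized=True)
    except Exception as exc:
        raise RuntimeError(f"UQ pipeline failed in stage '{stage}': {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "stages": [
            "build_dataset",
            "normalize",
            "train_autoencoder",
            "train_surrogate",
            "evaluate",
            "monte_carlo",
        ],
        "dataset_hash": _sha(ds.fields),
        "mc_configs_hash": _sha(mc_configs),
        "summary_mean_hash": _sha(summary.mean),
        "summary_std_hash": _sha(summary.std),
        "n_samples": {
            "ae_train": cfg.n_ae_train,
            "ae_test": cfg.n_ae_test,
            "reg_train": cfg.n_reg_train,
            "reg_test": cfg.n_reg_test,
            "ensemble": cfg.n_ensemble,
        },
        "reports": {
            "autoencoder": ae_report.as_dict(),
            "regressor": reg_report.as_dict(),
        },
        "test_metrics": test_metrics,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return UqResult(
        surrogate_summary=summary,
        surrogate_summary_normalized=summary_norm,
        pair=pair,
        ae_report=ae_report,
        reg_report=reg_report,
        test_metrics=test_metrics,
        manifest=manifest,
    )


def save_summary(summary: UqSummary, path) -> None:
    """CSV export: voxel index, mean, std, cv_ratio (percent)."""
    summary.to_frame().to_csv(path, index=False)


def save_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
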