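"""Canonical study setups: shipped network specs and test fixtures.

Four fixture kinds are provided:

``tiny``
    A two-electrode, 5³-voxel pipeline with small networks; the whole UQ
    chain runs in seconds and its 81-configuration design space can be
    enumerated exhaustively.
``rank_limited``
    The autoencoder benchmark: fields with exact low-rank structure
    (rank 40 ≤ bottleneck 50) on a 14³ grid, so the truncated-SVD
    reconstruction floor is exactly zero and every unit of held-out MSE is
    attributable to the network.
``linear_codes``
    The regressor benchmark: latent codes that are an exact affine function
    of the normalized ordinal index vector, so ordinary least squares gives
    a zero error floor.
``paper_scale``
    The full-scale protocol: 64 electrodes, 30³ = 27,000-dim fields,
    100-dim codes, full-width networks.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .doe import default_layout, fibonacci_cap_layout, sample_configurations, save_layout
from .forward import (
    Dataset,
    ForwardModelParams,
    TissueModel,
    VoxelGrid,
    build_dataset,
    save_dataset,
)
from .nets import AUTOENCODER_SPEC, REGRESSOR_SPEC, NetworkSpec
from .uq import PipelineConfig

__all__ = [
    "AUTOENCODER_SCALED_SPEC",
    "REGRESSOR_SCALED_SPEC",
    "tiny_pipeline_config",
    "paper_scale_pipeline_config",
    "rank_limited_dataset",
    "linear_codes_data",
    "make_fixtures",
]

#: desk-scale counterparts of the full-scale specs: one-tenth layer widths
#: around a 50-wide bottleneck, same batch structure, epoch budgets chosen
#: for convergence on the engineered benchmark data
AUTOENCODER_SCALED_SPEC = NetworkSpec(
    hidden_widths=(300, 300, 300, 50, 300, 300, 300),
    epochs=5000,
    batch_size=25,
    learning_rate=1e-3,
    activation_margin=6.0,
)
REGRESSOR_SCALED_SPEC = NetworkSpec(
    hidden_widths=(250, 250, 50),
    epochs=3000,
    batch_size=50,
    learning_rate=1e-3,
    activation_margin=6.0,
)

#: grid whose voxel count is the cube closest to one tenth of the
#: full-scale 27,000: 14³ = 2744
SCALED_GRID = VoxelGrid(n_per_axis=14, extent_mm=68.0)
SCALED_RANK = 40


def tiny_pipeline_config(seed: int = 0) -> PipelineConfig:
    """L=2, D=125 pipeline that exercises every stage in under a minute."""
    layout = fibonacci_cap_layout(L=2, radius_mm=74.7, delta=np.deg2rad(2.0))
    ae_spec = NetworkSpec(
        hidden_widths=(40, 10, 40),
        epochs=800,
        batch_size=10,
        learning_rate=1e-3,
        activation_margin=6.0,
        seed=seed,
    )
    reg_spec = NetworkSpec(
        hidden_widths=(20, 10),
        epochs=2000,
        batch_size=10,
        learning_rate=3e-3,
        activation_margin=6.0,
        seed=seed,
    )
    return PipelineConfig(
        layout=layout,
        tissue=TissueModel.three_layer_child_900mhz(),
        grid=VoxelGrid(n_per_axis=5, extent_mm=68.0),
        forward_params=ForwardModelParams(),
        ae_spec=ae_spec,
        reg_spec=reg_spec,
        n_ae_train=60,
        n_ae_test=40,
        n_reg_train=120,
        n_reg_test=60,
        n_ensemble=150,
        seed=seed,
    )


def paper_scale_pipeline_config(seed: int = 0) -> PipelineConfig:
    """The full protocol: 27,000-dim fields, 100-dim codes, Table-scale nets."""
    return PipelineConfig(
        layout=default_layout(),
        tissue=TissueModel.three_layer_child_900mhz(),
        grid=VoxelGrid(n_per_axis=30, extent_mm=68.0),
        forward_params=ForwardModelParams(),
        ae_spec=AUTOENCODER_SPEC,
        reg_spec=REGRESSOR_SPEC,
        seed=seed,
    )


def rank_limited_dataset(
    seed: int,
    n_samples: int = 500,
    rank: int = SCALED_RANK,
    grid: VoxelGrid = SCALED_GRID,
) -> Dataset:
    """Exact-low-rank SAR dataset for the autoencoder benchmark."""
    layout = default_layout()
    params = ForwardModelParams(rank_limited=True, rank=rank)
    return build_dataset(
        layout, TissueModel.three_layer_child_900mhz(), grid, params, n_samples, seed
    )


def linear_codes_data(
    seed: int,
    L: int = 64,
    d: int = 50,
    n_train: int = 200,
    n_test: int = 200,
    decay: float = 0.75,
    leading_std: float = 0.015,
):
    """Configurations plus codes that are exactly affine in the normalized
    ordinal indices.

    Column strengths decay geometrically (``decay``), emulating the steep
    mode spectrum an encoder inherits from smooth field data; the leading
    latent dimension fluctuates with standard deviation ``leading_std``
    around a mid-range intercept, i.e. a few percent of its magnitude.

    Returns ``(configs_train, configs_test, codes_train, codes_test, (A, b))``.
    """
    configs_train = sample_configurations(L, n_train, seed)
    configs_test = sample_configurations(L, n_test, seed + 1)
    z_train = (configs_train - 1) / 8.0
    z_test = (configs_test - 1) / 8.0
    rng = np.random.default_rng(seed + 2)
    A = rng.normal(size=(L, d))
    A /= np.linalg.norm(A, axis=0)
    z_std = np.sqrt(((np.arange(9) / 8.0 - 0.5) ** 2).mean())  # std of one index
    A *= (leading_std / z_std) * decay ** np.arange(d)
    b = rng.uniform(0.3, 0.7, size=d)
    return configs_train, configs_test, z_train @ A + b, z_test @ A + b, (A, b)


def make_fixtures(kind: str, seed: int, outdir) -> dict:
    """Write the fixture files for ``kind`` under ``outdir``.

    Returns a manifest of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    if kind == "tiny":
        from .config import save_config

        cfg = tiny_pipeline_config(seed)
        save_config(cfg, outdir / "tiny.yaml")
        save_layout(cfg.layout, outdir / "tiny_layout.csv")
        written = {"config": "tiny.yaml", "layout": "tiny_layout.csv"}
    elif kind == "rank_limited":
        ds = rank_limited_dataset(seed)
        save_dataset(ds, outdir / "rank_limited.npz")
        written = {"dataset": "rank_limited.npz", "metadata": "rank_limited.json"}
    elif kind == "linear_codes":
        ctr, cte, ytr, yte, _ = linear_codes_data(seed)
        np.savez(
            outdir / "linear_codes.npz",
            configs_train=ctr,
            configs_test=cte,
            codes_train=ytr,
            codes_test=yte,
        )
        (outdir / "linear_codes.json").write_text(
            json.dumps({"seed": seed, "L": 64, "d": 50})
        )
        written = {"dataset": "linear_codes.npz", "metadata": "linear_codes.json"}
    elif kind == "paper_scale":
        from .config import save_config

        cfg = paper_scale_pipeline_config(seed)
        save_config(cfg, outdir / "paper_scale.yaml")
        save_layout(cfg.layout, outdir / "paper_scale_layout.csv")
        # a two-sample dataset demonstrating the 27,000-dim field shape
        ds = build_dataset(
            cfg.layout, cfg.tissue, cfg.grid, cfg.forward_params, 2, seed
        )
        save_dataset(ds, outdir / "paper_scale_sample.npz")
        written = {
            "config": "paper_scale.yaml",
            "layout": "paper_scale_layout.csv",
            "sample_dataset": "paper_scale_sample.npz",
        }
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return {"kind": kind, "seed": seed, "files": written}
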