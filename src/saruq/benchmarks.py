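"""Benchmark procedures on engineered data with known error floors.

Both benchmarks mirror the full-scale training protocol at one-tenth width:
the autoencoder benchmark trains on exact-low-rank SAR data (truncated-SVD
reconstruction floor = 0), the regressor benchmark on codes that are an
exact affine function of the normalized indices (least-squares floor = 0).
Every unit of held-out error is therefore attributable to the network and
its training, and the full-scale held-out errors are upper-bounded by
construction.
"""

from __future__ import annotations

import numpy as np

from .fixtures import (
    AUTOENCODER_SCALED_SPEC,
    REGRESSOR_SCALED_SPEC,
    linear_codes_data,
    rank_limited_dataset,
)
from .nets import MinMaxNormalizer, mse, train_autoencoder, train_surrogate
from .uq import normalize_indices

__all__ = ["autoencoder_benchmark", "regressor_benchmark"]


def svd_reconstruction_floor(
    train: np.ndarray, test: np.ndarray, rank: int
) -> float:
    """Held-out MSE of rank-``rank`` PCA reconstruction fitted on ``train``.

    This is the attainable lower bound for any autoencoder with a
    ``rank``-wide linear bottleneck trained on the same data.
    """
    mean = train.mean(axis=0)
    _, _, vt = np.linalg.svd(train - mean, full_matrices=False)
    v = vt[:rank]
    recon = (test - mean) @ v.T @ v + mean
    return mse(test, recon)


def ols_floor(
    z_train: np.ndarray, y_train: np.ndarray, z_test: np.ndarray, y_test: np.ndarray
) -> float:
    """Held-out MSE of the ordinary-least-squares affine fit."""
    X = np.column_stack([z_train, np.ones(len(z_train))])
    beta, *_ = np.linalg.lstsq(X, y_train, rcond=None)
    Xt = np.column_stack([z_test, np.ones(len(z_test))])
    return mse(y_test, Xt @ beta)


def autoencoder_benchmark(
    seed: int,
    n_train: int = 100,
    n_test: int = 400,
    spec=AUTOENCODER_SCALED_SPEC,
) -> dict:
    """Train the scaled autoencoder on rank-limited data; report held-out MSE.

    Protocol: ``n_train`` training + ``n_test`` testing samples, one global
    min–max normalization fitted on the training fields, a 30% validation
    split inside the training set, and Eq-style MSE on the held-out set.
    """
    ds = rank_limited_dataset(seed, n_samples=n_train + n_test)
    norm = MinMaxNormalizer(mode="global").fit(ds.fields[:n_train])
    x_train = norm.transform(ds.fields[:n_train])
    x_test = norm.transform(ds.fields[n_train:])

    spec = spec.__class__(**{**spec.__dict__, "seed": seed})
    model, report = train_autoencoder(x_train, spec, val_fraction=0.30)
    test_mse = mse(x_test, model.reconstruct(x_test))
    d = model.code_dim
    return {
        "train_mse": report.train_mse,
        "validation_mse": report.validation_mse,
        "test_mse": test_mse,
        "svd_floor": svd_reconstruction_floor(x_train, x_test, d),
        "n_train": n_train,
        "n_test": n_test,
        "D": ds.fields.shape[1],
        "code_dim": d,
        "model": model,
        "report": report,
    }


def regressor_benchmark(
    seed: int,
    n_train: int = 200,
    n_test: int = 200,
    spec=REGRESSOR_SCALED_SPEC,
) -> dict:
    """Train the scaled index→code regressor on affine codes; held-out MSE."""
    cfg_train, cfg_test, codes_train, codes_test, _ = linear_codes_data(
        seed, n_train=n_train, n_test=n_test
    )
    z_train = normalize_indices(cfg_train)
    z_test = normalize_indices(cfg_test)

    spec = spec.__class__(**{**spec.__dict__, "seed": seed})
    model, report = train_surrogate(z_train, codes_train, spec, val_fraction=0.30)
    test_mse = mse(codes_test, model.predict_codes(z_test))
    return {
        "train_mse": report.train_mse,
        "validation_mse": report.validation_mse,
        "test_mse": test_mse,
        "ols_floor": ols_floor(z_train, codes_train, z_test, codes_test),
        "n_train": n_train,
        "n_test": n_test,
        "S": cfg_train.shape[1],
        "code_dim": codes_train.shape[1],
        "model": model,
        "report": report,
    }
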