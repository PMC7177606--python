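"""Feed-forward networks of the surrogate: autoencoder and index→code regressor.

Both networks are plain fully-connected multilayer perceptrons with rectified
linear (ReLU) hidden units and linear input/output activations, trained by
backpropagation with the Adam optimizer under a mean-squared-error loss.
The autoencoder compresses a D-dimensional SAR vector through a bottleneck of
width d ≪ D (encoder) and reconstructs it (decoder); the regressor maps the
normalized vector of discrete electrode-position indices to the d-dimensional
bottleneck code.

Everything here is deterministic given the spec's seed: weight initialisation
(He-uniform), minibatch shuffling, and the single-threaded NumPy arithmetic.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "relu",
    "linear_activation",
    "mse",
    "MinMaxNormalizer",
    "NetworkSpec",
    "TrainingReport",
    "MLP",
    "split_train_val",
    "AutoencoderModel",
    "SurrogateRegressor",
    "train_autoencoder",
    "train_surrogate",
    "save_checkpoint",
    "load_checkpoint",
]


def relu(a):
    """Rectified linear unit: 0 for a < 0, a for a >= 0 (elementwise)."""
    return np.maximum(np.asarray(a), 0)


def linear_activation(a):
    """Identity activation used on the input and output layers."""
    return np.asarray(a)


def mse(observed, forecast) -> float:
    """Mean squared error over all entries of equally-shaped arrays."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(forecast, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("mse of empty arrays is undefined")
    d = y - yhat
    return float(np.mean(d * d))


class MinMaxNormalizer:
    """Min–max scaling onto [0, 1] with exact inversion.

    ``mode='global'`` uses one (min, max) over every entry — appropriate for
    SAR matrices whose columns share physical units.  ``mode='per_column'``
    scales each column independently — used for the index inputs.  Constant
    columns map to 0; their constant is recorded so inversion is exact.
    """

    def __init__(self, mode: str = "per_column"):
        if mode not in ("per_column", "global"):
            raise ValueError(f"unknown normalization mode {mode!r}")
        self.mode = mode
        self.data_min_: np.ndarray | None = None
        self.data_range_: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.data_min_ is not None

    def fit(self, X: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("fit requires a 2-D matrix with at least 2 rows")
        if self.mode == "global":
            mn = np.array([X.min()])
            mx = np.array([X.max()])
        else:
            mn = X.min(axis=0)
            mx = X.max(axis=0)
        self.data_min_ = mn
        self.data_range_ = mx - mn
        return self

    def _check(self):
        if not self.fitted:
            raise RuntimeError("normalizer has not been fitted")

    def transform(self, X: np.ndarray) -> np.ndarray:
        self._check()
        X = np.asarray(X, dtype=float)
        rng = np.where(self.data_range_ > 0, self.data_range_, 1.0)
        out = (X - self.data_min_) / rng
        if self.mode == "per_column":
            out = np.where(self.data_range_ > 0, out, 0.0)
        elif self.data_range_[0] == 0:
            out = np.zeros_like(out)
        return out

    def inverse_transform(self, Xn: np.ndarray) -> np.ndarray:
        self._check()
        Xn = np.asarray(Xn, dtype=float)
        return Xn * self.data_range_ + self.data_min_

    def state_dict(self) -> dict:
        self._check()
        return {
            "mode": self.mode,
            "data_min": self.data_min_.tolist(),
            "data_range": self.data_range_.tolist(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "MinMaxNormalizer":
        obj = cls(mode=state["mode"])
        obj.data_min_ = np.asarray(state["data_min"], dtype=float)
        obj.data_range_ = np.asarray(state["data_range"], dtype=float)
        return obj


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training hyperparameters of one MLP.

    ``hidden_widths`` excludes the input and output layers (their widths come
    from the data).  Hidden layers use ReLU; input and output are linear.
    ``lr_schedule`` is ``'constant'`` or ``'cosine'`` (cosine anneal to
    ``lr_final_fraction`` of the base rate over the run).
    """

    hidden_widths: tuple[int, ...]
    epochs: int
    batch_size: int
    learning_rate: float = 1e-3
    lr_schedule: str = "hold_cosine"
    lr_hold_fraction: float = 0.75
    lr_final_fraction: float = 0.001
    adam_beta2: float = 0.99
    adam_eps: float = 1e-10
    init: str = "lsuv"
    activation_margin: float = 4.0
    seed: int = 0
    dtype: str = "float64"
    bias_init: float = 0.1

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("layer widths must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lr_schedule not in ("constant", "cosine", "hold_cosine"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.init not in ("lsuv", "he"):
            raise ValueError(f"unknown init {self.init!r}")


#: shipped full-scale specs: autoencoder batch 25 / 8000 epochs with hidden
#: layers 3000,3000,3000,100,3000,3000,3000; regressor batch 50 / 6000 epochs
#: with hidden layers 500,500,100 and a d-wide linear output.
AUTOENCODER_SPEC = NetworkSpec(
    hidden_widths=(3000, 3000, 3000, 100, 3000, 3000, 3000),
    epochs=8000,
    batch_size=25,
)
REGRESSOR_SPEC = NetworkSpec(
    hidden_widths=(500, 500, 100),
    epochs=6000,
    batch_size=50,
)


@dataclass
class TrainingReport:
    """Final Eq-style MSEs plus the per-epoch loss trace."""

    train_mse: float
    validation_mse: float
    test_mse: float | None = None
    loss_history: list = field(default_factory=list)  # (epoch train mse, val mse)

    def as_dict(self) -> dict:
        return {
            "train_mse": self.train_mse,
            "validation_mse": self.validation_mse,
            "test_mse": self.test_mse,
        }


def split_train_val(n: int, val_fraction: float, seed) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled disjoint exhaustive split; validation size round(f·n), >= 1."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, round(val_fraction * n))
    if n_val >= n:
        n_val = n - 1
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


class MLP:
    """Fully-connected net: linear input, ReLU hidden layers, linear output.

    Each weight tensor carries a fixed scalar ``scale`` and the effective
    weights are ``scale * W``.  Keeping every stored tensor at unit RMS makes
    Adam's scale-free steps proportionate for every layer regardless of how
    the initialisation conditioned the effective weights (a muP-style
    reparameterisation).
    """

    def __init__(self, widths: list[int], seed: int = 0, dtype=np.float64, bias_init: float = 0.1):
        if len(widths) < 2:
            raise ValueError("need at least input and output widths")
        self.widths = [int(w) for w in widths]
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        n_layers = len(widths) - 1
        for i, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
            # He-uniform weights; small positive hidden biases keep the ReLU
            # units initially active (guards against dead bottleneck units,
            # which silently cap the effective code dimension)
            limit = math.sqrt(6.0 / fan_in)
            self.W.append(
                rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(self.dtype)
            )
            b0 = bias_init if i < n_layers - 1 else 0.0
            self.b.append(np.full(fan_out, b0, dtype=self.dtype))
        self.scale: list[float] = [1.0] * n_layers

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def effective_weights(self, i: int) -> np.ndarray:
        return self.scale[i] * self.W[i]

    def forward(self, X: np.ndarray, upto: int | None = None, start: int = 0) -> np.ndarray:
        """Propagate rows of X through layers [start, upto); ReLU on all but
        the final network layer."""
        upto = self.n_layers if upto is None else upto
        A = np.asarray(X, dtype=self.dtype)
        for i in range(start, upto):
            A = A @ (self.scale[i] * self.W[i]) + self.b[i]
            if i < self.n_layers - 1:
                A = relu(A)
        return A

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def _forward_cached(self, X):
        acts = [np.asarray(X, dtype=self.dtype)]
        pre = []
        A = acts[0]
        for i in range(self.n_layers):
            Z = A @ (self.scale[i] * self.W[i]) + self.b[i]
            pre.append(Z)
            A = relu(Z) if i < self.n_layers - 1 else Z
            acts.append(A)
        return acts, pre

    def _backward(self, acts, pre, Y):
        """Gradients of mean-over-all-entries squared error (wrt stored W)."""
        B, K = Y.shape
        delta = 2.0 * (acts[-1] - Y) / (B * K)
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        for i in range(self.n_layers - 1, -1, -1):
            gW[i] = self.scale[i] * (acts[i].T @ delta)
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ (self.scale[i] * self.W[i]).T) * (pre[i - 1] > 0)
        return gW, gb


def lsuv_init(model: MLP, X: np.ndarray, Y: np.ndarray, margin: float) -> None:
    """Data-dependent layer-sequential initialisation.

    Walks the training data through the net once.  Every hidden unit's
    preactivation is normalised to unit variance and centred at ``margin``
    standard deviations above zero, so the whole network starts well inside
    the active (locally linear) regime of every ReLU — the regime in which a
    deep network can represent the optimal linear reconstruction and from
    which gradient descent need not kill units to fit the data.  The output
    layer is scaled so its initial fluctuation matches the target's standard
    deviation and its bias starts at the target mean.  Tensors are then
    rescaled to unit RMS with the factor moved into ``model.scale``.
    """
    A = np.asarray(X, dtype=model.dtype)
    Y = np.asarray(Y, dtype=model.dtype)
    L = model.n_layers
    for i in range(L):
        Z = A @ model.W[i]
        if i < L - 1:
            s = Z.std(axis=0)
            s[s < 1e-12] = 1.0
            model.W[i] /= s
            Z = Z / s
            model.b[i][:] = margin - Z.mean(axis=0)
            A = relu(Z + model.b[i])
        else:
            z_std = float(Z.std())
            y_std = float(Y.std(axis=0).mean())
            if z_std > 0 and y_std > 0:
                model.W[i] *= y_std / z_std
                Z = Z * (y_std / z_std)
            model.b[i][:] = Y.mean(axis=0) - Z.mean(axis=0)
        rms = float(np.sqrt(np.mean(model.W[i] ** 2)))
        if rms > 0:
            model.W[i] /= rms
            model.scale[i] = rms


try:  # fused single-pass update; the pure-NumPy fallback is ~3x slower
    import numba

    @numba.njit(cache=True)
    def _adam_kernel(p, g, m, v, a, b1, b2, eps2):
        # p -= lr*(m/b1t)/(sqrt(v/b2t)+eps) rewritten with one sqrt + one
        # divide per element: a = lr*sqrt(b2t)/b1t, eps2 = eps*sqrt(b2t)
        for i in range(p.size):
            gi = g[i]
            mi = b1 * m[i] + (1 - b1) * gi
            vi = b2 * v[i] + (1 - b2) * gi * gi
            m[i] = mi
            v[i] = vi
            p[i] -= a * mi / (np.sqrt(vi) + eps2)

    def _adam_apply(p, g, m, v, lr, b1, b2, b1t, b2t, eps):
        sb2t = np.sqrt(b2t)
        _adam_kernel(p.reshape(-1), np.ascontiguousarray(g).reshape(-1),
                     m.reshape(-1), v.reshape(-1),
                     lr * sb2t / b1t, b1, b2, eps * sb2t)

except ImportError:  # pragma: no cover

    def _adam_apply(p, g, m, v, lr, b1, b2, b1t, b2t, eps):
        m *= b1
        m += (1 - b1) * g
        v *= b2
        v += (1 - b2) * (g * g)
        p -= lr * (m / b1t) / (np.sqrt(v / b2t) + eps)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            _adam_apply(p, g, m, v, lr, self.beta1, self.beta2, b1t, b2t, self.eps)


def _epoch_lr(spec: NetworkSpec, epoch: int) -> float:
    if spec.lr_schedule == "constant":
        return spec.learning_rate
    frac = spec.lr_final_fraction
    if spec.lr_schedule == "hold_cosine":
        hold = spec.lr_hold_fraction * spec.epochs
        if epoch < hold:
            return spec.learning_rate
        u = (epoch - hold) / max(1.0, (spec.epochs - hold) - 1)
    else:
        u = epoch / max(1, spec.epochs - 1)
    cos = 0.5 * (1 + math.cos(math.pi * u))
    return spec.learning_rate * (frac + (1 - frac) * cos)


def train_mlp(
    X: np.ndarray,
    Y: np.ndarray,
    spec: NetworkSpec,
    *,
    input_dim: int | None = None,
    output_dim: int | None = None,
    val_fraction: float = 0.3,
) -> tuple[MLP, TrainingReport]:
    """Train an MLP mapping X→Y by minibatch Adam under the MSE loss.

    The validation split is held out for reporting only — there is no early
    stopping; training runs for the full epoch budget.  Loss finiteness is
    checked every epoch so divergence fails loudly.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have matching sample counts")
    n = X.shape[0]
    widths = [input_dim or X.shape[1], *spec.hidden_widths, output_dim or Y.shape[1]]
    if spec.batch_size > n:
        raise ValueError(f"batch_size {spec.batch_size} exceeds sample count {n}")
    train_ids, val_ids = split_train_val(n, val_fraction, spec.seed)
    dt = np.dtype(spec.dtype)
    Xtr, Ytr = X[train_ids].astype(dt), Y[train_ids].astype(dt)
    Xva, Yva = X[val_ids].astype(dt), Y[val_ids].astype(dt)

    model = MLP(widths, seed=spec.seed, dtype=dt, bias_init=spec.bias_init)
    if spec.init == "lsuv":
        lsuv_init(model, Xtr, Ytr, spec.activation_margin)
    params = model.W + model.b
    opt = _Adam(params, spec.learning_rate, beta2=spec.adam_beta2, eps=spec.adam_eps)
    rng = np.random.default_rng(spec.seed + 1)
    ntr = Xtr.shape[0]
    history = []
    for epoch in range(spec.epochs):
        lr = _epoch_lr(spec, epoch)
        perm = rng.permutation(ntr)
        batch_losses = []
        for s in range(0, ntr, spec.batch_size):
            ids = perm[s : s + spec.batch_size]
            acts, pre = model._forward_cached(Xtr[ids])
            batch_losses.append(mse(Ytr[ids], acts[-1]))
            gW, gb = model._backward(acts, pre, Ytr[ids])
            opt.step(params, gW + gb, lr=lr)
        train_loss = float(np.mean(batch_losses))
        if not math.isfinite(train_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={train_loss}"
            )
        val_loss = mse(Yva, model.predict(Xva))
        history.append((train_loss, val_loss))

    report = TrainingReport(
        train_mse=mse(Ytr, model.predict(Xtr)),
        validation_mse=mse(Yva, model.predict(Xva)),
        loss_history=history,
    )
    return model, report


@dataclass
class AutoencoderModel:
    """Encoder/decoder pair sharing one MLP; the bottleneck is the code layer.

    ``code_layer`` is the index into the MLP's layer list after which the
    activations are the d-dimensional code (ReLU-rectified, like every hidden
    layer).  ``normalizer`` is the min–max state the training data were scaled
    with; predictions can be mapped back to W/kg through it.
    """

    mlp: MLP
    code_layer: int
    normalizer: MinMaxNormalizer | None = None

    @property
    def input_dim(self) -> int:
        return self.mlp.widths[0]

    @property
    def code_dim(self) -> int:
        return self.mlp.widths[self.code_layer]

    def encode(self, fields: np.ndarray) -> np.ndarray:
        fields = np.atleast_2d(fields)
        if fields.shape[1] != self.input_dim:
            raise ValueError(
                f"expected fields of dimension {self.input_dim}, got {fields.shape[1]}"
            )
        return self.mlp.forward(fields, upto=self.code_layer)

    def decode(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(codes)
        if codes.shape[1] != self.code_dim:
            raise ValueError(
                f"expected codes of dimension {self.code_dim}, got {codes.shape[1]}"
            )
        return self.mlp.forward(codes, start=self.code_layer)

    def reconstruct(self, fields: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(fields))


def train_autoencoder(
    data: np.ndarray, spec: NetworkSpec, val_fraction: float = 0.3
) -> tuple[AutoencoderModel, TrainingReport]:
    """Train the autoencoder on an N×D matrix of normalized SAR vectors.

    The hidden stack must be symmetric about the bottleneck (odd length), and
    the bottleneck strictly narrower than D.
    """
    data = np.asarray(data, dtype=float)
    h = spec.hidden_widths
    if len(h) % 2 == 0 or h != tuple(reversed(h)):
        raise ValueError("autoencoder hidden widths must be symmetric about the bottleneck")
    code_pos = len(h) // 2
    d = h[code_pos]
    D = data.shape[1]
    if d >= D:
        raise ValueError(f"bottleneck width {d} must be smaller than input dimension {D}")
    mlp, report = train_mlp(data, data, spec, val_fraction=val_fraction)
    return AutoencoderModel(mlp=mlp, code_layer=code_pos + 1), report


@dataclass
class SurrogateRegressor:
    """MLP mapping the normalized index vector to the bottleneck code."""

    mlp: MLP
    normalizer: MinMaxNormalizer | None = None

    @property
    def input_dim(self) -> int:
        return self.mlp.widths[0]

    @property
    def output_dim(self) -> int:
        return self.mlp.widths[-1]

    def predict_codes(self, inputs: np.ndarray) -> np.ndarray:
        inputs = np.atleast_2d(inputs)
        if inputs.shape[1] != self.input_dim:
            raise ValueError(
                f"expected inputs of dimension {self.input_dim}, got {inputs.shape[1]}"
            )
        return self.mlp.forward(inputs)


def train_surrogate(
    inputs: np.ndarray,
    codes: np.ndarray,
    spec: NetworkSpec,
    val_fraction: float = 0.3,
) -> tuple[SurrogateRegressor, TrainingReport]:
    """Train the index→code regressor on M×S inputs and M×d codes."""
    inputs = np.asarray(inputs, dtype=float)
    codes = np.asarray(codes, dtype=float)
    if inputs.shape[0] != codes.shape[0]:
        raise ValueError(
            f"inputs have {inputs.shape[0]} rows but codes have {codes.shape[0]}"
        )
    mlp, report = train_mlp(
        inputs, codes, spec, output_dim=codes.shape[1], val_fraction=val_fraction
    )
    return SurrogateRegressor(mlp=mlp), report


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model, spec: NetworkSpec, path) -> None:
    """Weights in an ``.npz`` container, spec + normalizer in a JSON sidecar."""
    path = Path(path)
    mlp = model.mlp
    arrays = {"scale": np.asarray(mlp.scale)}
    for i, (W, b) in enumerate(zip(mlp.W, mlp.b)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)
    meta = {
        "widths": mlp.widths,
        "spec": dataclasses.asdict(spec),
        "kind": type(model).__name__,
    }
    if isinstance(model, AutoencoderModel):
        meta["code_layer"] = model.code_layer
    if getattr(model, "normalizer", None) is not None and model.normalizer.fitted:
        meta["normalizer"] = model.normalizer.state_dict()
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path):
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = NetworkSpec(
        **{**meta["spec"], "hidden_widths": tuple(meta["spec"]["hidden_widths"])}
    )
    mlp = MLP(meta["widths"], seed=spec.seed, dtype=np.dtype(spec.dtype))
    with np.load(path) as z:
        for i in range(mlp.n_layers):
            mlp.W[i] = z[f"W{i}"]
            mlp.b[i] = z[f"b{i}"]
        if "scale" in z:
            mlp.scale = [float(s) for s in z["scale"]]
    norm = MinMaxNormalizer.from_state(meta["normalizer"]) if "normalizer" in meta else None
    if meta["kind"] == "AutoencoderModel":
        model = AutoencoderModel(mlp=mlp, code_layer=meta["code_layer"], normalizer=norm)
    else:
        model = SurrogateRegressor(mlp=mlp, normalizer=norm)
    return model, spec
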