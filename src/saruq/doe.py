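"""Electrode geometry and the discrete design of experiments (DoE).

EEG electrodes sit on a spherical scalp at positions ``(r, θ_p, φ_p)``.
Positional uncertainty is modelled by moving each electrode centre inside a
square of half-width Δ in the (θ, φ) plane, discretised to the 3×3 grid of
offsets ``{−Δ, 0, +Δ}²``.  Each corner/edge/centre of that grid carries an
index 1–9, so a full cap configuration is a length-L vector of indices and
the design space has exactly ``9**L`` members.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OFFSET_SIGNS",
    "ElectrodeLayout",
    "Configuration",
    "index_to_offset",
    "apply_configuration",
    "spherical_to_cartesian",
    "cartesian_to_spherical",
    "sample_configurations",
    "count_configurations",
    "fibonacci_cap_layout",
    "default_layout",
    "save_layout",
    "load_layout",
    "save_configurations",
    "load_configurations",
]

#: index -> (sign of θ offset, sign of φ offset); the index 9 is the
#: unperturbed position.  One-based on purpose, matching the field convention.
OFFSET_SIGNS: dict[int, tuple[int, int]] = {
    1: (-1, -1),
    2: (-1, 0),
    3: (-1, +1),
    4: (0, +1),
    5: (+1, +1),
    6: (+1, 0),
    7: (+1, -1),
    8: (0, -1),
    9: (0, 0),
}


def index_to_offset(index: int, delta: float) -> tuple[float, float]:
    """Map a position index 1–9 to its ``(dθ, dφ)`` offset in radians.

    Parameters
    ----------
    index : int
        Discrete position index in ``{1, …, 9}``.
    delta : float
        Angular half-width Δ of the perturbation square (rad), > 0.
    """
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    idx = int(index)
    if idx != index or idx not in OFFSET_SIGNS:
        raise ValueError(f"position index must be an integer in 1..9, got {index!r}")
    st, sp = OFFSET_SIGNS[idx]
    return (st * delta, sp * delta)


@dataclass(frozen=True)
class ElectrodeLayout:
    """L electrodes on a sphere of radius ``radius_mm``.

    ``theta`` is the polar angle from the +z axis in ``[0, π]``; ``phi`` is the
    azimuth, stored wrapped into ``[0, 2π)``.  ``delta`` is the DoE angular
    step Δ (rad).  ``cap_diameter_mm`` is carried as metadata only.
    """

    radius_mm: float
    ids: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    delta: float
    cap_diameter_mm: float = 13.0

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=int)
        theta = np.asarray(self.theta, dtype=float)
        phi = np.mod(np.asarray(self.phi, dtype=float), 2 * np.pi)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "phi", phi)
        if ids.ndim != 1 or ids.size < 1:
            raise ValueError("layout needs at least one electrode")
        if not (theta.shape == phi.shape == ids.shape):
            raise ValueError("ids, theta, phi must have equal length")
        if np.unique(ids).size != ids.size:
            raise ValueError("electrode ids must be unique")
        if np.any(theta < 0) or np.any(theta > np.pi):
            raise ValueError("polar angles must lie in [0, pi]")
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be positive")

    @property
    def L(self) -> int:
        return int(self.ids.size)

    def cartesian(self) -> np.ndarray:
        """(L, 3) Cartesian coordinates of the electrode centres (mm)."""
        return np.stack(
            spherical_to_cartesian(self.radius_mm, self.theta, self.phi), axis=-1
        )


@dataclass(frozen=True)
class Configuration:
    """A length-L vector of discrete position indices, each in 1–9."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("configuration must be a non-empty 1-D index vector")
        if np.any(idx < 1) or np.any(idx > 9):
            raise ValueError("configuration indices must lie in 1..9")

    @property
    def L(self) -> int:
        return int(self.indices.size)

    @classmethod
    def baseline(cls, L: int) -> "Configuration":
        """The all-9 configuration: every electrode at its nominal position."""
        return cls(np.full(L, 9))


def apply_configuration(layout: ElectrodeLayout, config: Configuration) -> ElectrodeLayout:
    """Return a new layout with every electrode moved per its index.

    φ offsets wrap modulo 2π.  A θ offset that would leave ``[0, π]`` is an
    error rather than a clamp: clamping would merge two of the nine discrete
    positions and silently break the DoE.
    """
    if config.L != layout.L:
        raise ValueError(
            f"configuration length {config.L} does not match layout L={layout.L}"
        )
    signs = np.array([OFFSET_SIGNS[int(i)] for i in config.indices], dtype=float)
    theta = layout.theta + signs[:, 0] * layout.delta
    phi = np.mod(layout.phi + signs[:, 1] * layout.delta, 2 * np.pi)
    bad = np.where((theta < 0) | (theta > np.pi))[0]
    if bad.size:
        eid = int(layout.ids[bad[0]])
        raise ValueError(
            f"electrode id {eid}: perturbed polar angle {theta[bad[0]]:.4f} rad "
            f"falls outside [0, pi]; keep electrodes at least delta from the poles"
        )
    return dataclasses.replace(layout, theta=theta, phi=phi)


def spherical_to_cartesian(r, theta, phi):
    """Physics convention (θ from +z): x = r sinθ cosφ, y = r sinθ sinφ, z = r cosθ."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be non-negative")
    if np.any(theta < 0) or np.any(theta > np.pi):
        raise ValueError("polar angle must lie in [0, pi]")
    st = np.sin(theta)
    return (r * st * np.cos(phi), r * st * np.sin(phi), r * np.cos(theta))


def cartesian_to_spherical(x, y, z):
    """Inverse of :func:`spherical_to_cartesian`; φ returned in [0, 2π)."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    r = np.sqrt(x * x + y * y + z * z)
    theta = np.where(r > 0, np.arccos(np.clip(np.divide(z, np.where(r > 0, r, 1.0)), -1, 1)), 0.0)
    phi = np.mod(np.arctan2(y, x), 2 * np.pi)
    return (r, theta, phi)


def sample_configurations(L: int, n: int, seed) -> np.ndarray:
    """Draw ``n`` independent configurations as an ``(n, L)`` int array.

    Every electrode index is i.i.d. uniform on {1, …, 9} — the electrodes move
    independently of one another.  ``seed`` may be an int or a Generator.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if n < 0:
        raise ValueError(f"number of configurations must be non-negative, got {n}")
    rng = np.random.default_rng(seed)
    return rng.integers(1, 10, size=(int(n), int(L)))


def count_configurations(L: int) -> int:
    """Size of the design space: exactly ``9**L`` (arbitrary precision)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return 9 ** int(L)


def enumerate_configurations(L: int) -> np.ndarray:
    """All 9**L configurations as a (9**L, L) array; small L only."""
    grids = np.meshgrid(*([np.arange(1, 10)] * L), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=-1)


def fibonacci_cap_layout(
    L: int,
    radius_mm: float,
    delta: float,
    theta_max: float = math.pi / 2,
    cap_diameter_mm: float = 13.0,
) -> ElectrodeLayout:
    """Quasi-uniform deterministic electrode layout on a spherical cap.

    A Fibonacci lattice in ``cos θ`` over ``[cos θ_max, cos θ_min]`` with the
    golden-angle azimuth spiral.  The top of the cap is kept ``2Δ`` below the
    pole so every perturbed position stays inside ``[0, π]``.
    """
    golden = (1 + math.sqrt(5)) / 2
    theta_min = 2 * delta  # keep θ − Δ safely off the pole
    if theta_min >= theta_max:
        raise ValueError("delta too large for the requested cap")
    k = np.arange(L, dtype=float)
    u = (k + 0.5) / L
    cos_t = math.cos(theta_min) + u * (math.cos(theta_max) - math.cos(theta_min))
    theta = np.arccos(np.clip(cos_t, -1, 1))
    phi = np.mod(2 * np.pi * k / golden, 2 * np.pi)
    return ElectrodeLayout(
        radius_mm=radius_mm,
        ids=np.arange(1, L + 1),
        theta=theta,
        phi=phi,
        delta=delta,
        cap_diameter_mm=cap_diameter_mm,
    )


#: default DoE step Δ: 2 degrees — comfortably larger than the surface-mesh
#: edge of a 13 mm cap on a 74.7 mm scalp, so every index is a distinct move.
DEFAULT_DELTA = math.radians(2.0)


def default_layout(L: int = 64, radius_mm: float = 74.7, delta: float = DEFAULT_DELTA) -> ElectrodeLayout:
    """The shipped 64-electrode cap on the scalp sphere (upper hemisphere)."""
    return fibonacci_cap_layout(L=L, radius_mm=radius_mm, delta=delta)


# ---------------------------------------------------------------------------
# plain-text I/O

def save_layout(layout: ElectrodeLayout, csv_path) -> None:
    """CSV columns id,theta_rad,phi_rad; radius/Δ in a JSON sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"id": layout.ids, "theta_rad": layout.theta, "phi_rad": layout.phi}
    ).to_csv(csv_path, index=False)
    meta = {
        "radius_mm": layout.radius_mm,
        "delta_rad": layout.delta,
        "cap_diameter_mm": layout.cap_diameter_mm,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_layout(csv_path) -> ElectrodeLayout:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return ElectrodeLayout(
        radius_mm=meta["radius_mm"],
        ids=df["id"].to_numpy(),
        theta=df["theta_rad"].to_numpy(),
        phi=df["phi_rad"].to_numpy(),
        delta=meta["delta_rad"],
        cap_diameter_mm=meta.get("cap_diameter_mm", 13.0),
    )


def save_configurations(configs: np.ndarray, path) -> None:
    """One configuration per row, L integer columns named e1..eL."""
    configs = np.atleast_2d(np.asarray(configs, dtype=int))
    cols = [f"e{i+1}" for i in range(configs.shape[1])]
    pd.DataFrame(configs, columns=cols).to_csv(path, index=False)


def load_configurations(path) -> np.ndarray:
    arr = pd.read_csv(path).to_numpy(dtype=int)
    if np.any(arr < 1) or np.any(arr > 9):
        raise ValueError(f"{path}: configuration indices must lie in 1..9")
    return arr
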