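"""Atomic-system data model, reaction coordinate, and umbrella-window scheduling.

The central geometric object is the distance-difference reaction coordinate

    xi = |R_A - R_P| - |R_P - R_B|

for a bond-breaking/bond-forming triple (A, P, B): in the phosphoryl-transfer
systems this tool targets, A is the leaving-group oxygen (O5'), P the
phosphorus, and B the nucleophile oxygen (O2').  Umbrella windows restrain xi
with a harmonic bias at a ladder of centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

QM = "QM"
MM = "MM"

__all__ = [
    "QM",
    "MM",
    "AtomicConfiguration",
    "LabeledSample",
    "ReactionCoordinateSpec",
    "UmbrellaWindow",
    "WindowSchedule",
    "compute_xi",
    "make_window_schedule",
    "stride_select",
    "select_endstate_windows",
]

_GRID_TOL = 1e-9  # A; matching window centers on a decimal grid


@dataclass
class AtomicConfiguration:
    """Chemical species, Cartesian coordinates and QM/MM region per atom.

    Parameters
    ----------
    species : (n_atoms,) int array
        Atomic numbers (Z > 0).
    positions : (n_atoms, 3) float array
        Cartesian coordinates in Angstrom.
    region : (n_atoms,) array of {"QM", "MM"}
        Per-atom region label; at least one atom must be QM.
    """

    species: np.ndarray
    positions: np.ndarray
    region: np.ndarray

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.region = np.asarray(self.region, dtype=object)
        n = self.species.shape[0]
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match {n} atoms"
            )
        if self.region.shape != (n,):
            raise ValueError("region must have one label per atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.species <= 0):
            raise ValueError("species must be positive atomic numbers")
        bad = set(self.region.tolist()) - {QM, MM}
        if bad:
            raise ValueError(f"unknown region labels: {bad!r}")
        if not np.any(self.qm_mask):
            raise ValueError("configuration must contain at least one QM atom")

    @property
    def n_atoms(self) -> int:
        return int(self.species.shape[0])

    @property
    def qm_mask(self) -> np.ndarray:
        return self.region == QM

    def with_positions(self, positions: np.ndarray) -> "AtomicConfiguration":
        return AtomicConfiguration(self.species, np.asarray(positions, float), self.region)


@dataclass
class ReactionCoordinateSpec:
    """Indices of the (leaving-group, phosphorus, nucleophile) triple."""

    idx_O5: int
    idx_P: int
    idx_O2: int

    def __post_init__(self) -> None:
        idx = (self.idx_O5, self.idx_P, self.idx_O2)
        if len(set(idx)) != 3:
            raise ValueError("reaction-coordinate indices must be distinct")
        if any(i < 0 for i in idx):
            raise IndexError("reaction-coordinate indices must be non-negative")


@dataclass
class LabeledSample:
    """A configuration with base- and target-level energies/forces and its xi.

    Energies in eV, forces in eV/A.
    """

    config: AtomicConfiguration
    e_base: float
    e_target: float
    f_base: np.ndarray
    f_target: np.ndarray
    xi: float

    def __post_init__(self) -> None:
        self.f_base = np.asarray(self.f_base, dtype=np.float64)
        self.f_target = np.asarray(self.f_target, dtype=np.float64)
        n = self.config.n_atoms
        if self.f_base.shape != (n, 3) or self.f_target.shape != (n, 3):
            raise ValueError("force arrays must match the atom count")

    @property
    def e_delta(self) -> float:
        return self.e_target - self.e_base

    @property
    def f_delta(self) -> np.ndarray:
        return self.f_target - self.f_base


@dataclass
class UmbrellaWindow:
    """Harmonic umbrella window: bias = k/2 (xi - center)^2.

    ``center`` in Angstrom, ``force_constant`` in kcal mol^-1 A^-2.
    """

    center: float
    force_constant: float = 300.0

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")


@dataclass
class WindowSchedule:
    """An ordered, evenly spaced ladder of umbrella windows along xi."""

    windows: list[UmbrellaWindow]
    xi_min: float
    xi_max: float
    step: float

    def __post_init__(self) -> None:
        centers = self.centers
        if len(centers) > 1:
            diffs = np.diff(centers)
            if np.any(diffs <= 0):
                raise ValueError("window centers must be strictly increasing")
            if np.any(np.abs(diffs - diffs[0]) > _GRID_TOL):
                raise ValueError("window centers must be evenly spaced")

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows], dtype=np.float64)

    def __len__(self) -> int:
        return len(self.windows)

    def index_of(self, center: float) -> int:
        """Index of the window whose center matches ``center`` on the grid."""
        hits = np.nonzero(np.abs(self.centers - center) <= _GRID_TOL)[0]
        if hits.size == 0:
            raise LookupError(f"no window with center {center} on this schedule")
        return int(hits[0])


def compute_xi(config: AtomicConfiguration, spec: ReactionCoordinateSpec) -> float:
    """Distance-difference reaction coordinate |R_A - R_P| - |R_P - R_B| in A.

    Invariant under rigid rotations and translations of the configuration.
    """
    n = config.n_atoms
    for i in (spec.idx_O5, spec.idx_P, spec.idx_O2):
        if not (0 <= i < n):
            raise IndexError(f"atom index {i} out of range for {n} atoms")
    r = config.positions
    d1 = float(np.linalg.norm(r[spec.idx_O5] - r[spec.idx_P]))
    d2 = float(np.linalg.norm(r[spec.idx_P] - r[spec.idx_O2]))
    return d1 - d2


def compute_xi_positions(positions: np.ndarray, spec: ReactionCoordinateSpec) -> np.ndarray:
    """Vectorized xi over a (..., n_atoms, 3) position array."""
    r = np.asarray(positions, dtype=np.float64)
    d1 = np.linalg.norm(r[..., spec.idx_O5, :] - r[..., spec.idx_P, :], axis=-1)
    d2 = np.linalg.norm(r[..., spec.idx_P, :] - r[..., spec.idx_O2, :], axis=-1)
    return d1 - d2


def make_window_schedule(
    xi_min: float, xi_max: float, step: float, force_constant: float = 300.0
) -> WindowSchedule:
    """Evenly spaced windows from xi_min to xi_max inclusive.

    The count is round((xi_max - xi_min)/step) + 1, e.g. 64 windows for the
    standard ladder (-3.3, 3.0, 0.1).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if xi_max < xi_min:
        raise ValueError("xi_max must be >= xi_min")
    n = int(round((xi_max - xi_min) / step)) + 1
    centers = xi_min + step * np.arange(n)
    windows = [UmbrellaWindow(float(c), force_constant) for c in centers]
    return WindowSchedule(windows, xi_min, xi_max, step)


def stride_select(schedule: WindowSchedule, stride: int) -> WindowSchedule:
    """Keep windows at ordinal positions 0, stride, 2*stride, ...

    The stride is anchored at the most negative window center, so the S:n
    selections of the 64-window ladder end at 3.0, 2.9, 2.7 and 2.3 A for
    n = 1, 2, 4, 8.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    kept = schedule.windows[::stride]
    return WindowSchedule(
        list(kept),
        xi_min=kept[0].center,
        xi_max=kept[-1].center,
        step=schedule.step * stride,
    )


def select_endstate_windows(
    schedules: list[WindowSchedule], endpoints: list[float]
) -> list[tuple[int, UmbrellaWindow]]:
    """One (reaction index, window) entry per schedule x endpoint.

    Each endpoint must match an existing window center within 1e-9 A.
    With 6 reactions and endpoints {-2.0, 3.0} this yields the 12 end-state
    ensembles used for end-state training.
    """
    out: list[tuple[int, UmbrellaWindow]] = []
    for i, sched in enumerate(schedules):
        for xi0 in endpoints:
            out.append((i, sched.windows[sched.index_of(xi0)]))
    return out
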