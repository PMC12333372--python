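"""Synthetic surrogate for the base/target QM/MM engines.

A small "QM solute" - a triatomic O-P-O analog with hydrogen spectators -
undergoes a two-basin exchange reaction along the distance-difference
coordinate xi = |R_A - R_P| - |R_P - R_B|, surrounded by MM particles held
in a harmonic radial shell (a cluster boundary instead of periodic
electrostatics).  Two analytic potentials play the roles of the cheap base
level and the expensive target level:

* the base potential has a symmetric double well along xi (one barrier);
* the target potential adds an intermediate well near xi = 0 (so its
  profile has two barriers separated by a metastable intermediate, the toy
  analog of a pentacoordinate phosphorane), a small reactant/product tilt,
  and a modified short-range QM/MM pair term inside the 6 A cutoff.

The target-minus-base correction vanishes identically for MM atoms beyond
the cutoff of every QM atom, which is exactly the structure the
range-corrected ΔMLP is built to learn.  All energies are in eV, positions
in Angstrom, masses in amu; gradients are analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    AtomicConfiguration,
    LabeledSample,
    ReactionCoordinateSpec,
    UmbrellaWindow,
    compute_xi_positions,
)
from .delta_model import EnergyForces
from .units import FS, KCALMOL_TO_EV, kt_ev

__all__ = [
    "ToySystemSpec",
    "ToyPotentialSpec",
    "DynamicsSpec",
    "ToyPotential",
    "DeltaCorrectedPotential",
    "base_energy_forces",
    "target_energy_forces",
    "run_umbrella_window",
    "run_umbrella_windows",
    "nve_verlet",
    "label_positions",
    "generate_reference_dataset",
    "toy_reaction_variants",
    "toy_profile",
    "initial_positions",
]

_MASS = {1: 1.008, 8: 15.999, 15: 30.974}


@dataclass
class ToySystemSpec:
    """Composition and confinement of the toy cluster.

    The first three QM atoms are the reaction triple (A, P, B); additional
    QM atoms are spectators bonded to P.
    """

    qm_species: tuple = (8, 15, 8, 1, 1)
    n_mm: int = 12
    mm_species: int = 8
    confine_radius: float = 6.5  # A
    confine_k: float = 1.0  # eV/A^2

    def __post_init__(self) -> None:
        if len(self.qm_species) < 3:
            raise ValueError("need at least the three reaction-coordinate atoms")
        if self.n_mm < 0:
            raise ValueError("n_mm must be >= 0")

    @property
    def n_atoms(self) -> int:
        return len(self.qm_species) + self.n_mm

    @property
    def species(self) -> np.ndarray:
        return np.array(list(self.qm_species) + [self.mm_species] * self.n_mm)

    @property
    def region(self) -> np.ndarray:
        return np.array(["QM"] * len(self.qm_species) + ["MM"] * self.n_mm, dtype=object)

    @property
    def rc_spec(self) -> ReactionCoordinateSpec:
        return ReactionCoordinateSpec(0, 1, 2)

    @property
    def masses(self) -> np.ndarray:
        return np.array([_MASS.get(int(z), float(z) * 2.0) for z in self.species])


@dataclass
class ToyPotentialSpec:
    """Analytic parameters of the base and target toy potentials (eV, A)."""

    # base double well along xi: h_b ((xi/w)^2 - 1)^2
    well_sep: float = 1.4  # w: basins at xi = +-w
    barrier: float = 0.35  # h_b
    # bond-sum restraint 0.5 k_s (r1 + r2 - s0)^2 and P-A-B angle term
    bondsum_k: float = 3.0
    bondsum_s0: float = 4.0
    angle_k: float = 1.5
    # spectator bonds to P and nonbonded QM repulsion
    spect_r0: float = 1.4
    spect_k: float = 15.0
    qm_rep_a: float = 30.0
    qm_rep_rho: float = 0.3
    # MM-MM soft repulsion eps (sig/r)^9
    mm_eps: float = 0.005
    mm_sig: float = 3.0
    # QM/MM short-range pair term A (sig/r)^8 * envelope(r/r_cut)
    qmmm_a: float = 0.02
    qmmm_sig: float = 3.0
    r_cut: float = 6.0
    envelope_order: int = 5
    # target-only terms
    target_well_depth: float = 0.30  # intermediate well at xi = 0
    target_well_sigma: float = 0.40
    target_tilt: float = 0.03  # tilt * tanh(xi/w)
    target_qmmm_da: float = 0.060  # change of the QM/MM pair strength
    target_qmmm_ga: float = 0.040  # QM/MM gaussian well at r0_g
    target_qmmm_rg: float = 3.0
    target_angle_dk: float = 0.20  # stiffer A-P-B angle at the target level


@dataclass
class DynamicsSpec:
    """Langevin (BAOAB) dynamics settings."""

    temperature: float = 298.0  # K
    friction: float = 5.0  # ps^-1
    dt: float = 0.5  # fs
    n_equil_steps: int = 2000
    n_prod_steps: int = 4000
    samples_saved: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples_saved > self.n_prod_steps:
            raise ValueError("samples_saved must not exceed n_prod_steps")


def _envelope_and_deriv(r: np.ndarray, rc: float, p: int):
    u = r / rc
    c1 = 0.5 * (p + 1) * (p + 2)
    c2 = p * (p + 2)
    c3 = 0.5 * p * (p + 1)
    f = 1.0 - c1 * u**p + c2 * u ** (p + 1) - c3 * u ** (p + 2)
    df = (-c1 * p * u ** (p - 1) + c2 * (p + 1) * u**p - c3 * (p + 2) * u ** (p + 1)) / rc
    inside = u < 1.0
    return np.where(inside, f, 0.0), np.where(inside, df, 0.0)


class ToyPotential:
    """Analytic toy potential with exact gradients; base or target level."""

    def __init__(self, system: ToySystemSpec, params: ToyPotentialSpec, target: bool):
        self.system = system
        self.params = params
        self.target = target
        nq = len(system.qm_species)
        self._spect = list(range(3, nq))
        bonded = {(0, 1), (1, 2)} | {(1, s) for s in self._spect}
        self._qm_nonbonded = [
            (i, j)
            for i in range(nq)
            for j in range(i + 1, nq)
            if (i, j) not in bonded
        ]

    # -- scalar profile along xi ------------------------------------------

    def f_xi(self, xi: np.ndarray):
        """Internal xi-dependent energy and its derivative."""
        p = self.params
        x = np.asarray(xi, dtype=float)
        t = (x / p.well_sep) ** 2 - 1.0
        e = p.barrier * t * t
        de = p.barrier * 4.0 * t * x / p.well_sep**2
        if self.target:
            g = np.exp(-(x**2) / (2 * p.target_well_sigma**2))
            e = e - p.target_well_depth * g
            de = de + p.target_well_depth * g * x / p.target_well_sigma**2
            th = np.tanh(x / p.well_sep)
            e = e + p.target_tilt * th
            de = de + p.target_tilt * (1 - th**2) / p.well_sep
        return e, de

    def qmmm_pair(self, r: np.ndarray):
        """QM/MM short-range pair energy and d/dr; zero beyond r_cut."""
        p = self.params
        env, denv = _envelope_and_deriv(r, p.r_cut, p.envelope_order)
        a = p.qmmm_a + (p.target_qmmm_da if self.target else 0.0)
        core = a * (p.qmmm_sig / r) ** 8
        dcore = -8.0 * core / r
        e = core * env
        de = dcore * env + core * denv
        if self.target:
            g = p.target_qmmm_ga * np.exp(-((r - p.target_qmmm_rg) ** 2) / 0.5)
            dg = g * (-2.0 * (r - p.target_qmmm_rg) / 0.5)
            e = e - g * env
            de = de - (dg * env + g * denv)
        return e, de

    # -- full evaluation ---------------------------------------------------

    def energy_forces_batch(self, pos: np.ndarray):
        """Energies (B,) and forces (B, N, 3) for a batch of positions."""
        p = self.params
        sys = self.system
        pos = np.asarray(pos, dtype=float)
        squeeze = pos.ndim == 2
        if squeeze:
            pos = pos[None]
        B, N, _ = pos.shape
        E = np.zeros(B)
        F = np.zeros_like(pos)

        def pair(i, j, efunc):
            d = pos[:, i] - pos[:, j]
            r = np.linalg.norm(d, axis=1)
            e, de = efunc(r)
            E[:] += e
            g = (de / r)[:, None] * d
            F[:, i] -= g
            F[:, j] += g

        # reaction triple: xi profile + bond-sum restraint + angle
        a = pos[:, 0] - pos[:, 1]
        b = pos[:, 2] - pos[:, 1]
        r1 = np.linalg.norm(a, axis=1)
        r2 = np.linalg.norm(b, axis=1)
        u1 = a / r1[:, None]
        u2 = -b / r2[:, None]  # unit vector from B to P
        xi = r1 - r2
        e, de = self.f_xi(xi)
        E += e
        F[:, 0] -= de[:, None] * u1
        F[:, 1] -= de[:, None] * (-u1 - u2)
        F[:, 2] -= de[:, None] * u2
        s = r1 + r2
        E += 0.5 * p.bondsum_k * (s - p.bondsum_s0) ** 2
        ds = p.bondsum_k * (s - p.bondsum_s0)
        F[:, 0] -= ds[:, None] * u1
        F[:, 1] -= ds[:, None] * (-u1 + u2)
        F[:, 2] -= ds[:, None] * (-u2)
        ua = a / r1[:, None]
        ub = b / r2[:, None]
        cosv = np.sum(ua * ub, axis=1)
        ak = p.angle_k + (p.target_angle_dk if self.target else 0.0)
        E += ak * (1.0 + cosv)
        ga = (ub - cosv[:, None] * ua) / r1[:, None]
        gb = (ua - cosv[:, None] * ub) / r2[:, None]
        F[:, 0] -= ak * ga
        F[:, 2] -= ak * gb
        F[:, 1] += ak * (ga + gb)

        for sidx in self._spect:
            pair(
                sidx,
                1,
                lambda r: (
                    0.5 * p.spect_k * (r - p.spect_r0) ** 2,
                    p.spect_k * (r - p.spect_r0),
                ),
            )
        for i, j in self._qm_nonbonded:
            pair(
                i,
                j,
                lambda r: (
                    p.qm_rep_a * np.exp(-r / p.qm_rep_rho),
                    -p.qm_rep_a / p.qm_rep_rho * np.exp(-r / p.qm_rep_rho),
                ),
            )

        nq = len(sys.qm_species)
        mm = list(range(nq, N))
        for mi in range(len(mm)):
            for mj in range(mi + 1, len(mm)):
                pair(
                    mm[mi],
                    mm[mj],
                    lambda r: (
                        p.mm_eps * (p.mm_sig / r) ** 9,
                        -9.0 * p.mm_eps * (p.mm_sig / r) ** 9 / r,
                    ),
                )
        for qi in range(nq):
            for mj in mm:
                pair(qi, mj, self.qmmm_pair)

        # confinement of MM atoms in a shell around the P atom (keeps the
        # potential translation invariant: the restraint is internal)
        if mm:
            dm = pos[:, mm] - pos[:, 1:2]
            rm = np.linalg.norm(dm, axis=2)
            over = np.maximum(rm - sys.confine_radius, 0.0)
            E += 0.5 * sys.confine_k * np.sum(over**2, axis=1)
            g = (sys.confine_k * over / np.maximum(rm, 1e-12))[:, :, None] * dm
            F[:, mm] -= g
            F[:, 1] += g.sum(axis=1)

        if squeeze:
            return E[0], F[0]
        return E, F


def base_energy_forces(
    config: AtomicConfiguration, system: ToySystemSpec, params: ToyPotentialSpec
) -> EnergyForces:
    e, f = ToyPotential(system, params, target=False).energy_forces_batch(config.positions)
    return EnergyForces(float(e), f)


def target_energy_forces(
    config: AtomicConfiguration, system: ToySystemSpec, params: ToyPotentialSpec
) -> EnergyForces:
    e, f = ToyPotential(system, params, target=True).energy_forces_batch(config.positions)
    return EnergyForces(float(e), f)


class DeltaCorrectedPotential:
    """Base toy potential plus a ΔMLP correction model."""

    def __init__(self, base: ToyPotential, model):
        self.base = base
        self.model = model

    def energy_forces_batch(self, pos: np.ndarray):
        from .delta_model import batch_energy_forces

        squeeze = pos.ndim == 2
        p = pos[None] if squeeze else pos
        e0, f0 = self.base.energy_forces_batch(p)
        sys = self.base.system
        e1, f1 = batch_energy_forces(self.model, sys.species, sys.region, p)
        e, f = e0 + e1, f0 + f1
        if squeeze:
            return e[0], f[0]
        return e, f


# ------------------------------------------------------------ initial state


def initial_positions(
    system: ToySystemSpec, params: ToyPotentialSpec, xi0: float, seed: int
) -> np.ndarray:
    """Near-minimum start: triple on the z axis at the window's xi, spectators
    perpendicular, MM particles placed collision-free in the shell."""
    rng = np.random.default_rng(seed)
    r1 = 0.5 * (params.bondsum_s0 + xi0)
    r2 = 0.5 * (params.bondsum_s0 - xi0)
    pos = [np.array([0.0, 0.0, r1]), np.zeros(3), np.array([0.0, 0.0, -r2])]
    nspect = len(system.qm_species) - 3
    for k in range(nspect):
        ang = 2 * np.pi * k / max(nspect, 1)
        pos.append(params.spect_r0 * np.array([np.cos(ang), np.sin(ang), 0.0]))
    placed = []
    while len(placed) < system.n_mm:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        cand = v * rng.uniform(3.8, system.confine_radius)
        pts = np.array(pos + placed)
        if np.min(np.linalg.norm(pts - cand, axis=1)) > 2.2:
            placed.append(cand)
    return np.array(pos + placed)


# ----------------------------------------------------------------- dynamics


class SimulationError(RuntimeError):
    def __init__(self, msg: str, frame: np.ndarray | None = None):
        super().__init__(msg)
        self.frame = frame


def _baoab(
    potential,
    pos: np.ndarray,
    masses: np.ndarray,
    dyn: DynamicsSpec,
    rng: np.random.Generator,
    n_steps: int,
    bias_centers: np.ndarray | None,
    bias_k_ev: float,
    rc_spec: ReactionCoordinateSpec,
    save_every: int = 0,
):
    """Batched BAOAB Langevin integration; returns (pos, vel, saved frames)."""
    dt = dyn.dt * FS
    gamma = dyn.friction * 1e-3 / FS  # ps^-1 -> internal rate
    kT = kt_ev(dyn.temperature)
    m = masses[None, :, None]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    vel = rng.normal(size=pos.shape) * np.sqrt(kT / m)

    def total_force(x):
        e, f = potential.energy_forces_batch(x)
        if bias_centers is not None:
            xi = compute_xi_positions(x, rc_spec)
            dxi = xi - bias_centers
            e = e + 0.5 * bias_k_ev * dxi**2
            a = x[:, rc_spec.idx_O5] - x[:, rc_spec.idx_P]
            b = x[:, rc_spec.idx_P] - x[:, rc_spec.idx_O2]
            u1 = a / np.linalg.norm(a, axis=1, keepdims=True)
            u2 = b / np.linalg.norm(b, axis=1, keepdims=True)
            g = (bias_k_ev * dxi)[:, None]
            f = f.copy()
            f[:, rc_spec.idx_O5] -= g * u1
            f[:, rc_spec.idx_P] -= g * (-u1 - u2)
            f[:, rc_spec.idx_O2] -= g * u2
        return e, f

    e, f = total_force(pos)
    saved = []
    for step in range(n_steps):
        vel = vel + 0.5 * dt * f / m
        pos = pos + 0.5 * dt * vel
        vel = c1 * vel + c2 / np.sqrt(m) * rng.normal(size=pos.shape)
        pos = pos + 0.5 * dt * vel
        e, f = total_force(pos)
        if not np.all(np.isfinite(e)):
            raise SimulationError(f"non-finite energy at step {step}", frame=pos)
        vel = vel + 0.5 * dt * f / m
        if save_every and (step + 1) % save_every == 0:
            saved.append(pos.copy())
    return pos, vel, saved


def nve_verlet(
    potential,
    pos: np.ndarray,
    masses: np.ndarray,
    dt_fs: float,
    n_steps: int,
    temperature: float,
    seed: int,
) -> np.ndarray:
    """Microcanonical velocity-Verlet; returns the total-energy trace (eV).

    Velocities are drawn from the Maxwell-Boltzmann distribution at
    ``temperature`` once; afterwards the dynamics is strictly energy
    conserving up to integrator error, which is what the trace measures.
    """
    rng = np.random.default_rng(seed)
    dt = dt_fs * FS
    squeeze = pos.ndim == 2
    x = (pos[None] if squeeze else pos).copy()
    m = masses[None, :, None]
    kT = kt_ev(temperature)
    v = rng.normal(size=x.shape) * np.sqrt(kT / m)
    e_pot, f = potential.energy_forces_batch(x)
    energies = np.empty((n_steps + 1,) + e_pot.shape)
    energies[0] = e_pot + 0.5 * np.sum(m * v * v, axis=(1, 2))
    for step in range(n_steps):
        v = v + 0.5 * dt * f / m
        x = x + dt * v
        e_pot, f = potential.energy_forces_batch(x)
        v = v + 0.5 * dt * f / m
        energies[step + 1] = e_pot + 0.5 * np.sum(m * v * v, axis=(1, 2))
        if not np.all(np.isfinite(energies[step + 1])):
            raise SimulationError(f"non-finite energy at step {step}", frame=x)
    return energies[:, 0] if squeeze else energies


def run_umbrella_windows(
    potential,
    windows: list[UmbrellaWindow],
    system: ToySystemSpec,
    params: ToyPotentialSpec,
    dynamics: DynamicsSpec,
    seed: int,
) -> list[np.ndarray]:
    """Sample every window in one batched Langevin run.

    Returns, per window, an array of saved production positions with shape
    (samples_saved, n_atoms, 3).
    """
    rng = np.random.default_rng(seed)
    centers = np.array([w.center for w in windows])
    ks = {w.force_constant for w in windows}
    if len(ks) != 1:
        raise ValueError("windows must share a force constant for batched runs")
    k_ev = ks.pop() * KCALMOL_TO_EV
    pos = np.stack([initial_positions(system, params, c, seed) for c in centers])
    rc = system.rc_spec
    pos, vel, _ = _baoab(
        potential, pos, system.masses, dynamics, rng, dynamics.n_equil_steps,
        centers, k_ev, rc,
    )
    save_every = max(dynamics.n_prod_steps // dynamics.samples_saved, 1)
    _, _, saved = _baoab(
        potential, pos, system.masses, dynamics, rng, dynamics.n_prod_steps,
        centers, k_ev, rc, save_every=save_every,
    )
    frames = np.stack(saved[-dynamics.samples_saved :])  # (n_save, B, N, 3)
    return [frames[:, b] for b in range(len(windows))]


def run_umbrella_window(
    potential,
    window: UmbrellaWindow,
    system: ToySystemSpec,
    params: ToyPotentialSpec,
    dynamics: DynamicsSpec,
    seed: int,
) -> np.ndarray:
    """Positions sampled from a single umbrella window."""
    return run_umbrella_windows(potential, [window], system, params, dynamics, seed)[0]


def label_positions(
    positions: np.ndarray, system: ToySystemSpec, params: ToyPotentialSpec
) -> list[LabeledSample]:
    """Annotate sampled positions with base/target energies and forces."""
    base = ToyPotential(system, params, target=False)
    targ = ToyPotential(system, params, target=True)
    eb, fb = base.energy_forces_batch(positions)
    et, ft = targ.energy_forces_batch(positions)
    xi = compute_xi_positions(positions, system.rc_spec)
    out = []
    for i in range(positions.shape[0]):
        cfg = AtomicConfiguration(system.species, positions[i], system.region)
        out.append(
            LabeledSample(cfg, float(eb[i]), float(et[i]), fb[i], ft[i], float(xi[i]))
        )
    return out


def generate_reference_dataset(
    variants,
    windows: list[UmbrellaWindow],
    dynamics: DynamicsSpec,
    seed: int,
) -> dict:
    """Base-potential umbrella sampling of every variant, fully labeled.

    Returns {variant_name: [per-window list of LabeledSample]}.
    """
    out = {}
    for v, (name, system, params) in enumerate(variants):
        base = ToyPotential(system, params, target=False)
        per_window = run_umbrella_windows(
            base, windows, system, params, dynamics, seed + 104729 * v
        )
        out[name] = [label_positions(p, system, params) for p in per_window]
    return out


def toy_reaction_variants(n: int = 6) -> list:
    """The 6 toy "reactions": 2 nucleophile analogs x 3 leaving-group analogs.

    Variants differ in spectator species and in the strength of the
    short-range QM/MM pair term, emulating different solutes.
    """
    base_sys = ToySystemSpec()
    out = []
    specs = [
        ("mNuc-EtO", (8, 15, 8, 1, 1), 0.020, 0.300),
        ("mNuc-AcO", (8, 15, 8, 1, 8), 0.024, 0.280),
        ("mNuc-PhO", (8, 15, 8, 8, 1), 0.016, 0.320),
        ("Nuc-EtO", (8, 15, 8, 1), 0.022, 0.310),
        ("Nuc-AcO", (8, 15, 8, 8), 0.018, 0.290),
        ("Nuc-PhO", (8, 15, 8), 0.020, 0.330),
    ]
    for name, qm, qa, dwell in specs[:n]:
        system = replace(base_sys, qm_species=qm)
        params = ToyPotentialSpec(qmmm_a=qa, target_well_depth=dwell)
        out.append((name, system, params))
    return out


def toy_profile(params: ToyPotentialSpec, xi, target: bool) -> np.ndarray:
    """The internal xi profile of the isolated QM analog (eV).

    Up to an additive constant this is the analytic potential of mean force
    along xi of the solute with the orthogonal modes integrated out (they
    separate in the (r1 + r2, xi) coordinates).
    """
    pot = ToyPotential(ToySystemSpec(n_mm=0), params, target=target)
    e, _ = pot.f_xi(np.asarray(xi, dtype=float))
    return e
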