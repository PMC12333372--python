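"""Committee training and the "simplify" data-selection workflow.

The loss matches correction energies and forces jointly,

    L = p_e(t) (dE)^2 + p_f (1/3N) sum_i |dF_i|^2,

with the energy weight p_e rising exponentially from 1 to 100 eV^-2 over the
optimization while the force weight stays at 100 A^2 eV^-2, and an Adam
optimizer under an exponential learning-rate decay from 1e-3 to 1e-5.
Training is repeated with 4 random seeds to produce a committee whose force
disagreement drives data selection: a sample is discarded from the test pool
when the *maximum* per-member force RMSE falls below 0.08 eV/A.  The
simplify workflow trains on a random 50% of the database, filters the
remainder with the committee, and retrains on survivors capped at 25% of the
original database per round - which bounds it to 3 rounds of optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, grad, tsum
from .geometry import AtomicConfiguration, LabeledSample
from .delta_model import CorrectionModel, _sites_tensor, init_model
from .rc_graph import MM_SPECIES_OFFSET

__all__ = [
    "LossSchedule",
    "LRSchedule",
    "SimplifyConfig",
    "AugmentSpec",
    "Committee",
    "TrainingError",
    "loss",
    "lr_at",
    "train_model",
    "train_committee",
    "force_rmse_filter",
    "simplify_workflow",
    "augment_endstates",
    "fine_tune",
]


class TrainingError(RuntimeError):
    pass


@dataclass
class LossSchedule:
    """Energy/force loss weights; p_e rises exponentially, p_f is fixed."""

    p_e_start: float = 1.0  # eV^-2
    p_e_limit: float = 100.0  # eV^-2
    p_f: float = 100.0  # A^2 eV^-2

    def p_e_at(self, step_fraction: float) -> float:
        t = min(max(step_fraction, 0.0), 1.0)
        return self.p_e_start * (self.p_e_limit / self.p_e_start) ** t


@dataclass
class LRSchedule:
    """Exponential decay lr_start -> lr_stop over n_steps, clamped after."""

    lr_start: float = 1e-3
    lr_stop: float = 1e-5
    n_steps: int = 400_000


def lr_at(schedule: LRSchedule, step: int) -> float:
    if step < 0:
        raise ValueError("step must be >= 0")
    t = min(step, schedule.n_steps) / schedule.n_steps
    return schedule.lr_start * (schedule.lr_stop / schedule.lr_start) ** t


@dataclass
class SimplifyConfig:
    init_fraction: float = 0.5
    round_cap_fraction: float = 0.25
    force_rmse_threshold: float = 0.08  # eV/A
    committee_size: int = 4


@dataclass
class AugmentSpec:
    copies_per_ensemble: int = 50
    heavy_max_disp: float = 0.15  # A
    h_bond_range: tuple = (0.7, 1.2)  # A

    def __post_init__(self) -> None:
        lo, hi = self.h_bond_range
        if lo <= 0 or hi < lo or self.heavy_max_disp < 0:
            raise ValueError("augmentation ranges must be positive")


@dataclass
class Committee:
    models: list
    seeds: list

    def __len__(self) -> int:
        return len(self.models)


# ------------------------------------------------------------------- loss


def _group_samples(samples: list[LabeledSample]):
    """Group samples by shared (species, region) topology for batching."""
    groups: dict = {}
    for i, s in enumerate(samples):
        key = (tuple(s.config.species.tolist()), tuple(s.config.region.tolist()))
        groups.setdefault(key, []).append(i)
    return list(groups.values())


def _batch_loss_graph(model: CorrectionModel, samples: list[LabeledSample], p_e: float, p_f: float):
    """Traced loss for samples sharing one topology; returns (loss, E, F)."""
    cfg0 = samples[0].config
    n = cfg0.n_atoms
    for s in samples:
        if s.config.n_atoms != n:
            raise ValueError("mismatched atom counts within a batch")
    codes = cfg0.species.copy()
    qm = cfg0.qm_mask
    codes[~qm] += MM_SPECIES_OFFSET
    pos = np.stack([s.config.positions for s in samples])  # (B, N, 3)
    X = Tensor(np.transpose(pos, (1, 0, 2)).copy(), requires_grad=True)
    site = _sites_tensor(model, codes, qm, X)
    e_pred = tsum(site, axis=0)  # (B,)
    (gX,) = grad(tsum(e_pred), [X], create_graph=True)
    e_ref = Tensor(np.array([s.e_delta for s in samples]))
    f_ref = Tensor(np.transpose(np.stack([s.f_delta for s in samples]), (1, 0, 2)))
    de = e_pred - e_ref
    df = gX + f_ref  # gX = -F_pred, so residual F_pred - F_ref = -(gX + f_ref)
    per_e = tsum(de * de) * (p_e / len(samples))
    per_f = tsum(df * df) * (p_f / (3.0 * n * len(samples)))
    return per_e + per_f, per_e, per_f


def loss(model: CorrectionModel, batch: list[LabeledSample], step_fraction: float,
         schedule: LossSchedule | None = None) -> float:
    """Weighted energy+force correction loss of a batch at a schedule point."""
    if not batch:
        raise ValueError("batch must be nonempty")
    schedule = schedule or LossSchedule()
    p_e = schedule.p_e_at(step_fraction)
    total = 0.0
    weight = 0.0
    for idx in _group_samples(batch):
        sub = [batch[i] for i in idx]
        lval, _, _ = _batch_loss_graph(model, sub, p_e, schedule.p_f)
        total += lval.item() * len(sub)
        weight += len(sub)
    return total / weight


# ---------------------------------------------------------------- training


class _Adam:
    def __init__(self, params: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train_model(
    model: CorrectionModel,
    samples: list[LabeledSample],
    n_steps: int,
    lr_schedule: LRSchedule,
    loss_schedule: LossSchedule,
    seed: int,
    batch_size: int = 4,
) -> dict:
    """Adam-optimize a model in place; returns a JSON-able history."""
    if not samples:
        raise ValueError("training database must be nonempty")
    rng = np.random.default_rng(seed)
    groups = _group_samples(samples)
    sizes = np.array([len(g) for g in groups], dtype=float)
    pnames = sorted(model.params)
    ptensors = [model.params[k] for k in pnames]
    opt = _Adam(ptensors)
    history = {"loss": [], "loss_energy": [], "loss_force": [], "lr": [], "p_e": []}
    for step in range(n_steps):
        frac = step / max(n_steps - 1, 1)
        p_e = loss_schedule.p_e_at(frac)
        lr = lr_at(lr_schedule, step)
        gidx = int(rng.choice(len(groups), p=sizes / sizes.sum()))
        g = groups[gidx]
        take = min(batch_size, len(g))
        sel = rng.choice(len(g), size=take, replace=False)
        batch = [samples[g[i]] for i in sel]
        lval, l_e, l_f = _batch_loss_graph(model, batch, p_e, loss_schedule.p_f)
        if not np.isfinite(lval.data):
            raise TrainingError(
                f"non-finite loss at step {step} (lr={lr:.2e}, p_e={p_e:.2e})"
            )
        grads = grad(lval, ptensors)
        opt.step([g_.data for g_ in grads], lr)
        history["loss"].append(float(lval.data))
        history["loss_energy"].append(float(l_e.data))
        history["loss_force"].append(float(l_f.data))
        history["lr"].append(lr)
        history["p_e"].append(p_e)
    return history


def train_committee(
    database: list[LabeledSample],
    architecture: str,
    hyperparams,
    lr_schedule: LRSchedule,
    loss_schedule: LossSchedule,
    seeds: list[int],
    species_table=None,
    n_steps: int | None = None,
    batch_size: int = 4,
) -> tuple[Committee, list[dict]]:
    """Train one model per seed on the same database."""
    if not database:
        raise ValueError("training database must be nonempty")
    if species_table is None:
        species_table = _species_table_from(database)
    n_steps = n_steps if n_steps is not None else lr_schedule.n_steps
    models, hists = [], []
    for seed in seeds:
        m = init_model(architecture, hyperparams, species_table, seed)
        h = train_model(
            m, database, n_steps, lr_schedule, loss_schedule, seed=seed + 7919,
            batch_size=batch_size,
        )
        models.append(m)
        hists.append(h)
    return Committee(models, list(seeds)), hists


def _species_table_from(samples: list[LabeledSample]):
    codes: set[int] = set()
    for s in samples:
        c = s.config.species.copy()
        c[~s.config.qm_mask] += MM_SPECIES_OFFSET
        codes.update(int(x) for x in c)
    return sorted(codes)


# ------------------------------------------------------- committee filter


def _committee_force_rmse(committee: Committee, samples: list[LabeledSample]) -> np.ndarray:
    """(n_samples,) max-over-members force-component RMSE vs labels."""
    out = np.zeros(len(samples))
    for idx in _group_samples(samples):
        sub = [samples[i] for i in idx]
        cfg0 = sub[0].config
        pos = np.stack([s.config.positions for s in sub])
        f_ref = np.stack([s.f_delta for s in sub])
        worst = np.zeros(len(sub))
        for m in committee.models:
            from .delta_model import batch_energy_forces

            _, f_pred = batch_energy_forces(m, cfg0.species, cfg0.region, pos)
            rmse = np.sqrt(np.mean((f_pred - f_ref) ** 2, axis=(1, 2)))
            worst = np.maximum(worst, rmse)
        out[list(idx)] = worst
    return out


def force_rmse_filter(committee: Committee, sample: LabeledSample, threshold: float) -> bool:
    """True to keep: max-over-members force RMSE >= threshold (strict-less
    discards, so a sample exactly at the threshold is kept)."""
    rmse = _committee_force_rmse(committee, [sample])[0]
    return bool(rmse >= threshold)


# ------------------------------------------------------------- simplify


def simplify_workflow(
    database: list[LabeledSample],
    config: SimplifyConfig,
    architecture: str,
    hyperparams,
    lr_schedule: LRSchedule,
    loss_schedule: LossSchedule,
    seed: int,
    n_steps: int | None = None,
    batch_size: int = 4,
) -> tuple[Committee, list[dict]]:
    """Iterative train/filter/retrain selection; at most 3 rounds.

    Round 1 trains a fresh committee on a random ``init_fraction`` of the
    database; each later round restarts the optimization from the previous
    parameters on surviving test samples capped at ``round_cap_fraction`` of
    the original database size.  Terminates when the filtered test set is
    empty or every sample has been consumed.
    """
    if not database:
        raise ValueError("database must be nonempty")
    rng = np.random.default_rng(seed)
    n0 = len(database)
    all_idx = np.arange(n0)
    n_train = max(1, int(round(config.init_fraction * n0)))
    train_idx = np.sort(rng.choice(all_idx, size=n_train, replace=False))
    test_idx = np.setdiff1d(all_idx, train_idx)
    species_table = _species_table_from(database)
    seeds = [seed + 1 + i for i in range(config.committee_size)]
    committee, _ = train_committee(
        [database[i] for i in train_idx], architecture, hyperparams,
        lr_schedule, loss_schedule, seeds, species_table=species_table,
        n_steps=n_steps, batch_size=batch_size,
    )
    history = []
    rounds = 1
    cap = max(1, int(round(config.round_cap_fraction * n0)))
    while True:
        if test_idx.size:
            rmse = _committee_force_rmse(committee, [database[i] for i in test_idx])
            keep = rmse >= config.force_rmse_threshold
            survivors = test_idx[keep]
            discarded = test_idx[~keep]
        else:
            survivors = discarded = np.array([], dtype=int)
        history.append(
            {
                "round": rounds,
                "train": train_idx.tolist(),
                "test": test_idx.tolist(),
                "discarded": discarded.tolist(),
                "survivors": survivors.tolist(),
            }
        )
        if survivors.size == 0:
            break
        if rounds >= 3:  # bounded by construction: 0.5 + 2 * 0.25 >= 1
            raise TrainingError("simplify exceeded its 3-round termination bound")
        take = min(cap, survivors.size)
        sel = np.sort(rng.choice(survivors, size=take, replace=False))
        test_idx = np.setdiff1d(survivors, sel)
        train_idx = sel
        n_train_steps = n_steps if n_steps is not None else lr_schedule.n_steps
        for m, s in zip(committee.models, committee.seeds):
            train_model(
                m, [database[i] for i in sel], n_train_steps, lr_schedule,
                loss_schedule, seed=s + 7919 + rounds, batch_size=batch_size,
            )
        rounds += 1
    return committee, history


# ----------------------------------------------------------- augmentation


def augment_endstates(
    ensembles: list[list[LabeledSample]], spec: AugmentSpec, seed: int
) -> list[AtomicConfiguration]:
    """Randomly displaced copies of end-state configurations.

    QM heavy atoms move by a uniform-direction displacement of magnitude up
    to ``heavy_max_disp``; each QM hydrogen is moved along its covalent bond
    (to the nearest QM heavy atom) so the bond length becomes uniform in
    ``h_bond_range``.  MM atoms are untouched.
    """
    rng = np.random.default_rng(seed)
    out: list[AtomicConfiguration] = []
    for ens in ensembles:
        if len(ens) < spec.copies_per_ensemble:
            raise ValueError("ensemble smaller than copies_per_ensemble")
        pick = rng.choice(len(ens), size=spec.copies_per_ensemble, replace=False)
        for i in pick:
            cfg = ens[i].config
            pos = cfg.positions.copy()
            qm = cfg.qm_mask
            heavy = qm & (cfg.species > 1)
            hyd = qm & (cfg.species == 1)
            for a in np.nonzero(heavy)[0]:
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                pos[a] += v * (spec.heavy_max_disp * rng.uniform())
            for a in np.nonzero(hyd)[0]:
                heavies = np.nonzero(heavy)[0]
                if heavies.size == 0:
                    raise ValueError("hydrogen with no identifiable bonded heavy atom")
                d = np.linalg.norm(pos[heavies] - pos[a], axis=1)
                b = heavies[np.argmin(d)]
                if d.min() > 2.0:
                    raise ValueError("hydrogen with no identifiable bonded heavy atom")
                axis = pos[a] - pos[b]
                axis /= np.linalg.norm(axis)
                lo, hi = spec.h_bond_range
                pos[a] = pos[b] + axis * rng.uniform(lo, hi)
            out.append(cfg.with_positions(pos))
    return out


# -------------------------------------------------------------- fine-tune


def fine_tune(
    committee: Committee,
    extra_data: list[LabeledSample],
    base_data: list[LabeledSample],
    lr_schedule: LRSchedule,
    loss_schedule: LossSchedule,
    n_steps: int,
    seed: int,
    batch_size: int = 4,
) -> Committee:
    """Restart each member's optimization on base + added-window data.

    With ``n_steps`` = 0 the returned committee is bit-identical to the
    input (parameters are copied, not aliased).
    """
    models = [m.copy() for m in committee.models]
    data = list(base_data) + list(extra_data)
    if n_steps > 0:
        if not data:
            raise ValueError("fine_tune requires data when n_steps > 0")
        for k, m in enumerate(models):
            train_model(
                m, data, n_steps, lr_schedule, loss_schedule,
                seed=seed + 7919 * (k + 1), batch_size=batch_size,
            )
    return Committee(models, list(committee.seeds))
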