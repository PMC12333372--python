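"""Schedules, loss, committee filter, simplify bookkeeping, augmentation."""

import numpy as np
import pytest

import rcdmlp.training as tr
from rcdmlp.delta_model import DpHyperParams, init_model
from rcdmlp.geometry import AtomicConfiguration, LabeledSample
from rcdmlp.rc_graph import RadialBasisSpec
from rcdmlp.training import (
    AugmentSpec,
    Committee,
    LossSchedule,
    LRSchedule,
    SimplifyConfig,
    augment_endstates,
    fine_tune,
    force_rmse_filter,
    loss,
    lr_at,
    simplify_workflow,
    train_committee,
)

from conftest import TOY_CODES


BASIS = RadialBasisSpec(6.0, 4, 5)
TINY_HP = DpHyperParams(fitting_layers=(8, 8), embedding_layers=(4, 8), axis_filters=4, basis=BASIS)


def _sample(seed, scale=1.0):
    rng = np.random.default_rng(seed)
    species = np.array([8, 15, 8, 8])
    region = np.array(["QM"] * 3 + ["MM"], dtype=object)
    pos = np.array([[0, 0, 2.0], [0, 0, 0], [0, 0, -2.0], [3.0, 0, 0]]) + rng.normal(
        scale=0.05, size=(4, 3)
    )
    cfg = AtomicConfiguration(species, pos, region)
    f = rng.normal(scale=0.01 * scale, size=(4, 3))
    xi = float(np.linalg.norm(pos[0] - pos[1]) - np.linalg.norm(pos[1] - pos[2]))
    return LabeledSample(cfg, 0.0, 0.02 * scale, np.zeros((4, 3)), f, xi)


def _database(n, scale=1.0):
    return [_sample(100 + i, scale) for i in range(n)]


# ------------------------------------------------------------- schedules


def test_lr_schedule_hits_printed_endpoints():
    sched = LRSchedule(1e-3, 1e-5, 400_000)
    assert lr_at(sched, 0) == pytest.approx(1e-3)
    assert lr_at(sched, 400_000) == pytest.approx(1e-5)
    assert lr_at(sched, 200_000) == pytest.approx(1e-4)  # geometric midpoint
    assert lr_at(sched, 10**7) == pytest.approx(1e-5)  # clamped
    steps = [lr_at(sched, s) for s in range(0, 400_000, 50_000)]
    assert all(a >= b for a, b in zip(steps, steps[1:]))


def test_energy_weight_schedule_endpoints():
    ls = LossSchedule()
    assert ls.p_e_at(0.0) == pytest.approx(1.0)
    assert ls.p_e_at(1.0) == pytest.approx(100.0)
    fr = [ls.p_e_at(t) for t in np.linspace(0, 1, 11)]
    assert all(a <= b for a, b in zip(fr, fr[1:]))


def test_loss_zero_for_perfect_predictions():
    m = init_model("dp_like", TINY_HP, TOY_CODES, seed=0)
    s = _sample(0)
    perfect = LabeledSample(
        s.config,
        0.0,
        0.0,
        np.zeros((4, 3)),
        np.zeros((4, 3)),
        s.xi,
    )
    # make the model's own prediction the label
    from rcdmlp.delta_model import delta_energy_forces

    ef = delta_energy_forces(m, s.config)
    labelled = LabeledSample(s.config, 0.0, ef.energy, np.zeros((4, 3)), ef.forces, s.xi)
    assert loss(m, [labelled], 0.5) == pytest.approx(0.0, abs=1e-20)
    assert loss(m, [perfect], 0.5) > 0.0
    with pytest.raises(ValueError):
        loss(m, [], 0.5)


# ------------------------------------------------------- committee filter


class _StubModel:
    """Predicts a constant force error against zero labels."""

    def __init__(self, rmse):
        self.rmse = rmse


def _stub_committee(rmses, sample):
    # build a committee of real models but monkeypatch the rmse computation
    models = [object() for _ in rmses]
    return Committee(models, list(range(len(rmses)))), rmses


def test_force_rmse_filter_maximum_governs(monkeypatch):
    s = _sample(1)
    for rmses, expected_keep in [
        ((0.05, 0.05, 0.05, 0.05), False),  # all below threshold -> discard
        ((0.05, 0.09, 0.05, 0.05), True),  # one above -> keep
        ((0.08, 0.05, 0.05, 0.05), True),  # boundary: strict less-than discards
    ]:
        committee, values = _stub_committee(rmses, s)
        monkeypatch.setattr(
            tr, "_committee_force_rmse",
            lambda com, samples, v=values: np.array([max(v)] * len(samples)),
        )
        assert force_rmse_filter(committee, s, 0.08) is expected_keep


def test_force_rmse_filter_on_real_committee():
    m = init_model("dp_like", TINY_HP, TOY_CODES, seed=0)
    committee = Committee([m], [0])
    s = _sample(2, scale=0.0)  # zero labels; untrained model is near zero
    assert force_rmse_filter(committee, s, threshold=1e9) is False
    assert force_rmse_filter(committee, s, threshold=0.0) is True


# ------------------------------------------------------------- training


@pytest.fixture(scope="module")
def tiny_committee():
    db = _database(12)
    committee, hists = train_committee(
        db, "dp_like", TINY_HP, LRSchedule(1e-3, 1e-5, 20), LossSchedule(),
        seeds=[1, 2, 3, 4], n_steps=20, batch_size=4,
    )
    return db, committee, hists


def test_committee_training_reproducible_and_distinct(tiny_committee):
    db, committee, hists = tiny_committee
    assert len(committee) == 4
    committee2, _ = train_committee(
        db, "dp_like", TINY_HP, LRSchedule(1e-3, 1e-5, 20), LossSchedule(),
        seeds=[1, 2, 3, 4], n_steps=20, batch_size=4,
    )
    for m1, m2 in zip(committee.models, committee2.models):
        assert all(np.array_equal(m1.params[k].data, m2.params[k].data) for k in m1.params)
    p0, p1 = committee.models[0].params, committee.models[1].params
    assert any(not np.array_equal(p0[k].data, p1[k].data) for k in p0)


def test_training_reduces_loss_on_realizable_correction():
    # labels produced by a fixed teacher of the same model class are exactly
    # realizable; training must reduce the (fixed-weight) loss from init
    from rcdmlp.delta_model import delta_energy_forces

    teacher = init_model("dp_like", TINY_HP, TOY_CODES, seed=42)
    for k in teacher.params:
        teacher.params[k].data *= 1.5
    db = []
    for s in _database(16):
        ef = delta_energy_forces(teacher, s.config)
        db.append(LabeledSample(s.config, 0.0, ef.energy, np.zeros((4, 3)), ef.forces, s.xi))
    student = init_model("dp_like", TINY_HP, TOY_CODES, seed=5)
    before = loss(student, db, 1.0)
    tr.train_model(student, db, 150, LRSchedule(1e-3, 1e-5, 150), LossSchedule(), seed=6, batch_size=8)
    after = loss(student, db, 1.0)
    assert after < before


def test_divergent_loss_raises():
    db = _database(4)
    m = init_model("dp_like", TINY_HP, TOY_CODES, seed=0)
    m.params["fit_w0"].data[:] = np.inf
    with pytest.raises(tr.TrainingError):
        tr.train_model(m, db, 3, LRSchedule(1e-3, 1e-5, 3), LossSchedule(), seed=0)


# ------------------------------------------------------------- simplify


def _run_simplify(n_db, keep_fn, seed=0):
    """Run simplify with a stubbed committee filter (bookkeeping test)."""
    db = _database(n_db)
    cfg = SimplifyConfig()

    import unittest.mock as mock

    def fake_rmse(committee, samples):
        return np.array([1.0 if keep_fn(s) else 0.0 for s in samples])

    with mock.patch.object(tr, "_committee_force_rmse", fake_rmse):
        committee, history = simplify_workflow(
            db, cfg, "dp_like", TINY_HP, LRSchedule(1e-3, 1e-5, 2), LossSchedule(),
            seed=seed, n_steps=2, batch_size=4,
        )
    return db, history


def test_simplify_worst_case_runs_three_rounds():
    db, history = _run_simplify(40, keep_fn=lambda s: True)
    assert len(history) == 3
    assert len(history[0]["train"]) == 20
    assert len(history[1]["train"]) == 10
    assert len(history[2]["train"]) == 10
    # after round 3 everything is consumed
    assert history[-1]["survivors"] == []


def test_simplify_stops_after_one_round_when_filter_discards_all():
    db, history = _run_simplify(40, keep_fn=lambda s: False)
    assert len(history) == 1
    assert history[0]["survivors"] == []
    assert len(history[0]["discarded"]) == 20


def test_simplify_partitions_are_disjoint_and_bounded():
    for keep_mod in (2, 3):
        db, history = _run_simplify(24, keep_fn=lambda s, m=keep_mod: hash(round(s.xi, 6)) % m != 0)
        assert len(history) <= 3
        seen_train = set()
        for rec in history:
            train = set(rec["train"])
            test = set(rec["test"])
            assert not train & test
            assert not train & seen_train
            seen_train |= train
        assert seen_train <= set(range(24))


def test_simplify_terminates_for_all_filter_behaviors_small_case():
    # exhaustive over all 2^4 filter outcomes of 4 distinguishable samples
    # grouped by round: the filter keeps a sample iff its bit is set
    for mask in range(16):
        db, history = _run_simplify(
            8, keep_fn=lambda s, m=mask: bool(m & (1 << (abs(hash(round(s.xi, 6))) % 4)))
        )
        assert 1 <= len(history) <= 3


# ----------------------------------------------------------- augmentation


def _endstate_ensemble(n, seed, jitter=0.02):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        species = np.array([8, 15, 8, 1, 8])
        region = np.array(["QM"] * 4 + ["MM"], dtype=object)
        pos = np.array(
            [[0, 0, 2.0], [0, 0, 0], [0, 0, -2.0], [1.0, 0.5, 0], [3.5, 0, 0]]
        ) + rng.normal(scale=jitter, size=(5, 3))
        cfg = AtomicConfiguration(species, pos, region)
        out.append(LabeledSample(cfg, 0.0, 0.0, np.zeros((5, 3)), np.zeros((5, 3)), 0.0))
    return out


def test_augmentation_counts_ten_percent_rule():
    # 12 ensembles of 500 with 50 copies each extend the database by 10%
    ensembles = [_endstate_ensemble(60, seed=i) for i in range(4)]
    spec = AugmentSpec(copies_per_ensemble=6)
    new = augment_endstates(ensembles, spec, seed=0)
    assert len(new) == 6 * 4
    assert len(new) / sum(len(e) for e in ensembles) == pytest.approx(0.10)


def test_augmentation_displacement_statistics():
    # identical source configurations so displacements are attributable to
    # the augmentation alone regardless of which samples were selected
    ensembles = [_endstate_ensemble(300, seed=9, jitter=0.0)]
    spec = AugmentSpec(copies_per_ensemble=300, heavy_max_disp=0.15, h_bond_range=(0.7, 1.2))
    new = augment_endstates(ensembles, spec, seed=1)
    heavy_disp, h_bonds, mm_moved = [], [], []
    for orig, cfg in zip(ensembles[0], new):
        d = np.linalg.norm(cfg.positions - orig.config.positions, axis=1)
        heavy_disp.extend(d[[0, 2]])  # QM heavy atoms away from the H anchor
        mm_moved.append(d[4])
        bond = np.linalg.norm(cfg.positions[3] - cfg.positions[1])
        h_bonds.append(bond)
    heavy_disp = np.array(heavy_disp)
    assert heavy_disp.max() <= 0.15 + 1e-12
    assert heavy_disp.min() >= 0.0
    assert np.mean(heavy_disp) == pytest.approx(0.075, abs=0.02)
    h_bonds = np.array(h_bonds)
    assert h_bonds.min() >= 0.7 - 1e-12 and h_bonds.max() <= 1.2 + 1e-12
    assert np.all(np.array(mm_moved) == 0.0)  # MM atoms untouched


def test_augmentation_degenerate_hydrogen_range():
    ensembles = [_endstate_ensemble(5, seed=3)]
    spec = AugmentSpec(copies_per_ensemble=5, heavy_max_disp=0.0, h_bond_range=(0.9, 0.9))
    new = augment_endstates(ensembles, spec, seed=2)
    for cfg in new:
        bond = np.linalg.norm(cfg.positions[3] - cfg.positions[1])
        assert bond == pytest.approx(0.9, abs=1e-12)


def test_augmentation_orphan_hydrogen_raises():
    species = np.array([1, 8])
    region = np.array(["QM", "MM"], dtype=object)
    cfg = AtomicConfiguration(species, np.array([[0.0, 0, 0], [5.0, 0, 0]]), region)
    s = LabeledSample(cfg, 0, 0, np.zeros((2, 3)), np.zeros((2, 3)), 0.0)
    with pytest.raises(ValueError):
        augment_endstates([[s]], AugmentSpec(copies_per_ensemble=1), seed=0)


# --------------------------------------------------- correlation order


def test_higher_correlation_order_fits_angular_correction_better():
    """The toy correction includes a genuinely 3-body (angle) term: with
    equal channel count and training budget, a nu=3 model reaches lower
    held-out force RMSE than a nu=1 model (seeded, directional claim)."""
    from dataclasses import replace

    from rcdmlp.delta_model import MaceHyperParams
    from rcdmlp.geometry import make_window_schedule
    from rcdmlp.toysim import (
        DynamicsSpec,
        ToyPotential,
        label_positions,
        run_umbrella_windows,
        toy_reaction_variants,
    )

    name, system, params = toy_reaction_variants(1)[0]
    system = replace(system, n_mm=4)
    pot_b = ToyPotential(system, params, target=False)
    sched = make_window_schedule(-2.0, 2.0, 0.5)
    dyn = DynamicsSpec(n_equil_steps=300, n_prod_steps=600, samples_saved=30)
    frames = run_umbrella_windows(pot_b, sched.windows, system, params, dyn, seed=8)
    data = []
    for fr in frames:
        data += label_positions(fr, system, params)
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(data))
    train = [data[i] for i in idx[:180]]
    test = [data[i] for i in idx[180:]]
    rmse = {}
    for nu in (1, 3):
        hp = MaceHyperParams(L=0, T=2, nu=nu, N=8, l_max=2, radial_mlp=(8, 8), basis=RadialBasisSpec(6.0, 8, 5))
        m = init_model("mace_like", hp, sorted({1, 8, 15, 58}), seed=7)
        tr.train_model(m, train, 300, LRSchedule(1e-3, 1e-5, 300), LossSchedule(), seed=3, batch_size=8)
        rmse[nu] = float(tr._committee_force_rmse(Committee([m], [7]), test).mean())
    assert rmse[3] < rmse[1]


# -------------------------------------------------------------- fine-tune


def test_fine_tune_zero_steps_is_bit_identical(tiny_committee):
    db, committee, _ = tiny_committee
    tuned = fine_tune(
        committee, [], db, LRSchedule(1e-3, 1e-5, 10), LossSchedule(),
        n_steps=0, seed=0,
    )
    for m1, m2 in zip(committee.models, tuned.models):
        assert all(np.array_equal(m1.params[k].data, m2.params[k].data) for k in m1.params)
        assert m1.params is not m2.params  # copied, not aliased


def test_fine_tune_improves_loss_on_added_windows(tiny_committee):
    db, committee, _ = tiny_committee
    extra = _database(8, scale=3.0)
    tuned = fine_tune(
        committee, extra, db, LRSchedule(5e-4, 1e-5, 120), LossSchedule(),
        n_steps=120, seed=0, batch_size=8,
    )
    before = np.mean([loss(m, extra, 1.0) for m in committee.models])
    after = np.mean([loss(m, extra, 1.0) for m in tuned.models])
    assert after <= before
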