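"""MBAR, FES construction, wTP/gwTP reweighting and RE diagnostics."""

import numpy as np
import pytest
from scipy.special import logsumexp

from rcdmlp.feanalysis import (
    BiasedEnsemble,
    FES,
    SmoothingSpec,
    average_surfaces,
    dos_smoothing,
    ensemble_from_windows,
    fes_from_weights,
    gwtp_estimate,
    mbar_fes,
    mbar_solve,
    reweighting_entropy,
    wtp_estimate,
)
from rcdmlp.feanalysis import mbar_f_k_standard_errors
from rcdmlp.units import kt_kcalmol


def _harmonic_samples(seed, kap=2.0, kb=60.0, centers=None, nper=300):
    rng = np.random.default_rng(seed)
    centers = np.linspace(-1.5, 1.5, 13) if centers is None else centers
    xs, urefs = [], []
    for c in centers:
        prec = kap + kb
        x = rng.normal(kb * c / prec, 1 / np.sqrt(prec), size=nper)
        xs.append(x)
        urefs.append(0.5 * kap * x**2)
    return xs, urefs, centers


def _harmonic_ensemble(seed, kap=2.0, kb=60.0, centers=None, nper=300):
    """Gaussian window samples with analytically known free energies."""
    xs, urefs, centers = _harmonic_samples(seed, kap, kb, centers, nper)
    f_exact = 0.5 * kap * kb * centers**2 / (kap + kb)
    return ensemble_from_windows(xs, urefs, centers, kb), f_exact - f_exact[0]


def test_mbar_identical_states_have_zero_free_energy_difference():
    rng = np.random.default_rng(0)
    u = np.tile(rng.normal(size=200), (2, 1))
    ens = BiasedEnsemble(rng.normal(size=200), u, np.array([100, 100]), u[0])
    res = mbar_solve(ens)
    assert res.f_k[1] == pytest.approx(0.0, abs=1e-12)


def test_mbar_recovers_harmonic_free_energies_within_errors():
    # replicate-averaged estimate against the closed-form Gaussian result
    errs, ses = [], []
    for rep in range(6):
        ens, f_exact = _harmonic_ensemble(seed=200 + rep)
        res = mbar_solve(ens)
        errs.append(res.f_k - f_exact)
        ses.append(mbar_f_k_standard_errors(ens, res))
    errs = np.array(errs)
    sem = np.array(ses).mean(axis=0) / np.sqrt(len(errs))
    assert np.all(np.abs(errs.mean(axis=0))[1:] < 3 * sem[1:])


def test_mbar_agrees_with_independent_iteration_oracle():
    rng = np.random.default_rng(3)
    K, n = 5, 200
    u = rng.normal(size=(K, n)) * 0.5
    counts = np.array([40] * K)
    ens = BiasedEnsemble(rng.normal(size=n), u, counts, np.zeros(n))
    res = mbar_solve(ens)
    # brute-force self-consistent iteration, written independently
    f = np.zeros(K)
    for _ in range(500_000):
        logD = logsumexp(np.log(counts)[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - logD[None, :], axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < 1e-15:
            f = f_new
            break
        f = f_new
    assert np.abs(res.f_k - f).max() < 1e-6


def test_mbar_shift_invariance():
    rng = np.random.default_rng(4)
    u = rng.normal(size=(4, 120))
    counts = np.array([30] * 4)
    ens = BiasedEnsemble(rng.normal(size=120), u, counts, np.zeros(120))
    res = mbar_solve(ens)
    u2 = u.copy()
    u2[2] += 7.5
    res2 = mbar_solve(BiasedEnsemble(ens.xi, u2, counts, ens.u_ref))
    diff = res2.f_k - res.f_k
    assert diff[2] == pytest.approx(7.5, abs=1e-9)
    assert np.abs(np.delete(diff, 2)).max() < 1e-9


def test_mbar_weights_normalize():
    ens, _ = _harmonic_ensemble(seed=7)
    res = mbar_solve(ens)
    w = np.exp(res.unbiased_log_weights(ens.u_ref))
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    # per-state normalized weights also sum to one
    logw_k = ens.u_matrix[4] * -1.0 - res.log_denominators
    assert np.exp(logw_k - logsumexp(logw_k)).sum() == pytest.approx(1.0)


# ------------------------------------------------------------------- FES


def test_fes_uniform_weights_single_interval_is_flat():
    xi = np.random.default_rng(0).uniform(-0.05, 0.049, size=500)
    fes = fes_from_weights(np.full(500, 1 / 500), xi, bin_width=0.1)
    occ = fes.occupied
    assert occ.sum() == 1
    np.testing.assert_allclose(fes.values[occ], 0.0, atol=1e-12)


def test_fes_two_bin_ratio_gives_kt():
    # weight ratio e^-1 -> free-energy gap exactly kT = 0.5924 kcal/mol
    xi = np.array([0.0] * 10 + [0.1] * 10)
    w = np.array([1.0] * 10 + [np.exp(-1.0)] * 10)
    fes = fes_from_weights(w / w.sum(), xi, bin_width=0.1, temperature=298.0)
    gap = fes.values[1] - fes.values[0]
    assert gap == pytest.approx(kt_kcalmol(298.0), abs=1e-9)
    assert gap == pytest.approx(0.5924, abs=5e-4)


def test_fes_grid_aligns_with_window_centers():
    xi = np.array([-0.26, -0.06, 0.24])
    fes = fes_from_weights(np.full(3, 1 / 3), xi, bin_width=0.1)
    steps = fes.bin_centers / 0.1
    np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)
    # empty interior bins are flagged, not interpolated
    assert np.isnan(fes.values[~fes.occupied]).all()


# ----------------------------------------------------------- RE and wTP


@pytest.mark.parametrize(
    "weights,expected",
    [
        (np.ones(2), 1.0),
        (np.ones(10), 1.0),
        (np.ones(1000), 1.0),
        (np.array([1.0, 0, 0, 0]), 0.0),
        (np.array([0.5, 0.5, 0, 0]), np.log(2) / np.log(4)),
    ],
)
def test_reweighting_entropy_values(weights, expected):
    assert reweighting_entropy(weights) == pytest.approx(expected, abs=1e-12)


def test_reweighting_entropy_monotone_under_concentration():
    w = np.ones(20)
    last = reweighting_entropy(w)
    for boost in (2.0, 5.0, 20.0, 100.0):
        w2 = np.ones(20)
        w2[0] = boost
        re = reweighting_entropy(w2)
        assert re < last
        last = re


def test_reweighting_entropy_input_validation():
    with pytest.raises(ValueError):
        reweighting_entropy(np.array([1.0]))
    with pytest.raises(ValueError):
        reweighting_entropy(np.array([0.0, 0.0]))
    with pytest.raises(ValueError):
        reweighting_entropy(np.array([1.0, -0.5]))


def test_wtp_self_perturbation_reproduces_mbar_exactly():
    ens, _ = _harmonic_ensemble(seed=11)
    res = mbar_solve(ens)
    ref = mbar_fes(ens, res)
    rep = wtp_estimate(ens, np.zeros(ens.xi.size), result=res)
    np.testing.assert_array_equal(rep.fes.values, ref.values)
    occupied_re = rep.re_per_bin[np.isfinite(rep.re_per_bin)]
    np.testing.assert_allclose(occupied_re, 1.0, atol=1e-12)


def test_wtp_outlier_sample_drives_re_to_zero():
    ens, _ = _harmonic_ensemble(seed=12, centers=np.array([0.0]), nper=100)
    du = np.zeros(100)
    du[0] = -20.0  # one sample dominates the perturbation weights
    rep = wtp_estimate(ens, du)
    b = np.nanargmin(rep.re_per_bin)
    assert np.nanmin(rep.re_per_bin) < 0.05


def test_wtp_recovers_analytic_target_shift():
    # target adds a linear field: closed-form harmonic statistics again
    kap, kb = 2.0, 60.0
    ens, _ = _harmonic_ensemble(seed=13, kap=kap, kb=kb)
    alpha = 0.8
    du = alpha * ens.xi  # beta (U_target - U_ref) for U_t = U_r + alpha x / beta
    rep = wtp_estimate(ens, du, bin_width=0.1)
    # analytic target pmf: 0.5 kap x^2 + alpha x (dimensionless)
    occ = rep.fes.occupied & (rep.re_per_bin > 0.6)
    x = rep.fes.bin_centers[occ]
    kT = kt_kcalmol(298.0)
    expected = (0.5 * kap * x**2 + alpha * x) * kT
    expected -= expected.min()
    got = rep.fes.values[occ] - np.nanmin(rep.fes.values[occ])
    assert np.mean(np.abs(got - expected)) < 0.5 * kT


def test_gwtp_single_reference_reduces_to_wtp():
    ens, _ = _harmonic_ensemble(seed=14)
    du = 0.3 * np.sin(ens.xi)
    a = wtp_estimate(ens, du)
    b = gwtp_estimate([ens], [ens.u_ref + du])
    np.testing.assert_allclose(a.fes.values, b.fes.values, atol=1e-12)
    np.testing.assert_allclose(a.re_per_bin, b.re_per_bin, atol=1e-12)


def test_gwtp_pools_identical_references_consistently():
    # two bit-identical reference models with disjoint sample sets must give
    # the same estimate as wTP on the union of their samples: duplicating
    # identical states in MBAR leaves the denominators unchanged
    xs1, urefs1, centers = _harmonic_samples(seed=15)
    xs2, urefs2, _ = _harmonic_samples(seed=16)
    ens1 = ensemble_from_windows(xs1, urefs1, centers, 60.0)
    ens2 = ensemble_from_windows(xs2, urefs2, centers, 60.0)
    du1 = 0.2 * ens1.xi
    du2 = 0.2 * ens2.xi
    rep = gwtp_estimate(
        [ens1, ens2],
        [ens1.u_ref + du1, ens2.u_ref + du2],
        u_cross=[[None, ens1.u_ref], [ens2.u_ref, None]],
    )
    merged = ensemble_from_windows(
        [np.concatenate([a, b]) for a, b in zip(xs1, xs2)],
        [np.concatenate([a, b]) for a, b in zip(urefs1, urefs2)],
        centers,
        60.0,
    )
    du_merged = 0.2 * merged.xi
    ref = wtp_estimate(merged, du_merged)
    got = {round(c, 6): v for c, v in zip(rep.fes.bin_centers, rep.fes.values)}
    want = {round(c, 6): v for c, v in zip(ref.fes.bin_centers, ref.fes.values)}
    for c, v in want.items():
        if np.isfinite(v):
            assert got[c] == pytest.approx(v, abs=1e-9)


def test_dos_smoothing_identical_values_unchanged():
    du = np.full(50, 0.37)
    factors = dos_smoothing(du, SmoothingSpec())
    np.testing.assert_allclose(factors, np.exp(-0.37), atol=1e-12)


def test_dos_smoothing_within_band_collapses_to_one_bin():
    rng = np.random.default_rng(5)
    du = rng.uniform(0.0, 0.19, size=40)
    factors = dos_smoothing(du, SmoothingSpec(0.2))
    assert np.unique(factors).size == 1
    # the common factor carries the bin's total weight
    np.testing.assert_allclose(factors, np.exp(-du).mean(), atol=1e-12)


def test_dos_smoothing_does_not_reduce_re_for_outlier_bin():
    rng = np.random.default_rng(6)
    du = np.concatenate([rng.normal(0.0, 0.4, size=99), [-10.0]])
    raw = np.exp(-(du - du.min()))
    re_before = reweighting_entropy(raw)
    factors = dos_smoothing(du, SmoothingSpec(0.2))
    re_after = reweighting_entropy(factors / factors.max())
    assert re_after >= re_before


def test_average_surfaces_offset_invariance():
    centers = np.arange(-3, 4) * 0.1
    vals = np.abs(centers) * 2.0
    n = np.ones(7, dtype=int)
    a = FES(centers, vals - vals.min(), n)
    b = FES(centers, vals + 3.0 - (vals + 3.0).min(), n)
    mean = average_surfaces([a, b])
    np.testing.assert_allclose(mean.values, a.values, atol=1e-12)
    same = average_surfaces([a, a])
    np.testing.assert_allclose(same.values, a.values, atol=1e-12)
    with pytest.raises(ValueError):
        average_surfaces([a, FES(centers + 0.05, vals, n)])
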