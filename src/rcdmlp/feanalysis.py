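"""Free-energy estimation and reweighting-reliability diagnostics.

Biased umbrella ensembles are combined with the multistate Bennett
acceptance ratio (MBAR); free-energy surfaces along xi are histograms of
MBAR sample weights on a fixed-width grid.  The weighted thermodynamic
perturbation (wTP) estimates a *target* potential's surface from sampling
generated under a single reference potential, by scaling each sample's
unbiased MBAR weight with exp(-beta dU); the generalized form (gwTP) pools
the sampling of several reference potentials under one joint MBAR and
reweights the pool.  Per spatial bin, the reweighting entropy

    RE = -sum w~ ln w~ / ln n

of the normalized perturbation weights diagnoses reliability: RE = 1 when
the perturbation leaves the weights uniform, RE -> 0 when a few samples
dominate; experience places the trust threshold near RE = 0.6.  A
density-of-states smoothing step histograms the dU values inside each
spatial bin on a 0.2 kT grid and assigns every member of an energy bin the
factor exp(-mean dU), damping outlier weights without smoothing free-energy
values across spatial bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .units import kt_kcalmol

__all__ = [
    "BiasedEnsemble",
    "MBARResult",
    "FES",
    "ReweightingReport",
    "SmoothingSpec",
    "EstimationError",
    "ensemble_from_windows",
    "mbar_solve",
    "mbar_fes",
    "fes_from_weights",
    "wtp_estimate",
    "gwtp_estimate",
    "reweighting_entropy",
    "dos_smoothing",
    "average_surfaces",
]


class EstimationError(RuntimeError):
    pass


@dataclass
class BiasedEnsemble:
    """Pooled samples from biased states, as reduced potentials.

    u_matrix[k, n] is the dimensionless reduced potential of sample n
    evaluated in state k (beta * [U_ref + bias_k]); counts[k] samples were
    generated in state k; u_ref[n] is the unbiased reduced reference
    potential used for unbiased weights; xi[n] the reaction coordinate.
    ``origin`` maps each sample to the index of its generating state.
    """

    xi: np.ndarray
    u_matrix: np.ndarray
    counts: np.ndarray
    u_ref: np.ndarray
    origin: np.ndarray | None = None
    bias_centers: np.ndarray | None = None  # window centers (K,), A
    bias_kred: float | None = None  # reduced bias force constant, 1/A^2

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, float)
        self.u_matrix = np.asarray(self.u_matrix, float)
        self.counts = np.asarray(self.counts, int)
        self.u_ref = np.asarray(self.u_ref, float)
        K, n = self.u_matrix.shape
        if self.counts.shape != (K,) or self.counts.sum() != n:
            raise ValueError("counts must sum to the number of samples")
        if not np.all(np.isfinite(self.u_matrix)):
            raise ValueError("u_matrix must be finite")


@dataclass
class MBARResult:
    """Dimensionless state free energies (f[0] = 0) and sample denominators."""

    f_k: np.ndarray
    log_denominators: np.ndarray  # log D_n = logsumexp_k(log N_k + f_k - u_kn)
    residual: float

    def unbiased_log_weights(self, u_ref: np.ndarray) -> np.ndarray:
        """Normalized log-weights of each sample under reduced potential u_ref."""
        lw = -np.asarray(u_ref, float) - self.log_denominators
        return lw - logsumexp(lw)


def ensemble_from_windows(
    xi_per_window: list[np.ndarray],
    u_ref_per_window: list[np.ndarray],
    centers: np.ndarray,
    kred: float,
) -> BiasedEnsemble:
    """Assemble a BiasedEnsemble from per-window samples.

    ``u_ref_per_window`` holds the reduced (beta-scaled) unbiased potential
    of the sampling reference on each window's samples; ``kred`` is the
    reduced harmonic bias constant beta*k (1/A^2).
    """
    xi = np.concatenate([np.asarray(x, float) for x in xi_per_window])
    u_ref = np.concatenate([np.asarray(u, float) for u in u_ref_per_window])
    centers = np.asarray(centers, float)
    counts = np.array([len(x) for x in xi_per_window])
    u_matrix = u_ref[None, :] + 0.5 * kred * (xi[None, :] - centers[:, None]) ** 2
    origin = np.repeat(np.arange(len(centers)), counts)
    return BiasedEnsemble(
        xi, u_matrix, counts, u_ref, origin,
        bias_centers=centers, bias_kred=float(kred),
    )


def mbar_solve(
    ensemble: BiasedEnsemble, tol: float = 1e-10, max_iter: int = 10_000
) -> MBARResult:
    """Solve the MBAR self-consistent equations.

    A quasi-Newton pass on the convex MBAR objective is polished by
    self-consistent iteration to relative tolerance ``tol`` on f_k.
    Invariant: adding a constant c to row k of u_matrix shifts f_k by c and
    changes nothing else.
    """
    u = ensemble.u_matrix
    N_k = ensemble.counts.astype(float)
    K, n = u.shape
    active = N_k > 0
    logN = np.where(active, np.log(np.where(active, N_k, 1.0)), -np.inf)

    def grad_hess(f):
        logP = logN[:, None] + f[:, None] - u
        logD = logsumexp(logP, axis=0)
        P = np.exp(logP - logD[None, :])  # (K, n), columns sum to 1
        g = (P.sum(axis=1) - N_k) / n
        H = (np.diag(P.sum(axis=1)) - P @ P.T) / n
        return logD, g, H

    # initial guess: one self-consistent sweep from uniform denominators
    f = -logsumexp(-u, axis=1)
    f = np.where(active, f, 0.0)
    f -= f[0]
    # damped Newton on the convex MBAR objective (f_0 pinned to 0)
    gnorm = np.inf
    for _ in range(200):
        logD, g, H = grad_hess(f)
        gnorm = float(np.max(np.abs(g)))
        if gnorm < 1e-14:
            break
        Hr = H[1:, 1:] + 1e-13 * np.eye(K - 1)
        try:
            step = np.linalg.solve(Hr, -g[1:])
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hr, -g[1:], rcond=None)[0]
        nrm = np.max(np.abs(step))
        if nrm > 50.0:  # keep early steps inside the exp() comfort zone
            step *= 50.0 / nrm
        f[1:] += step
        if nrm < 1e-12:
            break
    # bounded self-consistent polish; the final sweep's change is the
    # self-consistency residual reported as the convergence certificate
    delta = np.inf
    for _ in range(min(max_iter, 500)):
        logD = logsumexp(logN[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - logD[None, :], axis=1)
        f_new = np.where(active, f_new, f)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol * max(1.0, np.max(np.abs(f))):
            break
    else:
        if gnorm > 1e-10:
            raise EstimationError(
                f"MBAR did not converge: residual {delta:.3e}, grad {gnorm:.3e}"
            )
    logD = logsumexp(logN[:, None] + f[:, None] - u, axis=0)
    return MBARResult(f_k=f, log_denominators=logD, residual=float(delta))


def mbar_f_k_standard_errors(ensemble: BiasedEnsemble, result: MBARResult) -> np.ndarray:
    """Asymptotic standard errors of f_k - f_0 (dimensionless).

    Uses the standard MBAR covariance estimate Theta = V (I - S)^+ V^T with
    W the normalized weight matrix.
    """
    u = ensemble.u_matrix
    N_k = ensemble.counts.astype(float)
    K, n = u.shape
    logW = result.f_k[:, None] - u - result.log_denominators[None, :]
    W = np.exp(logW).T  # (n, K), columns sum to 1
    S = W * np.sqrt(N_k)[None, :]
    # Theta = W^T (I_n - S S^T)^+ W via the SVD of S: eigendirections of
    # S S^T with sigma^2 -> 1 are null directions of the pseudo-inverse.
    U_, s_, _ = np.linalg.svd(S, full_matrices=False)
    WtU = W.T @ U_  # (K, K)
    lam = 1.0 - s_**2
    inv = np.where(lam > 1e-10, 1.0 / np.where(lam > 1e-10, lam, 1.0), 0.0)
    theta = W.T @ W - WtU @ WtU.T + WtU @ (inv[:, None] * WtU.T)
    var = np.clip(np.diag(theta)[None, :] + np.diag(theta)[:, None] - 2 * theta, 0.0, None)
    return np.sqrt(var[0])


@dataclass
class FES:
    """Free-energy surface on a fixed xi grid (kcal/mol, min over occupied = 0)."""

    bin_centers: np.ndarray
    values: np.ndarray  # NaN on unoccupied bins
    n_samples: np.ndarray
    bin_width: float = 0.1
    temperature: float = 298.0

    @property
    def occupied(self) -> np.ndarray:
        return self.n_samples > 0


@dataclass
class SmoothingSpec:
    energy_bin_width: float = 0.2  # in kT

    def __post_init__(self) -> None:
        if self.energy_bin_width <= 0:
            raise ValueError("energy_bin_width must be positive")


@dataclass
class ReweightingReport:
    fes: FES
    re_per_bin: np.ndarray  # NaN where undefined (n < 2)
    mean_re: float
    std_re: float


def _bin_index(xi: np.ndarray, width: float) -> np.ndarray:
    """Bins centered on integer multiples of ``width`` (grid aligned with
    the umbrella window centers)."""
    return np.round(np.asarray(xi, float) / width).astype(int)


def fes_from_weights(
    weights: np.ndarray,
    xi: np.ndarray,
    bin_width: float = 0.1,
    temperature: float = 298.0,
) -> FES:
    """F(b) = -kT ln sum_{n in b} w_n, anchored so the occupied minimum is 0.

    Unoccupied bins are NaN and are never interpolated.
    """
    weights = np.asarray(weights, float)
    xi = np.asarray(xi, float)
    idx = _bin_index(xi, bin_width)
    lo, hi = idx.min(), idx.max()
    centers = np.arange(lo, hi + 1) * bin_width
    nbin = hi - lo + 1
    mass = np.zeros(nbin)
    count = np.zeros(nbin, dtype=int)
    np.add.at(mass, idx - lo, weights)
    np.add.at(count, idx - lo, 1)
    kT = kt_kcalmol(temperature)
    with np.errstate(divide="ignore"):
        vals = -kT * np.log(mass)
    vals[mass <= 0.0] = np.nan
    occ = np.isfinite(vals)
    vals[occ] -= np.nanmin(vals[occ])
    return FES(centers, vals, count, bin_width, temperature)


def mbar_fes(
    ensemble: BiasedEnsemble,
    result: MBARResult | None = None,
    bin_width: float = 0.1,
    temperature: float = 298.0,
) -> FES:
    """Unbiased reference-potential FES from MBAR weights."""
    result = result or mbar_solve(ensemble)
    w = np.exp(result.unbiased_log_weights(ensemble.u_ref))
    return fes_from_weights(w, ensemble.xi, bin_width, temperature)


def reweighting_entropy(weights: np.ndarray) -> float:
    """Normalized Shannon entropy -sum w~ ln w~ / ln n of bin weights.

    1 for uniform weights, 0 for a one-hot distribution.  Requires n >= 2
    samples and a nonzero total weight.
    """
    w = np.asarray(weights, float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("reweighting entropy requires >= 2 weights")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative and not all zero")
    wn = w / w.sum()
    nz = wn[wn > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(w.size))


def dos_smoothing(delta_u: np.ndarray, spec: SmoothingSpec) -> np.ndarray:
    """Smoothed perturbation factors for one spatial bin.

    The dimensionless dU values are histogrammed into ``energy_bin_width``
    (kT) energy bins; every sample in an energy bin receives the common
    factor exp(-dU_e), where dU_e = -ln<exp(-dU)>_e is the bin's
    exponential-mean energy.  This replaces exp(-dU_n) sample-wise while
    preserving each energy bin's total weight, so the perturbation estimate
    is untouched and the reweighting entropy can only increase (equalizing
    weights within a group at fixed group mass raises the entropy).
    """
    du = np.asarray(delta_u, float)
    if du.size == 0:
        raise ValueError("empty spatial bin")
    ebin = np.floor(du / spec.energy_bin_width).astype(int)
    ebin -= ebin.min()
    nbins = ebin.max() + 1
    log_mass = np.full(nbins, -np.inf)
    cnts = np.zeros(nbins)
    for b in range(nbins):
        sel = ebin == b
        if sel.any():
            log_mass[b] = logsumexp(-du[sel])
            cnts[b] = sel.sum()
    log_factor = log_mass - np.log(np.maximum(cnts, 1))
    return np.exp(log_factor[ebin])


def _perturbation_report(
    xi: np.ndarray,
    u_ref: np.ndarray,
    log_denominators: np.ndarray,
    delta_u: np.ndarray,
    smoothing: SmoothingSpec | None,
    bin_width: float,
    temperature: float,
) -> ReweightingReport:
    """FES and per-bin RE from target weights exp(-u_ref - dU)/D_n.

    The RE of a bin is the normalized entropy of the perturbation factors
    exp(-dU) (after optional density-of-states smoothing): it is exactly 1
    when the target coincides with the reference and approaches 0 when a
    few samples carry all the perturbation weight.
    """
    delta_u = np.asarray(delta_u, float)
    idx = _bin_index(xi, bin_width)
    log_factors = -delta_u
    if smoothing is not None:
        log_factors = log_factors.copy()
        for b in np.unique(idx):
            sel = idx == b
            log_factors[sel] = np.log(dos_smoothing(delta_u[sel], smoothing))
    log_w = -u_ref - log_denominators + log_factors
    log_w = log_w - logsumexp(log_w)
    fes = fes_from_weights(np.exp(log_w), xi, bin_width, temperature)
    lo = idx.min()
    re = np.full(fes.bin_centers.size, np.nan)
    for b in np.unique(idx):
        sel = idx == b
        if sel.sum() >= 2:
            lf = log_factors[sel]
            re[b - lo] = reweighting_entropy(np.exp(lf - lf.max()))
    finite = np.isfinite(re)
    mean_re = float(np.mean(re[finite])) if finite.any() else float("nan")
    std_re = float(np.std(re[finite])) if finite.any() else float("nan")
    return ReweightingReport(fes, re, mean_re, std_re)


def wtp_estimate(
    ensemble: BiasedEnsemble,
    delta_u: np.ndarray,
    smoothing: SmoothingSpec | None = None,
    result: MBARResult | None = None,
    bin_width: float = 0.1,
    temperature: float = 298.0,
) -> ReweightingReport:
    """Weighted thermodynamic perturbation from one reference's sampling.

    ``delta_u`` is beta (U_target - U_ref) per sample.  Target weights are
    w_n ∝ exp(-beta U_target(x_n)) / D_n; with delta_u identically zero the
    surface equals the MBAR reference surface exactly and every RE is 1.
    """
    result = result or mbar_solve(ensemble)
    delta_u = np.asarray(delta_u, float)
    if delta_u.shape != ensemble.xi.shape:
        raise ValueError("delta_u must have one entry per sample")
    return _perturbation_report(
        ensemble.xi, ensemble.u_ref, result.log_denominators, delta_u,
        smoothing, bin_width, temperature,
    )


def gwtp_estimate(
    ensembles: list[BiasedEnsemble],
    u_target: list[np.ndarray],
    smoothing: SmoothingSpec | None = None,
    bin_width: float = 0.1,
    temperature: float = 298.0,
    u_cross: list[list[np.ndarray]] | None = None,
) -> ReweightingReport:
    """Generalized wTP: pool several reference potentials' sampling.

    ``ensembles[m]`` holds the biased sampling generated under reference
    model m (with ``bias_centers`` and ``bias_kred`` set so its bias can be
    evaluated on other models' samples); ``u_target[m]`` is the reduced
    target potential on m's samples; ``u_cross[m][m2]`` gives reference
    m2's reduced *unbiased* potential on the samples of model m (m2 != m) -
    every model's energy is required on every pooled sample.  One joint
    MBAR over all (model, window) states yields pooled denominators D_n and
    target weights w_n ∝ exp(-beta U_target(x_n)) / D_n.
    """
    M = len(ensembles)
    if len(u_target) != M:
        raise ValueError("need target energies for every reference model")
    if M == 1:
        ens = ensembles[0]
        du = np.asarray(u_target[0], float) - ens.u_ref
        return wtp_estimate(ens, du, smoothing, None, bin_width, temperature)
    if u_cross is None:
        raise ValueError("gwtp with multiple models requires cross energies")
    for ens in ensembles:
        if ens.bias_centers is None or ens.bias_kred is None:
            raise ValueError("pooled gwTP requires bias_centers and bias_kred")
    n_m = [e.xi.size for e in ensembles]
    n_tot = int(np.sum(n_m))
    xi = np.concatenate([e.xi for e in ensembles])
    rows, counts = [], []
    for m, ens in enumerate(ensembles):
        for k in range(ens.u_matrix.shape[0]):
            row = np.empty(n_tot)
            off = 0
            for m2, ens2 in enumerate(ensembles):
                nn = n_m[m2]
                u_unb = ens.u_ref if m2 == m else np.asarray(u_cross[m2][m], float)
                bias = 0.5 * ens.bias_kred * (ens2.xi - ens.bias_centers[k]) ** 2
                row[off : off + nn] = u_unb + bias
                off += nn
            rows.append(row)
            counts.append(ens.counts[k])
    pooled = BiasedEnsemble(
        xi,
        np.array(rows),
        np.array(counts),
        u_ref=np.concatenate([e.u_ref for e in ensembles]),
    )
    result = mbar_solve(pooled)
    du = np.concatenate([np.asarray(u, float) for u in u_target]) - pooled.u_ref
    return _perturbation_report(
        pooled.xi, pooled.u_ref, result.log_denominators, du, smoothing,
        bin_width, temperature,
    )


def average_surfaces(surfaces: list[FES]) -> FES:
    """Per-bin arithmetic mean of surfaces on a common grid, re-anchored."""
    if not surfaces:
        raise ValueError("need at least one surface")
    ref = surfaces[0]
    for s in surfaces[1:]:
        if s.bin_centers.size != ref.bin_centers.size or not np.allclose(
            s.bin_centers, ref.bin_centers, atol=1e-9
        ):
            raise ValueError("surfaces must share a common bin grid")
    vals = np.stack([s.values for s in surfaces])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=0)
    n = np.stack([s.n_samples for s in surfaces]).sum(axis=0)
    occ = np.isfinite(mean)
    if occ.any():
        mean = mean - np.nanmin(mean[occ])
    return FES(ref.bin_centers.copy(), mean, n, ref.bin_width, ref.temperature)
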