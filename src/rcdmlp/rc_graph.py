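"""Range-corrected graph construction.

The correction model only touches internal-QM and short-range QM/MM
interactions, which is encoded at the graph level: an edge (i, j) exists iff
|r_i - r_j| <= r_cut and at least one of the pair is a QM atom.  MM-MM edges
are excluded, so an MM atom whose only neighbors are MM atoms appears in no
edge at all.  MM atoms are remapped to a reserved species range (Z + 50) so
their network parameters can differ from the same element in the QM region.

Radial features are Bessel functions under a polynomial envelope that takes
the feature (and its first derivatives) smoothly to zero at the cutoff, which
is what keeps the energy continuous as MM atoms cross r_cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AtomicConfiguration

__all__ = [
    "MM_SPECIES_OFFSET",
    "RadialBasisSpec",
    "EdgeList",
    "map_species",
    "build_edges",
    "candidate_pairs",
    "radial_features",
    "envelope",
]

MM_SPECIES_OFFSET = 50


@dataclass
class RadialBasisSpec:
    """Bessel radial basis with a polynomial cutoff envelope.

    r_cut in Angstrom (default 6), n_bessel basis functions (default 8),
    envelope polynomial order p (default 5).
    """

    r_cut: float = 6.0
    n_bessel: int = 8
    envelope_order: int = 5

    def __post_init__(self) -> None:
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.n_bessel < 1:
            raise ValueError("n_bessel must be >= 1")
        if self.envelope_order < 2:
            raise ValueError("envelope_order must be >= 2")


@dataclass
class EdgeList:
    """Directed edges of the range-corrected graph.

    Both directions of each retained pair are present; displacement is
    r[receiver] - r[sender] in Angstrom.
    """

    pairs: np.ndarray  # (n_edges, 2) int, (sender, receiver)
    displacement: np.ndarray  # (n_edges, 3) float
    distance: np.ndarray  # (n_edges,) float

    @property
    def n_edges(self) -> int:
        return int(self.pairs.shape[0])


def map_species(config: AtomicConfiguration) -> np.ndarray:
    """Species codes: QM atom -> Z, MM atom -> Z + 50."""
    codes = config.species.copy()
    codes[~config.qm_mask] += MM_SPECIES_OFFSET
    return codes


def candidate_pairs(qm_mask: np.ndarray) -> np.ndarray:
    """All directed (sender, receiver) pairs with at least one QM member.

    Distance-independent; the distance filter (or a smooth envelope) is
    applied separately.  Used both by build_edges and by the fixed-topology
    batched model evaluation.
    """
    qm_mask = np.asarray(qm_mask, dtype=bool)
    n = qm_mask.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    keep = (i != j) & (qm_mask[i] | qm_mask[j])
    return np.stack([i[keep], j[keep]], axis=1)


def build_edges(config: AtomicConfiguration, r_cut: float) -> EdgeList:
    """Edge set {(i,j): |r_i - r_j| <= r_cut, i != j, QM in {i,j}}."""
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    pairs = candidate_pairs(config.qm_mask)
    disp = config.positions[pairs[:, 1]] - config.positions[pairs[:, 0]]
    dist = np.linalg.norm(disp, axis=1)
    keep = dist <= r_cut
    return EdgeList(pairs[keep], disp[keep], dist[keep])


def envelope(u: np.ndarray, p: int) -> np.ndarray:
    """Polynomial cutoff envelope on u = r/r_cut, clamped to 0 for u >= 1.

    f(0) = 1, f(1) = 0 with the first p-1 derivatives vanishing at u = 1:
    f(u) = 1 - (p+1)(p+2)/2 u^p + p(p+2) u^(p+1) - p(p+1)/2 u^(p+2).
    """
    u = np.asarray(u, dtype=np.float64)
    f = (
        1.0
        - 0.5 * (p + 1) * (p + 2) * u**p
        + p * (p + 2) * u ** (p + 1)
        - 0.5 * p * (p + 1) * u ** (p + 2)
    )
    return np.where(u < 1.0, f, 0.0)


def radial_features(distance, spec: RadialBasisSpec) -> np.ndarray:
    """Enveloped Bessel features of an interatomic distance.

    feature_n(r) = sqrt(2/r_cut) sin(n pi r / r_cut) / r * f_env(r/r_cut),
    n = 1..n_bessel.  Features and their first derivatives vanish for
    r >= r_cut.  Scalar input gives shape (n_bessel,); array input appends
    the basis axis.
    """
    r = np.asarray(distance, dtype=np.float64)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    scalar = r.ndim == 0
    r = np.atleast_1d(r)[..., None]
    n = np.arange(1, spec.n_bessel + 1, dtype=np.float64)
    rc = spec.r_cut
    feats = np.sqrt(2.0 / rc) * np.sin(n * np.pi * r / rc) / r
    feats = feats * envelope(r / rc, spec.envelope_order)
    return feats[0] if scalar else feats
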