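"""Real spherical harmonics (l <= 3) and real Clebsch-Gordan couplings.

Harmonics follow the standard real convention (no Condon-Shortley phase in
the real components), ordered m = -l..l, orthonormal on the sphere.  The
coupling tensors C^{l1 l2 -> l3} are obtained from the complex CG
coefficients transformed to the real basis; parity-even couplings
(l1+l2+l3 even) are real, parity-odd ones are imaginary, and taking the
imaginary part yields the SO(3)-equivariant real form (e.g. the cross
product for 1 x 1 -> 1).  Everything is computed once and cached.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, _slice_last, mul, stack_last

__all__ = ["real_sph_harm", "real_cg", "allowed_couplings"]

_SQ = np.sqrt


def real_sph_harm(l: int, u) -> Tensor:
    """Real spherical harmonics of unit vectors, traced for autodiff.

    Parameters
    ----------
    l : angular order (0..3)
    u : Tensor of unit vectors, shape (..., 3)

    Returns a Tensor of shape (..., 2l+1), components ordered m = -l..l.
    """
    u = ad.tensor(u)
    x = _slice_last(u, 0)
    y = _slice_last(u, 1)
    z = _slice_last(u, 2)
    pi = np.pi
    if l == 0:
        c = 0.5 * _SQ(1 / pi)
        one = Tensor(np.ones(x.shape))
        return stack_last([mul(c, one)])
    if l == 1:
        c = _SQ(3 / (4 * pi))
        return stack_last([mul(c, y), mul(c, z), mul(c, x)])
    if l == 2:
        c1 = 0.5 * _SQ(15 / pi)
        c2 = 0.25 * _SQ(5 / pi)
        c3 = 0.25 * _SQ(15 / pi)
        return stack_last(
            [
                mul(c1, x * y),
                mul(c1, y * z),
                mul(c2, 3.0 * (z * z) - 1.0),
                mul(c1, x * z),
                mul(c3, x * x - y * y),
            ]
        )
    if l == 3:
        x2, y2, z2 = x * x, y * y, z * z
        return stack_last(
            [
                mul(0.25 * _SQ(35 / (2 * pi)), y * (3.0 * x2 - y2)),
                mul(0.5 * _SQ(105 / pi), x * (y * z)),
                mul(0.25 * _SQ(21 / (2 * pi)), y * (5.0 * z2 - 1.0)),
                mul(0.25 * _SQ(7 / pi), z * (5.0 * z2 - 3.0)),
                mul(0.25 * _SQ(21 / (2 * pi)), x * (5.0 * z2 - 1.0)),
                mul(0.25 * _SQ(105 / pi), z * (x2 - y2)),
                mul(0.25 * _SQ(35 / (2 * pi)), x * (x2 - 3.0 * y2)),
            ]
        )
    raise ValueError("real_sph_harm implemented for l <= 3")


@lru_cache(maxsize=None)
def _complex_cg_table(l1: int, l2: int, l3: int) -> np.ndarray:
    """<l1 m1 l2 m2 | l3 m3> as a dense (2l1+1, 2l2+1, 2l3+1) array."""
    from sympy.physics.quantum.cg import CG as _CG

    out = np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * l3 + 1))
    for i1, m1 in enumerate(range(-l1, l1 + 1)):
        for i2, m2 in enumerate(range(-l2, l2 + 1)):
            m3 = m1 + m2
            if abs(m3) > l3:
                continue
            val = _CG(l1, m1, l2, m2, l3, m3).doit()
            out[i1, i2, m3 + l3] = float(val)
    return out


@lru_cache(maxsize=None)
def _real_basis_matrix(l: int) -> np.ndarray:
    """U with S_{l mu} = sum_m U[mu, m] Y_{l m} (complex -> real)."""
    dim = 2 * l + 1
    U = np.zeros((dim, dim), dtype=complex)
    s2 = 1.0 / np.sqrt(2.0)
    for mu in range(-l, l + 1):
        i = mu + l
        if mu == 0:
            U[i, l] = 1.0
        elif mu > 0:
            U[i, mu + l] = (-1) ** mu * s2
            U[i, -mu + l] = s2
        else:
            m = -mu
            U[i, m + l] = -1j * (-1) ** m * s2
            U[i, -m + l] = 1j * s2
    return U


@lru_cache(maxsize=None)
def real_cg(l1: int, l2: int, l3: int) -> np.ndarray:
    """Real-basis coupling tensor C with shape (2l1+1, 2l2+1, 2l3+1).

    For real-component inputs A_{l1}, B_{l2}, the contraction
    T_{m3} = sum_{m1 m2} C[m1, m2, m3] A_{m1} B_{m2} transforms as order l3
    under rotations.  Returns the zero tensor if the triangle rule fails.
    """
    if not (abs(l1 - l2) <= l3 <= l1 + l2):
        return np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * l3 + 1))
    cg = _complex_cg_table(l1, l2, l3)
    U1 = _real_basis_matrix(l1)
    U2 = _real_basis_matrix(l2)
    U3 = _real_basis_matrix(l3)
    # complex components from real: A^c = U^{-1} A^r = U^dagger A^r
    V1 = U1.conj().T
    V2 = U2.conj().T
    C = np.einsum("Pc,abc,aQ,bR->PQR", U3, cg, V1, V2)
    if (l1 + l2 + l3) % 2 == 0:
        out = np.real(C)
    else:
        out = np.imag(C)
    # transpose to (m1, m2, m3)
    return np.ascontiguousarray(np.transpose(out, (1, 2, 0)))


def allowed_couplings(l_max: int, l_out_max: int):
    """All (l1, l2, l3) with l1, l2 <= l_max, l3 <= l_out_max, triangle rule."""
    out = []
    for l1 in range(l_max + 1):
        for l2 in range(l_max + 1):
            for l3 in range(l_out_max + 1):
                if abs(l1 - l2) <= l3 <= l1 + l2:
                    out.append((l1, l2, l3))
    return out
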