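"""Spherical-spline scalp interpolation and surface Laplacian (CSD).

Implements the classic spherical-spline framework for scalp potentials
(Perrin-style): potentials are expanded in the basis

    g(x) = 1/(4*pi) * sum_{l=1}^{L} (2l+1) / (l(l+1))^m * P_l(x)

where ``x`` is the cosine of the arc between two scalp points, ``P_l`` the
Legendre polynomial of degree l, ``m`` the spline order and ``L`` the series
truncation.  The surface Laplacian of a g-term follows from
``lap P_l(cos g) = -l(l+1) P_l(cos g)`` on the unit sphere.  The current
source density is reported as the negative Laplacian, so a focal positive
potential patch maps to a positive CSD peak with a surrounding sign
inversion.

Defaults: order m=4, 50 series terms, ridge regularisation 1e-5 on the
electrode Gram matrix.
"""

from __future__ import annotations

import numpy as np

DEFAULT_ORDER = 4
DEFAULT_N_TERMS = 50
DEFAULT_REG = 1e-5


def _legendre_factors(m: int, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """Series coefficients for the g (potential) and h (Laplacian) kernels."""
    l = np.arange(1, n_terms + 1, dtype=float)
    g = (2 * l + 1) / (l * (l + 1)) ** m / (4 * np.pi)
    # negative Laplacian: -(-l(l+1)) * g-coefficient
    h = (2 * l + 1) / (l * (l + 1)) ** (m - 1) / (4 * np.pi)
    return g, h


def _legval(cosang: np.ndarray, factors: np.ndarray) -> np.ndarray:
    coefs = np.concatenate([[0.0], factors])  # P_0 excluded
    return np.polynomial.legendre.legval(np.clip(cosang, -1.0, 1.0), coefs)


def _gram(pos_a: np.ndarray, pos_b: np.ndarray, factors: np.ndarray) -> np.ndarray:
    return _legval(pos_a @ pos_b.T, factors)


def _solve_spline(
    pos_from: np.ndarray, order: int, n_terms: int, reg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Factorised spline system for source electrodes.

    Returns ``(C, c0, gfac_hfac)`` where for data ``v`` the spline weights are
    ``c = C @ v`` and the constant term ``c0 = c0row @ v``.
    """
    gfac, hfac = _legendre_factors(order, n_terms)
    n = pos_from.shape[0]
    G = _gram(pos_from, pos_from, gfac)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.vstack([np.eye(n), np.zeros((1, n))])
    sol = np.linalg.solve(A, rhs)
    return sol[:n], sol[n], (gfac, hfac)


def interpolation_matrix(
    pos_from: np.ndarray,
    pos_to: np.ndarray,
    order: int = DEFAULT_ORDER,
    n_terms: int = DEFAULT_N_TERMS,
    reg: float = DEFAULT_REG,
) -> np.ndarray:
    """Matrix mapping potentials at ``pos_from`` to estimates at ``pos_to``.

    Positions are unit-sphere Cartesian coordinates.  The spline reproduces
    spatially constant fields exactly (the constant term is unpenalised).
    """
    C, c0, (gfac, _) = _solve_spline(pos_from, order, n_terms, reg)
    Gto = _gram(pos_to, pos_from, gfac)
    return Gto @ C + np.outer(np.ones(pos_to.shape[0]), c0)


def csd_matrix(
    pos: np.ndarray,
    order: int = DEFAULT_ORDER,
    n_terms: int = DEFAULT_N_TERMS,
    reg: float = DEFAULT_REG,
) -> np.ndarray:
    """Linear operator taking scalp potentials to current source density.

    CSD is the negative spherical-spline surface Laplacian evaluated at the
    electrode positions; the constant term drops out, so the operator is
    reference-free (rows sum to ~0 contribution from any common offset).
    """
    C, _, (_, hfac) = _solve_spline(pos, order, n_terms, reg)
    H = _gram(pos, pos, hfac)
    return H @ C
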