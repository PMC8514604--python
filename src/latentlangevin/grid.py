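"""Spectral discretization of the latent domain x in [-1, 1].

All continuous functions of the latent coordinate (potential, force,
densities, firing rate) are represented by their values at a set of
Gauss--Lobatto--Legendre (GLL) nodes.  The GLL rule is chosen because it
includes both endpoints, which is required to impose reflecting or
absorbing boundary conditions exactly, while retaining spectral accuracy
for quadrature (exact for polynomials up to degree ``2n - 3``) and
differentiation of smooth functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["Grid", "make_grid", "integrate"]


def _gll_nodes_weights(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and quadrature weights of the n-point Gauss-Lobatto-Legendre rule.

    Interior nodes are the roots of P'_{n-1}; weights are
    ``w_i = 2 / (n (n-1) P_{n-1}(x_i)^2)``.
    """
    # coefficients of P_{n-1} in the Legendre basis
    c = np.zeros(n)
    c[-1] = 1.0
    dc = npleg.legder(c)
    interior = npleg.legroots(dc)
    nodes = np.concatenate(([-1.0], np.sort(interior), [1.0]))
    pn = npleg.legval(nodes, c)
    weights = 2.0 / (n * (n - 1) * pn**2)
    return nodes, weights


def _lagrange_diff_matrix(nodes: np.ndarray) -> np.ndarray:
    """Differentiation matrix of the Lagrange interpolant through ``nodes``."""
    n = len(nodes)
    diff = nodes[:, None] - nodes[None, :]
    np.fill_diagonal(diff, 1.0)
    # barycentric weights
    bary = 1.0 / np.prod(diff, axis=1)
    D = np.empty((n, n))
    for i in range(n):
        D[i, :] = (bary / bary[i]) / diff[i, :]
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(D, -D.sum(axis=1))
    return D


@dataclass(frozen=True)
class Grid:
    """GLL discretization of [-1, 1].

    Attributes
    ----------
    nodes : (n,) array
        Strictly increasing, ``nodes[0] == -1``, ``nodes[-1] == +1``.
    quad_weights : (n,) array
        Positive quadrature weights; sum to 2 (the domain length).
    diff_matrix : (n, n) array
        Maps nodal values of a function to nodal values of its derivative.
    """

    nodes: np.ndarray
    quad_weights: np.ndarray
    diff_matrix: np.ndarray
    antideriv_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def n_points(self) -> int:
        return len(self.nodes)

    def integrate(self, values: np.ndarray) -> float:
        """Quadrature approximation of the integral of ``values`` over [-1, 1]."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_points:
            raise ValueError(
                f"expected {self.n_points} nodal values, got {values.shape[-1]}"
            )
        return values @ self.quad_weights

    def derivative(self, values: np.ndarray) -> np.ndarray:
        """Nodal values of the derivative of the interpolant of ``values``."""
        return self.diff_matrix @ np.asarray(values)

    def antiderivative(self, values: np.ndarray) -> np.ndarray:
        """Nodal values of x -> integral from -1 to x of the interpolant."""
        return self.antideriv_matrix @ np.asarray(values)

    def interpolate(self, values: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Evaluate the interpolating polynomial of nodal ``values`` at ``x``."""
        coef = np.linalg.solve(
            npleg.legvander(self.nodes, self.n_points - 1), np.asarray(values)
        )
        return npleg.legval(np.asarray(x), coef)

    def delta(self, x0: float) -> np.ndarray:
        """Discrete Dirac delta at the node nearest ``x0``.

        The quadrature-dual convention: value ``1/w_j`` at the nearest node j,
        zero elsewhere, so that the vector integrates to 1.
        """
        j = int(np.argmin(np.abs(self.nodes - x0)))
        v = np.zeros(self.n_points)
        v[j] = 1.0 / self.quad_weights[j]
        return v


def make_grid(n_points: int) -> Grid:
    """Build the n-point GLL grid on [-1, 1].

    ``n_points`` below 8 is rejected: the discretized Fokker-Planck
    operators are meaningless at coarser resolution.
    """
    if n_points < 8:
        raise ValueError(f"n_points must be >= 8, got {n_points}")
    nodes, weights = _gll_nodes_weights(n_points)
    D = _lagrange_diff_matrix(nodes)
    # spectral antiderivative: interpolate -> integrate Legendre coefficients
    # -> evaluate at the nodes (zero at x = -1 by construction)
    V = npleg.legvander(nodes, n_points - 1)
    Vinv = np.linalg.solve(V, np.eye(n_points))
    n = n_points
    int_coef = np.zeros((n + 1, n))
    for j in range(n):
        cj = np.zeros(n)
        cj[j] = 1.0
        int_coef[:, j] = npleg.legint(cj, lbnd=-1.0)
    S = npleg.legvander(nodes, n) @ int_coef @ Vinv
    return Grid(
        nodes=nodes, quad_weights=weights, diff_matrix=D, antideriv_matrix=S
    )


def integrate(grid: Grid, values: np.ndarray) -> float:
    """Module-level alias for :meth:`Grid.integrate`."""
    return grid.integrate(values)
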