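"""Discretized Fokker-Planck operators, propagators, and the absorption operator.

The density of the latent Langevin process obeys

    dp/dt = (-D d/dx F(x) + D d^2/dx^2) p  ==  -H0 p,

and between spike observations the un-normalized filtering density obeys
the modified equation with the spike sink, ``dp/dt = -(H0 + f(x)) p == -H p``.

Discretization.  Writing ``-H0 p = D d/dx [exp(-Phi) d/dx (exp(Phi) p)]``
and substituting ``q = exp(Phi/2) p`` turns H0 into an operator that is
symmetric under the quadrature inner product.  We assemble its weak
(Galerkin) form on the GLL grid with the diagonal (lumped) mass matrix
``M = diag(w)``:

    H0_sym = D R (Dx^T diag(w exp(-Phi)) Dx) R,   R = diag(exp(Phi/2)/sqrt(w)),

which is symmetric positive semi-definite, so its eigendecomposition is
real and the propagator ``exp(-H t)`` is evaluated in closed form per
time interval.  Boundary conditions: the weak form with boundary terms
dropped imposes zero probability flux (reflecting / Neumann) naturally;
absorbing (Dirichlet) conditions delete the boundary rows and columns.
The similarity transform is diagonal, so the spike sink remains
``diag(f)`` in the symmetrized frame and ``H - H0 = diag(f)`` exactly.

The absorption operator applied at the end of a reaction-time trial is
H0 itself: ``integral (H0 p) dx`` is the instantaneous probability flux
through the absorbing boundaries (minus the time derivative of the total
surviving mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .model import ABSORBING, REFLECTING, LatentModel

__all__ = [
    "OperatorBundle",
    "build_operators",
    "propagate",
    "equilibrium_density",
    "absorption_rate",
]


def sym_pieces(model: LatentModel):
    """Ingredients of the symmetrized operator: (m, r, active index).

    ``H0_sym = D * R (Dx^T diag(m) Dx) R`` with ``m = w exp(-Phi)`` and
    ``R = diag(r)``, ``r = exp(Phi/2)/sqrt(w)``; ``active`` indexes the
    nodes the operator acts on (interior only for absorbing conditions).
    """
    w = model.grid.quad_weights
    m = w * np.exp(-model.potential)
    r = np.exp(0.5 * model.potential) / np.sqrt(w)
    n = model.grid.n_points
    if model.boundary_mode == ABSORBING:
        active = np.arange(1, n - 1)
    else:
        active = np.arange(n)
    return m, r, active


@dataclass
class OperatorBundle:
    """Discretized H0 and H with cached spectral factorizations.

    For absorbing boundary conditions the matrices act on the interior
    nodes only (``active``); densities are restricted/embedded by the
    propagation helpers.  ``to_sym``/``from_sym`` are the diagonal
    similarity vectors mapping densities p to symmetrized coordinates
    ``s = to_sym * p`` on the active nodes.
    """

    model: LatentModel
    active: np.ndarray
    H0_sym: np.ndarray
    H_sym: np.ndarray
    eig_H0: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    eig_H: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    to_sym: np.ndarray = field(repr=False, default=None)
    from_sym: np.ndarray = field(repr=False, default=None)

    @property
    def boundary_mode(self) -> str:
        return self.model.boundary_mode

    @property
    def H0(self) -> np.ndarray:
        """H0 acting on nodal densities (active nodes)."""
        return (self.from_sym[:, None] * self.H0_sym) * self.to_sym[None, :]

    @property
    def H(self) -> np.ndarray:
        """H = H0 + diag(f) acting on nodal densities (active nodes)."""
        return self.H0 + np.diag(self.model.rate_fn[self.active])

    # -- state transport -------------------------------------------------
    def restrict(self, density: np.ndarray) -> np.ndarray:
        return np.asarray(density, dtype=float)[self.active]

    def embed(self, values: np.ndarray) -> np.ndarray:
        full = np.zeros(self.model.grid.n_points)
        full[self.active] = values
        return full

    def mass(self, density: np.ndarray) -> float:
        """Total probability of a full-grid nodal density."""
        return self.model.grid.integrate(density)

    def _exp_apply(self, eig, s: np.ndarray, dt: float) -> np.ndarray:
        lam, U = eig
        return U @ (np.exp(-lam * dt) * (U.T @ s))


def build_operators(model: LatentModel) -> OperatorBundle:
    """Assemble and factorize H0 and H for ``model``.

    Reflecting mode: H0 has an exact zero mode (the equilibrium density)
    and conserves probability.  Absorbing mode: H0 is positive definite
    and the total mass strictly decays.
    """
    if model.noise < 0:
        raise ValueError("noise magnitude D must be >= 0")
    grid = model.grid
    Dx = grid.diff_matrix
    m, r, active = sym_pieces(model)
    Mid = Dx.T @ (m[:, None] * Dx)
    H0s_full = model.noise * (r[:, None] * Mid * r[None, :])
    H0s = H0s_full[np.ix_(active, active)]
    H0s = 0.5 * (H0s + H0s.T)
    Hs = H0s + np.diag(model.rate_fn[active])
    lam0, U0 = scipy.linalg.eigh(H0s)
    lam, U = scipy.linalg.eigh(Hs)
    sw = np.sqrt(grid.quad_weights[active])
    e_half = np.exp(0.5 * model.potential[active])
    return OperatorBundle(
        model=model,
        active=active,
        H0_sym=H0s,
        H_sym=Hs,
        eig_H0=(lam0, U0),
        eig_H=(lam, U),
        to_sym=sw * e_half,
        from_sym=1.0 / (sw * e_half),
    )


def propagate(
    bundle: OperatorBundle,
    density: np.ndarray,
    dt: float,
    which: str = "H",
) -> np.ndarray:
    """Return ``exp(-H dt) density`` (or ``exp(-H0 dt)``) on the full grid.

    Linear in ``density``; for absorbing conditions, boundary values of
    the input are ignored (they are outside the Dirichlet subspace) and
    the output carries zeros there.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if which not in ("H", "H0"):
        raise ValueError("which must be 'H' or 'H0'")
    eig = bundle.eig_H if which == "H" else bundle.eig_H0
    s = bundle.to_sym * bundle.restrict(density)
    s = bundle._exp_apply(eig, s, dt)
    return bundle.embed(bundle.from_sym * s)


def equilibrium_density(model: LatentModel) -> np.ndarray:
    """Equilibrium density p_eq(x) proportional to exp(-Phi), normalized."""
    p = np.exp(-model.potential)
    return p / model.grid.integrate(p)


def absorption_rate(bundle: OperatorBundle, density: np.ndarray) -> float:
    """Instantaneous probability flux through both absorbing boundaries.

    Evaluates ``integral (A rho) dx`` with the absorption operator
    ``A = H0``; equals ``-d/dt`` of the total surviving mass under H0.
    Only defined for absorbing boundary conditions (under reflecting
    conditions there is no absorption term).
    """
    if bundle.boundary_mode != ABSORBING:
        raise ValueError("absorption_rate requires absorbing boundary conditions")
    s = bundle.to_sym * bundle.restrict(density)
    u = bundle.model.grid.quad_weights[bundle.active] * bundle.from_sym
    return float(u @ (bundle.H0_sym @ s))
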