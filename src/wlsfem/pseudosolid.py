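"""Pseudosolid (least-squares compressible elasticity) mesh motion.

The deforming fluid mesh is treated as a fictitious compressible elastic solid,
lam * grad(div u) + lap u = 0, rewritten first order with the displacement
gradient U = grad u:

    U - grad u                  = 0
    lam * grad(tr U) + div U    = 0
    curl U (row-wise)           = 0

minimized together with the weighted boundary misfit (1/h)||u - g_u||^2.  The
solve is linear least squares: one normal-equation solve.  Each time step is
solved on the REST mesh with the cumulative boundary displacement (total
Lagrangian), which avoids accumulating mesh distortion; the mesh velocity is the
backward difference of node positions, consistent with the backward Euler flow
discretization, and is handed to the flow solver as the ALE convective
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from . import backend
from .geometry import Mesh


@dataclass
class PseudosolidState:
    """Nodal displacement u and displacement gradient U over the mesh."""

    u: np.ndarray                 # (N, dim)
    U: np.ndarray                 # (N, dim, dim)
    lambda_coeff: float = 1.0
    functional_value: float | None = None
    breakdown: dict = field(default_factory=dict)

    def pack(self) -> np.ndarray:
        N, dim = self.u.shape
        return np.hstack([self.u, self.U.reshape(N, dim * dim)]).ravel()

    @classmethod
    def unpack(cls, x: np.ndarray, mesh: Mesh, lam: float) -> "PseudosolidState":
        dim = mesh.dim
        ndpn = dim + dim * dim
        arr = x.reshape(mesh.n_nodes, ndpn)
        return cls(arr[:, :dim].copy(),
                   arr[:, dim:].reshape(mesh.n_nodes, dim, dim).copy(), lam)


@dataclass
class DeformedMesh:
    """A displaced copy of a base mesh plus the nodal mesh velocity."""

    base: Mesh
    mesh: Mesh
    mesh_velocity: np.ndarray


def _ndpn(dim: int) -> int:
    return dim + dim * dim


def _field_offsets(dim: int) -> dict[str, slice]:
    return {"u": slice(0, dim), "U": slice(dim, dim + dim * dim)}


class InteriorElasticityTerm:
    """Interior residual rows of the first-order elasticity system."""

    name = "elasticity_interior"

    def __init__(self, mesh: Mesh, lam: float):
        self.mesh = mesh
        self.lam = lam
        dim = mesh.dim
        self.ndpn = _ndpn(dim)
        self.n_dof_per_node = self.ndpn
        conn = mesh.elements
        self.gdofs = (conn[:, :, None] * self.ndpn
                      + np.arange(self.ndpn)[None, None, :]).reshape(conn.shape[0], -1)
        ncurl = dim * (1 if dim == 2 else 3)
        self.families = (["gradient_def"] * (dim * dim) + ["equilibrium"] * dim
                         + ["curl_U"] * ncurl)

    def _eval(self, x):
        mesh, lam = self.mesh, self.lam
        dim, ndpn = mesh.dim, self.ndpn
        _, wdet, N, G = mesh.element_quadrature()
        E, nq, nn, _ = G.shape
        xe = x.reshape(mesh.n_nodes, ndpn)[mesh.elements]
        xu = xe[:, :, :dim]
        xU = xe[:, :, dim:]                                      # (E, nn, dim*dim)
        Uq = np.einsum("qn,enm->eqm", N, xU).reshape(E, nq, dim, dim)
        gu = np.einsum("eqnk,eni->eqik", G, xu)
        gU = np.einsum("eqnk,enm->eqmk", G, xU).reshape(E, nq, dim, dim, dim)
        # gU[e,q,i,k,l] = d U_ik / d x_l
        nr = len(self.families)
        R = np.zeros((E, nq, nr))
        J = np.zeros((E, nq, nr, nn, ndpn))
        Nb = np.broadcast_to(N[None, :, :], (E, nq, nn))
        row = 0
        # U - grad u
        for i in range(dim):
            for k in range(dim):
                R[:, :, row] = Uq[:, :, i, k] - gu[:, :, i, k]
                J[:, :, row, :, dim + i * dim + k] = Nb
                J[:, :, row, :, i] = -G[:, :, :, k]
                row += 1
        # lam grad(tr U) + div U
        for i in range(dim):
            R[:, :, row] = lam * sum(gU[:, :, k, k, i] for k in range(dim)) \
                + sum(gU[:, :, i, k, k] for k in range(dim))
            for k in range(dim):
                J[:, :, row, :, dim + k * dim + k] += lam * G[:, :, :, i]
                J[:, :, row, :, dim + i * dim + k] += G[:, :, :, k]
            row += 1
        # row-wise curl of U
        for i in range(dim):
            if dim == 2:
                R[:, :, row] = gU[:, :, i, 1, 0] - gU[:, :, i, 0, 1]
                J[:, :, row, :, dim + i * dim + 1] += G[:, :, :, 0]
                J[:, :, row, :, dim + i * dim + 0] += -G[:, :, :, 1]
                row += 1
            else:
                from .fosls import _levi_civita
                eps = _levi_civita()
                for a in range(3):
                    R[:, :, row] = sum(eps[a, k, l] * gU[:, :, i, l, k]
                                       for k in range(3) for l in range(3)
                                       if eps[a, k, l] != 0)
                    for k in range(3):
                        for l in range(3):
                            if eps[a, k, l] != 0:
                                J[:, :, row, :, dim + i * dim + l] += \
                                    eps[a, k, l] * G[:, :, :, k]
                    row += 1
        return R, J, wdet

    def contributions(self, x, want_jac=True):
        R, J, wdet = self._eval(x)
        E, nq, nr = R.shape
        nn = self.mesh.nodes_per_element
        w = np.repeat(wdet[:, :, None], nr, axis=2).reshape(E, nq * nr)
        yield (self.gdofs, J.reshape(E, nq * nr, nn * self.ndpn),
               R.reshape(E, nq * nr), w)

    def residual_batches(self, x):
        R, _, wdet = self._eval(x)
        fams = {}
        for i, fam in enumerate(self.families):
            fams.setdefault(fam, []).append(i)
        for fam, idx in fams.items():
            yield fam, R[:, :, idx], wdet[:, :, None]


class BoundaryDisplacementTerm:
    """(1/h) ||u - g_u||^2 over one tagged boundary surface."""

    name = "boundary_displacement"

    def __init__(self, mesh: Mesh, tag: str, g: Callable[[np.ndarray], np.ndarray]):
        self.mesh = mesh
        self.tag = tag
        self.g = g
        dim = mesh.dim
        self.ndpn = _ndpn(dim)
        self.n_dof_per_node = self.ndpn
        facets, xq, wq, N, normals, h = mesh.facet_quadrature(tag)
        self.fnodes = np.array([f.nodes for f in facets])
        self.xq, self.wq, self.N, self.h = xq, wq, N, h

    def _eval(self, x):
        dim = self.mesh.dim
        F, nqf, fn = self.xq.shape[0], self.xq.shape[1], self.fnodes.shape[1]
        g = np.array([np.asarray(self.g(self.xq[f]), dtype=float) for f in range(F)])
        gdofs = (self.fnodes[:, :, None] * self.ndpn
                 + np.arange(dim)[None, None, :]).reshape(F, fn * dim)
        xu = x.reshape(-1, self.ndpn)[self.fnodes][:, :, :dim]
        uq = np.einsum("qn,fni->fqi", self.N, xu)
        R = (uq - g.reshape(F, nqf, dim)).reshape(F, nqf * dim)
        J = np.zeros((F, nqf, dim, fn, dim))
        for i in range(dim):
            J[:, :, i, :, i] = self.N[None, :, :]
        J = J.reshape(F, nqf * dim, fn * dim)
        w = np.repeat(self.wq[:, :, None], dim, axis=2).reshape(F, nqf * dim) \
            / self.h[:, None]
        return gdofs, J, R, w

    def contributions(self, x, want_jac=True):
        yield self._eval(x)

    def residual_batches(self, x):
        _, _, R, w = self._eval(x)
        yield self.name, R, w


def solve_pseudosolid(mesh: Mesh,
                      boundary_displacement: dict[str, Callable | np.ndarray],
                      lambda_coeff: float = 1.0,
                      solver_opts: dict | None = None) -> PseudosolidState:
    """Minimize the elasticity functional for prescribed boundary displacement.

    ``boundary_displacement`` maps every boundary tag that carries data to a
    function g_u(points) -> (m, dim) (or a constant vector); tags not listed are
    natural (traction-free in the least-squares sense).  This is a linear
    least-squares problem: one normal-equation solve.
    """
    dim = mesh.dim
    terms = [InteriorElasticityTerm(mesh, lambda_coeff)]
    for tag, g in boundary_displacement.items():
        if not callable(g):
            vec = np.asarray(g, dtype=float)
            g = (lambda v: (lambda pts: np.broadcast_to(v, (pts.shape[0], dim)).copy()))(vec)
        terms.append(BoundaryDisplacementTerm(mesh, tag, g))
    x0 = np.zeros(mesh.n_nodes * _ndpn(dim))
    system = backend.assemble_normal_system(terms, x0, _ndpn(dim), _field_offsets(dim))
    opts = {"tol": 1e-12}
    opts.update(solver_opts or {})
    x, _ = backend.solve_spd(system, **opts)
    state = PseudosolidState.unpack(x, mesh, lambda_coeff)
    G, bd = backend.evaluate_functional(terms, x)
    state.functional_value = G
    state.breakdown = bd
    return state


def apply_displacement(mesh: Mesh, state: PseudosolidState, dt: float,
                       prev_u: np.ndarray | None = None) -> DeformedMesh:
    """Move the mesh nodes by the displacement field and compute mesh velocity.

    ``mesh`` is the rest (reference) mesh; ``prev_u`` the total displacement at
    the previous time level (zero if omitted).  mesh_velocity = (u - prev_u)/dt.
    Any nonpositive element Jacobian is a hard failure naming the worst element.
    """
    moved = mesh.copy()
    moved.nodes = mesh.nodes + state.u
    moved.invalidate()
    minJ = moved.check_jacobians()
    if minJ <= 0:
        vols = []
        try:
            _, wdet, _, _ = moved.element_quadrature()
            worst = int(np.argmin(wdet.min(axis=1)))
        except ValueError as err:
            raise ValueError(f"mesh tangling after displacement: {err}") from err
        raise ValueError(
            f"mesh tangling: nonpositive Jacobian (min {minJ:.3e}), "
            f"worst element {worst}")
    prev = np.zeros_like(state.u) if prev_u is None else prev_u
    vel = (state.u - prev) / dt
    return DeformedMesh(mesh, moved, vel)


# ---------------------------------------------------------------------------
# prescribed boundary motions for the two scenarios
# ---------------------------------------------------------------------------

class FlapMotion:
    """Flap-surface displacement from a table of 5th-order polynomials in y.

    Each table row gives the polynomial coefficients (ascending powers) of the
    horizontal flap deflection at one time; coefficients are interpolated
    linearly between table times.
    """

    def __init__(self, times: np.ndarray, coeffs: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
        if self.times.shape[0] != self.coeffs.shape[0]:
            raise ValueError("times and coefficient rows must match")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("table times must be strictly increasing")

    def _coeffs_at(self, t: float) -> np.ndarray:
        ts = self.times
        if t < ts[0] - 1e-12 or t > ts[-1] + 1e-12:
            raise ValueError(f"time {t} outside flap motion table "
                             f"[{ts[0]}, {ts[-1]}]")
        return np.array([np.interp(t, ts, self.coeffs[:, k])
                         for k in range(self.coeffs.shape[1])])

    def displacement(self, t: float) -> Callable[[np.ndarray], np.ndarray]:
        """Horizontal displacement field of the flap surface at time t."""
        c = self._coeffs_at(t)
        def g(points: np.ndarray) -> np.ndarray:
            points = np.atleast_2d(points)
            dx = np.polynomial.polynomial.polyval(points[:, 1], c)
            out = np.zeros_like(points)
            out[:, 0] = dx
            return out
        return g

    def rate(self, t: float, dt: float) -> Callable[[np.ndarray], np.ndarray]:
        """Backward-difference displacement rate (the no-slip velocity g1)."""
        c1 = self._coeffs_at(t)
        c0 = self._coeffs_at(max(t - dt, self.times[0]))
        c = (c1 - c0) / dt
        def g(points: np.ndarray, time: float | None = None) -> np.ndarray:
            points = np.atleast_2d(points)
            out = np.zeros_like(points)
            out[:, 0] = np.polynomial.polynomial.polyval(points[:, 1], c)
            return out
        return g


class LVWallMotion:
    """Half-ellipsoid wall motion matched to an ejection fraction.

    The cavity (semi-axes a, b, c; base plane z = 0 fixed; apex at z = -c) is
    deformed by the smooth family

        X = (x (1 + g z/c),  y (1 + g z/c),  z (1 + beta g z/c)),

    which keeps every base-plane point exactly fixed and contracts the wall
    radially with depth.  The amplitude g(t) is found by solving (closed-form
    polynomial quadrature + root finding) for the cavity volume
    V(g) = V_ED (1 - EF * phase(t)), so at end systole (phase = 1) the volume
    change equals the ejection fraction times the end-diastolic volume.
    """

    def __init__(self, semi_axes, ejection_fraction: float,
                 phase: Callable[[float], float], beta: float = 0.5):
        if not 0 < ejection_fraction < 1:
            raise ValueError("ejection fraction must be in (0, 1)")
        self.a, self.b, self.c = (float(s) for s in semi_axes)
        self.ef = ejection_fraction
        self.phase = phase
        self.beta = beta

    def rest_volume(self) -> float:
        return 2.0 / 3.0 * np.pi * self.a * self.b * self.c

    def volume(self, gamma: float) -> float:
        """Cavity volume of the deformed half-ellipsoid (exact quadrature)."""
        # V = pi a b c * int_{-1}^{0} (1+g z)^2 (1+2 beta g z) (1 - z^2) dz
        P = np.polynomial.Polynomial
        integrand = (P([1.0, gamma]) ** 2 * P([1.0, 2.0 * self.beta * gamma])
                     * P([1.0, 0.0, -1.0]))
        anti = integrand.integ()
        return float(np.pi * self.a * self.b * self.c * (anti(0.0) - anti(-1.0)))

    def gamma_at(self, t: float) -> float:
        target = self.rest_volume() * (1.0 - self.ef * float(self.phase(t)))
        if abs(target - self.rest_volume()) < 1e-14 * self.rest_volume():
            return 0.0
        return brentq(lambda g: self.volume(g) - target, 0.0, 0.999)

    def displacement(self, t: float) -> Callable[[np.ndarray], np.ndarray]:
        """Wall displacement field at time t (zero on the base plane z = 0)."""
        g = self.gamma_at(t)
        c, beta = self.c, self.beta
        def gu(points: np.ndarray) -> np.ndarray:
            points = np.atleast_2d(points)
            z = points[:, 2]
            f = g * z / c
            out = np.zeros_like(points)
            out[:, 0] = points[:, 0] * f
            out[:, 1] = points[:, 1] * f
            out[:, 2] = beta * z * f
            return out
        return gu

    def rate(self, t: float, dt: float) -> Callable[[np.ndarray], np.ndarray]:
        """Backward-difference wall velocity (the no-slip g1 on the wall)."""
        g1 = self.displacement(t)
        g0 = self.displacement(max(t - dt, 0.0))
        def gv(points: np.ndarray, time: float | None = None) -> np.ndarray:
            return (g1(points) - g0(points)) / dt
        return gv


def flap_surface_motion(times, coeffs) -> FlapMotion:
    """Flap displacement driver from a polynomial coefficient table."""
    return FlapMotion(times, coeffs)


def lv_wall_motion(semi_axes, ejection_fraction, phase, beta: float = 0.5
                   ) -> LVWallMotion:
    """Ventricle wall-motion driver scaled to the ejection fraction."""
    return LVWallMotion(semi_axes, ejection_fraction, phase, beta)
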