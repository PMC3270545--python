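"""First-order velocity-vorticity-total-pressure reformulation of the
incompressible Navier-Stokes equations, its weighted least-squares functional,
and the Gauss-Newton solver.

The momentum scaling keeps the Reynolds number on both the inertial and viscous
terms:  Re (dv/dt + v.grad v) = -grad p + (1/Re) lap v.  New unknowns are the
vorticity  omega = -curl v  and the total-pressure gradient
r = grad p + (Re/2) grad |v|^2, giving the first-order system

    curl v + omega                                   = 0
    div v                                            = 0
    (1/Re) curl omega - r - Re (v x omega + dv/dt)   = 0
    div omega                                        = 0      (3D only)
    curl r                                           = 0
    div r - Re |omega|^2 - c (v.r) - c' v.(dv/dt)    = 0

with the divergence-of-momentum closure in the last line; see
``pressure_link``.  On a moving mesh the convective velocity in ``v x omega``
is ``v - v_mesh`` (ALE correction).  All unknowns share the quadratic nodal
basis; there is no inf-sup condition to satisfy.

In 2D the vorticity is scalar, ``curl v`` is the scalar curl, ``curl omega``
is the rotated gradient (d omega/dy, -d omega/dx), ``v x omega`` means
``omega (v2, -v1)``, and the ``div omega`` equation is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import backend
from .geometry import Mesh, evaluate_field

#: coefficient of v.r in the last equation: "consistent" uses Re^2 as obtained
#: by taking the divergence of the momentum equation (exact solutions then
#: satisfy the equation at any Re); "verbatim" uses Re as commonly printed;
#: "off" drops the equation.
PRESSURE_LINK_MODES = ("consistent", "verbatim", "off")


def n_vorticity_components(dim: int) -> int:
    return 1 if dim == 2 else 3


def n_dof_per_node(dim: int) -> int:
    return 2 * dim + n_vorticity_components(dim)


def field_offsets(dim: int) -> dict[str, slice]:
    nw = n_vorticity_components(dim)
    return {"v": slice(0, dim), "omega": slice(dim, dim + nw),
            "r": slice(dim + nw, 2 * dim + nw)}


# ---------------------------------------------------------------------------
# state / problem containers
# ---------------------------------------------------------------------------

@dataclass
class FlowState:
    """Nodal fields (v, omega, r) at one time level."""

    v: np.ndarray
    omega: np.ndarray
    r: np.ndarray
    t: float = 0.0
    functional_value: float | None = None
    breakdown: dict = field(default_factory=dict)
    converged: bool = True
    iterations: int = 0

    def __post_init__(self):
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim == 1:
            self.omega = self.omega[:, None]
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        if not (np.all(np.isfinite(self.v)) and np.all(np.isfinite(self.omega))
                and np.all(np.isfinite(self.r))):
            raise ValueError("flow state contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.v.shape[1]

    @classmethod
    def zero(cls, mesh: Mesh, t: float = 0.0) -> "FlowState":
        nw = n_vorticity_components(mesh.dim)
        return cls(np.zeros((mesh.n_nodes, mesh.dim)), np.zeros((mesh.n_nodes, nw)),
                   np.zeros((mesh.n_nodes, mesh.dim)), t=t)

    def pack(self) -> np.ndarray:
        return np.hstack([self.v, self.omega, self.r]).ravel()

    @classmethod
    def unpack(cls, x: np.ndarray, mesh: Mesh, t: float = 0.0) -> "FlowState":
        dim = mesh.dim
        nw = n_vorticity_components(dim)
        arr = x.reshape(mesh.n_nodes, n_dof_per_node(dim))
        return cls(arr[:, :dim].copy(), arr[:, dim:dim + nw].copy(),
                   arr[:, dim + nw:].copy(), t=t)


@dataclass
class BoundarySpec:
    """Weak boundary data: tag, constrained field, data function g(x, t), weight.

    ``fieldname`` is "velocity" (the w_Gamma/h term) or "normal_vorticity"
    (the 1/h vorticity term, 3D only: the scalar 2D vorticity has no normal
    trace equation).
    """

    tag: str
    fieldname: str
    g: Callable[[np.ndarray, float], np.ndarray]
    w: float = 1.0

    def __post_init__(self):
        if self.w < 0:
            raise ValueError("boundary weight must be nonnegative")
        if self.fieldname not in ("velocity", "normal_vorticity"):
            raise ValueError(f"unknown constrained field {self.fieldname!r}")


@dataclass
class FlowProblem:
    """A weighted least-squares flow problem on one mesh at one time level."""

    mesh: Mesh
    Re: float
    dt: float | None = None
    time: float = 0.0
    boundary_specs: list[BoundarySpec] = field(default_factory=list)
    piv_terms: list = field(default_factory=list)   # data_assimilation.PIVTerm
    prev_state: FlowState | None = None
    mesh_velocity: np.ndarray | None = None
    pressure_link: str = "consistent"
    stokes_limit: bool = False
    solver_opts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.Re <= 0:
            raise ValueError("Reynolds number must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("time step must be positive for transient problems")
        if self.pressure_link not in PRESSURE_LINK_MODES:
            raise ValueError(f"pressure_link must be one of {PRESSURE_LINK_MODES}")

    def validate(self):
        if self.dt is not None and self.prev_state is None:
            raise ValueError("transient problem (finite dt) requires prev_state")


# ---------------------------------------------------------------------------
# pointwise residuals (contract operation; also the cross-check for assembly)
# ---------------------------------------------------------------------------

def _nonlinear_coeffs(Re: float, mode: str, stokes_limit: bool):
    """Closure-row coefficients (s, c_w, c_vr, c_vt) of
    s * div(r) - c_w |omega|^2 - c_vr (v.r) - c_vt v.(dv/dt).

    The consistent form (divergence of the momentum equation) is
    div r - Re |omega|^2 - Re^2 v.r - Re^3 v.dv/dt = 0, normalized here by
    1/Re^2 so the row stays commensurate with the momentum row at high Re (a
    least-squares row weighting; the equation's zero set is unchanged).  The
    verbatim form is kept exactly as commonly printed.
    """
    if mode == "consistent":
        s = 1.0 / Re ** 2
        if stokes_limit:
            return s, 0.0, 0.0, 0.0
        return s, 1.0 / Re, 1.0, Re
    if stokes_limit or mode == "off":
        return 1.0, 0.0, 0.0, 0.0
    return 1.0, Re, Re, 0.0  # verbatim


def residual_algebra(dim: int, Re: float, v, gv, om, gom, r, gr,
                     vc=None, tder=None, pressure_link: str = "consistent",
                     stokes_limit: bool = False) -> dict[str, np.ndarray]:
    """Pointwise residuals of the first-order system from field values/gradients.

    ``gv[i, k] = d v_i / d x_k`` etc.; ``vc`` is the convective velocity
    (``v`` minus the mesh velocity; defaults to v) and ``tder`` the material
    velocity time derivative (defaults to zero = steady).  This pure algebra is
    shared by the finite element path and by analytic-field verification.
    """
    v, gv = np.asarray(v, dtype=float), np.asarray(gv, dtype=float)
    om, gom = np.atleast_1d(np.asarray(om, dtype=float)), np.atleast_2d(gom)
    r, gr = np.asarray(r, dtype=float), np.asarray(gr, dtype=float)
    vc = v if vc is None else np.asarray(vc, dtype=float)
    tder = np.zeros(dim) if tder is None else np.asarray(tder, dtype=float)
    out: dict[str, np.ndarray] = {}
    if dim == 2:
        out["vorticity_def"] = np.array([gv[1, 0] - gv[0, 1] + om[0]])
        out["continuity"] = np.array([gv[0, 0] + gv[1, 1]])
        curl_om = np.array([gom[0, 1], -gom[0, 0]])
        cross = om[0] * np.array([vc[1], -vc[0]])
        curl_r = np.array([gr[1, 0] - gr[0, 1]])
    else:
        eps = _levi_civita()
        curl_v = np.einsum("ikl,lk->i", eps, gv)
        out["vorticity_def"] = curl_v + om
        out["continuity"] = np.array([gv.trace()])
        curl_om = np.einsum("ikl,lk->i", eps, gom)
        cross = np.cross(vc, om)
        out["vorticity_div"] = np.array([gom.trace()])
        curl_r = np.einsum("ikl,lk->i", eps, gr)
    if stokes_limit:
        cross = 0.0 * np.asarray(cross)
    out["momentum"] = curl_om / Re - r - Re * (cross + tder)
    out["pressure_curl"] = curl_r
    s, cw, cr, ct = _nonlinear_coeffs(Re, pressure_link, stokes_limit)
    if pressure_link != "off":
        out["pressure_div"] = np.array(
            [s * gr.trace() - cw * float(om @ om) - cr * float(v @ r)
             - ct * float(v @ tder)])
    return out


def interior_residuals(state: FlowState, Re: float, point: np.ndarray, mesh: Mesh,
                       dt: float | None = None, prev_state: FlowState | None = None,
                       mesh_velocity: np.ndarray | None = None,
                       pressure_link: str = "consistent",
                       stokes_limit: bool = False) -> dict[str, np.ndarray]:
    """Pointwise residuals of the first-order system at one interior point.

    Fields are the finite element interpolants of the state's nodal values; for
    the exact analytic continuation of a Navier-Stokes solution with matching
    omega and r use :func:`exact_interior_residuals`, which avoids interpolation
    error.
    """
    if dt is not None and dt == 0:
        raise ValueError("dt must be positive when a transient term is requested")
    dim = mesh.dim
    v, gv = evaluate_field(mesh, state.v, point)           # gv[i, k] = d v_i / d x_k
    om, gom = evaluate_field(mesh, state.omega, point)
    r, gr = evaluate_field(mesh, state.r, point)
    vm = np.zeros(dim)
    if mesh_velocity is not None:
        vm, _ = evaluate_field(mesh, mesh_velocity, point)
    tder = None
    if dt is not None:
        if prev_state is None:
            raise ValueError("transient residual requires prev_state")
        vprev, _ = evaluate_field(mesh, prev_state.v, point)
        tder = (v - vprev) / dt
    return residual_algebra(dim, Re, v, gv, om, gom, r, gr, vc=v - vm, tder=tder,
                            pressure_link=pressure_link, stokes_limit=stokes_limit)


def exact_interior_residuals(flow, Re: float, point: np.ndarray, t: float = 0.0,
                             transient: bool = False,
                             pressure_link: str = "consistent"
                             ) -> dict[str, np.ndarray]:
    """Residuals evaluated on a flow's exact analytic fields and gradients.

    ``flow`` must provide v/omega/r and grad_v/grad_omega/grad_r (and dvdt when
    ``transient``); all residuals vanish identically for exact solutions.
    """
    pt = np.atleast_2d(np.asarray(point, dtype=float))
    dim = pt.shape[1]
    tder = np.asarray(flow.dvdt(pt, t))[0] if transient else None
    return residual_algebra(
        dim, Re, np.asarray(flow.v(pt, t))[0], np.asarray(flow.grad_v(pt, t))[0],
        np.asarray(flow.omega(pt, t))[0], np.asarray(flow.grad_omega(pt, t))[0],
        np.asarray(flow.r(pt, t))[0], np.asarray(flow.grad_r(pt, t))[0],
        tder=tder, pressure_link=pressure_link)


def _levi_civita() -> np.ndarray:
    eps = np.zeros((3, 3, 3))
    eps[0, 1, 2] = eps[1, 2, 0] = eps[2, 0, 1] = 1.0
    eps[0, 2, 1] = eps[2, 1, 0] = eps[1, 0, 2] = -1.0
    return eps


# ---------------------------------------------------------------------------
# least-squares terms
# ---------------------------------------------------------------------------

class InteriorNSTerm:
    """All interior residual rows of the first-order system, over all elements."""

    name = "interior"

    def __init__(self, problem: FlowProblem):
        self.p = problem
        self.mesh = problem.mesh
        dim = self.mesh.dim
        self.ndpn = n_dof_per_node(dim)
        self.n_dof_per_node = self.ndpn
        mesh = self.mesh
        conn = mesh.elements
        self.gdofs = (conn[:, :, None] * self.ndpn
                      + np.arange(self.ndpn)[None, None, :]).reshape(conn.shape[0], -1)
        # row family labels, for the functional breakdown
        nw = n_vorticity_components(dim)
        fams = ["vorticity_def"] * nw + ["continuity"] + ["momentum"] * dim
        if dim == 3:
            fams += ["vorticity_div"]
        fams += ["pressure_curl"] * nw
        if problem.pressure_link != "off":
            fams += ["pressure_div"]
        self.families = fams

    def _eval(self, x):
        """Residuals R (E, nq, nr) and Jacobian J (E, nq, nr, nn, ndpn)."""
        p, mesh = self.p, self.mesh
        dim, ndpn = mesh.dim, self.ndpn
        nw = n_vorticity_components(dim)
        Re = p.Re
        xq, wdet, N, G = mesh.element_quadrature()
        E, nq, nn = G.shape[0], G.shape[1], G.shape[2]
        xe = x.reshape(mesh.n_nodes, ndpn)[mesh.elements]   # (E, nn, ndpn)
        xv, xo, xr = xe[:, :, :dim], xe[:, :, dim:dim + nw], xe[:, :, dim + nw:]
        v = np.einsum("qn,eni->eqi", N, xv)
        om = np.einsum("qn,eni->eqi", N, xo)
        r = np.einsum("qn,eni->eqi", N, xr)
        gv = np.einsum("eqnk,eni->eqik", G, xv)
        gom = np.einsum("eqnk,eni->eqik", G, xo)
        gr = np.einsum("eqnk,eni->eqik", G, xr)
        vm = np.zeros_like(v)
        if p.mesh_velocity is not None:
            vm = np.einsum("qn,eni->eqi", N, p.mesh_velocity[mesh.elements])
        tder = np.zeros_like(v)
        inv_dt = 0.0
        if p.dt is not None:
            vprev = np.einsum("qn,eni->eqi", N, p.prev_state.v[mesh.elements])
            inv_dt = 1.0 / p.dt
            tder = (v - vprev) * inv_dt
        vc = v - vm
        nr = len(self.families)
        R = np.zeros((E, nq, nr))
        J = np.zeros((E, nq, nr, nn, ndpn))
        cs, cw, cvr, cvt = _nonlinear_coeffs(Re, p.pressure_link, p.stokes_limit)
        nl = 0.0 if p.stokes_limit else 1.0
        Nb = np.broadcast_to(N[None, :, :], (E, nq, nn))
        row = 0
        if dim == 2:
            # curl v + omega
            R[:, :, 0] = gv[:, :, 1, 0] - gv[:, :, 0, 1] + om[:, :, 0]
            J[:, :, 0, :, 0] = -G[:, :, :, 1]
            J[:, :, 0, :, 1] = G[:, :, :, 0]
            J[:, :, 0, :, 2] = Nb
            # div v
            R[:, :, 1] = gv[:, :, 0, 0] + gv[:, :, 1, 1]
            J[:, :, 1, :, 0] = G[:, :, :, 0]
            J[:, :, 1, :, 1] = G[:, :, :, 1]
            # momentum: (1/Re)(dw/dy, -dw/dx) - r - Re(omega*(vc2,-vc1) + tder)
            s = np.stack([vc[:, :, 1], -vc[:, :, 0]], axis=-1)
            R[:, :, 2] = gom[:, :, 0, 1] / Re - r[:, :, 0] \
                - Re * (nl * om[:, :, 0] * s[:, :, 0] + tder[:, :, 0])
            R[:, :, 3] = -gom[:, :, 0, 0] / Re - r[:, :, 1] \
                - Re * (nl * om[:, :, 0] * s[:, :, 1] + tder[:, :, 1])
            J[:, :, 2, :, 2] = G[:, :, :, 1] / Re - Re * nl * s[:, :, 0, None] * Nb
            J[:, :, 3, :, 2] = -G[:, :, :, 0] / Re - Re * nl * s[:, :, 1, None] * Nb
            J[:, :, 2, :, 3] = -Nb
            J[:, :, 3, :, 4] = -Nb
            # d(omega * vc2)/dv2 ; d(-omega * vc1)/dv1
            J[:, :, 2, :, 1] += -Re * nl * om[:, :, 0, None] * Nb
            J[:, :, 3, :, 0] += Re * nl * om[:, :, 0, None] * Nb
            J[:, :, 2, :, 0] += -Re * inv_dt * Nb
            J[:, :, 3, :, 1] += -Re * inv_dt * Nb
            # curl r
            R[:, :, 4] = gr[:, :, 1, 0] - gr[:, :, 0, 1]
            J[:, :, 4, :, 3] = -G[:, :, :, 1]
            J[:, :, 4, :, 4] = G[:, :, :, 0]
            row = 5
        else:
            eps = _levi_civita()
            # curl v + omega (3 rows)
            curl_v = np.einsum("ikl,eqlk->eqi", eps, gv)
            for i in range(3):
                R[:, :, i] = curl_v[:, :, i] + om[:, :, i]
                J[:, :, i, :, dim + i] = Nb
                for k in range(3):
                    for l in range(3):
                        if eps[i, k, l] != 0:
                            J[:, :, i, :, l] += eps[i, k, l] * G[:, :, :, k]
            # div v
            R[:, :, 3] = gv[:, :, 0, 0] + gv[:, :, 1, 1] + gv[:, :, 2, 2]
            for k in range(3):
                J[:, :, 3, :, k] = G[:, :, :, k]
            # momentum
            curl_om = np.einsum("ikl,eqlk->eqi", eps, gom)
            cross = np.cross(vc, om)
            for i in range(3):
                ri = 4 + i
                R[:, :, ri] = curl_om[:, :, i] / Re - r[:, :, i] \
                    - Re * (nl * cross[:, :, i] + tder[:, :, i])
                J[:, :, ri, :, dim + nw + i] = -Nb
                J[:, :, ri, :, i] += -Re * inv_dt * Nb
                for k in range(3):
                    for l in range(3):
                        if eps[i, k, l] != 0:
                            J[:, :, ri, :, dim + l] += eps[i, k, l] * G[:, :, :, k] / Re
                            # d cross_i/dv_k, d cross_i/d omega_l
                            J[:, :, ri, :, k] += -Re * nl * eps[i, k, l] \
                                * om[:, :, l, None] * Nb
                            J[:, :, ri, :, dim + l] += -Re * nl * eps[i, k, l] \
                                * vc[:, :, k, None] * Nb
            # div omega
            R[:, :, 7] = gom[:, :, 0, 0] + gom[:, :, 1, 1] + gom[:, :, 2, 2]
            for k in range(3):
                J[:, :, 7, :, dim + k] = G[:, :, :, k]
            # curl r
            curl_r = np.einsum("ikl,eqlk->eqi", eps, gr)
            for i in range(3):
                ri = 8 + i
                R[:, :, ri] = curl_r[:, :, i]
                for k in range(3):
                    for l in range(3):
                        if eps[i, k, l] != 0:
                            J[:, :, ri, :, dim + nw + l] += eps[i, k, l] * G[:, :, :, k]
            row = 11
        if self.p.pressure_link != "off":
            tr_gr = sum(gr[:, :, k, k] for k in range(dim))
            R[:, :, row] = cs * tr_gr - cw * np.einsum("eqi,eqi->eq", om, om) \
                - cvr * np.einsum("eqi,eqi->eq", v, r) \
                - cvt * np.einsum("eqi,eqi->eq", v, tder)
            nwoff = dim
            roff = dim + nw
            for k in range(dim):
                J[:, :, row, :, roff + k] = cs * G[:, :, :, k] \
                    - cvr * v[:, :, k, None] * Nb
                J[:, :, row, :, k] += -cvr * r[:, :, k, None] * Nb \
                    - cvt * (tder[:, :, k, None] + inv_dt * v[:, :, k, None]) * Nb
            for i in range(nw):
                J[:, :, row, :, nwoff + i] += -2.0 * cw * om[:, :, i, None] * Nb
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
        for i, fam in enumerate(self.families):
            yield fam, R[:, :, i], wdet


class BoundaryMisfitTerm:
    """Weighted boundary misfit (w/h) ||field - g||^2 over one tagged surface."""

    def __init__(self, problem: FlowProblem, spec: BoundarySpec):
        self.p = problem
        self.spec = spec
        self.mesh = problem.mesh
        dim = self.mesh.dim
        self.ndpn = n_dof_per_node(dim)
        self.n_dof_per_node = self.ndpn
        self.name = ("boundary_velocity" if spec.fieldname == "velocity"
                     else "boundary_vorticity")
        if spec.fieldname == "normal_vorticity" and dim == 2:
            raise ValueError("the normal-vorticity boundary term is 3D only")
        facets, xq, wq, N, normals, h = self.mesh.facet_quadrature(spec.tag)
        self.fnodes = np.array([f.nodes for f in facets])        # (F, fn)
        self.xq, self.wq, self.N, self.normals, self.h = xq, wq, N, normals, h

    def _eval(self, x):
        dim = self.mesh.dim
        spec = self.spec
        F, nqf = self.xq.shape[0], self.xq.shape[1]
        fn = self.fnodes.shape[1]
        g = np.array([np.asarray(spec.g(self.xq[f], self.p.time), dtype=float)
                      for f in range(F)])
        wfac = spec.w / self.h                                    # (F,)
        if spec.fieldname == "velocity":
            off = 0
            gdofs = (self.fnodes[:, :, None] * self.ndpn
                     + (off + np.arange(dim))[None, None, :]).reshape(F, fn * dim)
            xe = x.reshape(-1, self.ndpn)[self.fnodes][:, :, off:off + dim]
            vq = np.einsum("qn,fni->fqi", self.N, xe)
            R = (vq - g.reshape(F, nqf, dim)).reshape(F, nqf * dim)
            J = np.zeros((F, nqf, dim, fn, dim))
            for i in range(dim):
                J[:, :, i, :, i] = self.N[None, :, :]
            J = J.reshape(F, nqf * dim, fn * dim)
            w = np.repeat(self.wq[:, :, None], dim, axis=2).reshape(F, nqf * dim) \
                * wfac[:, None]
        else:  # normal vorticity, 3D
            nw = n_vorticity_components(dim)
            off = dim
            gdofs = (self.fnodes[:, :, None] * self.ndpn
                     + (off + np.arange(nw))[None, None, :]).reshape(F, fn * nw)
            xe = x.reshape(-1, self.ndpn)[self.fnodes][:, :, off:off + nw]
            omq = np.einsum("qn,fni->fqi", self.N, xe)
            R = np.einsum("fqi,fqi->fq", omq, self.normals) - g.reshape(F, nqf)
            J = np.einsum("qn,fqi->fqni", self.N, self.normals).reshape(F, nqf, fn * nw)
            w = self.wq * wfac[:, None]
        return gdofs, J.reshape(F, -1, gdofs.shape[1]), R, w

    def contributions(self, x, want_jac=True):
        yield self._eval(x)

    def residual_batches(self, x):
        _, _, R, w = self._eval(x)
        yield self.name, R, w


def build_terms(problem: FlowProblem):
    """The full list of least-squares terms of one flow problem.

    PIV terms with zero weight contribute nothing and are omitted entirely; a
    term whose dataset has no frame at the problem time (time_mode="none") is
    skipped for this step and logged.
    """
    from .assimilation import FrameMissingError, PIVMisfitTerm
    problem.validate()
    terms = [InteriorNSTerm(problem)]
    for spec in problem.boundary_specs:
        if spec.w > 0:
            terms.append(BoundaryMisfitTerm(problem, spec))
    for pt in problem.piv_terms:
        if pt.w_piv > 0:
            try:
                terms.append(PIVMisfitTerm(problem, pt))
            except FrameMissingError:
                logging.getLogger(__name__).info(
                    "no PIV frame at t=%g and interpolation disabled; "
                    "term skipped for this step", problem.time)
    return terms


# ---------------------------------------------------------------------------
# functional, Gauss-Newton, time stepping
# ---------------------------------------------------------------------------

def assemble_functional(problem: FlowProblem, state: FlowState
                        ) -> tuple[float, dict[str, float]]:
    """Value of the least-squares functional G(state) with per-family breakdown.

    The breakdown keys are the interior equation families plus
    ``boundary_velocity``, ``boundary_vorticity`` and ``piv``.
    """
    terms = build_terms(problem)
    return backend.evaluate_functional(terms, state.pack())


def assemble_normal_system(problem: FlowProblem, state: FlowState
                           ) -> backend.NormalSystem:
    terms = build_terms(problem)
    dim = problem.mesh.dim
    return backend.assemble_normal_system(terms, state.pack(), n_dof_per_node(dim),
                                          field_offsets(dim))


def gauss_newton_step(problem: FlowProblem, state: FlowState,
                      max_halvings: int = 5) -> tuple[FlowState, dict]:
    """One Gauss-Newton step with a halving line search on functional increase."""
    terms = build_terms(problem)
    x = state.pack()
    G0, _ = backend.evaluate_functional(terms, x)
    dim = problem.mesh.dim
    system = backend.assemble_normal_system(terms, x, n_dof_per_node(dim),
                                            field_offsets(dim))
    opts = dict(problem.solver_opts)
    xnew, lin = backend.solve_spd(system, **opts)
    step = xnew - x
    alpha = 1.0
    G1, bd = backend.evaluate_functional(terms, x + step)
    halvings = 0
    while G1 > G0 and halvings < max_halvings:
        alpha *= 0.5
        halvings += 1
        G1, bd = backend.evaluate_functional(terms, x + alpha * step)
    out = FlowState.unpack(x + alpha * step, problem.mesh, t=problem.time)
    out.functional_value = G1
    out.breakdown = bd
    xn = np.linalg.norm(x)
    diag = {"G_before": G0, "G_after": G1, "alpha": alpha,
            "cg_iterations": lin["iterations"], "cg_residual": lin["residual"],
            "step_norm": float(np.linalg.norm(alpha * step)),
            "rel_change": float(np.linalg.norm(alpha * step) / (xn if xn > 0 else 1.0))}
    return out, diag


def solve_timestep(problem: FlowProblem, initial_guess: FlowState | None = None,
                   tol: float = 1e-8, max_iter: int = 25) -> FlowState:
    """Iterate Gauss-Newton to the configured relative-functional-change tolerance.

    On nonconvergence the best iterate is returned flagged ``converged=False``.
    """
    problem.validate()
    state = initial_guess if initial_guess is not None \
        else (problem.prev_state if problem.prev_state is not None
              else FlowState.zero(problem.mesh, t=problem.time))
    state = FlowState(state.v.copy(), state.omega.copy(), state.r.copy(),
                      t=problem.time)
    G_prev = None
    for it in range(1, max_iter + 1):
        state, diag = gauss_newton_step(problem, state)
        G = diag["G_after"]
        if G_prev is not None and abs(G_prev - G) <= tol * max(G_prev, 1e-300):
            state.converged = True
            state.iterations = it
            return state
        if problem.stokes_limit and it >= 1 and diag["rel_change"] < 1e-12:
            state.converged = True
            state.iterations = it
            return state
        G_prev = G
    state.converged = False
    state.iterations = max_iter
    return state


# ---------------------------------------------------------------------------
# pressure recovery (post-processing, not part of the functional)
# ---------------------------------------------------------------------------

class _PotentialTerm:
    """min ||grad(phi) - target||^2 rows for a scalar nodal potential."""

    name = "potential"

    def __init__(self, mesh: Mesh, target: np.ndarray, anchor: int | None = 0):
        self.mesh = mesh
        self.target = target
        self.anchor = anchor
        self.n_dof_per_node = 1
        self.gdofs = mesh.elements

    def _eval(self, x):
        mesh = self.mesh
        _, wdet, N, G = mesh.element_quadrature()
        E, nq, nn, dim = G.shape
        phi = x[mesh.elements]                                  # (E, nn)
        gphi = np.einsum("eqnk,en->eqk", G, phi)
        tq = np.einsum("qn,enk->eqk", N, self.target[mesh.elements])
        R = (gphi - tq).reshape(E, nq * dim)
        J = G.transpose(0, 1, 3, 2).reshape(E, nq * dim, nn)
        w = np.repeat(wdet[:, :, None], dim, axis=2).reshape(E, nq * dim)
        return R, J, w

    def contributions(self, x, want_jac=True):
        R, J, w = self._eval(x)
        yield self.gdofs, J, R, w
        if self.anchor is not None:
            yield (np.array([[self.anchor]]), np.ones((1, 1, 1)),
                   np.array([[x[self.anchor]]]), np.ones((1, 1)))

    def residual_batches(self, x):
        R, _, w = self._eval(x)
        yield self.name, R, w


def recover_total_pressure(mesh: Mesh, state: FlowState, Re: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares potential reconstruction of pressure from r (post hoc).

    Solves min ||grad(phi) - r||^2 with phi anchored at node 0, then
    p = phi - (Re/2)|v|^2.  Returns (p, phi) as nodal arrays; both are defined
    up to the constant fixed by the anchor.
    """
    term = _PotentialTerm(mesh, state.r)
    x0 = np.zeros(mesh.n_nodes)
    system = backend.assemble_normal_system([term], x0, 1, {"phi": slice(0, 1)})
    phi, _ = backend.solve_spd(system, tol=1e-12)
    p = phi - 0.5 * Re * np.einsum("ni,ni->n", state.v, state.v)
    return p, phi
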