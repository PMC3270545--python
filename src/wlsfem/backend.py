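"""Assembly of least-squares normal equations and their SPD iterative solution.

Every least-squares term (interior residual, weighted boundary misfit, PIV plane
misfit) exposes the same protocol: it yields batches of linearized residual rows
``(gdofs, J, R, w)`` where ``J`` is the Jacobian of the residual rows with
respect to the local dofs at the current iterate, ``R`` the residual values, and
``w`` the positive quadrature/functional weights.  The normal system is then

    A = sum J^T diag(w) J,      b = sum J^T diag(w) (J x_loc - R),

so that ``A x = b`` is the Gauss-Newton step written for the new iterate, and
the functional value is ``sum w R^2``.  Assembly order is fixed by element
index, so results are bit-stable across runs on the same platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.io import mmwrite
from scipy.sparse.linalg import spilu, LinearOperator


class NotPositiveDefiniteError(Exception):
    """CG met negative curvature: the matrix violates the SPD contract."""


class SingularSystemError(Exception):
    """CG met (near-)zero curvature: the system has a nullspace."""


class ConvergenceError(Exception):
    """Iterative solve failed to reach the requested tolerance."""

    def __init__(self, msg, iterations=None, residual=None):
        super().__init__(msg)
        self.iterations = iterations
        self.residual = residual


@dataclass
class NormalSystem:
    """Sparse SPD normal equations ``A x = b`` with a documented dof layout.

    The dof index of (node, field component) is ``node * n_dof_per_node +
    offset`` where ``offset`` is given by ``field_offsets[field].start + comp``.
    """

    matrix: sparse.csr_matrix
    rhs: np.ndarray
    n_dof_per_node: int
    field_offsets: dict[str, slice] = field(default_factory=dict)

    def dof_index(self, node: int, fieldname: str, comp: int = 0) -> int:
        off = self.field_offsets[fieldname]
        if off.start + comp >= off.stop:
            raise IndexError(f"component {comp} out of range for field {fieldname}")
        return node * self.n_dof_per_node + off.start + comp

    def symmetry_error(self) -> float:
        d = (self.matrix - self.matrix.T)
        denom = max(abs(self.matrix).max(), 1e-300)
        return float(abs(d).max() / denom)

    def export_matrix_market(self, path: str) -> None:
        mmwrite(path, self.matrix.tocoo())


def assemble_normal_system(terms, x: np.ndarray, n_dof_per_node: int,
                           field_offsets: dict[str, slice] | None = None
                           ) -> NormalSystem:
    """Assemble ``A = B^T W B`` and the Gauss-Newton right-hand side.

    ``terms`` is an iterable of objects with ``contributions(x, want_jac)``;
    all must share the dof layout given by ``n_dof_per_node``.
    """
    n = x.shape[0]
    rows_i, rows_j, vals = [], [], []
    b = np.zeros(n)
    for term in terms:
        if getattr(term, "n_dof_per_node", n_dof_per_node) != n_dof_per_node:
            raise ValueError(f"term {term!r} uses an inconsistent dof layout")
        for gdofs, J, R, w in term.contributions(x, want_jac=True):
            if J.ndim == 2:  # single batch
                gdofs, J, R, w = gdofs[None], J[None], R[None], w[None]
            Jw = J * w[:, :, None]
            A_loc = np.einsum("brl,brm->blm", J, Jw)
            xloc = x[gdofs]
            b_loc = np.einsum("brl,br->bl", Jw,
                              np.einsum("brl,bl->br", J, xloc) - R)
            nloc = gdofs.shape[1]
            ii = np.repeat(gdofs, nloc, axis=1)
            jj = np.tile(gdofs, (1, nloc))
            rows_i.append(ii.ravel())
            rows_j.append(jj.ravel())
            vals.append(A_loc.reshape(-1))
            np.add.at(b, gdofs.ravel(), b_loc.ravel())
    if not rows_i:
        raise ValueError("no terms contributed to the normal system")
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows_i), np.concatenate(rows_j))),
        shape=(n, n)).tocsr()
    A = 0.5 * (A + A.T)  # enforce exact symmetry against roundoff
    return NormalSystem(A, b, n_dof_per_node, field_offsets or {})


def evaluate_functional(terms, x: np.ndarray) -> tuple[float, dict[str, float]]:
    """Value of the least-squares functional and a per-term-family breakdown."""
    breakdown: dict[str, float] = {}
    for term in terms:
        for key, R, w in term.residual_batches(x):
            acc = float(np.sum(w * R * R))
            breakdown[key] = breakdown.get(key, 0.0) + acc
    return sum(breakdown.values()), breakdown


def _make_preconditioner(A: sparse.csr_matrix, kind: str):
    """Preconditioner applied to the diagonally-scaled matrix."""
    if kind in ("jacobi", "none"):
        # the matrix is already symmetrically diagonal-scaled, so Jacobi is I
        return lambda r: r
    if kind == "ilu":
        # strong incomplete factorization: the squared first-order systems are
        # severely ill-conditioned at high Re, so aggressive fill pays off
        try:
            ilu = spilu(A.tocsc(), drop_tol=1e-12, fill_factor=300)
            return lambda r: ilu.solve(r)
        except RuntimeError:
            return lambda r: r
    if kind == "ilu_exact":
        try:
            ilu = spilu(A.tocsc(), drop_tol=1e-16, fill_factor=2000)
            return lambda r: ilu.solve(r)
        except RuntimeError:
            return lambda r: r
    raise ValueError(f"unknown preconditioner {kind!r}")


def solve_spd(system: NormalSystem, tol: float = 1e-10, max_iter: int = 2000,
              preconditioner: str = "ilu", x0: np.ndarray | None = None
              ) -> tuple[np.ndarray, dict]:
    """Preconditioned conjugate gradients for the SPD normal equations.

    Raises :class:`NotPositiveDefiniteError` on negative curvature (the matrix
    is not PD, falsifying the least-squares contract),
    :class:`SingularSystemError` when the search direction has near-zero
    curvature (a nullspace), and :class:`ConvergenceError` with the iteration
    count and final residual when ``max_iter`` is exhausted.
    """
    if system.symmetry_error() > 1e-12:
        raise ValueError("normal matrix fails the symmetry check")
    # symmetric diagonal (Jacobi) scaling: equilibrates the widely different
    # row scales of the squared residual equations before preconditioning
    diag = system.matrix.diagonal()
    d = np.sqrt(np.where(diag > 0, diag, 1.0))
    Dinv = sparse.diags(1.0 / d)
    A = (Dinv @ system.matrix @ Dinv).tocsr()
    b = system.rhs / d
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return np.zeros_like(b), {"iterations": 0, "residual": 0.0}
    chain = [preconditioner]
    if preconditioner == "ilu":
        chain.append("ilu_exact")   # retry on severely ill-conditioned systems
    last_err: Exception | None = None
    for kind in chain:
        M = _make_preconditioner(A, kind)
        try:
            x, info = _pcg(A, b, M, tol, max_iter,
                           None if x0 is None else x0 * d)
            return x / d, info
        except (ConvergenceError, NotPositiveDefiniteError) as err:
            last_err = err
    raise last_err


def _pcg(A, b, M, tol, max_iter, x0):
    bnorm = np.linalg.norm(b)
    x = np.zeros_like(b) if x0 is None else x0.copy()
    r = b - A @ x
    z = M(r)
    p = z.copy()
    rz = r @ z
    scale = float(abs(A).max())
    for it in range(1, max_iter + 1):
        if np.linalg.norm(r) <= tol * bnorm:
            return x, {"iterations": it - 1,
                       "residual": float(np.linalg.norm(r) / bnorm)}
        Ap = A @ p
        pAp = p @ Ap
        pp = p @ p
        if pAp < -1e-12 * scale * pp:
            raise NotPositiveDefiniteError(
                f"negative curvature at iteration {it}: p'Ap = {pAp:.3e}")
        if pAp <= 1e-14 * scale * pp:
            raise SingularSystemError(
                f"near-zero curvature at iteration {it}: the system has a nullspace")
        alpha = rz / pAp
        x = x + alpha * p
        r = r - alpha * Ap
        z = M(r)
        rz_new = r @ z
        if rz_new < 0 or not np.isfinite(rz_new):
            raise ConvergenceError(
                "preconditioner is not positive definite", iterations=it,
                residual=float(np.linalg.norm(r) / bnorm))
        p = z + (rz_new / rz) * p
        rz = rz_new
    res = float(np.linalg.norm(r) / bnorm)
    if res <= max(tol * 100, 1e-8):
        # accept a mildly short solve but report it
        return x, {"iterations": max_iter, "residual": res, "converged": False}
    raise ConvergenceError(
        f"CG did not converge in {max_iter} iterations (residual {res:.3e})",
        iterations=max_iter, residual=res)
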