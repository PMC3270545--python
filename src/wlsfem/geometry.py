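"""Quadratic quad/hex meshes, reference elements, quadrature, and field evaluation.

All coordinates are dimensionless; the physical length scale of a scenario is a
configuration item carried in output metadata, never in the mesh itself.

Elements are tensor-product quadratic Lagrange elements (9-node quadrilaterals in
2D, 27-node hexahedra in 3D) with nodes ordered lexicographically on the
reference cube [-1, 1]^dim (x index fastest).  The geometric map is
isoparametric, so curved (ellipsoid) surfaces are approximated to third order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree


class PointNotFoundError(Exception):
    """A query point is not inside any element of the mesh."""


# ---------------------------------------------------------------------------
# reference element
# ---------------------------------------------------------------------------

def _lag1d(xi: np.ndarray) -> np.ndarray:
    """Quadratic Lagrange basis on [-1,1] with nodes at -1, 0, 1. Shape (..., 3)."""
    xi = np.asarray(xi, dtype=float)
    return np.stack([0.5 * xi * (xi - 1.0), 1.0 - xi * xi, 0.5 * xi * (xi + 1.0)], axis=-1)


def _dlag1d(xi: np.ndarray) -> np.ndarray:
    xi = np.asarray(xi, dtype=float)
    return np.stack([xi - 0.5, -2.0 * xi, xi + 0.5], axis=-1)


def shape_functions(dim: int, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product quadratic shape functions and reference gradients.

    Parameters
    ----------
    dim : 1, 2 or 3
    pts : (m, dim) points in the reference cube.

    Returns
    -------
    N : (m, 3**dim) values; dN : (m, 3**dim, dim) derivatives w.r.t. reference coords.
    Node ordering is lexicographic with the first axis fastest.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    m = pts.shape[0]
    vals = [_lag1d(pts[:, d]) for d in range(dim)]
    ders = [_dlag1d(pts[:, d]) for d in range(dim)]
    nn = 3 ** dim
    N = np.ones((m, nn))
    dN = np.ones((m, nn, dim))
    for a in range(nn):
        idx = [(a // 3 ** d) % 3 for d in range(dim)]
        for d in range(dim):
            N[:, a] *= vals[d][:, idx[d]]
            for dd in range(dim):
                dN[:, a, dd] *= ders[d][:, idx[d]] if d == dd else vals[d][:, idx[d]]
    return N, dN


def gauss_points(dim: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor Gauss-Legendre rule with `order` points per direction (x fastest)."""
    x1, w1 = np.polynomial.legendre.leggauss(order)
    if dim == 1:
        return x1[:, None], w1
    grids = np.meshgrid(*([x1] * dim), indexing="ij")
    pts = np.stack([g.reshape(-1, order="F") for g in grids], axis=-1)
    W = w1.copy()
    for _ in range(dim - 1):
        W = np.multiply.outer(W, w1)
    # W[i0, i1, ...] indexed like grids -> flatten with first index fastest
    ws = W.reshape(-1, order="F")
    return pts, ws


# ---------------------------------------------------------------------------
# plane frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneFrame:
    """Orthonormal frame of a planar cross-section (a line segment in 2D).

    In 3D ``e1, e2`` span the plane and ``normal = e1 x e2``.  In 2D ``e2`` is
    None, ``e1`` is the line tangent and ``normal`` the in-plane normal.
    """

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray | None
    normal: np.ndarray

    def __post_init__(self):
        for name in ("origin", "e1", "normal"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.e2 is not None:
            object.__setattr__(self, "e2", np.asarray(self.e2, dtype=float))
        for v, name in ((self.e1, "e1"), (self.normal, "normal")):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-10):
                raise ValueError(f"{name} must be a unit vector")
        if self.e2 is not None:
            if not np.isclose(np.linalg.norm(self.e2), 1.0, atol=1e-10):
                raise ValueError("e2 must be a unit vector")
            if abs(float(self.e1 @ self.e2)) > 1e-10:
                raise ValueError("e1 and e2 must be orthogonal")
            if not np.allclose(np.cross(self.e1, self.e2), self.normal, atol=1e-10):
                raise ValueError("normal must equal e1 x e2")

    @property
    def dim(self) -> int:
        return self.origin.shape[0]

    def to_world(self, s: np.ndarray) -> np.ndarray:
        """Map in-plane coordinates (m, 2) (s2 ignored in 2D) to world points."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        x = self.origin[None, :] + s[:, :1] * self.e1[None, :]
        if self.e2 is not None:
            x = x + s[:, 1:2] * self.e2[None, :]
        return x

    def in_plane_directions(self, mode: str = "tangential") -> np.ndarray:
        """Unit directions whose velocity components the plane data carries.

        3D tangential -> (e1, e2); 3D all -> (e1, e2, normal).
        2D: the imaging plane is the whole flow plane, so both Cartesian
        components are tangential -> (e1, normal) in either mode.
        """
        if self.dim == 2:
            return np.stack([self.e1, self.normal])
        if mode == "tangential":
            return np.stack([self.e1, self.e2])
        if mode == "all":
            return np.stack([self.e1, self.e2, self.normal])
        raise ValueError(f"unknown component mode {mode!r}")


def make_plane_frame(origin, normal) -> PlaneFrame:
    """Build a frame from origin and normal, choosing in-plane axes."""
    origin = np.asarray(origin, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    if origin.shape[0] == 2:
        e1 = np.array([n[1], -n[0]])
        return PlaneFrame(origin, e1, None, n)
    trial = np.array([1.0, 0.0, 0.0])
    if abs(n @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    e1 = trial - (trial @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return PlaneFrame(origin, e1, e2, n)


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass
class Facet:
    """One boundary facet: quadratic edge (3 nodes) or face (9 nodes)."""

    nodes: np.ndarray  # lexicographic in the facet's own reference frame
    owner: int         # owning element index


@dataclass
class Mesh:
    """Quadratic quad/hex mesh with tagged boundary facets.

    ``boundary_tags`` maps tag -> list of Facet.  ``primary_tags`` is the subset
    of tags that partitions the boundary (sub-patches such as an inlet carved out
    of a base disk are listed in ``boundary_tags`` but not in ``primary_tags``).
    """

    dim: int
    nodes: np.ndarray
    elements: np.ndarray
    boundary_tags: dict[str, list[Facet]] = field(default_factory=dict)
    primary_tags: set[str] = field(default_factory=set)
    quad_order: int = 3
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        self._cache: dict = {}
        if not self.primary_tags:
            self.primary_tags = set(self.boundary_tags)

    # -- basic quantities ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def nodes_per_element(self) -> int:
        return 3 ** self.dim

    def invalidate(self) -> None:
        """Drop cached quadrature data (call after moving nodes)."""
        self._cache = {}

    def copy(self) -> "Mesh":
        m = Mesh(self.dim, self.nodes.copy(), self.elements.copy(),
                 {t: [Facet(f.nodes.copy(), f.owner) for f in fs]
                  for t, fs in self.boundary_tags.items()},
                 set(self.primary_tags), self.quad_order, dict(self.metadata))
        return m

    # -- volume quadrature ----------------------------------------------------
    def element_quadrature(self):
        """Cached per-element quadrature.

        Returns (xq, wdet, N, grad) with shapes (E, nq, dim), (E, nq),
        (nq, nn), (E, nq, nn, dim); wdet includes the Jacobian determinant.
        """
        key = "equad"
        if key not in self._cache:
            ref, w = gauss_points(self.dim, self.quad_order)
            N, dN = shape_functions(self.dim, ref)
            X = self.nodes[self.elements]                       # (E, nn, dim)
            xq = np.einsum("qn,end->eqd", N, X)
            J = np.einsum("qnr,end->eqdr", dN, X)               # dX_d/dxi_r
            detJ = np.linalg.det(J)
            if np.any(detJ <= 0):
                bad = int(np.argwhere(np.any(detJ <= 0, axis=1))[0, 0])
                raise ValueError(f"nonpositive Jacobian in element {bad}")
            Jinv = np.linalg.inv(J)
            grad = np.einsum("qnr,eqrd->eqnd", dN, Jinv)
            self._cache[key] = (xq, detJ * w[None, :], N, grad)
        return self._cache[key]

    def element_sizes(self) -> np.ndarray:
        """Per-element characteristic size h = volume**(1/dim)."""
        _, wdet, _, _ = self.element_quadrature()
        return wdet.sum(axis=1) ** (1.0 / self.dim)

    def volume(self) -> float:
        _, wdet, _, _ = self.element_quadrature()
        return float(wdet.sum())

    def element_centroids(self) -> np.ndarray:
        xq, wdet, _, _ = self.element_quadrature()
        return (xq * wdet[..., None]).sum(axis=1) / wdet.sum(axis=1)[:, None]

    def check_jacobians(self) -> float:
        """Smallest Jacobian determinant over all quadrature points (must be > 0)."""
        try:
            _, wdet, _, _ = self.element_quadrature()
        except ValueError:
            return -1.0
        ref, w = gauss_points(self.dim, self.quad_order)
        return float((wdet / w[None, :]).min())

    # -- facet quadrature ------------------------------------------------------
    def facet_quadrature(self, tag: str):
        """Cached facet quadrature for one boundary tag.

        Returns (facets, xq, w, N, normals, h) where xq is (F, nq, dim), w the
        quadrature weights including the surface Jacobian, N the facet shape
        functions (nq, fn), normals outward unit normals (F, nq, dim), and h the
        per-facet diameter (length in 2D, sqrt(area) in 3D).
        """
        key = ("fquad", tag)
        if key not in self._cache:
            facets = self.boundary_tags[tag]
            fdim = self.dim - 1
            ref, w1 = gauss_points(fdim, self.quad_order)
            N, dN = shape_functions(fdim, ref)
            cents = self.element_centroids()
            xqs, ws, normals, hs = [], [], [], []
            for f in facets:
                X = self.nodes[f.nodes]                         # (fn, dim)
                xq = N @ X                                      # (nq, dim)
                T = np.einsum("qnr,nd->qdr", dN, X)             # tangents (nq, dim, fdim)
                if self.dim == 2:
                    t = T[:, :, 0]
                    scale = np.linalg.norm(t, axis=1)
                    nrm = np.stack([t[:, 1], -t[:, 0]], axis=1) / scale[:, None]
                else:
                    nrm = np.cross(T[:, :, 0], T[:, :, 1])
                    scale = np.linalg.norm(nrm, axis=1)
                    nrm = nrm / scale[:, None]
                # orient outward
                mid = xq.mean(axis=0)
                if (mid - cents[f.owner]) @ nrm.mean(axis=0) < 0:
                    nrm = -nrm
                area = float((scale * w1).sum())
                xqs.append(xq)
                ws.append(scale * w1)
                normals.append(nrm)
                hs.append(area ** (1.0 / fdim))
            self._cache[key] = (facets, np.array(xqs), np.array(ws), N,
                                np.array(normals), np.array(hs))
        return self._cache[key]

    def facet_area(self, tag: str) -> float:
        _, _, w, _, _, _ = self.facet_quadrature(tag)
        return float(w.sum())

    def check_boundary_partition(self) -> bool:
        """Every boundary facet belongs to exactly one primary tag."""
        seen: dict[tuple, int] = {}
        for tag in self.primary_tags:
            for f in self.boundary_tags[tag]:
                k = tuple(sorted(f.nodes.tolist()))
                seen[k] = seen.get(k, 0) + 1
        return all(c == 1 for c in seen.values())

    # -- point location --------------------------------------------------------
    def _centroid_tree(self) -> cKDTree:
        if "ctree" not in self._cache:
            self._cache["ctree"] = cKDTree(self.element_centroids())
        return self._cache["ctree"]

    def locate(self, point: np.ndarray, tol: float = 1e-9) -> tuple[int, np.ndarray]:
        """Find (element, reference coords) containing ``point``.

        Raises PointNotFoundError when the point is outside every element; that
        error is distinct from numerical (Newton) failure inside an element.
        """
        point = np.asarray(point, dtype=float)
        tree = self._centroid_tree()
        k = min(self.n_elements, 8)
        _, cand = tree.query(point, k=k)
        cand = np.atleast_1d(cand)
        for e in cand:
            xi = self._invert_map(int(e), point)
            if xi is not None and np.max(np.abs(xi)) <= 1.0 + 1e-8:
                return int(e), np.clip(xi, -1.0, 1.0)
        # exhaustive fallback for robustness on tiny meshes
        if self.n_elements > k:
            for e in range(self.n_elements):
                xi = self._invert_map(e, point)
                if xi is not None and np.max(np.abs(xi)) <= 1.0 + 1e-8:
                    return e, np.clip(xi, -1.0, 1.0)
        raise PointNotFoundError(f"point {point} not located in any element")

    def _invert_map(self, e: int, x: np.ndarray, tol: float = 1e-12) -> np.ndarray | None:
        X = self.nodes[self.elements[e]]
        xi = np.zeros(self.dim)
        for _ in range(40):
            N, dN = shape_functions(self.dim, xi[None, :])
            res = N[0] @ X - x
            if np.linalg.norm(res) < tol * (1.0 + np.linalg.norm(x)):
                return xi
            J = np.einsum("nr,nd->dr", dN[0], X)
            try:
                dxi = np.linalg.solve(J, res)
            except np.linalg.LinAlgError:
                return None
            xi = xi - dxi
            if np.max(np.abs(xi)) > 3.0:
                return None
        return xi if np.linalg.norm(res) < 1e-8 else None


def evaluate_field(mesh: Mesh, nodal_values: np.ndarray, point: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a nodal field and its spatial gradient at one point.

    Returns (value, gradient): for values of shape (n_nodes, m) the results have
    shapes (m,) and (m, dim); scalar nodal fields give () and (dim,).
    """
    vals = np.asarray(nodal_values, dtype=float)
    scalar = vals.ndim == 1
    if scalar:
        vals = vals[:, None]
    e, xi = mesh.locate(point)
    conn = mesh.elements[e]
    N, dN = shape_functions(mesh.dim, xi[None, :])
    X = mesh.nodes[conn]
    J = np.einsum("nr,nd->dr", dN[0], X)
    G = dN[0] @ np.linalg.inv(J)                    # (nn, dim) physical grads
    value = N[0] @ vals[conn]
    grad = G.T @ vals[conn]                          # (dim, m)
    if scalar:
        return value[0], grad[:, 0]
    return value, grad.T


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

_FACE_NAMES = {
    2: {(0, -1): "left", (0, +1): "right", (1, -1): "bottom", (1, +1): "top"},
    3: {(0, -1): "left", (0, +1): "right", (1, -1): "front", (1, +1): "back",
        (2, -1): "bottom", (2, +1): "top"},
}


def build_box_mesh(extent: Sequence[float], resolution: Sequence[int],
                   origin: Sequence[float] | None = None,
                   tags: dict | None = None) -> Mesh:
    """Structured quadratic mesh of an axis-aligned box.

    ``extent`` gives the side lengths per axis, ``resolution`` the number of
    elements per axis.  All 2*dim outer faces are tagged (left/right, bottom/top,
    and front/back in 3D), or by ``tags`` mapping the default names to new ones.
    """
    extent = np.asarray(extent, dtype=float)
    resolution = np.asarray(resolution, dtype=int)
    dim = extent.shape[0]
    if dim not in (2, 3) or resolution.shape[0] != dim:
        raise ValueError("extent and resolution must both have length 2 or 3")
    for d in range(dim):
        if extent[d] <= 0:
            raise ValueError(f"nonpositive extent along axis {d}")
        if resolution[d] < 1:
            raise ValueError(f"nonpositive resolution along axis {d}")
    origin = np.zeros(dim) if origin is None else np.asarray(origin, dtype=float)

    npts = 2 * resolution + 1
    axes = [np.linspace(origin[d], origin[d] + extent[d], npts[d]) for d in range(dim)]
    grids = np.meshgrid(*axes, indexing="ij")
    # lexicographic with x fastest
    nodes = np.stack([g.T.reshape(-1) if dim == 2 else g.transpose(2, 1, 0).reshape(-1)
                      for g in grids], axis=-1)

    def nid(idx):
        if dim == 2:
            return idx[0] + npts[0] * idx[1]
        return idx[0] + npts[0] * (idx[1] + npts[1] * idx[2])

    elems = []
    ranges = [range(resolution[d]) for d in range(dim)]
    if dim == 2:
        for ey in ranges[1]:
            for ex in ranges[0]:
                conn = [nid((2 * ex + i, 2 * ey + j))
                        for j in range(3) for i in range(3)]
                elems.append(conn)
    else:
        for ez in ranges[2]:
            for ey in ranges[1]:
                for ex in ranges[0]:
                    conn = [nid((2 * ex + i, 2 * ey + j, 2 * ez + k))
                            for k in range(3) for j in range(3) for i in range(3)]
                    elems.append(conn)
    elements = np.array(elems, dtype=int)

    # boundary facets
    boundary: dict[str, list[Facet]] = {}
    names = _FACE_NAMES[dim]
    if tags:
        names = {k: tags.get(v, v) for k, v in names.items()}

    def elem_index(cell):
        if dim == 2:
            return cell[0] + resolution[0] * cell[1]
        return cell[0] + resolution[0] * (cell[1] + resolution[1] * cell[2])

    for (axis, side), name in names.items():
        boundary.setdefault(name, [])
        tang = [d for d in range(dim) if d != axis]
        fixed_cell = 0 if side < 0 else resolution[axis] - 1
        fixed_node = 0 if side < 0 else npts[axis] - 1
        cell_ranges = [range(resolution[d]) for d in tang]
        if dim == 2:
            for c0 in cell_ranges[0]:
                cell = [0] * dim
                cell[axis] = fixed_cell
                cell[tang[0]] = c0
                nlist = []
                for i in range(3):
                    idx = [0] * dim
                    idx[axis] = fixed_node
                    idx[tang[0]] = 2 * c0 + i
                    nlist.append(nid(idx))
                boundary[name].append(Facet(np.array(nlist), elem_index(cell)))
        else:
            for c1 in cell_ranges[1]:
                for c0 in cell_ranges[0]:
                    cell = [0] * dim
                    cell[axis] = fixed_cell
                    cell[tang[0]] = c0
                    cell[tang[1]] = c1
                    nlist = []
                    for j in range(3):
                        for i in range(3):
                            idx = [0] * dim
                            idx[axis] = fixed_node
                            idx[tang[0]] = 2 * c0 + i
                            idx[tang[1]] = 2 * c1 + j
                            nlist.append(nid(idx))
                    boundary[name].append(Facet(np.array(nlist), elem_index(cell)))

    mesh = Mesh(dim, nodes, elements, boundary)
    mesh.metadata["generator"] = "box"
    return mesh


def _cube_to_ball(p: np.ndarray) -> np.ndarray:
    """Smooth volumetric map of the cube [-1,1]^3 onto the unit ball."""
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    x2, y2, z2 = x * x, y * y, z * z
    bx = x * np.sqrt(np.maximum(1 - y2 / 2 - z2 / 2 + y2 * z2 / 3, 0.0))
    by = y * np.sqrt(np.maximum(1 - z2 / 2 - x2 / 2 + z2 * x2 / 3, 0.0))
    bz = z * np.sqrt(np.maximum(1 - x2 / 2 - y2 / 2 + x2 * y2 / 3, 0.0))
    return np.stack([bx, by, bz], axis=-1)


def build_half_ellipsoid_mesh(semi_axes: Sequence[float],
                              resolution: int | Sequence[int] = 3,
                              inlet_center: Sequence[float] = (0.5, 0.0),
                              inlet_radius: float = 0.45,
                              outlet_center: Sequence[float] = (-0.55, 0.0),
                              outlet_radius: float = 0.38) -> Mesh:
    """All-hex mesh of a half-ellipsoid cavity (flat base at z=0, apex at z=-c).

    The unit cube is mapped smoothly onto the unit ball and the lower half kept,
    so the topology stays structured with positive Jacobians and no degenerate
    apex.  The flat top disk is tagged ``base`` and the curved surface ``wall``;
    disjoint ``inlet``/``outlet`` sub-patches of the base are selected by disks
    in base-plane coordinates normalised by the in-plane semi-axes.
    """
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError("all semi-axes must be positive")
    if np.isscalar(resolution):
        res = (int(resolution), int(resolution), max(1, int(round(resolution * 0.75))))
    else:
        res = tuple(int(r) for r in resolution)
    box = build_box_mesh([2.0, 2.0, 1.0], res, origin=[-1.0, -1.0, -1.0])
    mapped = _cube_to_ball(box.nodes) * np.array([a, b, c])

    boundary: dict[str, list[Facet]] = {"base": [], "wall": [], "inlet": [], "outlet": []}
    for tag, facets in box.boundary_tags.items():
        for f in facets:
            if tag == "top":
                cen = mapped[f.nodes].mean(axis=0)
                u = (cen[0] / a - inlet_center[0], cen[1] / b - inlet_center[1])
                w = (cen[0] / a - outlet_center[0], cen[1] / b - outlet_center[1])
                in_in = np.hypot(*u) <= inlet_radius
                in_out = np.hypot(*w) <= outlet_radius
                if in_in and not in_out:
                    boundary["inlet"].append(f)
                elif in_out and not in_in:
                    boundary["outlet"].append(f)
                boundary["base"].append(f)
            else:
                boundary["wall"].append(f)

    mesh = Mesh(3, mapped, box.elements, boundary, primary_tags={"base", "wall"},
                quad_order=4)
    mesh.metadata.update(generator="half_ellipsoid", semi_axes=(a, b, c),
                         inlet_center=(inlet_center[0] * a, inlet_center[1] * b),
                         inlet_radius=inlet_radius * a)
    if mesh.check_jacobians() <= 0:
        raise ValueError("half-ellipsoid mapping produced a nonpositive Jacobian")
    return mesh


def split_interior_surface(mesh: Mesh, x0: float, y_top: float,
                           tag_left: str = "flap_left",
                           tag_right: str = "flap_right") -> Mesh:
    """Split a 2D box mesh along the vertical segment x=x0, 0 <= y < y_top.

    Nodes strictly between the bottom wall and the tip are duplicated so the two
    sides of the zero-thickness surface carry independent velocity unknowns; the
    root node (on the wall) and the tip node stay shared.  New boundary tags
    ``flap_left``/``flap_right`` hold the element edges on each side.
    """
    if mesh.dim != 2:
        raise ValueError("interior-surface split implemented for 2D meshes")
    nodes = mesh.nodes.copy()
    elements = mesh.elements.copy()
    tol = 1e-9
    on_line = (np.abs(nodes[:, 0] - x0) < tol) & (nodes[:, 1] > tol) \
        & (nodes[:, 1] < y_top - tol)
    line_ids = np.where(on_line)[0]
    if line_ids.size == 0:
        raise ValueError("flap line does not coincide with mesh lines")
    dup_map = {}
    new_nodes = [nodes]
    nid = nodes.shape[0]
    for i in line_ids:
        dup_map[int(i)] = nid
        nid += 1
    new_nodes.append(nodes[line_ids])
    nodes = np.vstack(new_nodes)

    cents = mesh.element_centroids()
    right = cents[:, 0] > x0
    for e in np.where(right)[0]:
        for k, n in enumerate(elements[e]):
            if int(n) in dup_map:
                elements[e, k] = dup_map[int(n)]

    # build flap facets: edges of elements adjacent to the line
    left_facets, right_facets = [], []
    for e in range(elements.shape[0]):
        conn = mesh.elements[e]  # pre-duplication connectivity for geometry test
        X = mesh.nodes[conn]
        # local right edge of a left element: lexicographic i=2 column
        if not right[e]:
            col = [2, 5, 8]
        else:
            col = [0, 3, 6]
        edge_nodes = conn[col]
        pos = mesh.nodes[edge_nodes]
        if np.all(np.abs(pos[:, 0] - x0) < tol) and np.all(pos[:, 1] <= y_top + tol) \
                and pos[:, 1].min() >= -tol:
            # use post-duplication ids
            edge_post = elements[e][col]
            f = Facet(np.array(edge_post), e)
            (left_facets if not right[e] else right_facets).append(f)

    boundary = {t: [Facet(f.nodes.copy(), f.owner) for f in fs]
                for t, fs in mesh.boundary_tags.items()}
    boundary[tag_left] = left_facets
    boundary[tag_right] = right_facets
    out = Mesh(2, nodes, elements, boundary,
               primary_tags=set(mesh.primary_tags) | {tag_left, tag_right},
               quad_order=mesh.quad_order, metadata=dict(mesh.metadata))
    out.metadata["flap"] = {"x0": x0, "y_top": y_top,
                            "duplicates": {int(k): int(v) for k, v in dup_map.items()}}
    return out


# ---------------------------------------------------------------------------
# VTK I/O (legacy ASCII unstructured grid)
# ---------------------------------------------------------------------------

# lexicographic node index for each position of the VTK quadratic cell orderings
_VTK_BIQUAD_QUAD = [0, 2, 8, 6, 1, 5, 7, 3, 4]                       # type 28
_VTK_TRIQUAD_HEX = [0, 2, 8, 6, 18, 20, 26, 24,                      # corners
                    1, 5, 7, 3, 19, 23, 25, 21, 9, 11, 17, 15,       # edges
                    10, 14, 16, 12, 4, 22,                           # face centers
                    13]                                              # type 29
_VTK_QUAD_EDGE = [0, 2, 1]                                           # type 21


def write_vtk_quadratic(mesh: Mesh, path: str,
                        point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh with native quadratic VTK cells and tagged boundary facets.

    Volume elements become biquadratic quads (type 28) or triquadratic hexes
    (type 29); boundary facets are appended as quadratic edge/face cells with
    an integer ``boundary_tag`` CELL_DATA array (0 on volume cells).  The
    tag-name map is encoded in the file title, so :func:`read_vtk` round-trips
    the mesh including its boundary tags.
    """
    pts = mesh.nodes
    if mesh.dim == 2:
        pts = np.hstack([pts, np.zeros((pts.shape[0], 1))])
        vol_cells = mesh.elements[:, _VTK_BIQUAD_QUAD]
        vol_type = 28
        facet_order, facet_type = _VTK_QUAD_EDGE, 21
    else:
        vol_cells = mesh.elements[:, _VTK_TRIQUAD_HEX]
        vol_type = 29
        facet_order, facet_type = _VTK_BIQUAD_QUAD, 28
    tag_names = sorted(mesh.boundary_tags)
    tag_ids = {name: i + 1 for i, name in enumerate(tag_names)}
    cells, types, tags = [list(vol_cells)], [np.full(len(vol_cells), vol_type)], \
        [np.zeros(len(vol_cells), dtype=int)]
    for name in tag_names:
        fs = mesh.boundary_tags[name]
        if not fs:
            continue
        arr = np.array([f.nodes[facet_order] for f in fs])
        cells.append(list(arr))
        types.append(np.full(len(fs), facet_type))
        tags.append(np.full(len(fs), tag_ids[name]))
    types = np.concatenate(types)
    tags = np.concatenate(tags)
    title = "wlsfem mesh; tags: " + " ".join(
        f"{n}={tag_ids[n]}" for n in tag_names) + "; primary: " + ",".join(
        sorted(mesh.primary_tags)) + f"; qorder: {mesh.quad_order}"
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {pts.shape[0]} double\n")
        np.savetxt(fh, pts, fmt="%.17g")
        ncells = types.shape[0]
        total = sum(len(c) + 1 for block in cells for c in block)
        fh.write(f"CELLS {ncells} {total}\n")
        for block in cells:
            for c in block:
                fh.write(str(len(c)) + " " + " ".join(map(str, c)) + "\n")
        fh.write(f"CELL_TYPES {ncells}\n")
        np.savetxt(fh, types, fmt="%d")
        fh.write(f"CELL_DATA {ncells}\n")
        fh.write("SCALARS boundary_tag int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, tags, fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {pts.shape[0]}\n")
            _write_point_data(fh, point_data)


def read_vtk(path: str) -> Mesh:
    """Read a quadratic-cell legacy VTK unstructured grid written by
    :func:`write_vtk_quadratic`, reconstructing elements and boundary tags."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    title = lines[1]
    tag_ids: dict[int, str] = {}
    primary: set[str] = set()
    qorder = 3
    if "tags:" in title:
        part = title.split("tags:")[1]
        tag_part = part.split(";")[0].strip()
        for item in tag_part.split():
            name, _, num = item.partition("=")
            tag_ids[int(num)] = name
        if "primary:" in part:
            primary = {s for s in
                       part.split("primary:")[1].split(";")[0].strip().split(",")
                       if s}
        if "qorder:" in part:
            qorder = int(part.split("qorder:")[1].split(";")[0].strip())
    i = 0
    pts = cells = types = tags = None
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        if tok[0] == "POINTS":
            n = int(tok[1])
            flat = " ".join(lines[i + 1:]).split()
            # points occupy the next 3n numbers
            vals = np.array(flat[:3 * n], dtype=float).reshape(n, 3)
            pts = vals
            # advance: count lines consumed
            cnt, j = 0, i + 1
            while cnt < 3 * n:
                cnt += len(lines[j].split())
                j += 1
            i = j
        elif tok[0] == "CELLS":
            ncells = int(tok[1])
            cells = []
            j = i + 1
            for _ in range(ncells):
                row = list(map(int, lines[j].split()))
                cells.append(row[1:1 + row[0]])
                j += 1
            i = j
        elif tok[0] == "CELL_TYPES":
            n = int(tok[1])
            flat = []
            j = i + 1
            while len(flat) < n:
                flat.extend(lines[j].split())
                j += 1
            types = np.array(flat[:n], dtype=int)
            i = j
        elif tok[0] == "SCALARS" and tok[1] == "boundary_tag":
            n = types.shape[0]
            flat = []
            j = i + 2  # skip LOOKUP_TABLE line
            while len(flat) < n:
                flat.extend(lines[j].split())
                j += 1
            tags = np.array(flat[:n], dtype=int)
            i = j
        else:
            i += 1
    if pts is None or cells is None or types is None:
        raise ValueError("not a legacy VTK unstructured grid")
    dim = 3 if np.any(types == 29) else 2
    nodes = pts if dim == 3 else pts[:, :2]
    inv_vol = np.argsort(_VTK_TRIQUAD_HEX if dim == 3 else _VTK_BIQUAD_QUAD)
    facet_order = _VTK_BIQUAD_QUAD if dim == 3 else _VTK_QUAD_EDGE
    inv_facet = np.argsort(facet_order)
    vol_type = 29 if dim == 3 else 28
    facet_type = 28 if dim == 3 else 21
    elements = np.array([np.array(c)[inv_vol] for c, t in zip(cells, types)
                         if t == vol_type])
    # map nodes -> owning elements for facet ownership
    node_elems: dict[int, set[int]] = {}
    for e, conn in enumerate(elements):
        for nd in conn:
            node_elems.setdefault(int(nd), set()).add(e)
    boundary: dict[str, list[Facet]] = {name: [] for name in tag_ids.values()}
    for c, t, tg in zip(cells, types, tags if tags is not None
                        else np.zeros(len(cells), dtype=int)):
        if t != facet_type or tg == 0 or (dim == 2 and t == vol_type):
            continue
        fnodes = np.array(c)[inv_facet]
        owners = set.intersection(*(node_elems[int(nd)] for nd in fnodes))
        owner = min(owners) if owners else 0
        boundary[tag_ids[int(tg)]].append(Facet(fnodes, owner))
    mesh = Mesh(dim, nodes, elements, boundary,
                primary_tags=primary or set(boundary), quad_order=qorder)
    mesh.metadata["source"] = path
    return mesh


def _write_point_data(fh, point_data: dict[str, np.ndarray]) -> None:
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.10g")
        else:
            a3 = np.zeros((arr.shape[0], 3))
            a3[:, :arr.shape[1]] = arr
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, a3, fmt="%.10g")


def write_vtk(mesh: Mesh, path: str, point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid.

    Each quadratic element is subdivided into 4 (2D) or 8 (3D) linear sub-cells,
    which every VTK reader handles; nodal fields are written as POINT_DATA and
    per-element fields replicated onto the sub-cells as CELL_DATA.  For a
    lossless round trip with boundary tags use :func:`write_vtk_quadratic`.
    """
    pts = mesh.nodes
    if mesh.dim == 2:
        pts = np.hstack([pts, np.zeros((pts.shape[0], 1))])
        subcells = [np.array([[0, 1, 4, 3], [1, 2, 5, 4], [3, 4, 7, 6], [4, 5, 8, 7]])]
        ctype, npc = 9, 4  # VTK_QUAD
        subs = subcells[0]
    else:
        corners = []
        for k in range(2):
            for j in range(2):
                for i in range(2):
                    base = i + 3 * j + 9 * k
                    corners.append([base, base + 1, base + 4, base + 3,
                                    base + 9, base + 10, base + 13, base + 12])
        subs = np.array(corners)
        ctype, npc = 12, 8  # VTK_HEXAHEDRON
    cells = mesh.elements[:, subs.reshape(-1)].reshape(-1, npc)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nwlsfem output\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {pts.shape[0]} double\n")
        np.savetxt(fh, pts, fmt="%.10g")
        fh.write(f"CELLS {cells.shape[0]} {cells.shape[0] * (npc + 1)}\n")
        np.savetxt(fh, np.hstack([np.full((cells.shape[0], 1), npc), cells]), fmt="%d")
        fh.write(f"CELL_TYPES {cells.shape[0]}\n")
        np.savetxt(fh, np.full(cells.shape[0], ctype), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {pts.shape[0]}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.10g")
                else:
                    a3 = np.zeros((arr.shape[0], 3))
                    a3[:, :arr.shape[1]] = arr
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, a3, fmt="%.10g")
        if cell_data:
            nsub = subs.shape[0]
            fh.write(f"CELL_DATA {cells.shape[0]}\n")
            for name, arr in cell_data.items():
                arr = np.repeat(np.asarray(arr, dtype=float), nsub)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr, fmt="%.10g")
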