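"""Planar PIV data, the weighted plane-misfit term, and sigma -> weight calibration.

A PIV dataset lives on a planar cross-section of the domain (a line segment in
2D).  It stores the in-plane velocity components measured on a rectangular
sample grid at a series of time stamps, with a noise level sigma and a validity
mask.  The misfit term integrates the squared difference between the trace of
the computed velocity and the data over the plane, scaled by w_PIV/h with the
local size h of the mesh element containing each quadrature point; the
accuracy-based weight choice is w ~ 1/sigma^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .geometry import Mesh, PlaneFrame, PointNotFoundError, shape_functions

log = logging.getLogger(__name__)


class FrameMissingError(Exception):
    """No stored PIV frame matches the requested time (mode="none")."""


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class PIVDataSet:
    """Gridded planar velocity data with noise level and time stamps.

    velocities has shape (nt, n1, n2, ncomp) with components along
    ``directions`` (rows are unit vectors in world coordinates); in 2D the grid
    is a line (n2 == 1).  ``sigma`` is a global standard deviation or an array
    broadcastable to (nt, n1, n2).
    """

    frame: PlaneFrame
    s1: np.ndarray
    s2: np.ndarray
    velocities: np.ndarray
    sigma: float | np.ndarray
    times: np.ndarray
    directions: np.ndarray
    validity_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s1 = np.asarray(self.s1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.directions = np.asarray(self.directions, dtype=float)
        if self.validity_mask is None:
            self.validity_mask = np.ones(self.velocities.shape[:3], dtype=bool)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma must be positive")
        if not np.all(np.isfinite(self.velocities[self.validity_mask])):
            raise ValueError("velocities must be finite wherever the mask is true")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.s1.shape[0], self.s2.shape[0]

    def sample_points(self) -> np.ndarray:
        """In-plane sample coordinates, shape (n1*n2, 2) (s1 fastest)."""
        S1, S2 = np.meshgrid(self.s1, self.s2, indexing="ij")
        return np.stack([S1.reshape(-1, order="F"), S2.reshape(-1, order="F")], axis=-1)

    def world_points(self) -> np.ndarray:
        return self.frame.to_world(self.sample_points())

    def area_weights(self) -> np.ndarray:
        """Trapezoidal quadrature weight of each sample point (s1 fastest)."""
        def trap(s):
            if s.shape[0] == 1:
                return np.array([1.0])
            w = np.zeros_like(s)
            w[1:] += 0.5 * np.diff(s)
            w[:-1] += 0.5 * np.diff(s)
            return w
        w1, w2 = trap(self.s1), trap(self.s2)
        return np.multiply.outer(w1, w2).reshape(-1, order="F")

    def area(self) -> float:
        return float(self.area_weights().sum())


@dataclass
class PIVTerm:
    """One PIV dataset with its functional weight and component selection."""

    dataset: PIVDataSet
    w_piv: float
    component_mode: str = "tangential"
    time_mode: str = "linear"

    def __post_init__(self):
        if self.w_piv < 0:
            raise ValueError("w_piv must be nonnegative")


def weight_from_sigma(sigma: float, normalize_to: float | None = None) -> float:
    """Accuracy-based functional weight w = 1/sigma^2.

    With ``normalize_to`` set to the standard deviation of the most accurate
    data stream, that stream gets weight 1.0 and the others (sigma_ref/sigma)^2.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if normalize_to is None:
        return 1.0 / sigma ** 2
    if normalize_to <= 0:
        raise ValueError("reference sigma must be positive")
    return (normalize_to / sigma) ** 2


# ---------------------------------------------------------------------------
# time selection / in-plane interpolation
# ---------------------------------------------------------------------------

@dataclass
class PIVFrameData:
    """PIV values resolved at one simulation time."""

    dataset: PIVDataSet
    values: np.ndarray          # (n1, n2, ncomp)
    mask: np.ndarray            # (n1, n2)
    time: float

    def __call__(self, s: np.ndarray) -> np.ndarray:
        """Bilinear in-plane interpolation at coordinates s (m, 2)."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        ds = self.dataset
        out = np.empty((s.shape[0], self.values.shape[2]))
        for c in range(self.values.shape[2]):
            if ds.s2.shape[0] == 1:
                out[:, c] = np.interp(s[:, 0], ds.s1, self.values[:, 0, c])
            else:
                from scipy.interpolate import RegularGridInterpolator
                rgi = RegularGridInterpolator((ds.s1, ds.s2), self.values[:, :, c],
                                              bounds_error=False, fill_value=None)
                out[:, c] = rgi(s)
        return out

    def flat_values(self) -> np.ndarray:
        return self.values.reshape(-1, self.values.shape[2], order="F")

    def flat_mask(self) -> np.ndarray:
        return self.mask.reshape(-1, order="F")


def data_at_time(dataset: PIVDataSet, time: float, mode: str = "linear",
                 match_tol: float = 1e-9) -> PIVFrameData:
    """Resolve the dataset at one time: exact/nearest frame or linear in time.

    Raises ValueError outside the dataset's time span (no extrapolation) and
    FrameMissingError when mode="none" and no frame matches within tolerance.
    """
    t = dataset.times
    span = (t[0] - match_tol, t[-1] + match_tol)
    if not (span[0] <= time <= span[1]):
        raise ValueError(f"time {time} outside dataset span [{t[0]}, {t[-1]}]")
    scale = max(abs(t[0]), abs(t[-1]), 1.0)
    hit = np.where(np.abs(t - time) <= match_tol * scale)[0]
    if hit.size:
        i = int(hit[0])
        return PIVFrameData(dataset, dataset.velocities[i],
                            dataset.validity_mask[i], time)
    if mode == "none":
        raise FrameMissingError(f"no PIV frame at t={time} and interpolation disabled")
    if mode == "nearest":
        i = int(np.argmin(np.abs(t - time)))
        return PIVFrameData(dataset, dataset.velocities[i],
                            dataset.validity_mask[i], time)
    if mode == "linear":
        j = int(np.searchsorted(t, time))
        i = j - 1
        th = (time - t[i]) / (t[j] - t[i])
        vals = (1 - th) * dataset.velocities[i] + th * dataset.velocities[j]
        mask = dataset.validity_mask[i] & dataset.validity_mask[j]
        return PIVFrameData(dataset, vals, mask, time)
    raise ValueError(f"unknown time mode {mode!r}")


# ---------------------------------------------------------------------------
# plane misfit
# ---------------------------------------------------------------------------

def _locate_plane_points(mesh: Mesh, dataset: PIVDataSet):
    """Locate sample points in the mesh; cached per (mesh state, dataset)."""
    key = ("piv_loc", id(dataset))
    if key not in mesh._cache:
        pts = dataset.world_points()
        nn = mesh.nodes_per_element
        elem = np.full(pts.shape[0], -1, dtype=int)
        Np = np.zeros((pts.shape[0], nn))
        h = mesh.element_sizes()
        hp = np.ones(pts.shape[0])
        for p in range(pts.shape[0]):
            try:
                e, xi = mesh.locate(pts[p])
            except PointNotFoundError:
                log.debug("PIV sample point %s outside the mesh; skipped", pts[p])
                continue
            elem[p] = e
            N, _ = shape_functions(mesh.dim, xi[None, :])
            Np[p] = N[0]
            hp[p] = h[e]
        if np.all(elem < 0):
            raise ValueError("PIV plane does not intersect the mesh")
        mesh._cache[key] = (elem, Np, hp)
    return mesh._cache[key]


class PIVMisfitTerm:
    """(w_PIV/h) ||v - g_PIV||^2 rows over the plane's sample-point quadrature."""

    name = "piv"

    def __init__(self, problem, term: PIVTerm, time: float | None = None):
        from .fosls import n_dof_per_node
        self.mesh = problem.mesh if hasattr(problem, "mesh") else problem
        self.term = term
        self.time = problem.time if time is None and hasattr(problem, "time") else time
        self.ndpn = n_dof_per_node(self.mesh.dim)
        self.n_dof_per_node = self.ndpn
        ds = term.dataset
        self.frame_data = data_at_time(ds, self.time, mode=term.time_mode)
        # stored components used by the misfit: "tangential" keeps the two
        # imaging-plane components (both stored components in 2D), "all" keeps
        # every stored component (synthetic 3-component data)
        if term.component_mode == "all":
            self.dirs = ds.directions
        else:
            keep = 2 if self.mesh.dim == 3 else ds.directions.shape[0]
            self.dirs = ds.directions[:keep]
        elem, Np, hp = _locate_plane_points(self.mesh, ds)
        valid = (elem >= 0) & self.frame_data.flat_mask()
        self.elem, self.Np, self.hp = elem[valid], Np[valid], hp[valid]
        self.aw = ds.area_weights()[valid]
        self.g = self.frame_data.flat_values()[valid]
        self.valid = valid

    def _eval(self, x):
        mesh = self.mesh
        dim = mesh.dim
        P = self.elem.shape[0]
        nn = mesh.nodes_per_element
        conn = mesh.elements[self.elem]                         # (P, nn)
        gdofs = (conn[:, :, None] * self.ndpn
                 + np.arange(dim)[None, None, :]).reshape(P, nn * dim)
        xv = x.reshape(-1, self.ndpn)[conn][:, :, :dim]         # (P, nn, dim)
        vq = np.einsum("pn,pni->pi", self.Np, xv)
        nc = self.dirs.shape[0]
        R = np.einsum("ci,pi->pc", self.dirs, vq) - self.g[:, :nc]
        J = np.einsum("pn,ci->pcni", self.Np, self.dirs).reshape(P, nc, nn * dim)
        w = (self.aw * self.term.w_piv / self.hp)[:, None] * np.ones((1, nc))
        return gdofs, J, R, w

    def contributions(self, x, want_jac=True):
        yield self._eval(x)

    def residual_batches(self, x):
        _, _, R, w = self._eval(x)
        yield self.name, R, w


def plane_misfit(state, term: PIVTerm, mesh: Mesh, time: float
                 ) -> tuple[float, np.ndarray]:
    """Weighted plane misfit of a flow state against one PIV term.

    Returns the functional term value (w_PIV/h scaling included) and the
    per-sample-point residual vectors (masked-out points excluded).
    """
    t = PIVMisfitTerm(mesh, term, time=time)
    _, _, R, w = t._eval(state.pack())
    return float(np.sum(w * R * R)), R


def unweighted_plane_misfit(state, term: PIVTerm, mesh: Mesh, time: float) -> float:
    """integral |v - g_PIV|^2 over the plane (no w/h scaling); noise-floor metric."""
    t = PIVMisfitTerm(mesh, term, time=time)
    _, _, R, _ = t._eval(state.pack())
    return float(np.sum(t.aw[:, None] * R * R))


# ---------------------------------------------------------------------------
# outlier flagging (advisory; nothing is filtered automatically)
# ---------------------------------------------------------------------------

def flag_outliers(dataset: PIVDataSet, k: float = 5.0) -> np.ndarray:
    """Flag vectors deviating more than k*sigma from a 3x3 local median.

    Returns a boolean array (nt, n1, n2); nothing is removed — the caller may
    fold the flags into the validity mask if desired.
    """
    nt, n1, n2, nc = dataset.velocities.shape
    sig = np.broadcast_to(np.asarray(dataset.sigma, dtype=float),
                          (nt, n1, n2)).astype(float)
    flags = np.zeros((nt, n1, n2), dtype=bool)
    for it in range(nt):
        dev2 = np.zeros((n1, n2))
        for c in range(nc):
            med = median_filter(dataset.velocities[it, :, :, c], size=3,
                                mode="nearest")
            dev2 += (dataset.velocities[it, :, :, c] - med) ** 2
        flags[it] = np.sqrt(dev2) > k * sig[it]
    return flags


# ---------------------------------------------------------------------------
# CSV I/O (long format, bit-stable round trip)
# ---------------------------------------------------------------------------

def write_piv_csv(dataset: PIVDataSet, path: str) -> None:
    """Write the dataset as long-format CSV with the plane frame in a header block."""
    ds = dataset
    with open(path, "w") as fh:
        def emit(key, arr):
            fh.write(f"# {key}: " + " ".join(repr(float(v)) for v in np.atleast_1d(arr))
                     + "\n")
        fh.write(f"# dim: {ds.frame.dim}\n")
        emit("origin", ds.frame.origin)
        emit("e1", ds.frame.e1)
        if ds.frame.e2 is not None:
            emit("e2", ds.frame.e2)
        emit("normal", ds.frame.normal)
        fh.write(f"# grid: {ds.s1.shape[0]} {ds.s2.shape[0]}\n")
        for c in range(ds.directions.shape[0]):
            emit(f"direction{c + 1}", ds.directions[c])
        cols = ["time", "s1", "s2"] + [f"u{c + 1}" for c in
                                       range(ds.velocities.shape[3])] \
            + ["sigma", "valid"]
        fh.write(",".join(cols) + "\n")
        sp = ds.sample_points()
        sig = np.broadcast_to(np.asarray(ds.sigma, dtype=float),
                              ds.velocities.shape[:3])
        for it, t in enumerate(ds.times):
            u = ds.velocities[it].reshape(-1, ds.velocities.shape[3], order="F")
            m = ds.validity_mask[it].reshape(-1, order="F")
            s = sig[it].reshape(-1, order="F")
            for p in range(sp.shape[0]):
                row = [repr(float(t)), repr(float(sp[p, 0])), repr(float(sp[p, 1]))]
                row += [repr(float(x)) for x in u[p]]
                row += [repr(float(s[p])), str(int(m[p]))]
                fh.write(",".join(row) + "\n")


def read_piv_csv(path: str) -> PIVDataSet:
    """Read a dataset written by :func:`write_piv_csv` (bit-stable round trip)."""
    header: dict[str, list[float] | int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, rest = line[1:].partition(":")
            key = key.strip()
            vals = rest.split()
            header[key] = [float(v) for v in vals] if key != "dim" else int(vals[0])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    dim = header["dim"]
    e2 = np.array(header["e2"]) if "e2" in header else None
    frame = PlaneFrame(np.array(header["origin"]), np.array(header["e1"]), e2,
                       np.array(header["normal"]))
    n1, n2 = int(header["grid"][0]), int(header["grid"][1])
    dirs = np.array([header[f"direction{c + 1}"]
                     for c in range(sum(1 for k in header if k.startswith("direction")))])
    times = np.unique(df["time"].to_numpy())
    nt = times.shape[0]
    ucols = [c for c in df.columns if c.startswith("u")]
    nc = len(ucols)
    vel = df[ucols].to_numpy().reshape(nt, n2, n1, nc).transpose(0, 2, 1, 3)
    mask = df["valid"].to_numpy().astype(bool).reshape(nt, n2, n1).transpose(0, 2, 1)
    sig = df["sigma"].to_numpy().reshape(nt, n2, n1).transpose(0, 2, 1)
    s = df[["s1", "s2"]].to_numpy()[: n1 * n2]
    s1 = s[:n1, 0]
    s2 = s[::n1, 1]
    sigma = float(sig.flat[0]) if np.all(sig == sig.flat[0]) else sig
    return PIVDataSet(frame, s1, s2, vel, sigma, times, dirs, mask)
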