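"""Synthetic planar PIV data from analytic or solver-generated flows.

This module stands in for the optical / echocardiographic PIV experiments: it
projects a velocity field onto a plane's measured components on a rectangular
sample grid, then corrupts it with Gaussian noise, dropout (masked-invalid
vectors), and occasional gross outliers that mimic spurious cross-correlation
peaks.  Identical seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .assimilation import PIVDataSet
from .geometry import PlaneFrame


@dataclass
class NoiseModel:
    """Additive Gaussian noise plus dropout and direction-randomized outliers."""

    sigma: float = 0.0
    dropout_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_scale: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        for name in ("dropout_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# analytic oracle flows
# ---------------------------------------------------------------------------

class AnalyticFlow:
    """Base class: exact v(x, t); omega/r where a closed form exists."""

    has_first_order_fields = False

    def v(self, x: np.ndarray, t: float = 0.0) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x, t=0.0):
        return self.v(x, t)


class Poiseuille2D(AnalyticFlow):
    """Steady plane channel flow v = (4 u_max y(H-y)/H^2, 0) with exact omega, r."""

    has_first_order_fields = True

    def __init__(self, u_max: float = 1.0, H: float = 1.0, Re: float = 1.0):
        self.u_max, self.H, self.Re = u_max, H, Re

    def v(self, x, t=0.0):
        x = np.atleast_2d(x)
        y = x[:, 1]
        out = np.zeros_like(x, dtype=float)
        out[:, 0] = 4.0 * self.u_max * y * (self.H - y) / self.H ** 2
        return out

    def omega(self, x, t=0.0):
        # omega = -curl v = d v1 / d y
        x = np.atleast_2d(x)
        y = x[:, 1]
        return (4.0 * self.u_max * (self.H - 2.0 * y) / self.H ** 2)[:, None]

    def r(self, x, t=0.0):
        # steady momentum: grad p = (1/Re) lap v; r = grad p + (Re/2) grad |v|^2
        x = np.atleast_2d(x)
        y = x[:, 1]
        v1 = 4.0 * self.u_max * y * (self.H - y) / self.H ** 2
        dv1 = 4.0 * self.u_max * (self.H - 2.0 * y) / self.H ** 2
        out = np.zeros_like(x, dtype=float)
        out[:, 0] = -8.0 * self.u_max / (self.Re * self.H ** 2)
        out[:, 1] = self.Re * v1 * dv1
        return out

    def grad_v(self, x, t=0.0):
        x = np.atleast_2d(x)
        g = np.zeros((x.shape[0], 2, 2))
        g[:, 0, 1] = 4.0 * self.u_max * (self.H - 2.0 * x[:, 1]) / self.H ** 2
        return g

    def grad_omega(self, x, t=0.0):
        x = np.atleast_2d(x)
        g = np.zeros((x.shape[0], 1, 2))
        g[:, 0, 1] = -8.0 * self.u_max / self.H ** 2
        return g

    def grad_r(self, x, t=0.0):
        x = np.atleast_2d(x)
        y = x[:, 1]
        u, H = self.u_max, self.H
        v1 = 4.0 * u * y * (H - y) / H ** 2
        dv1 = 4.0 * u * (H - 2.0 * y) / H ** 2
        g = np.zeros((x.shape[0], 2, 2))
        g[:, 1, 1] = self.Re * (dv1 ** 2 + v1 * (-8.0 * u / H ** 2))
        return g


class RigidRotation2D(AnalyticFlow):
    """Solid-body rotation v = Omega (-y, x); omega = -2 Omega, r = 2 Re Omega^2 x."""

    has_first_order_fields = True

    def __init__(self, Omega: float = 1.0, Re: float = 1.0):
        self.Omega, self.Re = Omega, Re

    def v(self, x, t=0.0):
        x = np.atleast_2d(x)
        return self.Omega * np.stack([-x[:, 1], x[:, 0]], axis=-1)

    def omega(self, x, t=0.0):
        x = np.atleast_2d(x)
        return np.full((x.shape[0], 1), -2.0 * self.Omega)

    def r(self, x, t=0.0):
        x = np.atleast_2d(x)
        return 2.0 * self.Re * self.Omega ** 2 * x[:, :2]

    def grad_v(self, x, t=0.0):
        x = np.atleast_2d(x)
        g = np.zeros((x.shape[0], 2, 2))
        g[:, 0, 1] = -self.Omega
        g[:, 1, 0] = self.Omega
        return g

    def grad_omega(self, x, t=0.0):
        x = np.atleast_2d(x)
        return np.zeros((x.shape[0], 1, 2))

    def grad_r(self, x, t=0.0):
        x = np.atleast_2d(x)
        g = np.zeros((x.shape[0], 2, 2))
        g[:, 0, 0] = g[:, 1, 1] = 2.0 * self.Re * self.Omega ** 2
        return g


class DecayingVortex2D(AnalyticFlow):
    """Taylor vortex array decaying as exp(-2 k^2 t / Re^2) in the Re-on-both-
    terms scaling; exact omega and r in closed form."""

    has_first_order_fields = True

    def __init__(self, Re: float = 10.0, k: float = np.pi, amplitude: float = 1.0):
        self.Re, self.k, self.A = Re, k, amplitude

    @property
    def decay_rate(self) -> float:
        return 2.0 * self.k ** 2 / self.Re ** 2

    def _F(self, t):
        return self.A * np.exp(-self.decay_rate * t)

    def v(self, x, t=0.0):
        x = np.atleast_2d(x)
        k, F = self.k, self._F(t)
        return F * np.stack([-np.cos(k * x[:, 0]) * np.sin(k * x[:, 1]),
                             np.sin(k * x[:, 0]) * np.cos(k * x[:, 1])], axis=-1)

    def dvdt(self, x, t=0.0):
        return -self.decay_rate * self.v(x, t)

    def omega(self, x, t=0.0):
        x = np.atleast_2d(x)
        k, F = self.k, self._F(t)
        return (-2.0 * k * F * np.cos(k * x[:, 0]) * np.cos(k * x[:, 1]))[:, None]

    def r(self, x, t=0.0):
        # p = -(Re F^2/4)(cos 2kx + cos 2ky); r = grad p + (Re/2) grad |v|^2
        x = np.atleast_2d(x)
        k, F, Re = self.k, self._F(t), self.Re
        s2x, s2y = np.sin(2 * k * x[:, 0]), np.sin(2 * k * x[:, 1])
        c2x, c2y = np.cos(2 * k * x[:, 0]), np.cos(2 * k * x[:, 1])
        out = np.empty_like(x, dtype=float)
        out[:, 0] = 0.5 * Re * F * F * k * s2x * (1.0 + c2y)
        out[:, 1] = 0.5 * Re * F * F * k * s2y * (1.0 + c2x)
        return out

    def grad_v(self, x, t=0.0):
        x = np.atleast_2d(x)
        k, F = self.k, self._F(t)
        sx, cx = np.sin(k * x[:, 0]), np.cos(k * x[:, 0])
        sy, cy = np.sin(k * x[:, 1]), np.cos(k * x[:, 1])
        g = np.empty((x.shape[0], 2, 2))
        g[:, 0, 0] = F * k * sx * sy
        g[:, 0, 1] = -F * k * cx * cy
        g[:, 1, 0] = F * k * cx * cy
        g[:, 1, 1] = -F * k * sx * sy
        return g

    def grad_omega(self, x, t=0.0):
        x = np.atleast_2d(x)
        k, F = self.k, self._F(t)
        g = np.empty((x.shape[0], 1, 2))
        g[:, 0, 0] = 2.0 * k * k * F * np.sin(k * x[:, 0]) * np.cos(k * x[:, 1])
        g[:, 0, 1] = 2.0 * k * k * F * np.cos(k * x[:, 0]) * np.sin(k * x[:, 1])
        return g

    def grad_r(self, x, t=0.0):
        x = np.atleast_2d(x)
        k, F, Re = self.k, self._F(t), self.Re
        s2x, s2y = np.sin(2 * k * x[:, 0]), np.sin(2 * k * x[:, 1])
        c2x, c2y = np.cos(2 * k * x[:, 0]), np.cos(2 * k * x[:, 1])
        g = np.empty((x.shape[0], 2, 2))
        A = Re * F * F * k * k
        g[:, 0, 0] = A * c2x * (1.0 + c2y)
        g[:, 0, 1] = -A * s2x * s2y
        g[:, 1, 0] = -A * s2y * s2x
        g[:, 1, 1] = A * c2y * (1.0 + c2x)
        return g


class JetProfile(AnalyticFlow):
    """Paraboloid jet: v = v_max (1 - rho^2/R^2)_+ along ``direction``.

    ``rho`` is the distance from the jet axis through ``center`` (measured
    perpendicular to ``direction``); an optional time envelope models the pump
    being switched on and off.
    """

    def __init__(self, center, radius: float, v_max: float = 1.0,
                 direction=None, envelope: Callable[[float], float] | None = None):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)
        self.v_max = float(v_max)
        dim = self.center.shape[0]
        d = np.zeros(dim)
        d[0] = 1.0
        self.direction = d if direction is None \
            else np.asarray(direction, dtype=float) / np.linalg.norm(direction)
        self.envelope = envelope or (lambda t: 1.0)

    def v(self, x, t=0.0):
        x = np.atleast_2d(x)
        rel = x - self.center
        rel = rel - np.outer(rel @ self.direction, self.direction)
        rho2 = np.einsum("pi,pi->p", rel, rel)
        mag = self.v_max * np.maximum(1.0 - rho2 / self.radius ** 2, 0.0) \
            * self.envelope(t)
        return mag[:, None] * self.direction[None, :]


_FLOWS = {"poiseuille": Poiseuille2D, "rigid_rotation": RigidRotation2D,
          "decaying_vortex": DecayingVortex2D, "jet_profile": JetProfile}


def analytic_flow(name: str, **params) -> AnalyticFlow:
    """Build a named analytic flow (the oracle flows used in verification)."""
    if name not in _FLOWS:
        raise ValueError(f"unknown flow {name!r}; valid names: {sorted(_FLOWS)}")
    return _FLOWS[name](**params)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_piv(flow, frame: PlaneFrame, grid_spec, times,
               noise: NoiseModel | None = None) -> PIVDataSet:
    """Project a flow onto a plane's measured components and corrupt it.

    ``grid_spec`` is (n1, n2, (s1_min, s1_max), (s2_min, s2_max)); in 2D pass
    n2 = 1 and any s2 range.  ``flow`` is a callable v(x, t) -> (m, dim) (an
    AnalyticFlow works directly).  The dataset records the noise sigma (a small
    floor is used when sigma = 0 so downstream 1/sigma^2 weights stay finite).
    """
    noise = noise or NoiseModel()
    n1, n2, s1r, s2r = grid_spec
    if n1 < 1 or n2 < 1:
        raise ValueError("grid counts must be positive")
    s1 = np.linspace(s1r[0], s1r[1], n1) if n1 > 1 else np.array([np.mean(s1r)])
    s2 = np.linspace(s2r[0], s2r[1], n2) if n2 > 1 else np.array([np.mean(s2r)])
    dirs = frame.in_plane_directions("tangential")
    ncomp = dirs.shape[0]
    times = np.atleast_1d(np.asarray(times, dtype=float))
    S1, S2 = np.meshgrid(s1, s2, indexing="ij")
    sp = np.stack([S1.reshape(-1, order="F"), S2.reshape(-1, order="F")], axis=-1)
    pts = frame.to_world(sp)
    rng = np.random.default_rng(noise.seed)
    nt, P = times.shape[0], pts.shape[0]
    vel = np.zeros((nt, P, ncomp))
    mask = np.ones((nt, P), dtype=bool)
    for it, t in enumerate(times):
        truth = np.asarray(flow(pts, t), dtype=float) @ dirs.T
        u = truth + rng.normal(0.0, noise.sigma, size=truth.shape) \
            if noise.sigma > 0 else truth.copy()
        if noise.dropout_rate > 0:
            mask[it] = rng.random(P) >= noise.dropout_rate
        if noise.outlier_rate > 0:
            hit = rng.random(P) < noise.outlier_rate
            speed = np.linalg.norm(truth, axis=1)
            mag = noise.outlier_scale * np.maximum(speed, max(noise.sigma, 1e-3))
            direction = rng.normal(size=(P, ncomp))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            u[hit] = mag[hit, None] * direction[hit]
        vel[it] = u
    sigma = noise.sigma if noise.sigma > 0 else 1e-12
    # flat order is s1-fastest: p = i1 + n1*i2
    ds = PIVDataSet(frame, s1, s2,
                    vel.reshape(nt, n2, n1, ncomp).transpose(0, 2, 1, 3),
                    sigma, times, dirs,
                    mask.reshape(nt, n2, n1).transpose(0, 2, 1))
    ds.metadata.update(noise=vars(noise).copy(), generator=type(flow).__name__)
    return ds
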