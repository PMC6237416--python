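"""Reduced potential energy of the translocase-nucleosome system.

The total energy is a sum of closed-form terms in the 16 reduced coordinates:

* periodic histone-DNA contact wells, ``depth_j (1 - cos 2 pi x_j)/2``;
* a linear positioning tilt ``tilt_j x_j`` (nonzero only for strongly
  positioning sequences);
* three-well twist-defect energies at the 13 integer SHLs, with local minima
  at d = -1, 0, +1 of energies mu_minus, 0, mu_plus, harmonic curvature k
  around each well, blended by a log-sum-exp with smoothing temperature
  ``smoothing`` so the gradient is continuous;
* periodic lobe grip wells in y1 and y2 with chemical-state-dependent depths;
* an open/closed conformational term: a cosine double well in u = y1 - y2
  with minima at u = 0 (open) and u = 1 (closed) separated by the barrier
  ``closure_barrier``, a soft flat-bottom confinement of u to the
  open/closed corridor [-0.25, 1.25], and a smoothstep offset putting the
  closed minimum at closure_offset - lobe_coupling (penalized in the apo
  and ADP states, nearly level with ATP bound);
* the ATP-state lobe-1 strain, a saturating destabilization of the
  unadvanced lobe-1 register measured from the cycle-start registration
  (``y_anchor``): it encodes the body-frame asymmetry of closure (the
  closed native structure has lobe 1, not lobe 2, displaced) and carries
  the ATP binding work that loads the ratchet;
* a flat-bottom steric wall on the excursion of the remodeler body relative
  to the DNA at its binding site, rho = (x_1.5 + x_2.5)/2 - (y1 + y2)/2;
* the electrostatic spring between the lobe-1 basic patch and the distal
  DNA gyre, a Gaussian well in r1 = (x_1.5 + x_2.5)/2 - y1.

All kernels are vectorized: ``X`` has shape (..., 14) and ``Y`` (..., 2);
energies come back with shape (...,).  In bare-DNA mode (``ps.naked``) only
the lobe terms (grips, conformational well, strain) are active.
"""

from __future__ import annotations

import numpy as np

from .model import IX_P15, IX_P25, GRID, DefectSiteParams, ParameterSet, SystemState

__all__ = [
    "twist_energy",
    "twist_energy_grad",
    "total_energy",
    "gradient",
    "batch_energy",
    "batch_gradient",
    "smoothstep",
    "WindowRestraint",
]

TWO_PI = 2.0 * np.pi
FLANK_WIDTH = 0.2  # bp, saturation range of the contact flank term
CONFINE_K = 25.0  # kT/bp^2, soft wall keeping u = y1 - y2 in [-0.25, 1.25]


def smoothstep(t: np.ndarray) -> np.ndarray:
    """C1 switch: 0 for t <= 0, 1 for t >= 1, 3t^2 - 2t^3 between."""
    tc = np.clip(t, 0.0, 1.0)
    return tc * tc * (3.0 - 2.0 * tc)


def smoothstep_deriv(t: np.ndarray) -> np.ndarray:
    tc = np.clip(t, 0.0, 1.0)
    return 6.0 * tc * (1.0 - tc)


def _twist_lse(d, k, mu_plus, mu_minus, temp):
    """Smoothed minimum over the three harmonic defect branches.

    Branch energies are mu_m + k/2 (d - m)^2 for m in {-1, 0, +1}; the
    log-sum-exp at temperature ``temp`` picks the lowest branch smoothly.
    For |d| beyond the outer wells the outermost branch simply continues
    quadratically, which acts as the documented clamp.
    """
    d = np.asarray(d, dtype=float)
    e = np.stack(
        [
            mu_minus + 0.5 * k * (d + 1.0) ** 2,
            0.5 * k * d**2,
            mu_plus + 0.5 * k * (d - 1.0) ** 2,
        ],
        axis=-1,
    )
    emin = e.min(axis=-1, keepdims=True)
    w = np.exp(-(e - emin) / temp)
    z = w.sum(axis=-1)
    u = emin[..., 0] - temp * np.log(z)
    # softmin-weighted mean force
    f = np.stack([k * (d + 1.0), k * d, k * (d - 1.0)], axis=-1)
    du = (w * f).sum(axis=-1) / z
    return u, du


def twist_energy(d, p: DefectSiteParams, smoothing: float = 0.2):
    """Twist-defect energy (kT) at displacement ``d`` (bp) for one site."""
    u, _ = _twist_lse(d, p.k, p.mu_plus, p.mu_minus, smoothing)
    return u if np.ndim(d) else float(u)


def twist_energy_grad(d, p: DefectSiteParams, smoothing: float = 0.2):
    _, du = _twist_lse(d, p.k, p.mu_plus, p.mu_minus, smoothing)
    return du if np.ndim(d) else float(du)


class WindowRestraint:
    """Flat-bottom restraint on (x_1.5 + x_2.5)/2, used by the held-state
    equilibrium protocols to confine sampling to the analysis window.

    Inside ``|xbar - center| <= halfwidth`` the restraint energy is exactly
    zero, so relative Boltzmann weights inside the window are unbiased.
    """

    def __init__(self, center: float = 0.5, halfwidth: float = 1.0, k: float = 50.0):
        self.center = center
        self.halfwidth = halfwidth
        self.k = k

    def energy(self, X: np.ndarray) -> np.ndarray:
        xbar = 0.5 * (X[..., IX_P15] + X[..., IX_P25])
        excess = np.maximum(np.abs(xbar - self.center) - self.halfwidth, 0.0)
        return self.k * excess**2

    def add_gradient(self, X: np.ndarray, gX: np.ndarray) -> None:
        xbar = 0.5 * (X[..., IX_P15] + X[..., IX_P25])
        dev = xbar - self.center
        excess = np.maximum(np.abs(dev) - self.halfwidth, 0.0)
        g = 2.0 * self.k * excess * np.sign(dev) * 0.5
        gX[..., IX_P15] += g
        gX[..., IX_P25] += g


def batch_energy(X: np.ndarray, Y: np.ndarray, ps: ParameterSet) -> np.ndarray:
    """Total energy (kT) for a batch of states."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[-1] != GRID.n_contacts or Y.shape[-1] != 2:
        raise ValueError("X must have 14 contact coordinates and Y two lobe coordinates")
    y1, y2 = Y[..., 0], Y[..., 1]
    u = y1 - y2
    sy1, su = smoothstep(y1 - ps.y_anchor), smoothstep(u)

    # lobe grips (well depth = per-contact strength x engaged contacts)
    e = ps.grip_mult * ps.grip1 * 0.5 * (1.0 - np.cos(TWO_PI * y1))
    e = e + ps.grip_mult * ps.grip2 * 0.5 * (1.0 - np.cos(TWO_PI * y2))
    # conformational double well; the closed minimum sits at
    # closure_offset - lobe_coupling (above the open one except with ATP);
    # cosine form keeps the curvature bounded for the explicit integrator,
    # a flat-bottom wall confines u to the open/closed corridor
    e = e + ps.closure_barrier * 0.5 * (1.0 - np.cos(TWO_PI * u))
    e = e + CONFINE_K * (
        np.maximum(-(u + 0.25), 0.0) ** 2 + np.maximum(u - 1.25, 0.0) ** 2
    )
    e = e + (ps.closure_offset - ps.lobe_coupling) * su
    # ATP lobe-1 strain, anchored to the cycle-start registration
    e = e + ps.lobe1_strain * (1.0 - sy1)

    if ps.naked:
        return e

    # histone-DNA contact wells and tilt; the flank term saturates within
    # ~0.2 bp of each register, penalizing partial (distributed) DNA
    # displacement without raising the barrier top for full 1-bp hops
    e = e + np.sum(ps.contact_depth * 0.5 * (1.0 - np.cos(TWO_PI * X)), axis=-1)
    delta = np.abs(X - np.round(X))
    e = e + np.sum(ps.contact_flank * smoothstep(delta / FLANK_WIDTH), axis=-1)
    e = e + np.sum(ps.tilt * X, axis=-1)
    # twist defects
    d = np.diff(X, axis=-1)
    ut, _ = _twist_lse(d, ps.twist_k, ps.twist_mu_plus, ps.twist_mu_minus, ps.smoothing)
    e = e + ut.sum(axis=-1)
    # steric wall
    xbar = 0.5 * (X[..., IX_P15] + X[..., IX_P25])
    rho = xbar - 0.5 * (y1 + y2)
    excess = np.maximum(np.abs(rho) - ps.wall_halfwidth, 0.0)
    e = e + ps.wall_height * excess**2
    # electrostatic spring
    r1 = xbar - y1
    e = e - ps.eps_elec * np.exp(-(r1**2) / (2.0 * ps.elec_width**2))
    return e


def batch_gradient(X: np.ndarray, Y: np.ndarray, ps: ParameterSet):
    """Analytic gradient; returns (gX, gY) with shapes matching X, Y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    y1, y2 = Y[..., 0], Y[..., 1]
    u = y1 - y2
    sy1, su = smoothstep(y1 - ps.y_anchor), smoothstep(u)
    dsy1, dsu = smoothstep_deriv(y1 - ps.y_anchor), smoothstep_deriv(u)

    gX = np.zeros_like(X)
    g1 = ps.grip_mult * ps.grip1 * np.pi * np.sin(TWO_PI * y1)
    g2 = ps.grip_mult * ps.grip2 * np.pi * np.sin(TWO_PI * y2)
    dV_du = ps.closure_barrier * np.pi * np.sin(TWO_PI * u)
    dV_du = dV_du + 2.0 * CONFINE_K * (
        np.maximum(u - 1.25, 0.0) - np.maximum(-(u + 0.25), 0.0)
    )
    dV_du = dV_du + (ps.closure_offset - ps.lobe_coupling) * dsu
    g1 = g1 + dV_du
    g2 = g2 - dV_du
    g1 = g1 - ps.lobe1_strain * dsy1

    if not ps.naked:
        gX += ps.contact_depth * np.pi * np.sin(TWO_PI * X) + ps.tilt
        dev = X - np.round(X)
        gX += (
            ps.contact_flank
            * smoothstep_deriv(np.abs(dev) / FLANK_WIDTH)
            / FLANK_WIDTH
            * np.sign(dev)
        )
        d = np.diff(X, axis=-1)
        _, dud = _twist_lse(d, ps.twist_k, ps.twist_mu_plus, ps.twist_mu_minus, ps.smoothing)
        gX[..., 1:] += dud
        gX[..., :-1] -= dud

        xbar = 0.5 * (X[..., IX_P15] + X[..., IX_P25])
        rho = xbar - 0.5 * (y1 + y2)
        excess = np.maximum(np.abs(rho) - ps.wall_halfwidth, 0.0)
        dwall = 2.0 * ps.wall_height * excess * np.sign(rho)
        gX[..., IX_P15] += 0.5 * dwall
        gX[..., IX_P25] += 0.5 * dwall
        g1 = g1 - 0.5 * dwall
        g2 = g2 - 0.5 * dwall

        r1 = xbar - y1
        delec = ps.eps_elec * r1 / ps.elec_width**2 * np.exp(
            -(r1**2) / (2.0 * ps.elec_width**2)
        )
        gX[..., IX_P15] += 0.5 * delec
        gX[..., IX_P25] += 0.5 * delec
        g1 = g1 - delec

    gY = np.stack([g1, g2], axis=-1)
    return gX, gY


def total_energy(s: SystemState, ps: ParameterSet) -> float:
    """Total reduced energy (kT) of a single state."""
    return float(batch_energy(s.x[None, :], np.array([[s.y1, s.y2]]), ps)[0])


def gradient(s: SystemState, ps: ParameterSet) -> np.ndarray:
    """Analytic 16-component gradient (kT/bp), ordered x_-6.5 ... x_6.5, y1, y2."""
    gX, gY = batch_gradient(s.x[None, :], np.array([[s.y1, s.y2]]), ps)
    return np.concatenate([gX[0], gY[0]])
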