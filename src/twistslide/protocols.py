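"""Higher-level study protocols built from the core modules.

These functions assemble the standard computations: fixed-chemical-state
equilibrium sampling (with the analysis-window restraint), Boltzmann-
inverted sliding profiles, and label-state Markov models of the closed
ensemble.  Problem sizes (replica counts, run lengths) are arguments with
desk-scale defaults.
"""

from __future__ import annotations

import numpy as np

from .dynamics import IntegratorConfig, Trajectory, _propagate
from .energy import WindowRestraint
from .model import (
    ChemicalState,
    RemodelerParams,
    SequenceProfile,
    SystemState,
    effective_params,
)
from . import cv, msm

__all__ = [
    "no_remodeler_params",
    "run_held",
    "sliding_profile",
    "closed_label_msm",
    "closed_mfpt",
    "LANDSCAPE_EDGES_2D",
]

# analysis grid: 0.1 bp bins over the SHL-2 sliding coordinate and the
# dyad-defect coordinate, closed-ensemble convention
LANDSCAPE_EDGES_2D = (
    np.arange(-0.5, 1.5001, 0.1),
    np.arange(-0.5, 2.5001, 0.1),
)


def no_remodeler_params() -> RemodelerParams:
    """Parameters of the bare nucleosome: every translocase term off."""
    return RemodelerParams(
        eps_lobe_dna=(0.0, 0.0),
        eps_lobes={c: 0.0 for c in ChemicalState},
        lobe1_strain=0.0,
        closure_offset=0.0,
        closure_barrier=0.0,
        eps_elec=0.0,
        wall_height=0.0,
    )


def run_held(
    base: RemodelerParams,
    seq: SequenceProfile,
    chem: ChemicalState,
    n_replicas: int = 32,
    t_total: float = 500.0,
    t_burnin: float = 50.0,
    seed0: int = 0,
    cfg: IntegratorConfig | None = None,
    s0: SystemState | None = None,
    restrain: bool = True,
    closed: bool = False,
):
    """Equilibrium sampling with one chemical-state parameter set held fixed.

    A flat-bottom window restraint confines the SHL-2 sliding coordinate to
    the analysis window [-0.5, 1.5]; inside the window relative Boltzmann
    weights are unbiased.  ``closed`` adds a flat-bottom floor keeping
    u = y1 - y2 above 0.7, i.e. sampling restricted to the closed-translocase
    manifold.  Returns a list of per-replica Trajectory objects with the
    burn-in removed.
    """
    cfg = cfg or IntegratorConfig(stride=0.1)
    s0 = s0 or SystemState.zeros()
    ps = effective_params(base, seq, chem)
    n_steps = int(round(t_total / cfg.dt))
    seeds = np.arange(seed0, seed0 + n_replicas)
    restraint = WindowRestraint(center=0.5, halfwidth=1.0, k=50.0) if restrain else None
    if isinstance(s0, (list, tuple)):
        # per-replica starting states, cycled over the ensemble
        X0 = np.stack([s0[r % len(s0)].x for r in range(n_replicas)])
        Y0 = np.array([[s0[r % len(s0)].y1, s0[r % len(s0)].y2] for r in range(n_replicas)])
    else:
        X0 = np.tile(s0.x, (n_replicas, 1))
        Y0 = np.tile([s0.y1, s0.y2], (n_replicas, 1))
    times, chems, Xs, Ys = _propagate(
        X0,
        Y0,
        [(ps, n_steps)],
        cfg,
        seeds,
        restraint=restraint,
        u_floor=0.7 if closed else None,
    )
    keep = times >= t_burnin
    return [
        Trajectory(
            times=times[keep],
            chem=chems[keep],
            X=Xs[keep, r],
            Y=Ys[keep, r],
            seed=int(seeds[r]),
            param_digest=ps.digest(),
        )
        for r in range(n_replicas)
    ]


def sliding_profile(trajs, bins=None, closed_only: bool = False, min_count: int = 10):
    """Boltzmann-inverted free-energy profile along (x_1.5 + x_2.5)/2."""
    if bins is None:
        bins = [LANDSCAPE_EDGES_2D[0]]
    samples = []
    for traj in trajs:
        xbar = cv.shl2_coordinate(traj)
        if closed_only:
            u = traj.Y[:, 0] - traj.Y[:, 1]
            xbar = xbar[u >= 0.5]
        samples.append(xbar)
    return msm.boltzmann_invert(np.concatenate(samples), bins, min_count=min_count)


def well_depth_difference(fep, a: float, b: float, halfwidth: float = 0.15) -> float:
    """F(minimum near a) - F(minimum near b) on a 1-D profile."""
    (c,) = fep.centers
    fa = np.nanmin(np.where(np.abs(c - a) <= halfwidth, fep.F, np.nan))
    fb = np.nanmin(np.where(np.abs(c - b) <= halfwidth, fep.F, np.nan))
    return float(fa - fb)


def barrier_height(fep, a: float, b: float, halfwidth: float = 0.3) -> float:
    """Max F between the minima near a and b, relative to the lower-F
    minimum location's basin (1-D profile)."""
    (c,) = fep.centers
    ia = int(np.nanargmin(np.where(np.abs(c - a) <= halfwidth, fep.F, np.nan)))
    ib = int(np.nanargmin(np.where(np.abs(c - b) <= halfwidth, fep.F, np.nan)))
    lo, hi = sorted((ia, ib))
    seg = fep.F[lo : hi + 1]
    return float(np.nanmax(seg) - fep.F[ia])


def closed_label_msm(trajs, lag_time: float = 2.5, ref: SystemState | None = None,
                     dwell_min: float = 0.3):
    """Label-state Markov model from held-ensemble trajectories.

    Frames are labeled with the metastable-state grammar; one dtraj per
    replica (single chemical phase, so no phase bridging arises); counts
    symmetrized; lag in time units (must be a multiple of the stride).
    """
    stride = trajs[0].times[1] - trajs[0].times[0]
    lag = int(round(lag_time / stride))
    if abs(lag * stride - lag_time) > 1e-9:
        raise ValueError("lag must be a multiple of the snapshot stride")
    all_labels = [cv.milestoned_labels(t, dwell_min, ref) for t in trajs]
    states = sorted(set().union(*[set(l) for l in all_labels]))
    lut = {k: i for i, k in enumerate(states)}
    dtrajs = [np.array([lut[k] for k in l]) for l in all_labels]
    C = msm.count_matrix(dtrajs, lag, n_states=len(states))
    return msm.transition_matrix(C, symmetrize=True, lag=lag_time, states=states)


def closed_mfpt(model, source: str = "cB1", target: str = "cD1") -> float:
    """Mean first-passage time (time units) between two label states."""
    m = msm.mfpt(model, [model.state_index(target)])
    return float(m[model.state_index(source)])
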