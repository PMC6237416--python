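"""Overdamped Langevin dynamics under a chemical-state switching schedule.

The 16 reduced coordinates evolve by Euler-Maruyama,

    q  <-  q - dE/dq * D_q * dt + sqrt(2 D_q dt) * xi,

with independent standard-normal noise per coordinate and step; DNA contact
coordinates use ``D_dna`` and lobe coordinates ``D_lobe``.  An ATP cycle is
simulated by switching the ParameterSet instantaneously at phase boundaries
(apo -> ATP -> ADP); the final switch back to apo changes interaction
parameters only and needs no extra phase.

One reduced time unit corresponds to 1e5 steps of the residue-level
simulations this model condenses, so the default cycle (apo 200, ATP 100,
ADP 100) mirrors a 2e7/1e7/1e7-step protocol.

Randomness is generator-per-trajectory (Philox keyed by the trajectory
seed), so ensembles are order-independent and each member is bit-identical
to the same trajectory run alone.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import WindowRestraint, batch_gradient
from ._kernels import HAVE_NUMBA, step_block
from .model import (
    GRID,
    ChemicalState,
    ParameterSet,
    RemodelerParams,
    SequenceProfile,
    SystemState,
    effective_params,
)

__all__ = [
    "IntegratorConfig",
    "Schedule",
    "Trajectory",
    "step",
    "run_schedule",
    "run_naked",
    "run_ensemble",
]

_NOISE_BLOCK = 2048  # steps of noise drawn per generator call


@dataclass(frozen=True)
class IntegratorConfig:
    """Time step, diffusion coefficients (bp^2 per reduced time unit) and
    snapshot stride."""

    dt: float = 5e-4
    D_dna: float = 0.05
    D_dna_outer: float = 0.05
    D_lobe: float = 1.0
    stride: float = 0.05

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.D_dna <= 0 or self.D_lobe <= 0 or self.D_dna_outer <= 0:
            raise ValueError("dt and diffusion coefficients must be positive")
        if self.stride < self.dt:
            raise ValueError("stride must be at least one time step")

    def dna_diffusion(self) -> np.ndarray:
        """Per-contact diffusion coefficients: the strongly held central
        region (|SHL| < 3) moves with D_dna, the weakly held outer arms
        with D_dna_outer."""
        return np.where(np.abs(GRID.contact_shls) < 3.0, self.D_dna, self.D_dna_outer)

    @property
    def record_every(self) -> int:
        return max(1, int(round(self.stride / self.dt)))


@dataclass(frozen=True)
class Schedule:
    """Ordered (ChemicalState, duration) phases of one ATP cycle."""

    phases: tuple

    def __post_init__(self) -> None:
        for chem, dur in self.phases:
            if not isinstance(chem, ChemicalState):
                raise TypeError(f"unknown chemical state {chem!r}")
            if dur <= 0:
                raise ValueError("phase durations must be positive")

    @classmethod
    def default(cls) -> "Schedule":
        return cls(
            (
                (ChemicalState.APO, 200.0),
                (ChemicalState.ATP, 100.0),
                (ChemicalState.ADP, 100.0),
            )
        )

    @classmethod
    def short_hydrolysis(cls) -> "Schedule":
        """ATP phase cut to a tenth: hydrolysis before sliding can complete."""
        return cls(
            (
                (ChemicalState.APO, 200.0),
                (ChemicalState.ATP, 10.0),
                (ChemicalState.ADP, 100.0),
            )
        )

    @classmethod
    def held(cls, chem: ChemicalState, duration: float) -> "Schedule":
        return cls(((chem, duration),))

    @property
    def total_time(self) -> float:
        return float(sum(d for _, d in self.phases))

    def boundaries(self) -> list:
        """Cumulative phase end times."""
        return list(np.cumsum([d for _, d in self.phases]))


@dataclass
class Trajectory:
    """Snapshots of one run at a fixed stride, with reproduction metadata."""

    times: np.ndarray  # (T,)
    chem: np.ndarray  # (T,) object array of ChemicalState
    X: np.ndarray  # (T, 14)
    Y: np.ndarray  # (T, 2)
    seed: int
    param_digest: str = ""
    phase_bounds: tuple = ()
    naked: bool = False

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> SystemState:
        return SystemState(x=self.X[i].copy(), y1=float(self.Y[i, 0]), y2=float(self.Y[i, 1]))

    @property
    def final_state(self) -> SystemState:
        return self.state(len(self) - 1)

    def to_tsv(self, path) -> None:
        cols = [f"x_{s:g}" for s in GRID.contact_shls] + ["y1", "y2"]
        header = (
            f"# twistslide trajectory\n"
            f"# seed={self.seed} digest={self.param_digest} naked={int(self.naked)}\n"
            f"# phase_bounds={','.join(f'{b:g}' for b in self.phase_bounds)}\n"
        )
        df = pd.DataFrame(self.X, columns=cols[:-2])
        df.insert(0, "time", self.times)
        df.insert(1, "chem", [c.value for c in self.chem])
        df["y1"] = self.Y[:, 0]
        df["y2"] = self.Y[:, 1]
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        meta = {"seed": 0, "digest": "", "naked": 0, "phase_bounds": ()}
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            if k == "seed":
                                meta["seed"] = int(v)
                            elif k == "digest":
                                meta["digest"] = v
                            elif k == "naked":
                                meta["naked"] = int(v)
                            elif k == "phase_bounds" and v:
                                meta["phase_bounds"] = tuple(float(x) for x in v.split(","))
                else:
                    lines.append(line)
        df = pd.read_csv(io.StringIO("".join(lines)), sep="\t")
        xcols = [c for c in df.columns if c.startswith("x_")]
        return cls(
            times=df["time"].to_numpy(),
            chem=np.array([ChemicalState(c) for c in df["chem"]], dtype=object),
            X=df[xcols].to_numpy(),
            Y=df[["y1", "y2"]].to_numpy(),
            seed=meta["seed"],
            param_digest=meta["digest"],
            phase_bounds=meta["phase_bounds"],
            naked=bool(meta["naked"]),
        )


def step(
    s: SystemState,
    ps: ParameterSet,
    cfg: IntegratorConfig,
    rng: np.random.Generator,
    noise: bool = True,
) -> SystemState:
    """Advance a single state by one Euler-Maruyama step."""
    X = s.x[None, :].copy()
    Y = np.array([[s.y1, s.y2]])
    gX, gY = batch_gradient(X, Y, ps)
    if not np.all(np.isfinite(gX)) or not np.all(np.isfinite(gY)):
        raise RuntimeError(f"non-finite force at state {s!r}")
    Dx = cfg.dna_diffusion()
    fmax = max((np.abs(gX) * Dx).max(), np.abs(gY).max() * cfg.D_lobe)
    if fmax * cfg.dt > 0.2:
        warnings.warn("time step too large for the current force; reduce dt", stacklevel=2)
    xi = rng.standard_normal(16) if noise else np.zeros(16)
    X = X - gX * Dx * cfg.dt + np.sqrt(2 * Dx * cfg.dt) * xi[:14]
    Y = Y - gY * cfg.D_lobe * cfg.dt + np.sqrt(2 * cfg.D_lobe * cfg.dt) * xi[14:]
    return SystemState(x=X[0], y1=float(Y[0, 0]), y2=float(Y[0, 1]))


def _propagate(
    X0: np.ndarray,
    Y0: np.ndarray,
    phases: list,
    cfg: IntegratorConfig,
    seeds: np.ndarray,
    naked: bool = False,
    restraint: WindowRestraint | None = None,
    u_floor: float | None = None,
):
    """Batched Euler-Maruyama over replicas.

    ``phases`` is a list of (ParameterSet, n_steps).  Returns
    (times, chem_per_frame, Xs, Ys) with Xs of shape (T, R, 14).  Each
    replica r consumes an independent Philox stream keyed by seeds[r], drawn
    in fixed-size blocks so the stream is identical regardless of how many
    replicas run together.
    """
    R = len(seeds)
    X = np.array(X0, dtype=float).copy()
    Y = np.array(Y0, dtype=float).copy()
    dim = 2 if naked else 16
    rngs = [np.random.Generator(np.random.Philox(key=int(s))) for s in seeds]
    m = cfg.record_every
    total = sum(n for _, n in phases)
    n_frames = total // m + 1
    Xs = np.empty((n_frames, R, GRID.n_contacts))
    Ys = np.empty((n_frames, R, 2))
    times = np.empty(n_frames)
    chem = np.empty(n_frames, dtype=object)

    Dx = cfg.dna_diffusion()
    sx = np.sqrt(2.0 * Dx * cfg.dt)
    sy = np.sqrt(2.0 * cfg.D_lobe * cfg.dt)
    cx = Dx * cfg.dt
    cy = cfg.D_lobe * cfg.dt

    frame = 0
    Xs[0], Ys[0] = X, Y
    times[0] = 0.0
    chem[0] = phases[0][0].chem
    frame = 1
    gstep = 0
    noise = np.empty((_NOISE_BLOCK, R, dim))
    for ps, n_steps in phases:
        done = 0
        while done < n_steps:
            b = min(_NOISE_BLOCK, n_steps - done)
            for r in range(R):
                noise[:b, r, :] = rngs[r].standard_normal((b, dim))
            frame_before = frame
            if HAVE_NUMBA:
                frame = step_block(
                    X, Y, noise, b, naked, cfg.dt, Dx, cfg.D_lobe,
                    ps.contact_depth, ps.contact_flank, ps.tilt, ps.twist_k, ps.twist_mu_plus,
                    ps.twist_mu_minus, ps.smoothing, ps.grip1, ps.grip2,
                    ps.grip_mult, ps.closure_offset - ps.lobe_coupling, ps.closure_barrier,
                    ps.lobe1_strain, ps.y_anchor, ps.eps_elec, ps.elec_width,
                    ps.wall_halfwidth, ps.wall_height,
                    restraint is not None,
                    restraint.center if restraint else 0.0,
                    restraint.halfwidth if restraint else 0.0,
                    restraint.k if restraint else 0.0,
                    u_floor is not None,
                    u_floor if u_floor is not None else 0.0,
                    50.0,
                    m, gstep, frame, Xs, Ys,
                )
                gstep += b
            else:  # pure-numpy fallback, identical arithmetic
                for i in range(b):
                    gX, gY = batch_gradient(X, Y, ps)
                    if restraint is not None:
                        restraint.add_gradient(X, gX)
                    if u_floor is not None:
                        uu = Y[:, 0] - Y[:, 1]
                        g = -2.0 * 50.0 * np.maximum(u_floor - uu, 0.0)
                        gY[:, 0] += g
                        gY[:, 1] -= g
                    if naked:
                        Y = Y - gY * cy + sy * noise[i]
                    else:
                        X = X - gX * cx + sx * noise[i, :, :14]
                        Y = Y - gY * cy + sy * noise[i, :, 14:]
                    gstep += 1
                    if gstep % m == 0:
                        Xs[frame], Ys[frame] = X, Y
                        frame += 1
            done += b
            # frame f is recorded at global step f * m
            for f in range(frame_before, frame):
                times[f] = f * m * cfg.dt
                chem[f] = ps.chem
            if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
                bad = np.where(~np.isfinite(X).all(axis=-1) | ~np.isfinite(Y).all(axis=-1))[0]
                raise RuntimeError(
                    f"non-finite coordinates in replicas {bad.tolist()} near t={gstep * cfg.dt:g}"
                )
    return times[:frame], chem[:frame], Xs[:frame], Ys[:frame]


def _phases_in_steps(sched: Schedule, base, seq, cfg, naked=False):
    out = []
    for chem, dur in sched.phases:
        ps = effective_params(base, seq, chem, naked=naked)
        out.append((ps, int(round(dur / cfg.dt))))
    return out


def run_schedule(
    s0: SystemState,
    sched: Schedule,
    base: RemodelerParams,
    seq: SequenceProfile,
    cfg: IntegratorConfig,
    seed: int = 0,
) -> Trajectory:
    """Propagate one trajectory through a full chemical-state schedule."""
    phases = _phases_in_steps(sched, base, seq, cfg)
    times, chem, Xs, Ys = _propagate(
        s0.x[None, :], np.array([[s0.y1, s0.y2]]), phases, cfg, np.array([seed])
    )
    return Trajectory(
        times=times,
        chem=chem,
        X=Xs[:, 0],
        Y=Ys[:, 0],
        seed=seed,
        param_digest=phases[0][0].digest(),
        phase_bounds=tuple(sched.boundaries()),
    )


def run_naked(
    sched: Schedule,
    base: RemodelerParams,
    cfg: IntegratorConfig,
    seed: int = 0,
) -> Trajectory:
    """Translocase on bare DNA: only the lobe coordinates evolve."""
    seq = SequenceProfile.uniform()
    phases = _phases_in_steps(sched, base, seq, cfg, naked=True)
    s0 = SystemState.zeros()
    times, chem, Xs, Ys = _propagate(
        s0.x[None, :], np.array([[0.0, 0.0]]), phases, cfg, np.array([seed]), naked=True
    )
    return Trajectory(
        times=times,
        chem=chem,
        X=Xs[:, 0],
        Y=Ys[:, 0],
        seed=seed,
        param_digest=phases[0][0].digest(),
        phase_bounds=tuple(sched.boundaries()),
        naked=True,
    )


def run_ensemble(
    n: int,
    seed0: int,
    sched: Schedule,
    base: RemodelerParams,
    seq: SequenceProfile,
    cfg: IntegratorConfig,
    s0: SystemState | None = None,
    naked: bool = False,
    keep_trajectories: bool = True,
):
    """Run ``n`` independent cycles with seeds seed0 ... seed0 + n - 1.

    Returns (trajectories, summary) where summary is one row per cycle with
    the DNA and lobe steps, the closure time (first passage of y1 - y2 over
    0.8) and the run-length-condensed label path.  Replicas are propagated
    together but each consumes its own noise stream, so results are
    independent of ensemble composition and mergeable across seed ranges.
    """
    from . import cv  # late import: cv depends on Trajectory

    if n < 1:
        raise ValueError("need at least one trajectory")
    if s0 is None:
        s0 = SystemState.zeros()
    seeds = np.arange(seed0, seed0 + n)
    phases = _phases_in_steps(sched, base, seq, cfg, naked=naked)
    X0 = np.tile(s0.x, (n, 1))
    Y0 = np.tile([s0.y1, s0.y2], (n, 1))
    times, chem, Xs, Ys = _propagate(X0, Y0, phases, cfg, seeds, naked=naked)
    bounds = tuple(sched.boundaries())
    digest = phases[0][0].digest()

    trajs = []
    rows = []
    for r in range(n):
        traj = Trajectory(
            times=times,
            chem=chem,
            X=Xs[:, r],
            Y=Ys[:, r],
            seed=int(seeds[r]),
            param_digest=digest,
            phase_bounds=bounds,
            naked=naked,
        )
        dna_step, lobe_step = cv.cycle_outcome(traj)
        path = cv.label_path(traj)
        rows.append(
            {
                "seed": int(seeds[r]),
                "dna_step": dna_step,
                "lobe_step": lobe_step,
                "closure_time": cv.closure_time(traj),
                "label_path": "->".join(lbl for lbl, _, _ in path),
            }
        )
        if keep_trajectories:
            trajs.append(traj)
    return trajs, pd.DataFrame(rows)
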