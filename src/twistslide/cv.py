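"""Collective variables, metastable-state labels and cycle outcomes.

Labels follow the grammar ``[oc][ABCD]?[012]``: the first letter marks the
translocase conformation (open/closed, split at u = y1 - y2 = 0.5); closed
frames get a capital letter for the configuration at the binding site
(A partial lobe-1 motion, B lobe-1 advanced, C DNA slid at contact 1.5,
D DNA slid past contact 2.5); the digit counts +1 bp twist defects at the
three central SHLs, clamp(round(x_1.5 - x_-1.5), 0, 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import IX_M15, IX_P15, IX_P25, GRID, SystemState
from .dynamics import Trajectory

__all__ = [
    "DefectTimeline",
    "defect_series",
    "shl2_coordinate",
    "projection_2d",
    "label_frame",
    "label_frames",
    "label_path",
    "cycle_outcome",
    "closure_time",
    "closure_lobe",
    "ensemble_probability",
]

CLOSURE_THRESHOLD = 0.8  # u = y1 - y2 first passage defining translocase closure


@dataclass
class DefectTimeline:
    """Per-snapshot twist defects d_i at the 13 integer SHLs."""

    times: np.ndarray
    d: np.ndarray  # (T, 13)

    def at_shl(self, shl: int) -> np.ndarray:
        return self.d[:, GRID.defect_index(shl)]


def defect_series(traj: Trajectory) -> DefectTimeline:
    """d_i(t) = x_{i+0.5}(t) - x_{i-0.5}(t); sums telescope to the end-to-end
    contact difference exactly."""
    return DefectTimeline(times=traj.times, d=np.diff(traj.X, axis=-1))


def shl2_coordinate(traj: Trajectory) -> np.ndarray:
    """Average contact index at the remodeler site, (x_1.5 + x_2.5)/2."""
    return 0.5 * (traj.X[:, IX_P15] + traj.X[:, IX_P25])


def projection_2d(traj: Trajectory):
    """Low-dimensional projection: (y1 + y2 + x_1.5 + x_2.5) against the
    dyad twist-defect count coordinate (x_1.5 - x_-1.5)."""
    a = traj.Y.sum(axis=-1) + traj.X[:, IX_P15] + traj.X[:, IX_P25]
    b = traj.X[:, IX_P15] - traj.X[:, IX_M15]
    return a, b


def _labels_from_arrays(X, Y, refX, refY) -> np.ndarray:
    u = Y[..., 0] - Y[..., 1]
    y1adv = Y[..., 0] - refY[0]
    x15adv = X[..., IX_P15] - refX[IX_P15]
    x25adv = X[..., IX_P25] - refX[IX_P25]
    # defect count near the dyad is registration-independent
    digit = np.clip(
        np.round(X[..., IX_P15] - X[..., IX_M15]).astype(int), 0, 2
    )
    closed = u >= 0.5
    letters = np.where(
        x25adv >= 0.5, "D", np.where(x15adv >= 0.5, "C", np.where(y1adv >= 0.8, "B", "A"))
    )
    out = np.where(
        closed,
        np.char.add(np.char.add("c", letters), digit.astype(str)),
        np.char.add("o", digit.astype(str)),
    )
    return out


def label_frame(s: SystemState, ref: SystemState | None = None) -> str:
    """Metastable-state label of one frame, measured against the cycle-start
    registration ``ref`` (defaults to the zero state)."""
    if ref is None:
        ref = SystemState.zeros()
    return str(
        _labels_from_arrays(
            s.x[None, :], np.array([[s.y1, s.y2]]), ref.x, np.array([ref.y1, ref.y2])
        )[0]
    )


def label_frames(traj: Trajectory, ref: SystemState | None = None) -> np.ndarray:
    if ref is None:
        ref = SystemState.zeros()
    return _labels_from_arrays(traj.X, traj.Y, ref.x, np.array([ref.y1, ref.y2]))


def milestoned_labels(traj: Trajectory, dwell_min: float = 0.3, ref: SystemState | None = None) -> np.ndarray:
    """Per-frame labels with flicker suppression (milestoning).

    A raw frame label is accepted as the current state only once it has
    persisted for ``dwell_min`` time units; frames inside shorter flickers
    keep the previously accepted state.  This gives Markov-state
    trajectories whose transitions are genuine crossings rather than
    threshold noise.
    """
    labels = label_frames(traj, ref)
    t = traj.times
    dt = t[1] - t[0] if len(t) > 1 else dwell_min
    need = max(1, int(np.ceil(dwell_min / dt)))
    out = np.empty_like(labels)
    current = labels[0]
    run_label = labels[0]
    run_len = 0
    for i, lbl in enumerate(labels):
        if lbl == run_label:
            run_len += 1
        else:
            run_label = lbl
            run_len = 1
        if run_len >= need and run_label != current:
            current = run_label
            # retroactively assign the run start to the new state
            out[i - run_len + 1 : i] = current
        out[i] = current
    return out


def label_path(traj: Trajectory, dwell_min: float = 0.25, ref: SystemState | None = None):
    """Debounced, run-length-condensed label sequence.

    A label must persist for at least ``dwell_min`` time units to enter the
    path; shorter flickers are absorbed into the surrounding dwell.  Returns
    a list of (label, entry_time, dwell_duration).
    """
    if dwell_min < 0:
        raise ValueError("dwell_min must be non-negative")
    labels = label_frames(traj, ref)
    t = traj.times
    # run-length encode
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    dt = t[1] - t[0] if len(t) > 1 else dwell_min
    path = []
    for s_, e_ in zip(starts, ends):
        dur = (e_ - s_) * dt
        lbl = labels[s_]
        if dur + 1e-12 >= dwell_min or not path:
            if path and path[-1][0] == lbl:
                continue
            path.append((str(lbl), float(t[s_]), dur))
    # entry times kept; dwell of each entry runs to the next accepted entry
    out = []
    for i, (lbl, entry, _) in enumerate(path):
        end = path[i + 1][1] if i + 1 < len(path) else float(t[-1]) + dt
        out.append((lbl, entry, end - entry))
    return out


def cycle_outcome(traj: Trajectory, at_time: float | None = None):
    """Integer (dna_step, lobe_step) of a cycle.

    By default both are read from the final snapshot: the nearest integer to
    the mean contact index at the binding site and to the mean lobe index.
    ``at_time`` evaluates at the last snapshot not later than that time
    instead (e.g. the end of the ATP phase).
    """
    if traj.phase_bounds and traj.times[-1] + 1e-9 < traj.phase_bounds[-1]:
        raise ValueError("trajectory does not cover the full schedule")
    if at_time is None:
        i = len(traj) - 1
    else:
        i = int(np.searchsorted(traj.times, at_time + 1e-9) - 1)
    dna = 0.5 * (traj.X[i, IX_P15] + traj.X[i, IX_P25])
    lobe = 0.5 * (traj.Y[i, 0] + traj.Y[i, 1])
    return int(np.round(dna)), int(np.round(lobe))


def closure_time(traj: Trajectory, threshold: float = CLOSURE_THRESHOLD) -> float:
    """First time u = y1 - y2 reaches ``threshold``; NaN if it never does."""
    u = traj.Y[:, 0] - traj.Y[:, 1]
    idx = np.flatnonzero(u >= threshold)
    return float(traj.times[idx[0]]) if len(idx) else float("nan")


def closure_lobe(traj: Trajectory, threshold: float = CLOSURE_THRESHOLD) -> int | None:
    """Which lobe made the ~1 bp step at the moment of first closure.

    Returns 1 if lobe 1 advanced, 2 if lobe 2 moved backward, None if the
    translocase never closed.
    """
    u = traj.Y[:, 0] - traj.Y[:, 1]
    idx = np.flatnonzero(u >= threshold)
    if not len(idx):
        return None
    i = idx[0]
    dy1 = traj.Y[i, 0] - traj.Y[0, 0]
    dy2 = traj.Y[0, 1] - traj.Y[i, 1]
    return 1 if dy1 >= dy2 else 2


def ensemble_probability(outcomes) -> pd.DataFrame:
    """Per-outcome fractions with Wilson 95% confidence intervals."""
    outcomes = np.asarray(list(outcomes))
    if outcomes.size == 0:
        raise ValueError("need at least one outcome")
    n = len(outcomes)
    z = norm.ppf(0.975)
    rows = []
    for val in np.unique(outcomes):
        k = int(np.sum(outcomes == val))
        p = k / n
        denom = 1.0 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        rows.append(
            {"outcome": val, "count": k, "p": p,
             "ci_low": max(0.0, center - half), "ci_high": min(1.0, center + half)}
        )
    return pd.DataFrame(rows)
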