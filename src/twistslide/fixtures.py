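"""Synthetic inputs with known statistical structure.

Every analysis stage can be exercised without running any dynamics:
scripted label-path trajectories (piecewise-constant coordinates at
label-consistent targets plus Gaussian noise), discrete Markov chains
sampled from a known transition matrix, and exact i.i.d. samples from a
known 1-D Boltzmann distribution via inverse-CDF on a quadrature grid.
All generators are seed-deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .model import IX_M15, IX_P15, IX_P25, GRID, ChemicalState, SystemState
from .dynamics import Trajectory

__all__ = [
    "PathScript",
    "label_to_state",
    "scripted_trajectory",
    "markov_sampler",
    "toy_well_sampler",
]

_LABEL_RE = re.compile(r"^(o|c[ABCD])([012])$")


def label_to_state(label: str) -> SystemState:
    """A canonical coordinate target consistent with a metastable label.

    Convention: the digit is realized as a +1 bp defect stored on the dyad
    side (x_-1.5 lowered), letters advance y1 and then the contacts at 1.5
    and outward.  The mapping is label-consistent, not dynamically
    continuous between arbitrary label pairs.
    """
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"malformed label {label!r}")
    head, digit = m.group(1), int(m.group(2))
    x = np.zeros(GRID.n_contacts)
    y1 = y2 = 0.0
    if head == "o":
        pass
    elif head == "cA":
        y1 = 0.6
    else:
        y1 = 1.0
        if head == "cC":
            x[IX_P15] = 1.0
        elif head == "cD":
            x[IX_P15:] = 1.0
    advanced = 1.0 if x[IX_P15] >= 0.5 else 0.0
    x[IX_M15] = advanced - digit
    x[: IX_M15 + 1] = x[IX_M15]
    s = SystemState(x=x, y1=y1, y2=y2)
    return s


@dataclass
class PathScript:
    """Ordered (label, dwell) pairs with optional explicit coordinate
    targets, a Gaussian noise amplitude (bp) and a seed."""

    steps: list  # [(label, dwell), ...]
    targets: dict = field(default_factory=dict)  # label -> SystemState
    noise: float = 0.05
    seed: int = 0
    stride: float = 0.05

    def __post_init__(self) -> None:
        from . import cv

        if not self.steps:
            raise ValueError("empty script")
        for label, dwell in self.steps:
            if dwell <= 0:
                raise ValueError("dwell durations must be positive")
            target = self.targets.get(label) or label_to_state(label)
            if cv.label_frame(target) != label:
                raise ValueError(
                    f"target for {label!r} labels as {cv.label_frame(target)!r}"
                )
            self.targets.setdefault(label, target)


def scripted_trajectory(script: PathScript) -> Trajectory:
    """Piecewise-constant trajectory realizing a scripted label path."""
    rng = np.random.Generator(np.random.Philox(key=script.seed))
    frames_X, frames_Y, chem = [], [], []
    for label, dwell in script.steps:
        tgt = script.targets[label]
        n = max(1, int(round(dwell / script.stride)))
        X = np.tile(tgt.x, (n, 1))
        Y = np.tile([tgt.y1, tgt.y2], (n, 1))
        if script.noise > 0:
            X = X + rng.normal(0.0, script.noise, X.shape)
            Y = Y + rng.normal(0.0, script.noise, Y.shape)
        frames_X.append(X)
        frames_Y.append(Y)
        chem += [ChemicalState.ATP if label.startswith("c") else ChemicalState.APO] * n
    X = np.vstack(frames_X)
    Y = np.vstack(frames_Y)
    times = np.arange(len(X)) * script.stride
    return Trajectory(
        times=times,
        chem=np.array(chem, dtype=object),
        X=X,
        Y=Y,
        seed=script.seed,
        param_digest="scripted",
    )


def markov_sampler(T_true: np.ndarray, n: int, seed: int = 0, initial: int = 0) -> np.ndarray:
    """Sample an n-step chain from a known row-stochastic matrix."""
    T = np.asarray(T_true, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("matrix is not row-stochastic")
    rng = np.random.Generator(np.random.Philox(key=seed))
    cum = np.cumsum(T, axis=1)
    d = np.empty(n, dtype=int)
    state = initial
    u = rng.random(n)
    for t in range(n):
        d[t] = state
        state = int(np.searchsorted(cum[state], u[t], side="right"))
    return d


def toy_well_sampler(potential, n: int, seed: int = 0, domain=(-5.0, 5.0), grid: int = 4001):
    """Exact i.i.d. samples from p(x) ~ exp(-U(x)) on a bounded domain.

    The CDF is built by trapezoidal quadrature of exp(-U) on a fine grid and
    inverted by linear interpolation; accuracy is set by ``grid``.
    """
    xs = np.linspace(domain[0], domain[1], grid)
    U = np.asarray([potential(x) for x in xs], dtype=float)
    if not np.all(np.isfinite(U)):
        raise ValueError("potential must be finite on the domain")
    w = np.exp(-(U - U.min()))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(xs))])
    if cdf[-1] <= 0:
        raise ValueError("non-normalizable potential on this domain")
    cdf /= cdf[-1]
    rng = np.random.Generator(np.random.Philox(key=seed))
    return np.interp(rng.random(n), cdf, xs)
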