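"""Free-energy landscapes and Markov state models.

Free-energy profiles come from Boltzmann inversion of equilibrium
histograms, F = -ln p-hat, min-shifted to zero; bins with fewer counts than
a floor are masked rather than imputed.  Markov models are estimated from
lagged transition counts; detailed balance is enforced by count
symmetrization, C <- (C + C^T)/2, which makes the stationary distribution
proportional to the symmetrized row sums and guarantees a real spectrum for
implied timescales t_i = -lag / ln lambda_i.  Mean first-passage times to a
target set solve the absorbing-chain linear system (I - T_Q) m = lag * 1.
Minimum-energy pathways on 2-D landscapes minimize the maximum free energy
along 8-connected grid paths (bottleneck Dijkstra), with summed free energy
and lexicographic cell order as deterministic tie-breaks.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

__all__ = [
    "FreeEnergyProfile",
    "MarkovModel",
    "PathResult",
    "boltzmann_invert",
    "discretize",
    "count_matrix",
    "transition_matrix",
    "implied_timescales",
    "mfpt",
    "stationary_free_energy",
    "min_energy_path",
]


@dataclass
class FreeEnergyProfile:
    """Binned free energy (kT, min-shifted to 0) with raw counts.

    ``F`` is NaN on masked (under-sampled) bins.  ``edges`` is a tuple of
    bin-edge arrays, one per dimension; ``centers`` likewise.
    """

    edges: tuple
    F: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    @property
    def ndim(self) -> int:
        return len(self.edges)

    def error(self) -> np.ndarray:
        """Counting-statistics error per bin, kT: 1/sqrt(n)."""
        with np.errstate(divide="ignore"):
            return np.where(self.counts > 0, 1.0 / np.sqrt(self.counts), np.nan)


def boltzmann_invert(samples, bins, min_count: int = 10) -> FreeEnergyProfile:
    """Invert an equilibrium sample histogram into a free-energy profile.

    ``samples`` is (N,) for a 1-D profile or (N, D) for D coordinates;
    ``bins`` follows numpy.histogramdd conventions.  Bins with fewer than
    ``min_count`` samples are masked (NaN), never reported as zero.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    if len(samples) == 0:
        raise ValueError("no samples")
    if np.ndim(bins) == 1 and samples.shape[1] == 1:
        bins = [np.asarray(bins)]
    counts, edges = np.histogramdd(samples, bins=bins)
    retained = counts >= min_count
    if retained.sum() <= 1:
        warnings.warn("degenerate profile: all samples in a single retained bin")
    with np.errstate(divide="ignore"):
        F = -np.log(counts / counts.sum())
    F[~retained] = np.nan
    if np.any(retained):
        F -= np.nanmin(F)
    return FreeEnergyProfile(edges=tuple(np.asarray(e) for e in edges), F=F, counts=counts)


def discretize(values, grid_edges=None, labeler=None):
    """Map frames to integer states.

    Either ``grid_edges`` (tuple of bin-edge arrays; out-of-range values are
    clipped to the boundary cells) or ``labeler`` (callable returning
    hashable state keys per frame) must be given.  Returns (dtraj, states)
    where ``states`` records the cell/key for each integer index.
    """
    if (grid_edges is None) == (labeler is None):
        raise ValueError("provide exactly one of grid_edges or labeler")
    if labeler is not None:
        keys = [labeler(v) for v in values]
        states = sorted(set(keys))
        lut = {k: i for i, k in enumerate(states)}
        return np.array([lut[k] for k in keys], dtype=int), states
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("empty trajectory")
    if values.ndim == 1:
        values = values[:, None]
    idx = []
    shape = []
    for d, edges in enumerate(grid_edges):
        edges = np.asarray(edges)
        i = np.clip(np.searchsorted(edges, values[:, d], side="right") - 1, 0, len(edges) - 2)
        idx.append(i)
        shape.append(len(edges) - 1)
    flat = np.ravel_multi_index(idx, shape)
    states = [np.unravel_index(i, shape) for i in range(int(np.prod(shape)))]
    return flat.astype(int), states


def count_matrix(dtrajs, lag: int, n_states: int | None = None) -> np.ndarray:
    """Sliding-window lagged transition counts.

    ``dtrajs`` is one integer array or a list of them; pairs never cross
    array boundaries, so callers split trajectories at chemical-state
    switches before counting.  ``lag`` is in snapshot strides.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    if lag < 1:
        raise ValueError("lag must be >= 1 stride")
    if n_states is None:
        n_states = int(max(int(d.max()) for d in dtrajs if len(d)) + 1)
    C = np.zeros((n_states, n_states))
    any_pairs = False
    for d in dtrajs:
        d = np.asarray(d, dtype=int)
        if len(d) <= lag:
            continue
        any_pairs = True
        np.add.at(C, (d[:-lag], d[lag:]), 1.0)
    if not any_pairs:
        raise ValueError("lag is not shorter than any trajectory: no transition pairs")
    return C


@dataclass
class MarkovModel:
    """Row-stochastic transition model at a fixed lag.

    ``active`` maps the rows of T back to the original state indices (states
    outside the largest connected set are dropped).
    """

    T: np.ndarray
    pi: np.ndarray
    counts: np.ndarray
    lag: float  # in time units (or strides if the caller works unitless)
    active: np.ndarray
    states: list = field(default_factory=list)

    def state_index(self, key) -> int:
        """Row index of an original state key (requires ``states``)."""
        orig = self.states.index(key)
        hits = np.flatnonzero(self.active == orig)
        if not len(hits):
            raise KeyError(f"state {key!r} not in the connected set")
        return int(hits[0])

    def timescales(self, k: int = 4) -> np.ndarray:
        """Slowest implied relaxation timescales, -lag/ln lambda_i."""
        ev = np.sort(np.real(np.linalg.eigvals(self.T)))[::-1]
        lam = ev[1 : k + 1]
        out = np.full(len(lam), np.nan)
        ok = (lam > 0) & (lam < 1)
        out[ok] = -self.lag / np.log(lam[ok])
        return out


def transition_matrix(
    counts: np.ndarray,
    symmetrize: bool = True,
    lag: float = 1.0,
    states: list | None = None,
) -> MarkovModel:
    """Estimate a row-stochastic transition matrix from lagged counts.

    With ``symmetrize`` the counts are replaced by (C + C^T)/2 before row
    normalization, enforcing detailed balance; the stationary distribution
    is then exactly the normalized symmetrized row sum.  States without
    counts are dropped to the largest connected component.
    """
    C = np.asarray(counts, dtype=float)
    sym = 0.5 * (C + C.T)
    keep = sym.sum(axis=1) > 0
    # largest connected component on the symmetrized graph
    if keep.sum() == 0:
        raise ValueError("empty count matrix")
    sub = sym[np.ix_(keep, keep)]
    n_comp, labels = connected_components(csr_matrix(sub > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        biggest = np.argmax(sizes)
        mask = labels == biggest
        idx = np.flatnonzero(keep)[mask]
        warnings.warn(
            f"dropping {keep.sum() - mask.sum()} states outside the largest "
            f"connected set (components: {np.sort(sizes)[::-1].tolist()})"
        )
    else:
        idx = np.flatnonzero(keep)
    Cw = (sym if symmetrize else C)[np.ix_(idx, idx)]
    rows = Cw.sum(axis=1)
    if np.any(rows == 0):
        raise ValueError("retained state without outgoing counts")
    T = Cw / rows[:, None]
    if symmetrize:
        pi = rows / rows.sum()
    else:
        w, v = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi) / np.abs(pi).sum()
        if not np.allclose(np.linalg.matrix_power(T, 64).std(axis=0), 0, atol=0.5):
            pass  # non-reversible estimate; caller asked for it
    return MarkovModel(T=T, pi=pi, counts=C[np.ix_(idx, idx)], lag=lag,
                       active=idx, states=states or [])


def implied_timescales(dtrajs, lags, stride: float = 1.0, k: int = 4) -> pd.DataFrame:
    """Implied timescale table t_i(lag) over a list of lags (in strides).

    Timescales are reported in units of ``stride`` times strides.  A
    ``plateau`` flag marks lags whose slowest timescale changed by <25%
    from the previous lag, the usual convergence heuristic.
    """
    rows = []
    prev = None
    for lag in lags:
        C = count_matrix(dtrajs, int(lag))
        model = transition_matrix(C, symmetrize=True, lag=lag * stride)
        ts = model.timescales(k=k)
        row = {"lag": lag * stride}
        for i, t in enumerate(ts, start=2):
            row[f"t{i}"] = t
        row["plateau"] = bool(
            prev is not None and np.isfinite(ts[0]) and np.isfinite(prev)
            and abs(ts[0] - prev) / max(ts[0], prev) < 0.25
        )
        prev = ts[0] if len(ts) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def mfpt(model: MarkovModel, targets) -> np.ndarray:
    """Mean first-passage time (same units as ``model.lag``) from every
    state to the target set; zero on targets."""
    targets = np.atleast_1d(targets).astype(int)
    n = len(model.T)
    if len(targets) == 0 or np.any(targets < 0) or np.any(targets >= n):
        raise ValueError("invalid target states")
    q = np.setdiff1d(np.arange(n), targets)
    m = np.zeros(n)
    if len(q):
        TQ = model.T[np.ix_(q, q)]
        m[q] = np.linalg.solve(np.eye(len(q)) - TQ, model.lag * np.ones(len(q)))
    return m


def stationary_free_energy(model: MarkovModel) -> FreeEnergyProfile:
    """F_i = -ln pi_i, min-shifted; one 'bin' per Markov state."""
    F = -np.log(model.pi)
    F -= F.min()
    idx = np.arange(len(F) + 1, dtype=float) - 0.5
    return FreeEnergyProfile(edges=(idx,), F=F, counts=model.counts.sum(axis=1))


@dataclass
class PathResult:
    cells: list  # ordered (i, j) grid cells, source to sink
    profile: np.ndarray  # F along the path

    @property
    def bottleneck(self) -> float:
        return float(np.max(self.profile))


def min_energy_path(fep: FreeEnergyProfile, source, sink) -> PathResult:
    """Minimum-energy pathway across a 2-D landscape.

    8-connected bottleneck-Dijkstra: minimizes the maximum F along the
    path; among minimax ties, minimizes the summed F; remaining ties break
    lexicographically on the cell sequence.  Masked (NaN) cells are
    impassable.
    """
    if fep.ndim != 2:
        raise ValueError("need a 2-D profile")
    F = fep.F
    source, sink = tuple(source), tuple(sink)
    for cell in (source, sink):
        if not np.isfinite(F[cell]):
            raise ValueError(f"cell {cell} is masked or out of range")
    nb = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    best = {source: (F[source], F[source])}
    parent = {}
    heap = [(F[source], F[source], source)]
    while heap:
        bneck, tot, cell = heapq.heappop(heap)
        if cell == sink:
            break
        if (bneck, tot) > best.get(cell, (np.inf, np.inf)):
            continue
        for di, dj in nb:
            nxt = (cell[0] + di, cell[1] + dj)
            if not (0 <= nxt[0] < F.shape[0] and 0 <= nxt[1] < F.shape[1]):
                continue
            f = F[nxt]
            if not np.isfinite(f):
                continue
            cand = (max(bneck, f), tot + f)
            if cand < best.get(nxt, (np.inf, np.inf)):
                best[nxt] = cand
                parent[nxt] = cell
                heapq.heappush(heap, (cand[0], cand[1], nxt))
    if sink not in best:
        raise ValueError(
            f"sink unreachable; reachable set has {len(best)} cells"
        )
    cells = [sink]
    while cells[-1] != source:
        cells.append(parent[cells[-1]])
    cells.reverse()
    return PathResult(cells=cells, profile=np.array([F[c] for c in cells]))
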