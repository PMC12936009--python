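"""Binary functional-connectivity graphs and their indices.

Per trial and chromophore, channel-pairwise Pearson correlations are
thresholded into a 15x15 binary adjacency matrix; three indices summarise
each graph:

* degree centrality DC(i) = Σ_j a(i, j) (network value: mean over nodes),
* global efficiency GE = 1/(N(N−1)) Σ_{i≠j} 1/d(i, j) with unreachable pairs
  contributing 0,
* clustering coefficient CC(i) = 2 L_i / (Z_i (Z_i − 1)), zero when Z_i < 2
  (network value: mean over all N nodes).

The kernels are batched over arbitrary leading axes so a full threshold-grid
x trial x chromophore sweep is a handful of 15x15 matrix products; shortest
paths come from boolean matrix powers (edge-count BFS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants
from .preprocess import HemodynamicSeries


class GraphError(ValueError):
    pass


def correlation_matrix(segment: np.ndarray) -> np.ndarray:
    """Pearson correlation between every channel pair of a (ch, time) segment.

    Zero-variance channels would propagate NaN; their rows/columns are set to
    0 (diagonal kept at 1) with a warning instead.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise GraphError("segment must be (channels, >=2 time points)")
    sd = x.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance channel(s); correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    if dead.any():
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _validate_threshold(threshold: float) -> float:
    grid = constants.THRESHOLD_GRID
    if not np.any(np.isclose(grid, threshold, atol=1e-9)):
        raise GraphError(
            f"threshold {threshold} is not on the candidate grid 0.40..0.90 step 0.01"
        )
    return float(threshold)


def binarize(r: np.ndarray, threshold: float) -> np.ndarray:
    """Binary adjacency: a(i, j) = 1 iff r(i, j) > threshold (strict, signed r).

    Negative correlations never connect; the diagonal is forced to 0.
    """
    thr = _validate_threshold(threshold)
    r = np.asarray(r, dtype=float)
    a = (r > thr).astype(np.uint8)
    np.fill_diagonal(a, 0)
    return a


# ---------------------------------------------------------------------------
# Batched index kernels: A has shape (..., n, n), symmetric {0,1}, zero diag.
# ---------------------------------------------------------------------------

def _as_batch(a: np.ndarray) -> tuple[np.ndarray, tuple[int, ...], int]:
    a = np.asarray(a)
    n = a.shape[-1]
    lead = a.shape[:-2]
    return a.reshape(-1, n, n).astype(np.float32), lead, n


def degree_batch(a: np.ndarray) -> np.ndarray:
    """Per-node degrees, shape (..., n)."""
    return np.asarray(a).sum(axis=-1).astype(float)


def shortest_path_batch(a: np.ndarray) -> np.ndarray:
    """Unweighted shortest-path lengths by boolean matrix powers.

    Returns (..., n, n) float distances with np.inf for unreachable pairs and
    0 on the diagonal.
    """
    A, lead, n = _as_batch(a)
    reach = A > 0
    dist = np.where(reach, 1.0, np.inf)
    eye = np.eye(n, dtype=bool)
    dist[:, eye] = 0.0
    frontier = reach.copy()
    for k in range(2, n):
        frontier = np.matmul(frontier.astype(np.float32), A) > 0
        new = frontier & ~np.isfinite(dist)
        if not new.any():
            break
        dist[new] = float(k)
    return dist.reshape(*lead, n, n)


def global_efficiency_batch(a: np.ndarray) -> np.ndarray:
    """Network global efficiency per graph, shape (...,)."""
    d = shortest_path_batch(a)
    n = d.shape[-1]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return inv.sum(axis=(-2, -1)) / (n * (n - 1))


def clustering_batch(a: np.ndarray) -> np.ndarray:
    """Per-node clustering coefficients, shape (..., n).

    L_i (edges among neighbours of i) equals half the i-th diagonal entry of
    A³ for a simple graph, so CC(i) = (A³)_ii / (Z_i (Z_i − 1)).
    """
    A, lead, n = _as_batch(a)
    A2 = np.matmul(A, A)
    tri2 = np.einsum("bij,bji->bi", A2, A).astype(np.float64)  # (A^3)_ii = 2 L_i
    z = A.sum(axis=-1).astype(np.float64)
    denom = z * (z - 1)
    cc = np.where(denom > 0, tri2 / np.maximum(denom, 1), 0.0)
    return cc.reshape(*lead, n).astype(float)


@dataclass
class GraphIndexValue:
    metric: str
    value: float
    per_node: np.ndarray | None = None


def degree_centrality(a: np.ndarray) -> GraphIndexValue:
    per_node = degree_batch(a)
    return GraphIndexValue("DC", float(per_node.mean()), per_node)


def global_efficiency(a: np.ndarray) -> GraphIndexValue:
    return GraphIndexValue("GE", float(global_efficiency_batch(a)))


def clustering_coefficient(a: np.ndarray) -> GraphIndexValue:
    per_node = clustering_batch(a)
    return GraphIndexValue("CC", float(per_node.mean()), per_node)


# ---------------------------------------------------------------------------
# Trial sweep and period aggregation
# ---------------------------------------------------------------------------

def trial_index_sweep(segments: list[HemodynamicSeries]) -> np.ndarray:
    """Compute all indices for one subject's trials over the full threshold grid.

    Returns an array of shape
    (n_chromophores=3, n_metrics=3, n_thresholds=51, n_trials) ordered as
    ``constants.CHROMOPHORES`` x ``constants.GRAPH_METRICS`` x
    ``constants.THRESHOLD_GRID`` x chronological trials.
    """
    grid = constants.THRESHOLD_GRID
    n_tr = len(segments)
    out = np.empty((3, 3, grid.size, n_tr), dtype=float)
    for t, seg in enumerate(segments):
        for c, chrom in enumerate(constants.CHROMOPHORES):
            r = correlation_matrix(seg.chromophore(chrom))
            adj = (r[None, :, :] > grid[:, None, None]).astype(np.uint8)
            idx = np.arange(r.shape[0])
            adj[:, idx, idx] = 0
            out[c, 0, :, t] = degree_batch(adj).mean(axis=-1)
            out[c, 1, :, t] = global_efficiency_batch(adj)
            out[c, 2, :, t] = clustering_batch(adj).mean(axis=-1)
    return out


def aggregate_periods(
    trial_values: np.ndarray,
    trials_per_period: int = constants.TRIALS_PER_PERIOD,
) -> tuple[np.ndarray, np.ndarray]:
    """Average chronological trials into periods and form Δperiods.

    ``trial_values`` has trials on the last axis (length must be
    ``trials_per_period x 5``).  Returns ``(periods, deltas)`` where
    ``periods[..., p]`` is the mean of trials 3p..3p+2 and
    ``deltas[..., k]`` = period k+2 − period 1 for k = 0..3.
    """
    x = np.asarray(trial_values, dtype=float)
    n_tr = x.shape[-1]
    if n_tr != trials_per_period * constants.N_PERIODS:
        raise GraphError(
            f"expected {trials_per_period * constants.N_PERIODS} trials, got {n_tr}"
        )
    periods = x.reshape(*x.shape[:-1], constants.N_PERIODS, trials_per_period).mean(axis=-1)
    deltas = periods[..., 1:] - periods[..., :1]
    return periods, deltas
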