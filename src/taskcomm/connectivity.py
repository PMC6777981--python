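"""Fisher-z functional connectivity networks with the study's edge filters.

Pipeline order (fixed): Pearson correlation across trials -> Fisher z
transform -> drop negative edges -> drop edges between nodes closer than
20 mm -> optional wiring-cost thresholding (remove the weakest fraction of
surviving edges).  Group networks are element-wise means of the individual
filtered z matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .betas import TrialBetaSeries

_R_CLIP = 0.999999


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric node x node weighted network with filter provenance."""

    weights: np.ndarray
    node_ids: tuple[int, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != len(self.node_ids):
            raise ValueError("node_ids must match matrix size")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, w: np.ndarray, step: str) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            weights=w, node_ids=self.node_ids, provenance=self.provenance + (step,)
        )


def _as_series_matrix(series: TrialBetaSeries | np.ndarray) -> np.ndarray:
    if isinstance(series, TrialBetaSeries):
        return series.values
    return np.asarray(series, dtype=float)


def correlation_network(series: TrialBetaSeries | np.ndarray) -> ConnectivityMatrix:
    """Pearson correlation between all node series (raw r, zero diagonal)."""
    X = _as_series_matrix(series)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 observations per node")
    const = np.flatnonzero(np.ptp(X, axis=1) == 0)
    if const.size:
        raise ValueError(f"constant series for node(s) {const.tolist()}")
    r = np.corrcoef(X)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2.0  # enforce exact symmetry against float noise
    return ConnectivityMatrix(
        weights=r, node_ids=tuple(range(X.shape[0])), provenance=("pearson",)
    )


def fisher_and_filter(
    matrix: ConnectivityMatrix,
    nodes: pd.DataFrame,
    min_distance_mm: float = 20.0,
    drop_negative: bool = True,
) -> ConnectivityMatrix:
    """Fisher transform then zero out negative and short-distance edges.

    ``nodes`` must carry x_mm/y_mm/z_mm coordinates in matrix row order;
    edges between nodes closer than ``min_distance_mm`` are removed because
    short-range correlations can reflect shared local signal or motion
    rather than genuine interactions.
    """
    if len(nodes) != matrix.n_nodes:
        raise ValueError("node table does not match matrix size")
    coords = nodes[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(coords)):
        bad = np.flatnonzero(~np.isfinite(coords).all(axis=1))
        raise ValueError(f"missing coordinates for node(s) {bad.tolist()}")
    r = matrix.weights.copy()
    off = ~np.eye(matrix.n_nodes, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        warnings.warn("correlations at |r| >= 1 clipped before Fisher transform", stacklevel=2)
        r = np.clip(r, -_R_CLIP, _R_CLIP)
        np.fill_diagonal(r, 0.0)
    z = np.arctanh(r)
    steps = ["fisher"]
    if drop_negative:
        z[z < 0] = 0.0
        steps.append("nonnegative")
    dist = squareform(pdist(coords))
    z[(dist < min_distance_mm) & off] = 0.0
    steps.append(f"mindist={min_distance_mm}")
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        weights=z, node_ids=matrix.node_ids, provenance=matrix.provenance + tuple(steps)
    )


def threshold_by_cost(matrix: ConnectivityMatrix, cost: float) -> ConnectivityMatrix:
    """Zero the weakest ``ceil(cost * E)`` of the E currently nonzero edges.

    Higher cost means a sparser network.  Ties at the cut are broken by
    (i, j) lexicographic order so the result is deterministic, and the
    surviving edge set at a higher cost is a subset of that at a lower one.
    """
    if not 0.0 <= cost < 1.0:
        raise ValueError("cost must be in [0, 1)")
    w = matrix.weights
    if np.any(w < 0):
        raise ValueError("cost thresholding expects a non-negative (filtered) matrix")
    iu, ju = np.triu_indices(matrix.n_nodes, k=1)
    nz = w[iu, ju] > 0
    ei, ej, ew = iu[nz], ju[nz], w[iu, ju][nz]
    n_drop = int(np.ceil(cost * ew.size))
    out = w.copy()
    if n_drop:
        order = np.lexsort((ej, ei, ew))  # weight asc, then (i, j)
        drop = order[:n_drop]
        out[ei[drop], ej[drop]] = 0.0
        out[ej[drop], ei[drop]] = 0.0
    return matrix.with_weights(out, f"cost={cost}")


def group_average(matrices: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of individual (Fisher-z, filtered) networks."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.node_ids != first.node_ids:
            raise ValueError("matrices cover different node sets")
        if m.provenance != first.provenance:
            raise ValueError("matrices have mismatched filter provenance")
    mean = np.mean([m.weights for m in matrices], axis=0)
    return ConnectivityMatrix(
        weights=mean,
        node_ids=first.node_ids,
        provenance=first.provenance + (f"group_mean(n={len(matrices)})",),
    )
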