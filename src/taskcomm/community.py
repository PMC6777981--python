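"""Modularity maximization and two-level consensus community detection.

Communities are found by greedy two-phase modularity maximization (Louvain)
on positive weighted networks with resolution parameter gamma, then
stabilized in two stages:

1. per wiring cost: the network is cost-thresholded and clustered
   ``n_iterations`` times with different seeds; the co-assignment
   (consensus) matrix is thresholded at tau and re-clustered, iterating
   until the consensus matrix is block-binary (Lancichinetti-Fortunato
   convention, capped at 20 rounds);
2. across the cost grid: the per-cost partitions are combined through a
   second co-assignment matrix, thresholded at tau, and a final clustering
   pass yields the condition's partition.

The meet of the four condition partitions separates *stable modules*
(cells co-assigned in every condition) from *mover* nodes (cells smaller
than ``min_stable_size``), the study's flexible nodes.

The Louvain core is jit-compiled because consensus clustering multiplies a
cheap algorithm by iterations x costs x rounds; node sweep order is
shuffled per pass from the given seed and the greedy phase only accepts
strictly positive modularity gains, so the returned Q never falls below
the all-singletons starting point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix, threshold_by_cost

_SEED_MOD = 2**31 - 1
DEFAULT_COST_GRID: tuple[float, ...] = tuple(round(0.01 + 0.1 * k, 2) for k in range(10))


@dataclass(frozen=True)
class Partition:
    """Node -> module labeling; module ids contiguous from 1."""

    labels: np.ndarray
    node_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        uniq = np.unique(lab)
        if lab.size and not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("module ids must be contiguous integers from 1")

    @staticmethod
    def from_labels(raw: np.ndarray, node_ids: tuple[int, ...] | None = None) -> "Partition":
        """Canonicalize arbitrary labels to 1..K by order of first appearance."""
        raw = np.asarray(raw)
        _, first = np.unique(raw, return_index=True)
        order = {raw[i]: rank + 1 for rank, i in enumerate(np.sort(first))}
        return Partition(
            labels=np.array([order[v] for v in raw], dtype=int), node_ids=node_ids
        )

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_modules(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def module_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_modules + 1)[1:]

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.labels == module)


@dataclass(frozen=True)
class CommunityConfig:
    """Knobs of the consensus procedure.

    gamma: Louvain resolution (default 1.25, sized so module count matches
    typical resting-state parcellations); n_iterations: Louvain restarts per
    consensus round (default 100); consensus_tau: co-assignment proportion
    below which entries are zeroed (default 0.5); cost_grid: wiring-cost
    fractions swept (default 0.01, 0.11, ..., 0.91).
    """

    gamma: float = 1.25
    n_iterations: int = 100
    consensus_tau: float = 0.5
    cost_grid: tuple[float, ...] = DEFAULT_COST_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 < self.consensus_tau < 1.0:
            raise ValueError("consensus_tau must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")


@njit(cache=True)
def _louvain_core(W: np.ndarray, gamma: float, seed: int) -> np.ndarray:  # pragma: no cover
    np.random.seed(seed)
    n0 = W.shape[0]
    node_comm = np.arange(n0)
    cur = W.copy()
    while True:
        n = cur.shape[0]
        k = np.zeros(n)
        for i in range(n):
            s = 0.0
            for j in range(n):
                s += cur[i, j]
            k[i] = s
        two_m = k.sum()
        comm = np.arange(n)
        stot = k.copy()
        order = np.arange(n)
        improved = False
        while True:
            moved = 0
            np.random.shuffle(order)
            for oi in range(n):
                i = order[oi]
                c = comm[i]
                links = np.zeros(n)
                for j in range(n):
                    if j != i:
                        links[comm[j]] += cur[i, j]
                stot[c] -= k[i]
                best = c
                best_gain = links[c] - gamma * k[i] * stot[c] / two_m
                for d in range(n):
                    g = links[d] - gamma * k[i] * stot[d] / two_m
                    if g > best_gain + 1e-12:
                        best_gain = g
                        best = d
                comm[i] = best
                stot[best] += k[i]
                if best != c:
                    moved += 1
                    improved = True
            if moved == 0:
                break
        new_id = -np.ones(n, dtype=np.int64)
        n_new = 0
        for i in range(n):
            if new_id[comm[i]] < 0:
                new_id[comm[i]] = n_new
                n_new += 1
        for i in range(n0):
            node_comm[i] = new_id[comm[node_comm[i]]]
        if n_new == n or not improved:
            break
        agg = np.zeros((n_new, n_new))
        for i in range(n):
            ci = new_id[comm[i]]
            for j in range(n):
                agg[ci, new_id[comm[j]]] += cur[i, j]
        cur = agg
    return node_comm


def _weights_of(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, ConnectivityMatrix):
        return matrix.weights
    return np.asarray(matrix, dtype=float)


def modularity(
    matrix: ConnectivityMatrix | np.ndarray, partition: Partition | np.ndarray, gamma: float = 1.0
) -> float:
    """Newman modularity Q at resolution gamma for a weighted network.

    Q = (1/2W) * sum_ij [w_ij - gamma * s_i s_j / (2W)] * delta(c_i, c_j),
    summed over all ordered pairs including the diagonal (self-loops arise
    in aggregated and consensus matrices).
    """
    W = _weights_of(matrix)
    lab = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    k = W.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        raise ValueError("empty graph")
    same = lab[:, None] == lab[None, :]
    return float(((W - gamma * np.outer(k, k) / two_m)[same]).sum() / two_m)


def louvain(
    matrix: ConnectivityMatrix | np.ndarray, gamma: float = 1.25, seed: int = 0
) -> Partition:
    """Greedy modularity maximization; deterministic given the seed."""
    W = np.ascontiguousarray(_weights_of(matrix), dtype=float)
    if W.size == 0 or not np.any(W):
        raise ValueError("empty graph")
    if np.any(W < 0):
        raise ValueError("louvain requires non-negative weights")
    node_ids = tuple(matrix.node_ids) if isinstance(matrix, ConnectivityMatrix) else None
    raw = _louvain_core(W, float(gamma), int(seed) % _SEED_MOD)
    return Partition.from_labels(raw, node_ids=node_ids)


def coassignment_counts(label_runs: Sequence[np.ndarray]) -> np.ndarray:
    """Integer node x node matrix counting co-assignments across runs."""
    n = len(label_runs[0])
    counts = np.zeros((n, n), dtype=np.int64)
    for lab in label_runs:
        lab = np.asarray(lab)
        counts += lab[:, None] == lab[None, :]
    return counts


def _blocks_partition(adjacency: np.ndarray, node_ids) -> Partition:
    _, comp = connected_components(csr_matrix(adjacency), directed=False)
    return Partition.from_labels(comp, node_ids=node_ids)


def consensus_at_cost(
    matrix: ConnectivityMatrix,
    config: CommunityConfig,
    cost: float,
    base_seed: int | None = None,
) -> Partition:
    """Consensus partition of the cost-thresholded network.

    Runs Louvain ``n_iterations`` times (seeds ``seed+1 .. seed+n``), builds
    the co-assignment matrix, zeroes entries below tau, and re-clusters,
    repeating until the co-assignment matrix is block-binary (all runs
    agree) or 20 rounds have elapsed.  A block-binary matrix's connected
    blocks are the final partition.
    """
    thresholded = threshold_by_cost(matrix, cost)
    seed0 = config.seed if base_seed is None else base_seed
    M = thresholded.weights
    node_ids = matrix.node_ids
    offset = 1
    for _ in range(20):
        runs = [
            louvain(M, gamma=config.gamma, seed=(seed0 + offset + i) % _SEED_MOD).labels
            for i in range(config.n_iterations)
        ]
        offset += config.n_iterations
        counts = coassignment_counts(runs)
        if np.all((counts == 0) | (counts == config.n_iterations)):
            return _blocks_partition(counts > 0, node_ids)
        C = counts / config.n_iterations
        C[C < config.consensus_tau] = 0.0
        np.fill_diagonal(C, 1.0)
        M = C
    return louvain(M, gamma=config.gamma, seed=(seed0 + offset) % _SEED_MOD)


def multiscale_consensus(
    matrix: ConnectivityMatrix,
    config: CommunityConfig,
    final: str = "louvain",
    return_per_cost: bool = False,
) -> Partition | tuple[Partition, dict[float, Partition]]:
    """Final partition consolidating consensus partitions across the cost grid.

    The per-cost consensus partitions are combined through a cross-threshold
    co-assignment matrix, thresholded at tau, and reduced by a final Louvain
    pass (``final='louvain'``) or by connected components
    (``final='components'``).
    """
    if not config.cost_grid:
        raise ValueError("cost grid must be non-empty")
    if final not in ("louvain", "components"):
        raise ValueError("final must be 'louvain' or 'components'")
    per_cost: dict[float, Partition] = {}
    for j, cost in enumerate(config.cost_grid):
        per_cost[cost] = consensus_at_cost(
            matrix, config, cost, base_seed=(config.seed + (j + 1) * 100_000) % _SEED_MOD
        )
    counts = coassignment_counts([p.labels for p in per_cost.values()])
    n_runs = len(per_cost)
    if np.all((counts == 0) | (counts == n_runs)):
        part = _blocks_partition(counts > 0, matrix.node_ids)
    else:
        C = counts / n_runs
        C[C < config.consensus_tau] = 0.0
        np.fill_diagonal(C, 1.0)
        if final == "components":
            part = _blocks_partition(C > 0, matrix.node_ids)
        else:
            part = louvain(C, gamma=config.gamma, seed=config.seed)
    if return_per_cost:
        return part, per_cost
    return part


def meet_partition(partitions: Sequence[Partition]) -> Partition:
    """Meet (common refinement): cells are maximal node sets co-assigned in
    every partition.  Associative and independent of partition order."""
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    n = partitions[0].n_nodes
    for p in partitions[1:]:
        if p.n_nodes != n:
            raise ValueError("partitions cover different node sets")
    keys = np.stack([p.labels for p in partitions], axis=1)
    _, cell = np.unique(keys, axis=0, return_inverse=True)
    return Partition.from_labels(cell, node_ids=partitions[0].node_ids)


def stable_modules_and_movers(
    partitions: Mapping[str, Partition] | Sequence[Partition],
    min_stable_size: int = 5,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Split nodes into stable modules and movers across conditions.

    Cells of the meet partition with at least ``min_stable_size`` nodes are
    the stable modules (nodes consistently co-assigned in every condition);
    every remaining node is a mover, i.e. it changed community alliance in
    at least one condition relative to its stable peers.
    Returns ``(stable module node-index arrays, mover node indices)``.
    """
    parts = list(partitions.values()) if isinstance(partitions, Mapping) else list(partitions)
    meet = meet_partition(parts)
    stable: list[np.ndarray] = []
    movers: list[np.ndarray] = []
    for m in range(1, meet.n_modules + 1):
        cell = meet.members(m)
        (stable if len(cell) >= min_stable_size else movers).append(cell)
    mover_idx = np.sort(np.concatenate(movers)) if movers else np.array([], dtype=int)
    return stable, mover_idx
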