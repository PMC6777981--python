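"""Node-level and partition-level network metrics.

Implements the hub taxonomy (within-module degree z-score and participation
coefficient, classified into connector / provincial / satellite / peripheral
roles), the fragmentation of a reference subnetwork relative to a
data-driven partition, normalized mutual information between partitions,
the NMI-versus-cost curve with its area under the curve, and whole- or
sub-network similarity between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from sklearn.metrics import normalized_mutual_info_score

from .community import CommunityConfig, Partition, consensus_at_cost
from .connectivity import ConnectivityMatrix

NODE_IDENTITIES = ("connector", "provincial", "satellite", "peripheral")


@dataclass(frozen=True)
class FragmentationResult:
    """F = 1 - C/T: the fraction of a reference subnetwork's nodes that fall
    outside its largest data-driven module (0 = intact, near 1 = scattered)."""

    rsn_label: str
    total_nodes: int
    largest_block: int
    fragmentation: float


@dataclass(frozen=True)
class SimilarityResult:
    similarity_r: float
    n_edges_compared: int
    condition_pair: tuple[str, str] | None = None


def _weights_and_labels(
    matrix: ConnectivityMatrix | np.ndarray, partition: Partition | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    W = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    lab = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    if len(lab) != W.shape[0]:
        raise ValueError("partition does not cover the matrix nodes")
    return W, lab


def within_module_z(
    matrix: ConnectivityMatrix | np.ndarray, partition: Partition | np.ndarray
) -> np.ndarray:
    """Within-module degree z-score.

    z_i = (k_i(m_i) - mean_m) / sigma_m where k_i(m_i) is node i's summed
    edge weight to its own module and mean/sigma are the population moments
    of that module's within-degree distribution.  Modules with zero spread
    give z = 0 for all members.
    """
    W, lab = _weights_and_labels(matrix, partition)
    z = np.zeros(len(lab))
    for m in np.unique(lab):
        members = np.flatnonzero(lab == m)
        k = W[np.ix_(members, members)].sum(axis=1)
        sigma = k.std()  # population sd
        if sigma > 0:
            z[members] = (k - k.mean()) / sigma
    return z


def within_module_degree(
    matrix: ConnectivityMatrix | np.ndarray, partition: Partition | np.ndarray
) -> np.ndarray:
    """Unstandardized k_i(m_i): summed weight of a node's intra-module edges."""
    W, lab = _weights_and_labels(matrix, partition)
    k = np.zeros(len(lab))
    for m in np.unique(lab):
        members = np.flatnonzero(lab == m)
        k[members] = W[np.ix_(members, members)].sum(axis=1)
    return k


def participation(
    matrix: ConnectivityMatrix | np.ndarray, partition: Partition | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Participation coefficient PC_i = 1 - sum_m (k_i(m)/k_i)^2 and its
    z-scored version across all nodes of the network.

    PC is 0 when all of a node's weight stays inside one module and tends to
    1 as weight spreads evenly over modules; isolated nodes get PC = 0.
    PC is additionally z-scored across nodes because its raw distribution is
    typically narrow.
    """
    W, lab = _weights_and_labels(matrix, partition)
    modules = np.unique(lab)
    onehot = (lab[:, None] == modules[None, :]).astype(float)
    k_per_module = W @ onehot  # (n_nodes, n_modules)
    k_total = W.sum(axis=1)
    pc = np.zeros(len(lab))
    nz = k_total > 0
    pc[nz] = 1.0 - ((k_per_module[nz] / k_total[nz, None]) ** 2).sum(axis=1)
    sd = pc.std()
    pc_z = (pc - pc.mean()) / sd if sd > 0 else np.zeros_like(pc)
    return pc, pc_z


def classify_roles(z: np.ndarray, pc_z: np.ndarray) -> np.ndarray:
    """Node identities from the sign pair (z_i, z-scored PC).

    (z >= 0, pc >= 0) -> connector; (z >= 0, pc < 0) -> provincial;
    (z < 0, pc >= 0) -> satellite; (z < 0, pc < 0) -> peripheral.
    Exhaustive and exclusive: every node gets exactly one identity.
    """
    z = np.asarray(z, dtype=float)
    pc_z = np.asarray(pc_z, dtype=float)
    if z.shape != pc_z.shape:
        raise ValueError("z and pc_z must have equal length")
    out = np.where(
        z >= 0,
        np.where(pc_z >= 0, "connector", "provincial"),
        np.where(pc_z >= 0, "satellite", "peripheral"),
    )
    return out.astype(object)


def node_profiles(
    matrix: ConnectivityMatrix | np.ndarray, partition: Partition | np.ndarray
) -> pd.DataFrame:
    """Per-node hub metrics and identity as a tidy table."""
    z = within_module_z(matrix, partition)
    k = within_module_degree(matrix, partition)
    pc, pc_z = participation(matrix, partition)
    lab = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    return pd.DataFrame(
        {
            "node_id": np.arange(len(z)),
            "module": lab,
            "within_module_degree": k,
            "within_module_z": z,
            "participation": pc,
            "participation_z": pc_z,
            "identity": classify_roles(z, pc_z),
        }
    )


def fragmentation(
    partition: Partition | np.ndarray, nodes: pd.DataFrame, rsn_label: str
) -> FragmentationResult:
    """Fragmentation of one reference subnetwork under a data-driven partition.

    C is the largest number of the subnetwork's nodes sharing a single
    data-driven module; T is the subnetwork's node count; F = 1 - C/T.
    E.g. 8 of 10 subnetwork nodes in one module and 2 elsewhere -> 20%.
    """
    lab = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    mask = (nodes["rsn_label"] == rsn_label).to_numpy()
    if not mask.any():
        raise ValueError(f"unknown RSN label {rsn_label!r}")
    if len(mask) != len(lab):
        raise ValueError("partition does not cover the node table")
    counts = np.bincount(lab[mask])
    largest = int(counts.max())
    total = int(mask.sum())
    return FragmentationResult(
        rsn_label=rsn_label,
        total_nodes=total,
        largest_block=largest,
        fragmentation=(total - largest) / total,  # 1 - C/T without float residue
    )


def fragmentation_table(partition, nodes: pd.DataFrame) -> pd.DataFrame:
    """Fragmentation for every RSN label present in the node table."""
    rows = [fragmentation(partition, nodes, lab) for lab in pd.unique(nodes["rsn_label"])]
    return pd.DataFrame(
        {
            "rsn_label": [r.rsn_label for r in rows],
            "total_nodes": [r.total_nodes for r in rows],
            "largest_block": [r.largest_block for r in rows],
            "fragmentation": [r.fragmentation for r in rows],
        }
    )


def nmi(a: Partition | np.ndarray, b: Partition | np.ndarray) -> float:
    """Normalized mutual information between two partitions.

    2 I(a;b) / (H(a) + H(b)) with natural logarithms; 1 for identical
    partitions (up to relabeling) and 0 for independent ones.  Two
    single-cluster partitions are defined as identical (NMI = 1).
    """
    la = a.labels if isinstance(a, Partition) else np.asarray(a)
    lb = b.labels if isinstance(b, Partition) else np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError("partitions cover different node sets")
    return float(normalized_mutual_info_score(la, lb, average_method="arithmetic"))


def normalized_auc(grid: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoid area under a curve divided by the grid span, so a constant
    curve's AUC equals that constant."""
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.size < 2:
        raise ValueError("need at least two grid points")
    return float(np.trapezoid(values, grid) / (grid[-1] - grid[0]))


def nmi_cost_curve_auc(
    matrix: ConnectivityMatrix,
    reference: Partition | np.ndarray,
    config: CommunityConfig,
) -> tuple[np.ndarray, np.ndarray, float]:
    """NMI between the per-cost consensus partition and a reference partition
    over the cost grid, plus the span-normalized AUC.

    Returns ``(costs, nmi_values, auc)``.
    """
    if len(config.cost_grid) < 2:
        raise ValueError("cost grid must have at least two values")
    ref = reference if isinstance(reference, Partition) else Partition.from_labels(reference)
    values = []
    for j, cost in enumerate(config.cost_grid):
        part = consensus_at_cost(
            matrix, config, cost, base_seed=(config.seed + (j + 1) * 100_000) % (2**31 - 1)
        )
        values.append(nmi(part, ref))
    costs = np.asarray(config.cost_grid, dtype=float)
    values = np.asarray(values)
    return costs, values, normalized_auc(costs, values)


def network_similarity(
    a: ConnectivityMatrix | np.ndarray,
    b: ConnectivityMatrix | np.ndarray,
    node_subset: np.ndarray | Sequence[int] | None = None,
    condition_pair: tuple[str, str] | None = None,
) -> SimilarityResult:
    """Pearson correlation of the strictly-upper-triangle edge weights of two
    networks (optionally restricted to the submatrix induced by a node
    subset), summarizing how alike two connectivity states are."""
    Wa = a.weights if isinstance(a, ConnectivityMatrix) else np.asarray(a, float)
    Wb = b.weights if isinstance(b, ConnectivityMatrix) else np.asarray(b, float)
    if Wa.shape != Wb.shape:
        raise ValueError("matrices cover different node sets")
    if node_subset is not None:
        idx = np.asarray(node_subset)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        Wa = Wa[np.ix_(idx, idx)]
        Wb = Wb[np.ix_(idx, idx)]
    iu = np.triu_indices(Wa.shape[0], k=1)
    va, vb = Wa[iu], Wb[iu]
    if va.size < 3:
        raise ValueError("need at least 3 unique off-diagonal entries")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("degenerate similarity: constant edge vector")
    r, _ = _st.pearsonr(va, vb)
    return SimilarityResult(
        similarity_r=float(r), n_edges_compared=va.size, condition_pair=condition_pair
    )
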