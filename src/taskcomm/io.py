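"""Plain-text serialization: TSV tables, delimited matrices, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community import Partition
from .connectivity import ConnectivityMatrix
from .synthetic import GroundTruth, TrialSchedule


def write_node_table(nodes: pd.DataFrame, path: str | Path) -> None:
    nodes.to_csv(path, sep="\t", index=False)


def read_node_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Square TSV with a node-id header row; provenance in a JSON sidecar."""
    path = Path(path)
    pd.DataFrame(matrix.weights, columns=[str(i) for i in matrix.node_ids]).to_csv(
        path, sep="\t", index=False
    )
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"provenance": list(matrix.provenance)}, indent=1)
    )


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    provenance: tuple[str, ...] = ()
    if sidecar.exists():
        provenance = tuple(json.loads(sidecar.read_text())["provenance"])
    return ConnectivityMatrix(
        weights=df.to_numpy(dtype=float),
        node_ids=tuple(int(c) for c in df.columns),
        provenance=provenance,
    )


def write_series(values: np.ndarray, path: str | Path, conditions=None) -> None:
    """Node x column matrix as TSV with a JSON sidecar of trial metadata."""
    path = Path(path)
    pd.DataFrame(values).to_csv(path, sep="\t", index=False, header=False)
    if conditions is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"conditions": [str(c) for c in conditions]}, indent=1)
        )


def read_series(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
    sidecar = path.with_suffix(path.suffix + ".json")
    conditions = None
    if sidecar.exists():
        conditions = json.loads(sidecar.read_text()).get("conditions")
    return values, conditions


def write_partition(partition: Partition, path: str | Path) -> None:
    ids = partition.node_ids or tuple(range(partition.n_nodes))
    pd.DataFrame({"node_id": ids, "module_id": partition.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t")
    return Partition(
        labels=df["module_id"].to_numpy(dtype=int),
        node_ids=tuple(int(i) for i in df["node_id"]),
    )


def write_schedule(schedule: TrialSchedule, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "onsets": schedule.onsets.tolist(),
                "durations": schedule.durations.tolist(),
                "conditions": [str(c) for c in schedule.conditions],
                "repetition_time": schedule.repetition_time,
                "n_volumes": schedule.n_volumes,
            },
            indent=1,
        )
    )


def read_schedule(path: str | Path) -> TrialSchedule:
    d = json.loads(Path(path).read_text())
    return TrialSchedule(
        onsets=np.asarray(d["onsets"], dtype=float),
        durations=np.asarray(d["durations"], dtype=float),
        conditions=np.asarray(d["conditions"], dtype=object),
        repetition_time=float(d["repetition_time"]),
        n_volumes=int(d["n_volumes"]),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "n_nodes": truth.n_nodes,
                "conditions": list(truth.conditions),
                "partitions": {c: truth.labels(c).tolist() for c in truth.conditions},
                "movers": list(truth.movers),
                "within_r": truth.within_r,
                "between_r": truth.between_r,
                "seed": truth.seed,
            },
            indent=1,
        )
    )


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        n_nodes=int(d["n_nodes"]),
        conditions=tuple(d["conditions"]),
        partitions={c: np.asarray(v, dtype=int) for c, v in d["partitions"].items()},
        movers=tuple(d["movers"]),
        within_r=float(d["within_r"]),
        between_r=float(d["between_r"]),
        seed=int(d["seed"]),
    )
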