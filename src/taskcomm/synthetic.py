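"""Synthetic study fixtures with planted ground truth.

Everything downstream of raw fMRI — beta series, connectivity networks,
community partitions, mover nodes, and the behavior model — is exercised on
data generated here.  The generator plants a block (community) structure in
trial-wise node amplitudes, designates a subset of nodes as *movers* whose
block membership changes across the four task conditions, and couples a
behavioral score linearly to network dissimilarity, so every downstream
estimate has a known target.

Correlation structure is realized with a one-common-factor construction::

    x_i(t) = sqrt(b) * g(t) + sqrt(w - b) * f_{block(i)}(t) + sqrt(1 - w) * e_i(t)

with ``g``, ``f``, ``e`` independent standard normals, so the population
correlation is exactly ``w`` (``within_r``) inside a block and ``b``
(``between_r``) across blocks, and the implied covariance is positive
semidefinite for any ``0 <= b <= w < 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .betas import TrialBetaSeries, canonical_hrf, trial_regressors

#: Condition order used throughout: two encoding then two retrieval states,
#: each crossed with spatial vs temporal context.
CONDITIONS: tuple[str, ...] = (
    "space_encoding",
    "time_encoding",
    "space_retrieval",
    "time_retrieval",
)

NODE_TABLE_COLUMNS = ("node_id", "x_mm", "y_mm", "z_mm", "rsn_label")


@dataclass(frozen=True)
class GroundTruth:
    """Planted community structure for one synthetic cohort member.

    ``partitions`` maps each condition name to an integer block label per
    node.  Nodes listed in ``movers`` change block between at least two
    conditions; all other nodes keep one label throughout.
    """

    n_nodes: int
    conditions: tuple[str, ...]
    partitions: Mapping[str, np.ndarray]
    movers: tuple[int, ...]
    within_r: float
    between_r: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.between_r <= self.within_r < 1.0):
            raise ValueError(
                f"need 0 <= between_r <= within_r < 1, got "
                f"between_r={self.between_r}, within_r={self.within_r}"
            )
        if set(self.partitions) != set(self.conditions):
            raise ValueError("partitions must cover exactly the condition set")
        lab = np.stack([np.asarray(self.partitions[c]) for c in self.conditions])
        if lab.shape[1] != self.n_nodes:
            raise ValueError("each partition must label every node")
        mover_set = set(self.movers)
        varies = (lab != lab[0]).any(axis=0)
        for i in range(self.n_nodes):
            if i in mover_set and not varies[i]:
                raise ValueError(f"mover node {i} never changes block")
            if i not in mover_set and varies[i]:
                raise ValueError(f"non-mover node {i} changes block")

    def labels(self, condition: str) -> np.ndarray:
        return np.asarray(self.partitions[condition], dtype=int)


@dataclass(frozen=True)
class TrialSchedule:
    """Trial onsets/durations (seconds) on a fixed repetition-time grid."""

    onsets: np.ndarray
    durations: np.ndarray
    conditions: np.ndarray
    repetition_time: float
    n_volumes: int

    def __post_init__(self) -> None:
        on = np.asarray(self.onsets, dtype=float)
        du = np.asarray(self.durations, dtype=float)
        if on.ndim != 1 or on.shape != du.shape:
            raise ValueError("onsets and durations must be matching 1-D arrays")
        if len(on) and np.any(np.diff(on) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(on + du > self.n_volumes * self.repetition_time + 1e-9):
            raise ValueError("trial extends past the end of the scan")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.repetition_time


@dataclass(frozen=True)
class MotionTrace:
    """Per-volume framewise displacement in mm."""

    fd_per_volume: np.ndarray

    def __post_init__(self) -> None:
        fd = np.asarray(self.fd_per_volume, dtype=float)
        if np.any(fd < 0):
            raise ValueError("framewise displacement must be non-negative")

    @property
    def n_volumes(self) -> int:
        return len(self.fd_per_volume)


def make_ground_truth(
    n_nodes: int = 100,
    n_blocks: int = 4,
    n_movers: int = 12,
    within_r: float = 0.5,
    between_r: float = 0.1,
    conditions: Sequence[str] = CONDITIONS,
    seed: int = 0,
) -> GroundTruth:
    """Plant ``n_blocks`` stable communities plus ``n_movers`` flexible nodes.

    Stable nodes split into near-equal contiguous blocks.  Movers come in two
    flavours mirroring a 2x2 (context x memory stage) design: the first half
    switch block between encoding and retrieval conditions, the second half
    between spatial and temporal conditions.  Block pairs cycle so movers do
    not all share one reassignment pattern.
    """
    if n_nodes < n_blocks + n_movers:
        raise ValueError("n_nodes too small for requested blocks and movers")
    if len(conditions) != 4:
        raise ValueError("exactly four conditions are expected")
    n_stable = n_nodes - n_movers
    stable_labels = np.concatenate(
        [np.full(len(chunk), b + 1) for b, chunk in enumerate(np.array_split(np.arange(n_stable), n_blocks))]
    )
    partitions = {c: np.empty(n_nodes, dtype=int) for c in conditions}
    for c in conditions:
        partitions[c][:n_stable] = stable_labels
    movers = tuple(range(n_stable, n_nodes))
    for j, node in enumerate(movers):
        a = j % n_blocks + 1
        b = (j + 1) % n_blocks + 1
        if j < n_movers // 2:
            per_cond = (a, a, b, b)  # encoding -> retrieval switcher
        else:
            per_cond = (a, b, a, b)  # spatial -> temporal switcher
        for c, lab in zip(conditions, per_cond):
            partitions[c][node] = lab
    return GroundTruth(
        n_nodes=n_nodes,
        conditions=tuple(conditions),
        partitions={c: v for c, v in partitions.items()},
        movers=movers,
        within_r=within_r,
        between_r=between_r,
        seed=seed,
    )


def make_node_table(
    n_nodes: int,
    rsn_labels: Sequence[str],
    seed: int = 0,
    min_distance_mm: float = 8.0,
    cube_mm: float = 160.0,
) -> pd.DataFrame:
    """Node ids, 3-D coordinates in a ``cube_mm`` cube, cyclic RSN labels.

    Coordinates are rejection-sampled so every pair of nodes is at least
    ``min_distance_mm`` apart, which gives the short-distance edge filter
    something to act on.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not rsn_labels:
        raise ValueError("need at least one RSN label")
    rng = np.random.default_rng(seed)
    half = cube_mm / 2.0
    coords = np.empty((n_nodes, 3))
    placed = 0
    attempts = 0
    while placed < n_nodes:
        p = rng.uniform(-half, half, size=3)
        if placed == 0 or np.min(np.linalg.norm(coords[:placed] - p, axis=1)) >= min_distance_mm:
            coords[placed] = p
            placed += 1
        attempts += 1
        if attempts > 1000 * n_nodes:
            raise RuntimeError("could not place nodes at the requested separation")
    labels = [rsn_labels[i % len(rsn_labels)] for i in range(n_nodes)]
    return pd.DataFrame(
        {
            "node_id": np.arange(n_nodes),
            "x_mm": coords[:, 0],
            "y_mm": coords[:, 1],
            "z_mm": coords[:, 2],
            "rsn_label": labels,
        }
    )


def _plant_condition(
    labels: np.ndarray, within_r: float, between_r: float, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    uniq, idx = np.unique(labels, return_inverse=True)
    g = rng.standard_normal(n_trials)
    f = rng.standard_normal((len(uniq), n_trials))
    e = rng.standard_normal((len(labels), n_trials))
    return (
        np.sqrt(between_r) * g[None, :]
        + np.sqrt(within_r - between_r) * f[idx]
        + np.sqrt(1.0 - within_r) * e
    )


def plant_beta_series(
    truth: GroundTruth, n_trials: int = 40, seed: int = 0
) -> dict[str, TrialBetaSeries]:
    """Draw node x trial amplitudes per condition from the factor model.

    Movers use their condition-specific planted block, so their correlation
    profile flips between conditions.
    """
    if n_trials < 10:
        raise ValueError("need at least 10 trials per condition")
    if truth.between_r > truth.within_r:
        raise ValueError("between_r must not exceed within_r")
    rng = np.random.default_rng(seed)
    out: dict[str, TrialBetaSeries] = {}
    for c in truth.conditions:
        values = _plant_condition(truth.labels(c), truth.within_r, truth.between_r, n_trials, rng)
        out[c] = TrialBetaSeries(
            values=values,
            conditions=np.full(n_trials, c, dtype=object),
        )
    return out


def make_trial_schedule(
    n_trials_per_condition: int,
    conditions: Sequence[str] = CONDITIONS,
    duration_s: float = 6.0,
    repetition_time: float = 1.6,
    iti_choices_s: Sequence[float] = (1.0, 2.0, 3.0),
    start_s: float = 16.0,
    tail_s: float = 24.0,
    seed: int = 0,
) -> TrialSchedule:
    """Randomly interleaved trial order with jittered inter-trial intervals.

    Defaults mirror a rapid event-related design: 6 s trials on a 1.6 s
    repetition-time grid with 1-3 s jitter, plus a tail so the hemodynamic
    response of the last trial is sampled.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(np.asarray(conditions, dtype=object), n_trials_per_condition))
    onsets = np.empty(len(order))
    t = float(start_s)
    for k in range(len(order)):
        onsets[k] = t
        t += duration_s + rng.choice(iti_choices_s)
    n_volumes = int(np.ceil((onsets[-1] + duration_s + tail_s) / repetition_time))
    return TrialSchedule(
        onsets=onsets,
        durations=np.full(len(order), duration_s),
        conditions=order,
        repetition_time=repetition_time,
        n_volumes=n_volumes,
    )


def simulate_bold(
    truth: GroundTruth,
    schedule: TrialSchedule,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved node x time series plus the planted trial amplitudes.

    Each trial contributes ``amplitude * (boxcar (*) canonical HRF)``;
    amplitudes come from the factor model via :func:`plant_beta_series`
    using each trial's condition, and white noise of sd ``noise_sd`` is
    added.  Returns ``(bold, amplitudes)`` with shapes (n_nodes, n_volumes)
    and (n_nodes, n_trials) in schedule order.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    amplitudes = np.empty((truth.n_nodes, schedule.n_trials))
    for c in truth.conditions:
        mask = schedule.conditions == c
        if mask.any():
            amplitudes[:, mask] = _plant_condition(
                truth.labels(c), truth.within_r, truth.between_r, int(mask.sum()), rng
            )
    hrf = canonical_hrf(schedule.repetition_time)
    regressors = trial_regressors(schedule, hrf)  # (n_volumes, n_trials)
    bold = amplitudes @ regressors.T
    if noise_sd > 0:
        bold = bold + noise_sd * rng.standard_normal(bold.shape)
    return bold, amplitudes


def simulate_fd(
    n_volumes: int,
    base_mm: float = 0.2,
    spike_prob: float = 0.05,
    spike_mm: float = 1.0,
    seed: int = 0,
) -> MotionTrace:
    """Constant baseline motion with Bernoulli spikes of ``spike_mm``."""
    if base_mm < 0 or spike_mm < 0:
        raise ValueError("motion magnitudes must be non-negative")
    if not 0.0 <= spike_prob <= 1.0:
        raise ValueError("spike_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fd = np.full(n_volumes, base_mm, dtype=float)
    fd += spike_mm * (rng.random(n_volumes) < spike_prob)
    return MotionTrace(fd_per_volume=fd)


def simulate_performance(
    similarity_per_subject: Sequence[float],
    intercept: float = 0.9,
    slope: float = -0.5,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Behavioral score = clip(intercept + slope * similarity + noise, 0, 1).

    The default negative slope plants the study's key effect: subjects whose
    task networks are more dissimilar across encoding contexts perform
    better at retrieval.
    """
    sim = np.asarray(similarity_per_subject, dtype=float)
    if sim.size == 0:
        raise ValueError("similarity list must not be empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    perf = intercept + slope * sim
    if noise_sd > 0:
        perf = perf + noise_sd * rng.standard_normal(sim.shape)
    return np.clip(perf, 0.0, 1.0)
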