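"""Trial-wise GLM estimation of beta series and trial-level QC.

A *beta series* is the sequence of per-trial response amplitudes for one
node, obtained from a single GLM containing one regressor per trial
(boxcar convolved with the canonical double-gamma HRF), optional motion
nuisance regressors, and an intercept (least-squares-all).  Correlating beta
series across nodes gives task-state functional connectivity.  This module
also extracts residual time series for the task-free baseline network and
implements the motion (framewise displacement) trial exclusion and random
trial-count equalization steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats as _st

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .synthetic import MotionTrace, TrialSchedule


@dataclass(frozen=True)
class HRFKernel:
    """Canonical HRF sampled on the repetition-time grid, unit peak."""

    samples: np.ndarray
    repetition_time: float


@dataclass(frozen=True)
class DesignMatrix:
    """GLM design: one column per trial, then nuisance columns, then intercept."""

    matrix: np.ndarray
    n_trials: int
    column_names: tuple[str, ...]
    repetition_time: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def trial_columns(self) -> slice:
        return slice(0, self.n_trials)


@dataclass(frozen=True)
class TrialBetaSeries:
    """Node x trial amplitudes with per-trial metadata.

    ``values`` holds only the currently kept trials; trials removed by QC are
    recorded in ``dropped`` as ``(original_index, reason)`` pairs.
    """

    values: np.ndarray
    conditions: np.ndarray | None = None
    dropped: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a node x trial matrix")
        if self.conditions is not None and len(self.conditions) != self.n_trials:
            raise ValueError("one condition label per kept trial required")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def subset(self, keep: np.ndarray, reason: str) -> "TrialBetaSeries":
        """Return a copy with only ``keep`` (boolean mask) trials retained."""
        keep = np.asarray(keep, dtype=bool)
        newly_dropped = tuple((int(i), reason) for i in np.flatnonzero(~keep))
        return TrialBetaSeries(
            values=self.values[:, keep],
            conditions=None if self.conditions is None else np.asarray(self.conditions)[keep],
            dropped=self.dropped + newly_dropped,
        )

    def for_condition(self, condition: str) -> "TrialBetaSeries":
        if self.conditions is None:
            raise ValueError("series carries no condition labels")
        mask = np.asarray(self.conditions) == condition
        return TrialBetaSeries(values=self.values[:, mask], conditions=self.conditions[mask])


def canonical_hrf(repetition_time: float, length_s: float = 32.0) -> HRFKernel:
    """Double-gamma HRF: response gamma (shape 6) minus 1/6-weighted undershoot
    gamma (shape 16), sampled at the repetition time and scaled to unit peak.

    The response peaks near 5 s and the undershoot resolves within ~30 s.
    """
    if repetition_time <= 0:
        raise ValueError("repetition_time must be positive")
    if length_s < 20.0:
        raise ValueError("kernel must cover at least 20 s")
    t = np.arange(0.0, length_s + repetition_time / 2.0, repetition_time)
    h = _st.gamma.pdf(t, a=6.0) - _st.gamma.pdf(t, a=16.0) / 6.0
    return HRFKernel(samples=h / h.max(), repetition_time=repetition_time)


def trial_regressors(schedule: "TrialSchedule", hrf: HRFKernel) -> np.ndarray:
    """One boxcar-convolved-with-HRF column per trial, (n_volumes, n_trials)."""
    if abs(hrf.repetition_time - schedule.repetition_time) > 1e-9:
        raise ValueError("HRF and schedule repetition times differ")
    t = schedule.volume_times
    cols = np.empty((schedule.n_volumes, schedule.n_trials))
    for k in range(schedule.n_trials):
        onset, duration = schedule.onsets[k], schedule.durations[k]
        box = ((t >= onset) & (t < onset + duration)).astype(float)
        if not box.any():
            raise ValueError(f"trial {k} falls outside the scan window")
        cols[:, k] = np.convolve(box, hrf.samples)[: schedule.n_volumes]
    return cols


def _rank_deficient_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[j] for j in np.flatnonzero(diag <= tol)]


def build_design(
    schedule: "TrialSchedule",
    hrf: HRFKernel,
    nuisance: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the trial-wise GLM design (trials + nuisance + intercept)."""
    trial_cols = trial_regressors(schedule, hrf)
    names = [f"trial_{k}" for k in range(schedule.n_trials)]
    parts = [trial_cols]
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != schedule.n_volumes:
            raise ValueError("nuisance regressors must have one row per volume")
        parts.append(nuisance)
        names += [f"nuisance_{k}" for k in range(nuisance.shape[1])]
    parts.append(np.ones((schedule.n_volumes, 1)))
    names.append("intercept")
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _rank_deficient_columns(X, names)
        raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")
    return DesignMatrix(
        matrix=X,
        n_trials=schedule.n_trials,
        column_names=tuple(names),
        repetition_time=schedule.repetition_time,
    )


def estimate_beta_series(
    bold: np.ndarray,
    design: DesignMatrix,
    conditions: np.ndarray | None = None,
) -> TrialBetaSeries:
    """Ordinary least squares per node; returns the trial-column coefficients."""
    bold = np.asarray(bold, dtype=float)
    if bold.shape[1] != design.n_volumes:
        raise ValueError("bold time points must match design rows")
    X = design.matrix
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _rank_deficient_columns(X, design.column_names)
        raise ValueError(f"singular design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, bold.T, rcond=None)
    return TrialBetaSeries(values=coef[design.trial_columns].T, conditions=conditions)


def exclude_motion_trials(
    series: TrialBetaSeries,
    motion: "MotionTrace",
    schedule: "TrialSchedule",
    fd_threshold_mm: float = 0.55,
) -> TrialBetaSeries:
    """Drop every trial containing a volume with FD above the threshold.

    A volume at time ``v * repetition_time`` belongs to a trial when it falls
    in ``[onset, onset + duration)``; the default 0.55 mm cut-off is applied
    per volume.
    """
    if fd_threshold_mm <= 0:
        raise ValueError("fd threshold must be positive")
    if motion.n_volumes < schedule.n_volumes:
        raise ValueError("motion trace does not cover the scan")
    if series.n_trials != schedule.n_trials:
        raise ValueError("series and schedule disagree on trial count")
    fd = np.asarray(motion.fd_per_volume, dtype=float)
    t = schedule.volume_times
    keep = np.ones(schedule.n_trials, dtype=bool)
    for k in range(schedule.n_trials):
        in_trial = (t >= schedule.onsets[k]) & (t < schedule.onsets[k] + schedule.durations[k])
        if np.any(fd[: schedule.n_volumes][in_trial] > fd_threshold_mm):
            keep[k] = False
    return series.subset(keep, reason="fd")


def equalize_trials(
    a: TrialBetaSeries, b: TrialBetaSeries, seed: int = 0
) -> tuple[TrialBetaSeries, TrialBetaSeries]:
    """Randomly drop trials from the longer series so both have equal length."""
    if a.n_trials == 0 or b.n_trials == 0:
        raise ValueError("cannot equalize an empty beta series")
    n = min(a.n_trials, b.n_trials)
    rng = np.random.default_rng(seed)

    def trim(s: TrialBetaSeries) -> TrialBetaSeries:
        if s.n_trials == n:
            return s
        kept = np.sort(rng.choice(s.n_trials, size=n, replace=False))
        mask = np.zeros(s.n_trials, dtype=bool)
        mask[kept] = True
        return s.subset(mask, reason="equalize")

    return trim(a), trim(b)


def residual_baseline_series(
    bold: np.ndarray,
    design: DesignMatrix,
    block_windows: Sequence[tuple[float, float]],
    settle_offset_s: float = 18.0,
) -> np.ndarray:
    """Task-free baseline series: GLM residuals inside rest windows.

    Residuals are ``bold - X @ beta_hat``.  Within each ``(start, end)``
    window (seconds) the first ``settle_offset_s`` seconds are discarded so
    the hemodynamic tail of preceding trials has settled; surviving segments
    are concatenated in time order.
    """
    bold = np.asarray(bold, dtype=float)
    X = design.matrix
    coef, *_ = np.linalg.lstsq(X, bold.T, rcond=None)
    resid = bold - (X @ coef).T
    t = np.arange(design.n_volumes) * design.repetition_time
    segments = []
    for start, end in sorted(block_windows):
        if end > design.n_volumes * design.repetition_time + 1e-9:
            raise ValueError("window extends past the scan")
        if end - start <= settle_offset_s:
            warnings.warn(
                f"window ({start}, {end}) shorter than the {settle_offset_s} s "
                "settle offset contributes no samples",
                stacklevel=2,
            )
            continue
        keep = (t >= start + settle_offset_s) & (t < end)
        segments.append(resid[:, keep])
    if not segments:
        return np.empty((bold.shape[0], 0))
    return np.concatenate(segments, axis=1)
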