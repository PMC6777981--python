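"""End-to-end workflow helpers tying the stages together.

These wrap the per-stage modules into the two workflows used throughout:
(1) beta series -> filtered Fisher-z network for one subject/condition, and
(2) a whole synthetic cohort where each subject's encoding-network
similarity is measured from simulated BOLD through the full GLM +
connectivity path and behavior is planted on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import betas as _betas
from . import connectivity as _conn
from . import metrics as _metrics
from . import synthetic as _synth

ENCODING_PAIR = ("space_encoding", "time_encoding")


def series_to_network(
    series: _betas.TrialBetaSeries,
    node_table: pd.DataFrame,
    min_distance_mm: float = 20.0,
) -> _conn.ConnectivityMatrix:
    """Correlate a beta series and apply the Fisher-z + edge filters."""
    raw = _conn.correlation_network(series)
    return _conn.fisher_and_filter(raw, node_table, min_distance_mm=min_distance_mm)


@dataclass(frozen=True)
class SyntheticCohort:
    """One simulated cohort: per-subject encoding networks, their measured
    similarity, and behavior coupled to it."""

    similarities: np.ndarray
    performance: np.ndarray
    networks_a: tuple[_conn.ConnectivityMatrix, ...]
    networks_b: tuple[_conn.ConnectivityMatrix, ...]
    node_table: pd.DataFrame


def simulate_similarity_cohort(
    n_subjects: int = 18,
    n_nodes: int = 100,
    n_trials: int = 40,
    slope: float = -0.5,
    intercept: float = 0.9,
    behavior_noise_sd: float = 0.02,
    bold_noise_sd: float = 1.0,
    within_r_range: tuple[float, float] = (0.3, 0.6),
    between_r: float = 0.1,
    condition_pair: tuple[str, str] = ENCODING_PAIR,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate a cohort and run each subject through the full pipeline.

    Per subject: draw a within-block correlation from ``within_r_range``
    (between-subject heterogeneity in connectivity strength, which spreads
    the measured similarities), simulate HRF-convolved BOLD for the two
    conditions of ``condition_pair``, estimate beta series by trial-wise
    GLM, build filtered Fisher-z networks, and measure their whole-network
    similarity.  Behavior is then planted as
    ``clip(intercept + slope * similarity + noise, 0, 1)``.
    """
    rng = np.random.default_rng(seed)
    node_table = _synth.make_node_table(
        n_nodes, ["RSN%d" % k for k in range(10)], seed=int(rng.integers(2**31 - 1))
    )
    hrf = None
    sims: list[float] = []
    nets_a: list[_conn.ConnectivityMatrix] = []
    nets_b: list[_conn.ConnectivityMatrix] = []
    for _ in range(n_subjects):
        within_r = float(rng.uniform(*within_r_range))
        truth = _synth.make_ground_truth(
            n_nodes=n_nodes, within_r=within_r, between_r=between_r,
            seed=int(rng.integers(2**31 - 1)),
        )
        schedule = _synth.make_trial_schedule(
            n_trials, conditions=condition_pair, seed=int(rng.integers(2**31 - 1))
        )
        bold, _ = _synth.simulate_bold(
            truth, schedule, noise_sd=bold_noise_sd, seed=int(rng.integers(2**31 - 1))
        )
        if hrf is None or abs(hrf.repetition_time - schedule.repetition_time) > 1e-12:
            hrf = _betas.canonical_hrf(schedule.repetition_time)
        design = _betas.build_design(schedule, hrf)
        series = _betas.estimate_beta_series(bold, design, conditions=schedule.conditions)
        net = {
            c: series_to_network(series.for_condition(c), node_table) for c in condition_pair
        }
        a, b = condition_pair
        sims.append(_metrics.network_similarity(net[a], net[b]).similarity_r)
        nets_a.append(net[a])
        nets_b.append(net[b])
    performance = _synth.simulate_performance(
        sims, intercept=intercept, slope=slope, noise_sd=behavior_noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    return SyntheticCohort(
        similarities=np.asarray(sims),
        performance=performance,
        networks_a=tuple(nets_a),
        networks_b=tuple(nets_b),
        node_table=node_table,
    )
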