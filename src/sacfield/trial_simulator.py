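"""Deterministic single-trial simulation and randomly parameterized batches.

A trial starts at fixation onset with every node's internal state at the
reset value and runs in 1-ms steps until the first millisecond at which
the output activity of any non-central node reaches the saccade threshold,
or until ``timeout_ms`` after target onset.  The SRT is the crossing time
minus target onset.  All stochasticity lives in the per-trial parameter
draw (and the coin flip for target side); the field dynamics themselves
are noise free, so an identical assignment always reproduces the
identical trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .component_inputs import (
    InputModelOptions,
    TrialTimeline,
    drive_matrix,
    make_trial_inputs,
)
from .field_core import ModelConstants, interaction_matrix
from .parameter_space import ParameterAssignment, StepConfig, sample_trial_parameters


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial."""

    srt_ms: Optional[float]
    direction: str  # left | right | none
    crossing_node: Optional[int]
    category: Optional[str] = None  # filled by srt_analysis
    assignment: Optional[ParameterAssignment] = None

    @property
    def no_saccade(self) -> bool:
        return self.direction == "none"


@dataclass
class BatchResult:
    """SRT sample from a batch of randomly parameterized trials."""

    table: pd.DataFrame  # trial, srt_ms, direction, no_saccade
    config_id: str
    seed: int
    n_trials: int
    assignments: List[ParameterAssignment] = field(default_factory=list)

    @property
    def no_saccade_fraction(self) -> float:
        if self.n_trials == 0:
            return 0.0
        return float(self.table["no_saccade"].mean())

    def srt_values(self) -> np.ndarray:
        """SRTs (ms) of the trials that produced a saccade."""
        ok = ~self.table["no_saccade"]
        return self.table.loc[ok, "srt_ms"].to_numpy(dtype=float)


def default_timeline(target_side: int = +1, eccentricity_mm: float = 2.0) -> TrialTimeline:
    return TrialTimeline(target_position_mm=float(target_side) * eccentricity_mm)


def _crossing_from_activity(
    a: np.ndarray, mask: np.ndarray, threshold: float
) -> Optional[int]:
    """Index of the crossing node, or None.

    Ties across simultaneously crossing nodes are broken by largest
    activity, then smallest node index (argmax returns the first
    maximum).
    """
    masked = np.where(mask, a, -np.inf)
    j = int(np.argmax(masked))
    if masked[j] >= threshold:
        return j
    return None


def run_trial(
    assignment: ParameterAssignment,
    timeline: Optional[TrialTimeline] = None,
    constants: ModelConstants = ModelConstants(),
    options: InputModelOptions = InputModelOptions(),
) -> TrialResult:
    """Simulate one trial of the field model for a complete assignment."""
    timeline = timeline or default_timeline()
    specs, _states, internal_onset = make_trial_inputs(
        assignment, timeline, constants, options
    )
    t_end = timeline.target_onset_ms + constants.timeout_ms
    drives = drive_matrix(specs, timeline, constants, t_end, internal_onset)
    w = interaction_matrix(constants)
    mask = constants.noncentral_mask()
    positions = constants.node_positions()

    alpha = constants.dt_ms / constants.tau_ms
    u = np.full(constants.n_nodes, constants.reset_value, dtype=float)
    a = expit(constants.beta * u)
    for k in range(drives.shape[0]):
        u = (1.0 - alpha) * u + alpha * (drives[k] + w @ a)
        a = expit(constants.beta * u)
        node = _crossing_from_activity(a, mask, constants.threshold)
        if node is not None:
            t_cross = (k + 1) * constants.dt_ms
            direction = "right" if positions[node] > 0 else "left"
            return TrialResult(
                srt_ms=t_cross - timeline.target_onset_ms,
                direction=direction,
                crossing_node=node,
                assignment=assignment,
            )
    return TrialResult(
        srt_ms=None, direction="none", crossing_node=None, assignment=assignment
    )


def _run_chunk(
    assignments: Sequence[ParameterAssignment],
    sides: Sequence[int],
    constants: ModelConstants,
    options: InputModelOptions,
) -> List[TrialResult]:
    """Simulate a chunk of trials in lockstep (vectorized over trials).

    Arithmetically equivalent to :func:`run_trial` applied per trial; the
    equivalence is asserted in the test suite.
    """
    b = len(assignments)
    n = constants.n_nodes
    timelines = [
        default_timeline(s, options.target_eccentricity_mm) for s in sides
    ]
    t_end = timelines[0].target_onset_ms + constants.timeout_ms
    n_steps = int(round(t_end / constants.dt_ms))
    drives = np.empty((b, n_steps, n))
    for i, (asg, tl) in enumerate(zip(assignments, timelines)):
        specs, _s, onset = make_trial_inputs(asg, tl, constants, options)
        drives[i] = drive_matrix(specs, tl, constants, t_end, onset)

    w = interaction_matrix(constants)
    mask = constants.noncentral_mask()
    positions = constants.node_positions()
    alpha = constants.dt_ms / constants.tau_ms

    u = np.full((b, n), constants.reset_value, dtype=float)
    a = expit(constants.beta * u)
    cross_time = np.full(b, np.nan)
    cross_node = np.full(b, -1, dtype=int)
    pending = np.ones(b, dtype=bool)
    neg_inf = np.full(n, -np.inf)

    for k in range(n_steps):
        u = (1.0 - alpha) * u + alpha * (drives[:, k, :] + a @ w)
        a = expit(constants.beta * u)
        masked = np.where(mask, a, neg_inf)
        j = np.argmax(masked, axis=1)
        crossed = masked[np.arange(b), j] >= constants.threshold
        newly = crossed & pending
        if newly.any():
            cross_time[newly] = (k + 1) * constants.dt_ms
            cross_node[newly] = j[newly]
            pending &= ~newly
            if not pending.any():
                break

    results = []
    for i, (asg, tl) in enumerate(zip(assignments, timelines)):
        if cross_node[i] < 0:
            results.append(TrialResult(None, "none", None, assignment=asg))
        else:
            node = int(cross_node[i])
            results.append(
                TrialResult(
                    srt_ms=cross_time[i] - tl.target_onset_ms,
                    direction="right" if positions[node] > 0 else "left",
                    crossing_node=node,
                    assignment=asg,
                )
            )
    return results


def run_batch(
    config: StepConfig,
    n_trials: int,
    seed: int,
    constants: ModelConstants = ModelConstants(),
    options: InputModelOptions = InputModelOptions(),
    chunk_size: int = 128,
    keep_assignments: bool = False,
) -> BatchResult:
    """Simulate ``n_trials`` independently parameterized trials.

    Each trial draws one assignment from the grid and a target side
    (left/right, equal probability); the field model is mirror symmetric,
    so the side affects only the reported direction.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    rng = np.random.default_rng(seed)
    assignments = [sample_trial_parameters(config, rng) for _ in range(n_trials)]
    sides = (2 * rng.integers(0, 2, size=n_trials) - 1).astype(int)

    results: List[TrialResult] = []
    for start in range(0, n_trials, chunk_size):
        stop = min(start + chunk_size, n_trials)
        results.extend(
            _run_chunk(assignments[start:stop], sides[start:stop], constants, options)
        )

    table = pd.DataFrame(
        {
            "trial": np.arange(n_trials, dtype=int),
            "srt_ms": pd.array(
                [None if r.no_saccade else int(round(r.srt_ms)) for r in results],
                dtype="Int64",
            ),
            "direction": [r.direction for r in results],
            "no_saccade": [r.no_saccade for r in results],
        }
    )
    return BatchResult(
        table=table,
        config_id=config.config_id,
        seed=seed,
        n_trials=n_trials,
        assignments=assignments if keep_assignments else [],
    )
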