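"""The eight component inputs that drive the field on the gap-task timeline.

Each input abstracts a neural signal implicated in saccade generation
(visual burst, parietal motor command, frontal voluntary drive, nigral
inhibitory gate, ...).  An input is a spatial weight profile (a Gaussian
kernel on the torus, a uniform field, or a peripheral mask) multiplied by
a piecewise-linear temporal envelope.  The envelope rises from the input's
onset at a rate of ``RoR`` percent of its maximum strength (``MaxVal``)
per millisecond, and — depending on the input — either sustains at its
cap, decays straight back down (a brief visual burst), or is released
toward zero when a later event fires (fixation disengagement,
disinhibition).  The signed sum of the eight inputs is the external drive
``c_ext`` fed to the field at every millisecond.

Inputs 4-8 (the internally driven group) share one jointly drawn onset
delay relative to target onset, the "internal onset"; this joint delay is
the model's express/regular watershed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .field_core import ModelConstants, toroidal_distance

PROFILES = ("ramp_sustain", "ramp_decay", "ramp_release", "field_wide_release")
REFERENCE_EVENTS = (
    "trial_start",
    "fixation_onset",
    "gap_onset",
    "target_onset",
    "internal_onset",
)

#: Default standard deviation (mm) of the input spatial kernel.
KERNEL_GAMMA_MM = 0.6
#: Default amplitude of the input spatial kernel.
KERNEL_AMP = 1.05

INPUT_NAMES = {
    1: "visual_transient",
    2: "automated_motor",
    3: "automated_fixation",
    4: "voluntary_motor",
    5: "voluntary_fixation",
    6: "voluntary_preparation",
    7: "inhibitory_gate",
    8: "peripheral_inhibition",
}


@dataclass(frozen=True)
class TrialTimeline:
    """Event times of one gap trial, in ms from fixation onset.

    The fixation point appears at t = 0, disappears at ``gap_onset_ms``
    and the target appears 200 ms later at ``target_onset_ms``.
    """

    fixation_onset_ms: float = 0.0
    gap_onset_ms: float = 200.0
    target_onset_ms: float = 400.0
    target_position_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.gap_onset_ms <= self.fixation_onset_ms:
            raise ValueError("gap onset must follow fixation onset")
        if self.target_onset_ms != self.gap_onset_ms + 200.0:
            raise ValueError("target onset must be exactly gap onset + 200 ms")

    def event_time(self, event: str, internal_onset_ms: Optional[float] = None) -> float:
        if event == "trial_start":
            return 0.0
        if event == "fixation_onset":
            return self.fixation_onset_ms
        if event == "gap_onset":
            return self.gap_onset_ms
        if event == "target_onset":
            return self.target_onset_ms
        if event == "internal_onset":
            if internal_onset_ms is None:
                raise ValueError("internal onset time not supplied")
            return internal_onset_ms
        raise ValueError(f"unknown reference event {event!r}")


@dataclass(frozen=True)
class InputModelOptions:
    """Tunable conventions of the input model (all configurable).

    ``vm_reference_strength`` sets the drive-unit scale of the uncapped
    voluntary-motor ramp: its per-ms rise is ``RoR/100`` of this value
    (the voluntary motor has no MaxVal of its own; it rises until a
    saccade is made).  With the default of 1, RoR is read as an absolute
    rise of ``RoR/100`` drive units per millisecond, so a 1% voluntary
    build-up is genuinely sluggish (the delayed-saccade regime) while
    10-20% crosses within a few tens of ms of the internal onset.
    """

    kernel_gamma_mm: float = KERNEL_GAMMA_MM
    kernel_amp: float = KERNEL_AMP
    vm_reference_strength: float = 1.0
    target_eccentricity_mm: float = 2.0


@dataclass(frozen=True)
class InputSpec:
    """Static description of one component input."""

    input_id: int
    name: str
    reference_event: str
    onset_delay_ms: float
    ror: float
    maxval: float  # may be math.inf for the uncapped voluntary motor
    centers_mm: tuple
    polarity: int  # +1 excitatory, -1 inhibitory
    profile: str
    release_event: Optional[str] = None
    release_delay_ms: float = 0.0
    shape: str = "kernel"  # kernel | uniform | peripheral
    release_window: str = "uniform"  # uniform | kernel_at_target
    starts_at_cap: bool = False
    ror_basis: Optional[float] = None  # rise scale when maxval is unbounded
    kernel_gamma_mm: float = KERNEL_GAMMA_MM
    kernel_amp: float = KERNEL_AMP

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.reference_event not in REFERENCE_EVENTS:
            raise ValueError(f"unknown reference event {self.reference_event!r}")
        if self.ror < 0:
            raise ValueError("ror must be non-negative")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if math.isfinite(self.maxval) and self.maxval < 0:
            raise ValueError("maxval must be non-negative")

    @property
    def rate_per_ms(self) -> float:
        """Envelope growth per ms: RoR percent of MaxVal (or of the basis)."""
        basis = self.maxval if math.isfinite(self.maxval) else self.ror_basis
        if basis is None:
            raise ValueError("unbounded input requires ror_basis")
        return (self.ror / 100.0) * basis


@dataclass
class InputState:
    """Current (unsigned) spatial drive of one input plus a phase marker."""

    value: np.ndarray
    phase: str
    t_ms: float


def spatial_kernel(
    center_mm: float,
    constants: ModelConstants,
    gamma_mm: float = KERNEL_GAMMA_MM,
    amp: float = KERNEL_AMP,
) -> np.ndarray:
    """Gaussian spatial profile of an input on the toroidal field.

    ``kappa_i = amp * exp(-d_i^2 / (2 gamma^2))`` with ``d_i`` the toroidal
    distance from node i to the center.  Peaks at ``amp`` on the center
    node.
    """
    d = toroidal_distance(constants.node_positions(), center_mm, constants.period_mm)
    return amp * np.exp(-(d**2) / (2.0 * gamma_mm**2))


def input_shape(spec: InputSpec, constants: ModelConstants) -> np.ndarray:
    """Unsigned spatial weight profile of an input (kernel/uniform/mask)."""
    if spec.shape == "kernel":
        shape = np.zeros(constants.n_nodes)
        for c in spec.centers_mm:
            shape += spatial_kernel(c, constants, spec.kernel_gamma_mm, spec.kernel_amp)
        return shape
    if spec.shape == "uniform":
        return np.ones(constants.n_nodes)
    if spec.shape == "peripheral":
        return constants.noncentral_mask().astype(float)
    raise ValueError(f"unknown shape {spec.shape!r}")


def _release_window(
    spec: InputSpec, timeline: TrialTimeline, constants: ModelConstants
) -> np.ndarray:
    if spec.release_window == "uniform":
        return np.ones(constants.n_nodes)
    if spec.release_window == "kernel_at_target":
        return spatial_kernel(
            timeline.target_position_mm, constants, spec.kernel_gamma_mm, spec.kernel_amp
        )
    raise ValueError(f"unknown release window {spec.release_window!r}")


def envelope_value(
    spec: InputSpec,
    t,
    timeline: TrialTimeline,
    internal_onset_ms: Optional[float] = None,
):
    """Scalar temporal envelope of an input at time(s) ``t`` (ms).

    Piecewise linear; the per-node drive is this envelope multiplied by
    the spatial profile (for the two release-windowed inhibitory inputs
    the release term is additionally node dependent, see
    :func:`value_field`).  The ``ramp_decay`` profile turns over at the
    first whole millisecond at which the cap is reached.
    """
    t = np.asarray(t, dtype=float)
    t_on = timeline.event_time(spec.reference_event, internal_onset_ms) + spec.onset_delay_ms
    r = spec.rate_per_ms

    if spec.profile == "ramp_sustain":
        rise = r * np.maximum(0.0, t - t_on)
        return np.minimum(rise, spec.maxval) if math.isfinite(spec.maxval) else rise

    if spec.profile == "ramp_decay":
        if r <= 0:
            return np.zeros_like(t)
        # first whole-ms sample at the cap, then straight back down
        t_peak = t_on + math.ceil(spec.maxval / r)
        rise = np.minimum(r * np.maximum(0.0, t - t_on), spec.maxval)
        fall = spec.maxval - r * np.maximum(0.0, t - t_peak)
        return np.clip(np.minimum(rise, fall), 0.0, spec.maxval)

    if spec.profile in ("ramp_release", "field_wide_release"):
        if spec.release_event is None:
            raise ValueError(f"{spec.name} requires a release event")
        t_rel = (
            timeline.event_time(spec.release_event, internal_onset_ms)
            + spec.release_delay_ms
        )
        if spec.starts_at_cap:
            # held at cap from trial start; proportional release: the input
            # loses RoR percent of its *current* value per ms, so stronger
            # inhibition leaves a proportionally larger residual at every
            # time after release (geometric decay in discrete time)
            base = np.full_like(t, spec.maxval)
            if spec.profile == "field_wide_release":
                return base  # node-dependent release handled in value_field
            decay = (1.0 - spec.ror / 100.0) ** np.maximum(0.0, t - t_rel)
            return base * decay
        # rise from onset at RoR; the rise freezes once the release event
        # fires and the input then ramps linearly back toward zero
        base = np.minimum(r * np.maximum(0.0, np.minimum(t, t_rel) - t_on), spec.maxval)
        return np.clip(base - r * np.maximum(0.0, t - t_rel), 0.0, None)

    raise ValueError(f"unknown profile {spec.profile!r}")


def value_field(
    spec: InputSpec,
    t,
    timeline: TrialTimeline,
    constants: ModelConstants,
    internal_onset_ms: Optional[float] = None,
) -> np.ndarray:
    """Unsigned per-node drive of an input at time(s) ``t``.

    Returns shape ``(n_nodes,)`` for scalar ``t`` or ``(len(t), n_nodes)``
    for a vector of times.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    shape = input_shape(spec, constants)
    env = envelope_value(spec, t_arr, timeline, internal_onset_ms)
    values = env[:, None] * shape[None, :]
    if spec.profile == "field_wide_release":
        # proportional (geometric) release under the spatial window: each
        # ms the input loses RoR percent of its current value, fastest at
        # the window center
        t_rel = (
            timeline.event_time(spec.release_event, internal_onset_ms)
            + spec.release_delay_ms
        )
        window = _release_window(spec, timeline, constants)
        per_ms = np.clip(1.0 - (spec.ror / 100.0) * window, 0.0, 1.0)
        decay = per_ms[None, :] ** np.maximum(0.0, t_arr - t_rel)[:, None]
        values = values * decay
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return values[0]
    return values


def initial_input_state(
    spec: InputSpec,
    timeline: TrialTimeline,
    constants: ModelConstants,
    internal_onset_ms: Optional[float] = None,
) -> InputState:
    value = value_field(spec, 0.0, timeline, constants, internal_onset_ms)
    phase = "saturated" if spec.starts_at_cap else "pre_onset"
    return InputState(value=value, phase=phase, t_ms=0.0)


def input_update(
    state: InputState,
    spec: InputSpec,
    t: float,
    timeline: TrialTimeline,
    constants: ModelConstants,
    internal_onset_ms: Optional[float] = None,
) -> InputState:
    """Advance one input by one millisecond, from time ``t`` to ``t + dt``.

    The per-node value rises by ``kappa_i * (RoR/100) * MaxVal`` per ms
    (clipped at ``kappa_i * MaxVal``), and decays/releases at the same
    rate according to the input's profile.
    """
    t_new = t + constants.dt_ms
    value = value_field(spec, t_new, timeline, constants, internal_onset_ms)
    t_on = timeline.event_time(spec.reference_event, internal_onset_ms) + spec.onset_delay_ms
    if t_new <= t_on and not spec.starts_at_cap:
        phase = "pre_onset"
    elif np.allclose(value, 0.0) and t_new > t_on:
        phase = "released"
    elif spec.release_event is not None and t_new > timeline.event_time(
        spec.release_event, internal_onset_ms
    ) + spec.release_delay_ms:
        phase = "releasing"
    elif math.isfinite(spec.maxval) and np.isclose(
        np.max(value), spec.kernel_amp * spec.maxval if spec.shape == "kernel" else spec.maxval
    ):
        phase = "saturated"
    else:
        phase = "rising"
    return InputState(value=value, phase=phase, t_ms=t_new)


def assemble_external_drive(
    states: Sequence[InputState], specs: Sequence[InputSpec]
) -> np.ndarray:
    """Signed elementwise sum of the component inputs: ``c_ext``."""
    if len(states) != len(specs) or not states:
        raise ValueError("need one state per input spec")
    total = np.zeros_like(states[0].value)
    for st, sp in zip(states, specs):
        total = total + sp.polarity * st.value
    return total


def drive_matrix(
    specs: Sequence[InputSpec],
    timeline: TrialTimeline,
    constants: ModelConstants,
    t_end_ms: float,
    internal_onset_ms: Optional[float] = None,
) -> np.ndarray:
    """External drive ``c_ext`` for every millisecond of a trial.

    Row ``k`` is the signed drive at time ``k * dt`` (used to advance the
    field from ``k*dt`` to ``(k+1)*dt``).  Shape ``(T, n_nodes)``.
    """
    n_steps = int(round(t_end_ms / constants.dt_ms))
    t_grid = np.arange(n_steps) * constants.dt_ms
    total = np.zeros((n_steps, constants.n_nodes))
    for spec in specs:
        total += spec.polarity * value_field(
            spec, t_grid, timeline, constants, internal_onset_ms
        )
    return total


def make_trial_inputs(
    assignment,
    timeline: TrialTimeline,
    constants: ModelConstants,
    options: InputModelOptions = InputModelOptions(),
):
    """Configure the eight component inputs for one trial.

    ``assignment`` is a mapping from attribute names (``vt_onset``,
    ``am_ror``, ``internal_onset``, ...) to sampled values.  Returns
    ``(specs, states, internal_onset_ms)`` where ``internal_onset_ms`` is
    the absolute time of the jointly drawn internal onset shared by
    inputs 4-8.
    """
    tgt = timeline.target_position_mm
    kw = dict(kernel_gamma_mm=options.kernel_gamma_mm, kernel_amp=options.kernel_amp)
    internal_onset_ms = timeline.target_onset_ms + float(assignment["internal_onset"])

    specs = [
        InputSpec(
            1, "visual_transient", "target_onset", float(assignment["vt_onset"]),
            float(assignment["vt_ror"]), float(assignment["vt_maxval"]),
            (tgt,), +1, "ramp_decay", **kw,
        ),
        InputSpec(
            2, "automated_motor", "target_onset", float(assignment["am_onset"]),
            float(assignment["am_ror"]), float(assignment["am_maxval"]),
            (tgt,), +1, "ramp_sustain", **kw,
        ),
        InputSpec(
            3, "automated_fixation", "fixation_onset", float(assignment["af_onset"]),
            float(assignment["af_ror"]), float(assignment["af_maxval"]),
            (0.0,), +1, "ramp_release", release_event="gap_onset", **kw,
        ),
        InputSpec(
            4, "voluntary_motor", "internal_onset", 0.0,
            float(assignment["vm_ror"]), math.inf,
            (tgt,), +1, "ramp_sustain", ror_basis=options.vm_reference_strength, **kw,
        ),
        InputSpec(
            5, "voluntary_fixation", "fixation_onset", 0.0,
            float(assignment["vf_ror"]), float(assignment["vf_maxval"]),
            (0.0,), +1, "ramp_release", release_event="internal_onset", **kw,
        ),
        InputSpec(
            6, "voluntary_preparation", "internal_onset", 0.0,
            1.0, float(assignment["vp_maxval"]),
            (tgt, -tgt), +1, "ramp_sustain", **kw,
        ),
        # The gate spans the motor map (every non-central node) but spares
        # the rostral fixation zone: it suppresses motor commands, and a
        # gate that also extinguished fixation activity would paradoxically
        # accelerate saccades by removing the fixation zone's lateral
        # inhibition.  Its release is windowed on the target.
        InputSpec(
            7, "inhibitory_gate", "trial_start", 0.0,
            float(assignment["ig_ror"]), float(assignment["ig_maxval"]),
            (), -1, "field_wide_release", release_event="internal_onset",
            shape="peripheral", release_window="kernel_at_target", starts_at_cap=True, **kw,
        ),
        InputSpec(
            8, "peripheral_inhibition", "trial_start", 0.0,
            float(assignment["pi_ror"]), float(assignment["pi_maxval"]),
            (), -1, "ramp_release", release_event="internal_onset",
            shape="peripheral", starts_at_cap=True, **kw,
        ),
    ]
    states = [
        initial_input_state(s, timeline, constants, internal_onset_ms) for s in specs
    ]
    return specs, states, internal_onset_ms
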