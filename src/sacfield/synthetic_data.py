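"""Synthetic gap-task behavioural data with empirical SRT structure.

No behavioural recordings ship with the package, so this module generates
datasets carrying the statistical structure the analysis pipeline
assumes.  The marmoset configuration is bimodal: a truncated-normal
express component below ~75 ms plus a shifted log-normal regular
component, calibrated so that the composite median is ~122 ms, the
minimum latency is 61 ms and ~9.4% of saccades exceed 250 ms.  The human
configuration is a single shifted log-normal with median ~147 ms, minimum
108 ms and ~0.4% beyond 250 ms.  Component forms are standard
reaction-time models; every parameter is configurable and all draws are
seeded.

:func:`generate_landing_data` additionally emulates the landing-point
scatter used to locate the anticipatory boundary: a configurable fraction
of anticipatory saccades at latencies below the boundary with
chance-level (errant-biased) direction, while visually driven saccades
land near the target with small errant contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .srt_analysis import SRTSample


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic SRT generator for one species.

    The regular component is ``shift + LogNormal(mu, sigma)`` (ms); the
    express component (weight ``express_weight``, marmoset only by
    default) is a normal truncated below ``min_srt_ms``.
    """

    species: str
    n: int
    express_weight: float
    express_loc_ms: float
    express_scale_ms: float
    regular_shift_ms: float
    regular_mu: float
    regular_sigma: float
    min_srt_ms: float
    # landing-point / anticipatory-saccade model
    anticipatory_fraction: float = 0.12
    anticipatory_boundary_ms: float = 60.0
    anticipatory_min_ms: float = 20.0
    anticipatory_errant_prob: float = 0.6
    visual_errant_prob: float = 0.02
    target_eccentricity_deg: float = 6.0
    landing_noise_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 <= self.express_weight <= 1.0:
            raise ValueError("express_weight must lie in [0, 1]")
        if self.min_srt_ms > self.regular_shift_ms + np.exp(self.regular_mu):
            raise ValueError("truncation must lie below the regular component median")


def marmoset_spec(n: int) -> GeneratorSpec:
    """Marmoset defaults: bimodal, median ~122 ms, ~9.4% beyond 250 ms."""
    return GeneratorSpec(
        species="marmoset",
        n=n,
        express_weight=0.25,
        express_loc_ms=68.0,
        express_scale_ms=6.0,
        regular_shift_ms=75.0,
        regular_mu=4.2085,
        regular_sigma=0.8323,
        min_srt_ms=61.0,
    )


def human_spec(n: int) -> GeneratorSpec:
    """Human defaults: unimodal, median ~147 ms, ~0.4% beyond 250 ms."""
    return GeneratorSpec(
        species="human",
        n=n,
        express_weight=0.0,
        express_loc_ms=0.0,
        express_scale_ms=1.0,
        regular_shift_ms=100.0,
        regular_mu=3.8501,
        regular_sigma=0.4378,
        min_srt_ms=108.0,
    )


def species_spec(species: str, n: int) -> GeneratorSpec:
    if species == "marmoset":
        return marmoset_spec(n)
    if species == "human":
        return human_spec(n)
    raise ValueError(f"unknown species {species!r}")


def _draw_visually_driven(
    spec: GeneratorSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Visually driven latencies (>= min_srt_ms), integer ms."""
    if n == 0:
        return np.empty(0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        need = n - filled
        is_express = rng.random(need) < spec.express_weight
        draws = np.where(
            is_express,
            rng.normal(spec.express_loc_ms, spec.express_scale_ms, need),
            spec.regular_shift_ms
            + rng.lognormal(spec.regular_mu, spec.regular_sigma, need),
        )
        draws = np.round(draws)
        keep = draws >= spec.min_srt_ms  # hard lower truncation, by rejection
        k = int(keep.sum())
        out[filled : filled + k] = draws[keep]
        filled += k
    return out


def generate_species_srts(spec: GeneratorSpec, seed: int = 0) -> SRTSample:
    """Visually driven SRT sample for one species (no anticipatory trials)."""
    rng = np.random.default_rng(seed)
    values = _draw_visually_driven(spec, spec.n, rng)
    return SRTSample(values=values, species=spec.species)


def generate_landing_data(spec: GeneratorSpec, seed: int = 0) -> SRTSample:
    """SRT sample with correct/errant flags and landing x-coordinates.

    Trials toward a rightward target at ``target_eccentricity_deg``.
    Anticipatory trials (latency below the configured boundary) are errant
    with probability ``anticipatory_errant_prob``; visually driven trials
    are errant with the small probability ``visual_errant_prob``.  Errant
    saccades land with mirrored sign, so the boundary is recoverable from
    the correct-vs-errant counts.
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    is_anticipatory = rng.random(n) < spec.anticipatory_fraction
    n_ant = int(is_anticipatory.sum())

    values = np.empty(n)
    values[~is_anticipatory] = _draw_visually_driven(spec, n - n_ant, rng)
    values[is_anticipatory] = np.round(
        rng.uniform(spec.anticipatory_min_ms, spec.anticipatory_boundary_ms, n_ant)
    )

    errant = np.empty(n, dtype=bool)
    errant[is_anticipatory] = rng.random(n_ant) < spec.anticipatory_errant_prob
    errant[~is_anticipatory] = rng.random(n - n_ant) < spec.visual_errant_prob

    landing = np.where(
        errant, -spec.target_eccentricity_deg, spec.target_eccentricity_deg
    ) + rng.normal(0.0, spec.landing_noise_deg, n)
    return SRTSample(
        values=values,
        correct=~errant,
        landing_x_deg=landing,
        species=spec.species,
    )
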