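"""Controlled-variability parameter grids and per-trial sampling.

Trial-to-trial variability in the model is "controlled": every input
attribute (onset delay, rate of response, maximum strength) takes one of
a small ordered set of levels, drawn independently and uniformly per
trial.  The onset delays of the five internally driven inputs (4-8) are
drawn jointly — one value mirrored to all of them — so the level sets
multiply to the published combination counts (marmoset full grid
3^10 x 4^3 = 3,779,136; human full grid 3^13 = 1,594,323).

The level sets live in an editable packaged configuration file
(``configs/step_grids.yaml``); steps compose cumulatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

#: attribute name -> (input id, parameter kind, joint group)
ATTRIBUTE_META: Dict[str, Tuple[int, str, Optional[str]]] = {
    "vt_onset": (1, "onset", None),
    "vt_ror": (1, "ror", None),
    "vt_maxval": (1, "maxval", None),
    "am_onset": (2, "onset", None),
    "am_ror": (2, "ror", None),
    "am_maxval": (2, "maxval", None),
    "af_onset": (3, "onset", None),
    "af_ror": (3, "ror", None),
    "af_maxval": (3, "maxval", None),
    "internal_onset": (4, "onset", "internal_onset"),  # mirrored to inputs 4-8
    "vm_ror": (4, "ror", None),
    "vf_ror": (5, "ror", None),
    "vf_maxval": (5, "maxval", None),
    "vp_maxval": (6, "maxval", None),
    "ig_ror": (7, "ror", None),
    "ig_maxval": (7, "maxval", None),
    "pi_ror": (8, "ror", None),
    "pi_maxval": (8, "maxval", None),
}

SPECIES_STEPS = {"marmoset": (1, 2, 3), "human": (1, 2)}


@dataclass(frozen=True)
class LevelSet:
    """The admissible levels of one input attribute."""

    name: str
    input_id: int
    kind: str  # onset | ror | maxval
    values: Tuple[float, ...]
    joint_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"empty level set for {self.name}")
        vals = tuple(float(v) for v in self.values)
        if any(not np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite level in {self.name}")
        if list(vals) != sorted(set(vals)):
            raise ValueError(f"levels of {self.name} must be strictly increasing")
        if self.kind not in ("onset", "ror", "maxval"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")


@dataclass(frozen=True)
class StepConfig:
    """A species x step parameter grid: one LevelSet per attribute."""

    species: str
    step: int
    level_sets: Tuple[LevelSet, ...]

    def __post_init__(self) -> None:
        names = [ls.name for ls in self.level_sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate attribute in StepConfig")

    def level_set(self, name: str) -> LevelSet:
        for ls in self.level_sets:
            if ls.name == name:
                return ls
        raise KeyError(name)

    def level_counts(self) -> Dict[int, int]:
        """Histogram of level-set sizes (singleton attributes included)."""
        out: Dict[int, int] = {}
        for ls in self.level_sets:
            out[len(ls.values)] = out.get(len(ls.values), 0) + 1
        return out

    @property
    def config_id(self) -> str:
        return f"{self.species}-step{self.step}"


@dataclass(frozen=True)
class ParameterAssignment:
    """One sampled value per attribute for a single trial.

    The shared internal onset is stored once (attribute
    ``internal_onset``) and mirrored to inputs 4-8 when the trial inputs
    are built.
    """

    values: Dict[str, float] = field(default_factory=dict)
    species: Optional[str] = None
    step: Optional[int] = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    @property
    def internal_onset(self) -> float:
        return self.values["internal_onset"]

    def replace_value(self, name: str, value: float) -> "ParameterAssignment":
        new = dict(self.values)
        new[name] = float(value)
        return ParameterAssignment(values=new, species=self.species, step=self.step)


def enumerate_combination_count(config: StepConfig) -> int:
    """Size of the Cartesian product of the grid, one factor per joint group."""
    count = 1
    seen_groups = set()
    for ls in config.level_sets:
        if ls.joint_group is not None:
            if ls.joint_group in seen_groups:
                continue
            seen_groups.add(ls.joint_group)
        count *= len(ls.values)
    return count


def sample_trial_parameters(
    config: StepConfig, rng: np.random.Generator
) -> ParameterAssignment:
    """Draw one assignment: each attribute uniform over its levels.

    Attributes sharing a joint group receive one common draw.
    """
    values: Dict[str, float] = {}
    group_draw: Dict[str, float] = {}
    for ls in config.level_sets:
        if ls.joint_group is not None:
            if ls.joint_group not in group_draw:
                group_draw[ls.joint_group] = float(ls.values[int(rng.integers(len(ls.values)))])
            values[ls.name] = group_draw[ls.joint_group]
        else:
            values[ls.name] = float(ls.values[int(rng.integers(len(ls.values)))])
    return ParameterAssignment(values=values, species=config.species, step=config.step)


def _load_grid_file() -> dict:
    text = resources.files("sacfield.configs").joinpath("step_grids.yaml").read_text()
    return yaml.safe_load(text)


def config_from_levels(species: str, step: int, levels: Dict[str, list]) -> StepConfig:
    """Build a StepConfig from a flat attribute -> levels mapping."""
    level_sets = []
    for name, vals in levels.items():
        if name not in ATTRIBUTE_META:
            raise ValueError(f"unknown attribute {name!r}")
        input_id, kind, group = ATTRIBUTE_META[name]
        level_sets.append(
            LevelSet(name, input_id, kind, tuple(float(v) for v in vals), group)
        )
    missing = set(ATTRIBUTE_META) - set(levels)
    if missing:
        raise ValueError(f"grid missing attributes: {sorted(missing)}")
    return StepConfig(species=species, step=step, level_sets=tuple(level_sets))


def builtin_step_configs(species: str, step: int) -> StepConfig:
    """The shipped grid for a species/step, with cumulative step composition."""
    if species not in SPECIES_STEPS:
        raise ValueError(f"unknown species {species!r}")
    if step not in SPECIES_STEPS[species]:
        raise ValueError(f"unknown step {step} for {species}")
    raw = _load_grid_file()[species]
    levels: Dict[str, list] = {}
    for s in range(1, step + 1):
        levels.update(raw[f"step{s}"])
    return config_from_levels(species, step, levels)
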