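"""Parameter space, unit normalisation and the discrete experimentation grid.

Every parameter of the plugged-in model is normalised onto the unit
interval; the region of experimentation is a regular ``p``-level grid on
the resulting unit hypercube, and one-at-a-time perturbations of size
``delta`` (a whole number of grid steps) are applied from randomly
sampled grid points.  Base coordinates that would push a perturbation
outside the hypercube are resampled uniformly over the admissible levels
before the perturbation is applied, so perturbed points always remain on
the grid.

Physical units exist only at the two edges of the engine: when a
parameter table is read, and when a unit vector is denormalised for the
model adapter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "ParameterSpec",
    "ParameterSet",
    "ParameterVector",
    "GridConfig",
    "RangeError",
    "ConfigurationError",
    "normalize",
    "denormalize",
    "sample_grid_point",
    "constrain_for_perturbation",
]

CATEGORIES = frozenset(
    {"cardiac", "renal", "autoregulation", "hormonal", "local-circulation", "thirst", "other"}
)

_COLUMNS = ["name", "description", "unit", "low", "high", "default", "category"]


class RangeError(ValueError):
    """A physical value lies outside a parameter's [low, high] range."""


class ConfigurationError(ValueError):
    """An invalid grid / protocol configuration."""


@dataclass(frozen=True)
class ParameterSpec:
    """Metadata for one physiological parameter."""

    name: str
    description: str
    unit: str
    low: float
    high: float
    default: float
    category: str = "other"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("parameter name must be non-empty")
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high ({self.low} >= {self.high})")
        if not (self.low <= self.default <= self.high):
            raise ValueError(
                f"{self.name}: default {self.default} outside [{self.low}, {self.high}]"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")

    @property
    def span(self) -> float:
        return self.high - self.low


def normalize(value: float, spec: ParameterSpec) -> float:
    """Map a physical value into the unit interval."""
    if not (spec.low <= value <= spec.high):
        raise RangeError(
            f"value {value} for parameter {spec.name!r} outside [{spec.low}, {spec.high}]"
        )
    return (value - spec.low) / spec.span


def denormalize(coord: float, spec: ParameterSpec) -> float:
    """Map a unit-interval coordinate back to a physical value."""
    if not (-1e-12 <= coord <= 1 + 1e-12):
        raise RangeError(f"coordinate {coord} for parameter {spec.name!r} outside [0, 1]")
    return spec.low + coord * spec.span


class ParameterSet:
    """An ordered collection of uniquely named :class:`ParameterSpec`."""

    def __init__(self, specs: Iterable[ParameterSpec]):
        self._specs: dict[str, ParameterSpec] = {}
        for spec in specs:
            if spec.name in self._specs:
                raise ValueError(f"duplicate parameter name {spec.name!r}")
            self._specs[spec.name] = spec
        if not self._specs:
            raise ValueError("a ParameterSet needs at least one parameter")

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs.values())

    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._specs)

    def denormalize(self, x: "ParameterVector") -> dict[str, float]:
        """Physical parameter map for a unit vector (key sets must match)."""
        if set(x.values) != set(self._specs):
            missing = set(self._specs) - set(x.values)
            extra = set(x.values) - set(self._specs)
            raise KeyError(f"vector/parameter-set mismatch: missing={missing}, extra={extra}")
        return {name: denormalize(x[name], self._specs[name]) for name in self._specs}

    def normalize(self, physical: Mapping[str, float]) -> "ParameterVector":
        return ParameterVector(
            {name: normalize(physical[name], spec) for name, spec in self._specs.items()}
        )

    def defaults_vector(self) -> "ParameterVector":
        return ParameterVector(
            {name: normalize(spec.default, spec) for name, spec in self._specs.items()}
        )

    # -- delimited-table round trip ------------------------------------

    @classmethod
    def from_csv(cls, path) -> "ParameterSet":
        frame = pd.read_csv(path)
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"parameter table {path} lacks columns {missing}")
        specs = [
            ParameterSpec(
                name=str(row["name"]),
                description=str(row["description"]),
                unit=str(row["unit"]),
                low=float(row["low"]),
                high=float(row["high"]),
                default=float(row["default"]),
                category=str(row["category"]),
            )
            for _, row in frame.iterrows()
        ]
        return cls(specs)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "name": s.name,
                    "description": s.description,
                    "unit": s.unit,
                    "low": s.low,
                    "high": s.high,
                    "default": s.default,
                    "category": s.category,
                }
                for s in self
            ],
            columns=_COLUMNS,
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ParameterVector:
    """A point in the unit-normalised parameter space."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"coordinate {name}={v} outside [0, 1]")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)

    def replace(self, name: str, coord: float) -> "ParameterVector":
        if name not in self.values:
            raise KeyError(name)
        new = dict(self.values)
        new[name] = coord
        return ParameterVector(new)

    def shift(self, name: str, delta: float) -> "ParameterVector":
        """Perturb one coordinate by a signed amount, staying in [0, 1]."""
        return self.replace(name, self.values[name] + delta)


@dataclass(frozen=True)
class GridConfig:
    """The regular ``levels``-level grid and the perturbation step.

    ``delta`` is the perturbation magnitude as a fraction of the unit
    range and must be a positive whole number of grid steps
    ``1/(levels-1)``.
    """

    levels: int = 11
    delta: float = 0.1

    def __post_init__(self) -> None:
        if int(self.levels) != self.levels or self.levels < 2:
            raise ConfigurationError(f"levels must be an integer >= 2, got {self.levels}")
        # delta = 1 is admitted solely for the two-level grid, where one
        # step necessarily spans the whole unit range
        if not (0 < self.delta <= 1):
            raise ConfigurationError(f"delta must lie in (0, 1], got {self.delta}")
        steps = self.delta * (self.levels - 1)
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ConfigurationError(
                f"delta={self.delta} is not a positive multiple of 1/(levels-1)=1/{self.levels - 1}"
            )

    @property
    def step(self) -> float:
        return 1.0 / (self.levels - 1)

    @property
    def level_values(self) -> np.ndarray:
        return np.arange(self.levels) / (self.levels - 1)


def sample_grid_point(grid: GridConfig, names: Iterable[str], rng: np.random.Generator) -> ParameterVector:
    """Draw each coordinate independently and uniformly over the grid levels."""
    names = tuple(names)
    levels = rng.integers(0, grid.levels, size=len(names))
    denom = grid.levels - 1
    return ParameterVector({name: level / denom for name, level in zip(names, levels)})


def constrain_for_perturbation(
    x: ParameterVector,
    name: str,
    grid: GridConfig,
    direction: str,
    rng: np.random.Generator,
) -> ParameterVector:
    """Make coordinate ``name`` admissible for a +/- ``delta`` perturbation.

    For positive perturbations the base coordinate must satisfy
    ``x_i <= 1 - delta`` and for negative ones ``x_i >= delta`` so the
    perturbed point stays inside the unit hypercube.  An inadmissible
    coordinate is resampled uniformly over the admissible grid levels;
    all other coordinates are untouched.
    """
    if direction not in ("+", "-"):
        raise ValueError(f"direction must be '+' or '-', got {direction!r}")
    tol = 1e-9
    levels = grid.level_values
    if direction == "+":
        admissible = levels[levels <= 1.0 - grid.delta + tol]
    else:
        admissible = levels[levels >= grid.delta - tol]
    if admissible.size == 0:
        raise ConfigurationError(
            f"no admissible grid level for a {direction}{grid.delta} perturbation"
        )
    coord = x[name]
    lo, hi = admissible.min() - tol, admissible.max() + tol
    if lo <= coord <= hi:
        return x
    return x.replace(name, float(rng.choice(admissible)))
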