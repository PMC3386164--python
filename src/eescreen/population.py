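"""Virtual individuals, hypertension stratification and MAP densities.

A virtual individual is one parameter vector ("genotype", stored on the
physical scale) together with the steady-state outputs it produced
("phenotype").  Each accepted screening simulation contributes two:
the pre-perturbation and post-perturbation steady states.

Hypertension is defined on mean arterial pressure via the usual cuff
estimate MAP = DBP + (SBP - DBP)/3 applied to a stage-1 threshold of
140/90 mmHg, i.e. MAP >= 106.67 mmHg (boundary inclusive on the
hypertensive side); the 160/95 variant of the definition is a
configuration away.  MAP densities across a population are summarised
by maximum-likelihood gamma fits, with the chi-squared family handled
as the gamma sub-family whose scale is fixed at 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Population",
    "StratificationConfig",
    "DensityFit",
    "FitError",
    "map_from_cuff",
    "stratify",
    "fit_map_density",
    "load_dryad",
]

logger = logging.getLogger(__name__)

_CORE_COLUMNS = ["id", "phase", "perturbed_param", "direction", "alive"]


class FitError(ValueError):
    """A degenerate sample that cannot support a density fit."""


class Population:
    """A table of virtual individuals.

    Columns: ``id, phase, perturbed_param, direction, alive`` plus one
    ``param:<NAME>`` column per genotype parameter (physical scale) and
    one ``var:<NAME>`` column per phenotype output.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _CORE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"population frame lacks columns {missing}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(c[len("param:"):] for c in self.frame.columns if c.startswith("param:"))

    @property
    def var_names(self) -> tuple[str, ...]:
        return tuple(c[len("var:"):] for c in self.frame.columns if c.startswith("var:"))

    def params(self) -> pd.DataFrame:
        """Genotypes (physical scale), indexed by individual id."""
        cols = [c for c in self.frame.columns if c.startswith("param:")]
        out = self.frame.set_index("id")[cols]
        out.columns = [c[len("param:"):] for c in cols]
        return out

    def vars(self) -> pd.DataFrame:
        """Phenotypes, indexed by individual id."""
        cols = [c for c in self.frame.columns if c.startswith("var:")]
        out = self.frame.set_index("id")[cols]
        out.columns = [c[len("var:"):] for c in cols]
        return out

    def alive_only(self) -> "Population":
        return Population(self.frame[self.frame["alive"].astype(bool)])

    def select_phases(self, phases: Iterable[str]) -> "Population":
        phases = tuple(phases)
        return Population(self.frame[self.frame["phase"].isin(phases)])

    def map_values(self) -> pd.Series:
        if "var:MAP" not in self.frame.columns:
            raise KeyError("population has no var:MAP column")
        return self.frame.set_index("id")["var:MAP"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Population":
        frame = pd.read_csv(path)
        # the two free-text columns round-trip empty strings as NaN
        for col in ("perturbed_param", "direction"):
            if col in frame.columns:
                frame[col] = frame[col].fillna("")
        return cls(frame)

    @classmethod
    def concat(cls, pops: Sequence["Population"]) -> "Population":
        return cls(pd.concat([p.frame for p in pops], ignore_index=True))


def map_from_cuff(sbp: float, dbp: float) -> float:
    """Mean arterial pressure estimated from cuff readings.

    The standard one-third pulse-pressure formula DBP + (SBP - DBP)/3.
    """
    if not dbp > 0:
        raise ValueError(f"diastolic pressure must be positive, got {dbp}")
    if sbp < dbp:
        raise ValueError(f"systolic {sbp} below diastolic {dbp}")
    return dbp + (sbp - dbp) / 3.0


@dataclass(frozen=True)
class StratificationConfig:
    """Hypertension definition in cuff terms.

    The MAP threshold is always derived from the systolic/diastolic pair
    unless ``map_override`` is set explicitly.
    """

    sbp_threshold: float = 140.0
    dbp_threshold: float = 90.0
    map_override: float | None = None

    @property
    def map_threshold(self) -> float:
        if self.map_override is not None:
            return self.map_override
        return map_from_cuff(self.sbp_threshold, self.dbp_threshold)


def stratify(
    pop: Population, cfg: StratificationConfig | None = None
) -> tuple[Population, Population]:
    """Split a population into (normotensive, hypertensive) subsets.

    Hypertensive iff MAP >= the derived threshold; the two subsets
    partition the alive individuals with a recorded MAP.  Individuals
    with a missing MAP are rejected (logged).
    """
    if cfg is None:
        cfg = StratificationConfig()
    frame = pop.alive_only().frame
    if "var:MAP" not in frame.columns:
        raise KeyError("population has no var:MAP column")
    missing = frame["var:MAP"].isna()
    if missing.any():
        logger.warning("rejecting %d individuals with missing MAP", int(missing.sum()))
        frame = frame[~missing]
    hyper_mask = frame["var:MAP"] >= cfg.map_threshold
    return Population(frame[~hyper_mask]), Population(frame[hyper_mask])


@dataclass(frozen=True)
class DensityFit:
    """A maximum-likelihood gamma-family fit of a MAP sample."""

    family: str  # "gamma" | "chi-squared"
    shape: float
    scale: float
    loglik: float

    @property
    def df(self) -> float:
        """Chi-squared degrees of freedom equivalent (2 * shape)."""
        return 2.0 * self.shape


def fit_map_density(values, family: str = "gamma") -> DensityFit:
    """Fit a gamma or chi-squared density to positive MAP values.

    The chi-squared family is fitted as the gamma sub-family with the
    scale pinned at 2 (a chi-squared with 2*shape degrees of freedom),
    so the unconstrained gamma log-likelihood always dominates the
    chi-squared one on the same sample.  Location is fixed at zero in
    both families.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 100:
        raise FitError(f"need at least 100 values, got {vals.size}")
    if np.any(vals <= 0):
        raise FitError("all values must be strictly positive")
    if np.ptp(vals) == 0:
        raise FitError("degenerate (constant) sample")
    if family == "gamma":
        shape, _loc, scale = stats.gamma.fit(vals, floc=0)
    elif family == "chi-squared":
        shape, _loc, scale = stats.gamma.fit(vals, floc=0, fscale=2)
    else:
        raise ValueError(f"unknown family {family!r}")
    loglik = float(np.sum(stats.gamma.logpdf(vals, shape, loc=0, scale=scale)))
    return DensityFit(family=family, shape=float(shape), scale=float(scale), loglik=loglik)


def load_dryad(path, mapping: Mapping) -> Population:
    """Load a deposited population table into a :class:`Population`.

    The deposited archive's schema is not fixed, so the column mapping
    is configuration-driven::

        mapping = {
            "sep": ",",             # optional, default inferred
            "id": "sim_id",         # optional; row number when absent
            "phase": "phase",       # optional; "pre" when absent
            "alive": "alive",       # optional; True when absent
            "perturbed_param": ..., # optional
            "direction": ...,       # optional
            "params": {"AARK": "aark_col", ...},
            "vars": {"MAP": "map_col", ...},
        }

    ``params``/``vars`` map engine names to source column names.
    """
    sep = mapping.get("sep")
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    out = pd.DataFrame()
    out["id"] = (
        frame[mapping["id"]].astype(str) if "id" in mapping else frame.index.astype(str)
    )
    out["phase"] = frame[mapping["phase"]] if "phase" in mapping else "pre"
    out["perturbed_param"] = (
        frame[mapping["perturbed_param"]] if "perturbed_param" in mapping else ""
    )
    out["direction"] = frame[mapping["direction"]] if "direction" in mapping else ""
    out["alive"] = frame[mapping["alive"]].astype(bool) if "alive" in mapping else True
    for name, col in mapping.get("params", {}).items():
        out[f"param:{name}"] = pd.to_numeric(frame[col])
    for name, col in mapping.get("vars", {}).items():
        out[f"var:{name}"] = pd.to_numeric(frame[col])
    return Population(out)
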