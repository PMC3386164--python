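"""Two-phase steady-state protocol and elementary-effect computation.

One screening repeat works as follows.  A base point is sampled on the
experimentation grid (with the coordinate under study constrained so the
later perturbation stays inside the unit hypercube) and the model is
integrated from its default initial state for one phase (four simulated
weeks by default).  The run is *accepted* only if every monitored output
stayed inside the survival ("aliveness") bounds throughout and every
recorded output changed by less than ``steady_tol`` (relative) over the
final simulated day; otherwise the base point is discarded and
resampled.  The studied parameter is then shifted by +/- delta and the
integration continues for a second phase, with all outputs recorded at a
ladder of offsets after the perturbation (1 min, 1 h, 24 h, 1 week,
4 weeks by default) and the same survival/steady rules applied at phase
end.

The elementary effect of parameter i on output v at offset t is the
post-perturbation change normalised by the pre-perturbation steady
value,

    d_i = s * (v(t) - v_base) / |v_base|,

with s = +1 for increments and s = -1 for decrements, so both
directions estimate the same derivative-like quantity and can be pooled.
Across repeats (each from a fresh random base point) the sample mean of
d_i measures the sensitivity of v to i, while the sample deviation
measures how strongly the other parameters (or non-linearity) modulate
that effect.

Every accepted repeat contributes two virtual individuals — the pre- and
post-perturbation steady states — so a campaign of r repeats per
direction over k parameters yields 2*k*r accepted simulations and
4*k*r individuals.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ModelAdapter, SimResult
from .param_space import (
    ConfigurationError,
    GridConfig,
    ParameterSet,
    ParameterVector,
    constrain_for_perturbation,
    sample_grid_point,
)

__all__ = [
    "AlivenessBounds",
    "ProtocolConfig",
    "Discard",
    "SteadyRecord",
    "PerturbedRecord",
    "EETable",
    "CampaignResult",
    "CampaignError",
    "check_alive",
    "run_to_steady",
    "run_perturbed",
    "elementary_effect",
    "aggregate",
    "run_campaign",
]

logger = logging.getLogger(__name__)

#: variables already reported as absent from a model, to log only once
_warned_missing: set[str] = set()

MINUTES_PER_DAY = 1440.0
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY


class CampaignError(RuntimeError):
    """Raised when a repeat exhausts its restart budget."""


class AlivenessBounds:
    """Inclusive physiological survival ranges, one per monitored variable.

    The default table: GFR >= 0.015 L/min; serum sodium (CNA) in
    [120, 160] mEq/L; serum potassium (CKE) in [2.5, 8] mEq/L;
    hematocrit (HM) in [24, 80]; MAP in [50, 200] mmHg; heart rate in
    [20, 200] /min.  Variables a model does not expose are skipped.
    """

    def __init__(self, bounds: Mapping[str, tuple[float | None, float | None, str]]):
        self._bounds: dict[str, tuple[float | None, float | None, str]] = {}
        for var, (lo, hi, unit) in bounds.items():
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"{var}: min {lo} must be < max {hi}")
            if lo is None and hi is None:
                raise ValueError(f"{var}: at least one of min/max must be set")
            self._bounds[var] = (lo, hi, unit)

    @classmethod
    def default(cls) -> "AlivenessBounds":
        return cls(
            {
                "GFR": (0.015, None, "L/min"),
                "CNA": (120.0, 160.0, "mEq/L"),
                "CKE": (2.5, 8.0, "mEq/L"),
                "HM": (24.0, 80.0, ""),
                "MAP": (50.0, 200.0, "mmHg"),
                "HR": (20.0, 200.0, "1/min"),
            }
        )

    def __iter__(self):
        return iter(self._bounds.items())

    def __contains__(self, var: str) -> bool:
        return var in self._bounds

    def __len__(self) -> int:
        return len(self._bounds)

    def limits(self) -> dict[str, tuple[float | None, float | None]]:
        """Bounds without units, for handing to model adapters."""
        return {var: (lo, hi) for var, (lo, hi, _u) in self._bounds.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"variable": var, "min": lo, "max": hi, "unit": unit}
                for var, (lo, hi, unit) in self._bounds.items()
            ]
        )


@dataclass(frozen=True)
class ProtocolConfig:
    """Settings of the two-phase steady-state protocol.

    ``phase_duration`` and ``record_times`` are in simulated minutes;
    ``steady_tol`` is the maximum relative change of any recorded output
    over the final simulated day for a phase to count as pseudo-steady.
    """

    phase_duration: float = 4 * MINUTES_PER_WEEK  # 40,320 min
    record_times: tuple[float, ...] = (1.0, 60.0, MINUTES_PER_DAY, MINUTES_PER_WEEK, 4 * MINUTES_PER_WEEK)
    repeats_per_direction: int = 1000
    max_restarts: int = 100
    steady_tol: float = 1e-4
    rtol: float = 1e-8
    guard_eps: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.record_times, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise ConfigurationError("record_times must be strictly increasing and non-empty")
        if times[-1] > self.phase_duration + 1e-9:
            raise ConfigurationError(
                f"largest record time {times[-1]} exceeds phase_duration {self.phase_duration}"
            )
        if self.phase_duration <= MINUTES_PER_DAY:
            raise ConfigurationError("phase_duration must exceed one simulated day")


@dataclass(frozen=True)
class Discard:
    """Signal that a simulation attempt must be thrown away."""

    reason: str  # "bound_violated" | "not_steady" | "integration_failure"
    detail: str = ""

    @property
    def key(self) -> str:
        return f"{self.reason}:{self.detail}" if self.detail else self.reason


@dataclass
class SteadyRecord:
    """An accepted pre-perturbation steady state."""

    genotype: ParameterVector
    params: dict[str, float]
    state: object
    outputs: dict[str, float]
    pset: ParameterSet


@dataclass
class PerturbedRecord:
    """An accepted post-perturbation run with its record-time snapshots."""

    genotype: ParameterVector
    params: dict[str, float]
    state: object
    snapshots: dict[float, dict[str, float]]
    outputs: dict[str, float]  # phase-end steady outputs


def check_alive(
    snapshot: Mapping[str, float], bounds: AlivenessBounds
) -> tuple[bool, str | None]:
    """Inclusive bound check on one output snapshot.

    Returns ``(True, None)`` when every bounded variable present in the
    snapshot lies within its range, else ``(False, first violated)``.
    Bounded variables absent from the snapshot are skipped (logged once).
    """
    for var, (lo, hi, _unit) in bounds:
        if var not in snapshot:
            if var not in _warned_missing:
                _warned_missing.add(var)
                logger.info("aliveness variable %s not exposed by the model; skipped", var)
            continue
        v = snapshot[var]
        if lo is not None and v < lo:
            return False, var
        if hi is not None and v > hi:
            return False, var
    return True, None


def _phase_checks(
    result: SimResult, cfg: ProtocolConfig, bounds: AlivenessBounds
) -> Discard | None:
    """Shared survival + pseudo-steady validation of one integrated phase."""
    if result.status == "integration_failure":
        return Discard("integration_failure", result.message)
    if result.status == "bound_violated":
        return Discard("bound_violated", result.violated or "")
    # re-check the recorded snapshots even when the adapter enforces bounds
    for i in range(result.times.size):
        snap = {name: float(traj[i]) for name, traj in result.outputs.items()}
        ok, violated = check_alive(snap, bounds)
        if not ok:
            return Discard("bound_violated", violated or "")
    start = result.at(cfg.phase_duration - MINUTES_PER_DAY)
    end = result.at(cfg.phase_duration)
    for name, v_end in end.items():
        scale = max(abs(v_end), cfg.guard_eps)
        if abs(v_end - start[name]) / scale >= cfg.steady_tol:
            return Discard("not_steady", name)
    return None


def run_to_steady(
    model: ModelAdapter,
    x: ParameterVector,
    pset: ParameterSet,
    cfg: ProtocolConfig,
    bounds: AlivenessBounds,
) -> SteadyRecord | Discard:
    """Settle the model from its default initial state at base point ``x``.

    Parameters absent from ``pset`` keep the model's defaults.  Returns a
    :class:`SteadyRecord` on success, else a :class:`Discard` whose
    reason the caller should count before resampling ``x``.
    """
    params = pset.denormalize(x)
    t_checks = (cfg.phase_duration - MINUTES_PER_DAY, cfg.phase_duration)
    result = model.simulate(
        params,
        model.default_state(),
        cfg.phase_duration,
        t_checks,
        bounds=bounds.limits(),
        rtol=cfg.rtol,
    )
    problem = _phase_checks(result, cfg, bounds)
    if problem is not None:
        return problem
    return SteadyRecord(
        genotype=x,
        params=params,
        state=result.final_state,
        outputs=result.at(cfg.phase_duration),
        pset=pset,
    )


def run_perturbed(
    model: ModelAdapter,
    steady: SteadyRecord,
    name: str,
    delta: float,
    direction: str,
    cfg: ProtocolConfig,
    bounds: AlivenessBounds,
) -> PerturbedRecord | Discard:
    """Continue from a steady state with coordinate ``name`` shifted by delta.

    Outputs are recorded at every configured offset after the
    perturbation; the same survival and pseudo-steady rules as in the
    settling phase apply at phase end.
    """
    if direction not in ("+", "-"):
        raise ValueError(f"direction must be '+' or '-', got {direction!r}")
    signed = delta if direction == "+" else -delta
    x2 = steady.genotype.shift(name, signed)
    params2 = steady.pset.denormalize(x2)
    t_eval = sorted(
        set(cfg.record_times) | {cfg.phase_duration - MINUTES_PER_DAY, cfg.phase_duration}
    )
    result = model.simulate(
        params2, steady.state, cfg.phase_duration, t_eval, bounds=bounds.limits(), rtol=cfg.rtol
    )
    problem = _phase_checks(result, cfg, bounds)
    if problem is not None:
        return problem
    return PerturbedRecord(
        genotype=x2,
        params=params2,
        state=result.final_state,
        snapshots={t: result.at(t) for t in cfg.record_times},
        outputs=result.at(cfg.phase_duration),
    )


def elementary_effect(
    base_value: float, perturbed_value: float, direction: str, eps: float = 1e-12
) -> float | None:
    """Output-normalised elementary effect of one perturbation.

    Returns ``s * (perturbed - base) / |base|`` with s = +1 for "+" and
    -1 for "-", or ``None`` when ``|base| <= eps`` (the sample is flagged
    missing rather than zeroed).
    """
    if direction not in ("+", "-"):
        raise ValueError(f"direction must be '+' or '-', got {direction!r}")
    if abs(base_value) <= eps:
        return None
    s = 1.0 if direction == "+" else -1.0
    return s * (perturbed_value - base_value) / abs(base_value)


#: column order of the tidy elementary-effect sample table
SAMPLE_COLUMNS = [
    "parameter",
    "output",
    "time_min",
    "direction",
    "sample_id",
    "ee",
    "base_value",
    "value",
    "status",
    "pre_id",
    "post_id",
]


class EETable:
    """Aggregated elementary effects: mean, SD and counts per group.

    Wraps a data frame indexed by (parameter, output, time_min) with
    columns ``mean, sd, n`` plus the per-direction breakdown
    ``mean_pos, n_pos, mean_neg, n_neg``.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def get(self, parameter: str, output: str, time_min: float) -> pd.Series:
        return self.frame.loc[(parameter, output, time_min)]

    def mean_effects(self, output: str, time_min: float) -> pd.Series:
        """Mean elementary effect per parameter for one output and time."""
        sub = self.frame.xs((output, time_min), level=("output", "time_min"))
        return sub["mean"]

    def to_csv(self, path) -> None:
        self.frame.reset_index().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EETable":
        frame = pd.read_csv(path).set_index(["parameter", "output", "time_min"])
        return cls(frame)


def aggregate(samples: pd.DataFrame) -> EETable:
    """Aggregate elementary-effect samples by (parameter, output, time).

    Samples whose status is not ``"ok"`` (division-guarded base values)
    are excluded.  Groups with fewer than two valid samples report the
    sample SD as missing.
    """
    valid = samples[samples["status"] == "ok"]

    def _agg(group: pd.DataFrame) -> pd.Series:
        ee = group["ee"].to_numpy(dtype=float)
        pos = group.loc[group["direction"] == "+", "ee"].to_numpy(dtype=float)
        neg = group.loc[group["direction"] == "-", "ee"].to_numpy(dtype=float)
        return pd.Series(
            {
                "mean": ee.mean() if ee.size else np.nan,
                "sd": ee.std(ddof=1) if ee.size >= 2 else np.nan,
                "n": ee.size,
                "mean_pos": pos.mean() if pos.size else np.nan,
                "n_pos": pos.size,
                "mean_neg": neg.mean() if neg.size else np.nan,
                "n_neg": neg.size,
            }
        )

    grouped = valid.groupby(["parameter", "output", "time_min"]).apply(_agg, include_groups=False)
    grouped["n"] = grouped["n"].astype(int)
    grouped["n_pos"] = grouped["n_pos"].astype(int)
    grouped["n_neg"] = grouped["n_neg"].astype(int)
    return EETable(grouped)


@dataclass
class CampaignResult:
    """Everything one screening campaign produces."""

    ee_table: EETable
    samples: pd.DataFrame
    population: "Population"  # noqa: F821 - populated by eescreen.population
    discards: Counter
    seed: int


def run_campaign(
    model: ModelAdapter,
    pset: ParameterSet,
    grid: GridConfig,
    cfg: ProtocolConfig,
    bounds: AlivenessBounds | None = None,
    parameters: Sequence[str] | None = None,
) -> CampaignResult:
    """Run the full one-at-a-time screening campaign.

    For every parameter and both perturbation directions,
    ``cfg.repeats_per_direction`` accepted repeats are collected, each
    from an independently sampled base point; discarded attempts are
    resampled (up to ``cfg.max_restarts`` per repeat, then
    :class:`CampaignError`).  The run is fully reproducible from
    ``cfg.seed``: every (parameter, direction, repeat) slot draws from
    its own deterministically spawned random stream, so results do not
    depend on execution order.
    """
    from .population import Population  # deferred: population imports nothing from here

    if bounds is None:
        bounds = AlivenessBounds.default()
    names = tuple(parameters) if parameters is not None else pset.names
    unknown = [n for n in names if n not in pset]
    if unknown:
        raise KeyError(f"parameters not in the parameter set: {unknown}")

    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(2 * len(names))
    discards: Counter = Counter()
    sample_rows: list[dict] = []
    individual_rows: list[dict] = []

    for pi, pname in enumerate(names):
        for di, direction in enumerate(("+", "-")):
            repeat_streams = streams[2 * pi + di].spawn(cfg.repeats_per_direction)
            for rep in range(cfg.repeats_per_direction):
                rng = np.random.default_rng(repeat_streams[rep])
                steady, perturbed = _accepted_repeat(
                    model, pset, grid, cfg, bounds, pname, direction, rng, discards
                )
                sim_id = f"{pname}:{direction}:{rep}"
                pre_id, post_id = f"{sim_id}:pre", f"{sim_id}:post"
                individual_rows.append(
                    _individual_row(pre_id, "pre", None, None, steady.params, steady.outputs)
                )
                individual_rows.append(
                    _individual_row(
                        post_id, "post", pname, direction, perturbed.params, perturbed.outputs
                    )
                )
                for t in cfg.record_times:
                    snap = perturbed.snapshots[t]
                    for output, base in steady.outputs.items():
                        ee = elementary_effect(base, snap[output], direction, cfg.guard_eps)
                        sample_rows.append(
                            {
                                "parameter": pname,
                                "output": output,
                                "time_min": t,
                                "direction": direction,
                                "sample_id": sim_id,
                                "ee": np.nan if ee is None else ee,
                                "base_value": base,
                                "value": snap[output],
                                "status": "ok" if ee is not None else "guarded",
                                "pre_id": pre_id,
                                "post_id": post_id,
                            }
                        )

    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    population = Population(pd.DataFrame(individual_rows))
    logger.info(
        "campaign done: %d accepted simulations, %d discards (%s)",
        2 * len(names) * cfg.repeats_per_direction,
        sum(discards.values()),
        dict(discards),
    )
    return CampaignResult(
        ee_table=aggregate(samples),
        samples=samples,
        population=population,
        discards=discards,
        seed=cfg.seed,
    )


def _accepted_repeat(
    model: ModelAdapter,
    pset: ParameterSet,
    grid: GridConfig,
    cfg: ProtocolConfig,
    bounds: AlivenessBounds,
    pname: str,
    direction: str,
    rng: np.random.Generator,
    discards: Counter,
) -> tuple[SteadyRecord, PerturbedRecord]:
    """Resample until one base point survives both phases."""
    for _attempt in range(cfg.max_restarts + 1):
        x = sample_grid_point(grid, pset.names, rng)
        x = constrain_for_perturbation(x, pname, grid, direction, rng)
        steady = run_to_steady(model, x, pset, cfg, bounds)
        if isinstance(steady, Discard):
            discards[f"pre:{steady.key}"] += 1
            continue
        perturbed = run_perturbed(model, steady, pname, grid.delta, direction, cfg, bounds)
        if isinstance(perturbed, Discard):
            discards[f"post:{perturbed.key}"] += 1
            continue
        return steady, perturbed
    raise CampaignError(
        f"exceeded {cfg.max_restarts} restarts for parameter {pname!r} direction {direction!r}"
    )


def _individual_row(
    ind_id: str,
    phase: str,
    perturbed_param: str | None,
    direction: str | None,
    params: Mapping[str, float],
    outputs: Mapping[str, float],
) -> dict:
    row = {
        "id": ind_id,
        "phase": phase,
        "perturbed_param": perturbed_param if perturbed_param is not None else "",
        "direction": direction if direction is not None else "",
        "alive": True,
    }
    row.update({f"param:{k}": v for k, v in params.items()})
    row.update({f"var:{k}": v for k, v in outputs.items()})
    return row
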