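"""Reduced pressure-natriuresis model with a closed-form steady state.

A deliberately small Guyton-style model of long-term arterial-pressure
regulation, bundled as the test fixture and analytic oracle for the
screening pipeline.  Three states:

``VB``   blood volume (L)
``TPR``  total peripheral resistance (mmHg.min/L)
``NA``   extracellular sodium mass (mEq)

with the algebraic layer::

    CO  = max(0, c * (VB - VB0))          cardiac output (L/min)
    MAP = CO * TPR                        mean arterial pressure (mmHg)
    UO  = UO_b + k_r * max(0, MAP - P_set)   urine output (L/min)
    CNA = NA / VB                         serum sodium (mEq/L)

and the dynamics::

    dVB/dt  = W_in - UO
    dTPR/dt = (TPR0 * (CO/CO_ref)**g - TPR) / tau
    dNA/dt  = NID_d - CNA * UO

The renal function curve ``UO(MAP)`` gives the kidney infinite gain over
long-term pressure: at steady state ``UO = W_in`` forces

    MAP* = P_set + (W_in - UO_b) / k_r

independently of every vascular parameter (TPR0, c, VB0, CO_ref, tau).
Those parameters therefore have transient-but-not-permanent effects on
MAP — exactly the multi-timescale signature the screening engine must
resolve.  Serum sodium settles at ``CNA* = NID_d / W_in``, so the
survival bound on CNA kills a predictable slice of parameter space, and
the spread of ``MAP*`` across the sampled ranges yields both
normotensive and hypertensive virtual individuals.

The autoregulation time constant ``tau`` is chosen so that the transient
leak of a resistance perturbation into MAP is clearly visible at the
one-hour record time and fully renally compensated by four weeks: the
MAP-restoring renal time constant is ``1/(k_r*c*TPR)`` (about 50 min at
defaults), and the peak leak scales like that constant divided by
``tau``.

Exposed outputs: ``MAP``, ``QAO`` (:= CO), ``VUD`` (:= UO), ``CNA``,
``VB``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import BOUND_VIOLATED, INTEGRATION_FAILURE, OK, ModelAdapter, SimResult
from .param_space import ParameterSet

__all__ = [
    "DemoParams",
    "DemoModel",
    "closed_form_steady",
    "demo_parameter_set",
    "CAMPAIGN_PARAMS",
]

#: the nine parameters exercised by screening campaigns (UO_b and g stay fixed:
#: their defaults, 0 and 1, do not admit the +/-50% campaign range)
CAMPAIGN_PARAMS = ("k_r", "P_set", "W_in", "c", "VB0", "TPR0", "CO_ref", "tau", "NID_d")


@dataclass(frozen=True)
class DemoParams:
    """Physical parameters of the demo model (units in the field docs)."""

    k_r: float = 0.00025  # renal function-curve slope (L/min/mmHg)
    P_set: float = 96.0  # renal set-point pressure (mmHg)
    W_in: float = 0.001  # water intake (L/min)
    UO_b: float = 0.0  # basal urine output (L/min)
    c: float = 4.0  # cardiac-output volume gain (1/min)
    VB0: float = 3.75  # unstressed blood volume (L)
    TPR0: float = 20.0  # basal total peripheral resistance (mmHg.min/L)
    CO_ref: float = 5.0  # reference cardiac output (L/min)
    g: float = 1.0  # autoregulation exponent (dimensionless)
    tau: float = 400.0  # autoregulation time constant (min)
    NID_d: float = 0.14  # sodium intake (mEq/min)

    @classmethod
    def from_mapping(cls, params: Mapping[str, float]) -> "DemoParams":
        return replace(cls(), **dict(params))


def closed_form_steady(params: DemoParams | Mapping[str, float]) -> dict[str, float]:
    """Analytic steady state of the demo model.

    Requires a strictly positive renal slope and a net positive fluid
    intake; the steady state is the unique fixed point of the dynamics
    with ``CO > 0``.
    """
    p = params if isinstance(params, DemoParams) else DemoParams.from_mapping(params)
    if p.k_r <= 0:
        raise ValueError(f"k_r must be > 0, got {p.k_r}")
    if p.W_in <= p.UO_b:
        raise ValueError(f"need W_in > UO_b, got W_in={p.W_in}, UO_b={p.UO_b}")
    map_star = p.P_set + (p.W_in - p.UO_b) / p.k_r
    co_star = (map_star * p.CO_ref**p.g / p.TPR0) ** (1.0 / (1.0 + p.g))
    tpr_star = map_star / co_star
    vb_star = p.VB0 + co_star / p.c
    cna_star = p.NID_d / p.W_in
    return {
        "MAP": map_star,
        "QAO": co_star,
        "VUD": p.W_in,
        "CNA": cna_star,
        "VB": vb_star,
        "TPR": tpr_star,
        "NA": cna_star * vb_star,
    }


def _outputs(y: np.ndarray, p: DemoParams) -> dict[str, np.ndarray]:
    vb, tpr, na = y
    co = np.maximum(0.0, p.c * (vb - p.VB0))
    mean_ap = co * tpr
    uo = p.UO_b + p.k_r * np.maximum(0.0, mean_ap - p.P_set)
    cna = na / vb
    return {"MAP": mean_ap, "QAO": co, "VUD": uo, "CNA": cna, "VB": vb}


class DemoModel(ModelAdapter):
    """Adapter exposing the demo model to the screening engine."""

    name = "demo-pn"

    #: default initial state, deliberately off-steady so the four-week
    #: settling phase does real work: (VB, TPR, NA)
    DEFAULT_STATE = (5.2, 19.0, 700.0)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(DemoParams.__dataclass_fields__)

    @property
    def output_names(self) -> tuple[str, ...]:
        return ("MAP", "QAO", "VUD", "CNA", "VB")

    def default_state(self) -> tuple[float, float, float]:
        return self.DEFAULT_STATE

    def outputs_at_state(self, state, params: Mapping[str, float]) -> dict[str, float]:
        p = DemoParams.from_mapping(params)
        return {k: float(v) for k, v in _outputs(np.asarray(state, float), p).items()}

    def _rhs(self, t, y, p: DemoParams):
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite state {y} at t={t}")
        vb, tpr, na = y
        co = max(0.0, p.c * (vb - p.VB0))
        mean_ap = co * tpr
        uo = p.UO_b + p.k_r * max(0.0, mean_ap - p.P_set)
        dvb = p.W_in - uo
        dtpr = (p.TPR0 * (co / p.CO_ref) ** p.g - tpr) / p.tau
        dna = p.NID_d - (na / vb) * uo
        return (dvb, dtpr, dna)

    def simulate(
        self,
        params: Mapping[str, float],
        state,
        duration: float,
        record_times: Sequence[float],
        bounds: Mapping[str, tuple[float | None, float | None]] | None = None,
        rtol: float = 1e-8,
    ) -> SimResult:
        p = DemoParams.from_mapping(params)
        y0 = np.asarray(state, dtype=float)
        t_eval = np.unique(np.clip(np.asarray(record_times, dtype=float), 0.0, duration))

        # survival bounds become terminal root-finding events so dead
        # trajectories stop at the moment of violation
        events = []
        event_names = []
        if bounds:
            margin = 1e-9
            for var, (lo, hi) in bounds.items():
                if var not in self.output_names:
                    continue
                if lo is not None:
                    events.append(_bound_event(var, lo - margin, +1, p))
                    event_names.append(var)
                if hi is not None:
                    events.append(_bound_event(var, hi + margin, -1, p))
                    event_names.append(var)
            # an initially dead state never produces a sign change
            snap = self.outputs_at_state(y0, params)
            for var, (lo, hi) in bounds.items():
                if var not in snap:
                    continue
                if (lo is not None and snap[var] < lo) or (hi is not None and snap[var] > hi):
                    return SimResult(
                        status=BOUND_VIOLATED,
                        times=np.array([0.0]),
                        outputs={k: np.array([v]) for k, v in snap.items()},
                        final_state=tuple(y0),
                        violated=var,
                        message=f"{var}={snap[var]:.6g} outside bounds at start",
                    )

        try:
            sol = solve_ivp(
                self._rhs,
                (0.0, float(duration)),
                y0,
                method="LSODA",
                t_eval=t_eval,
                events=events or None,
                args=(p,),
                rtol=rtol,
                atol=(1e-9, 1e-8, 1e-6),
            )
        except FloatingPointError as exc:
            return SimResult(
                status=INTEGRATION_FAILURE,
                times=np.array([]),
                outputs={},
                final_state=tuple(y0),
                message=str(exc),
            )
        sol_t = np.atleast_1d(np.asarray(sol.t, dtype=float))
        sol_y = np.asarray(sol.y, dtype=float)
        if sol_y.size:
            outputs = {k: np.atleast_1d(v) for k, v in _outputs(sol_y, p).items()}
            final = tuple(sol_y[:, -1])
        else:
            outputs = {k: np.array([]) for k in self.output_names}
            final = tuple(y0)
        if sol.status < 0:
            return SimResult(
                status=INTEGRATION_FAILURE,
                times=sol_t,
                outputs=outputs,
                final_state=final,
                message=sol.message,
            )
        if sol.status == 1:  # a survival bound was crossed
            hit = [i for i, ev in enumerate(sol.t_events) if ev.size > 0]
            violated = event_names[hit[0]] if hit else None
            t_hit = float(sol.t_events[hit[0]][0]) if hit else float("nan")
            return SimResult(
                status=BOUND_VIOLATED,
                times=sol_t,
                outputs=outputs,
                final_state=final,
                violated=violated,
                message=f"bound on {violated} crossed at t={t_hit:.1f} min",
            )
        return SimResult(
            status=OK,
            times=sol_t,
            outputs=outputs,
            final_state=final,
        )


def _bound_event(var: str, limit: float, sign: int, p: DemoParams):
    """Terminal event crossing zero when ``var`` passes ``limit``."""

    def event(t, y, _p):
        return float(_outputs(np.asarray(y), p)[var]) - limit

    event.terminal = True
    event.direction = -sign  # crossing from inside the interval to outside
    return event


def demo_parameter_set() -> ParameterSet:
    """The packaged nine-parameter campaign table for the demo model.

    Each campaign parameter is uniform on [0.5, 1.5] times its default,
    per the bundled fixture table.
    """
    ref = resources.files("eescreen").joinpath("data/demo_params.csv")
    with resources.as_file(ref) as path:
        return ParameterSet.from_csv(path)
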