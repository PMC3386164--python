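"""Model-adapter contract.

The screening engine is model-agnostic: any ODE model of whole-body
physiology can be plugged in by implementing :class:`ModelAdapter`.  The
engine hands the adapter a *physical* parameter map (denormalisation from
the unit hypercube happens at this boundary and nowhere else), an initial
state, a duration and a set of record times; the adapter returns named
output trajectories and its final state.

Adapters may optionally enforce survival ("aliveness") bounds during
integration and terminate early; the engine re-checks every returned
sample regardless, so enforcement inside the adapter is an optimisation,
not a requirement.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["SimResult", "ModelAdapter"]

#: status codes for a simulation attempt
OK = "ok"
BOUND_VIOLATED = "bound_violated"
INTEGRATION_FAILURE = "integration_failure"


@dataclass
class SimResult:
    """Outcome of one adapter integration.

    Attributes
    ----------
    status : str
        ``"ok"``, ``"bound_violated"`` or ``"integration_failure"``.
    violated : str or None
        Name of the first survival bound crossed, when status is
        ``"bound_violated"``.
    times : ndarray
        Times (min, relative to the start of this integration) at which
        outputs were recorded.  May be truncated on early termination.
    outputs : dict of str -> ndarray
        One trajectory per named output, aligned with ``times``.
    final_state : object
        Opaque model state at the last integrated time; feed back into
        :meth:`ModelAdapter.simulate` to continue a run.
    message : str
        Diagnostic detail (integrator message, bound value, ...).
    """

    status: str
    times: np.ndarray
    outputs: dict[str, np.ndarray]
    final_state: object
    violated: str | None = None
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == OK

    def at(self, time: float) -> dict[str, float]:
        """Output snapshot at a recorded time (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.times, time, rtol=0, atol=1e-9))
        if idx.size == 0:
            raise KeyError(f"time {time!r} was not recorded")
        i = int(idx[0])
        return {name: float(traj[i]) for name, traj in self.outputs.items()}


class ModelAdapter(abc.ABC):
    """Contract for pluggable ODE models.

    Concrete adapters declare their parameter and output name sets and
    implement :meth:`simulate`.  State is opaque to the engine.
    """

    #: short registry name, e.g. ``"demo-pn"``
    name: str = "adapter"

    @property
    @abc.abstractmethod
    def parameter_names(self) -> tuple[str, ...]:
        """Names of the physical parameters the adapter accepts."""

    @property
    @abc.abstractmethod
    def output_names(self) -> tuple[str, ...]:
        """Names of the output variables exposed over time."""

    @abc.abstractmethod
    def default_state(self) -> object:
        """The model's default initial state."""

    @abc.abstractmethod
    def simulate(
        self,
        params: Mapping[str, float],
        state: object,
        duration: float,
        record_times: Sequence[float],
        bounds: Mapping[str, tuple[float | None, float | None]] | None = None,
        rtol: float = 1e-8,
    ) -> SimResult:
        """Integrate for ``duration`` minutes from ``state``.

        ``record_times`` are offsets (min) from the start of this call at
        which all outputs must be reported.  When ``bounds`` is given the
        adapter may terminate as soon as a bounded output leaves its
        inclusive ``[min, max]`` interval, reporting the crossed bound.
        """
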