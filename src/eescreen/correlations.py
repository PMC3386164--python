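"""Spearman rank-correlation screens.

Three uses, all rank-based because the relationships of interest are
monotone but rarely linear:

* parameter <-> output correlations across a virtual population (which
  parameters' absolute values track an output);
* elementary-effect <-> parameter correlations (which *other*
  parameters modulate the effect of the perturbed one — the screen that
  guides the choice of multi-parameter perturbations);
* normotensive vs hypertensive comparison of the first table.

No multiple-testing correction is applied; sample counts are always
reported so downstream users can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .population import Population

__all__ = [
    "spearman",
    "CorrelationTable",
    "correlate_population",
    "screen_interactions",
    "compare_strata",
]

#: column order of the delimited correlation table
TABLE_COLUMNS = ["parameter", "variable", "time_min", "stratum", "rho", "n"]


def spearman(xs, ys) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (missing) when either input is constant, where the
    statistic is undefined.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError(f"length mismatch: {xs.shape} vs {ys.shape}")
    if xs.size < 3:
        raise ValueError(f"need at least 3 observations, got {xs.size}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho)


@dataclass
class CorrelationTable:
    """Tidy (parameter, variable, time) -> rho table.

    ``time_min`` is NaN for steady-state rows computed from phenotypes.
    ``stability`` reports, per (parameter, variable), the maximum over
    record times of |rho(t) - rho(t_last)| — the time-variation of the
    correlation, near zero when correlations are time-stable.
    """

    frame: pd.DataFrame
    stability: pd.DataFrame | None = None

    def rho(self, parameter: str, variable: str, time_min: float | None = None) -> float:
        sel = (self.frame["parameter"] == parameter) & (self.frame["variable"] == variable)
        if time_min is None:
            sel &= self.frame["time_min"].isna()
        else:
            sel &= self.frame["time_min"] == time_min
        rows = self.frame[sel]
        if rows.empty:
            raise KeyError((parameter, variable, time_min))
        return float(rows["rho"].iloc[0])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CorrelationTable":
        frame = pd.read_csv(path)
        # the free-text stratum column round-trips empty strings as NaN
        frame["stratum"] = frame["stratum"].fillna("").astype(str)
        return cls(frame)


def correlate_population(
    pop: Population,
    parameters: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
    samples: pd.DataFrame | None = None,
    phases: Iterable[str] = ("pre", "post"),
    stratum: str = "",
) -> CorrelationTable:
    """Spearman correlations between parameters and output variables.

    Steady-state correlations are computed across the (alive) phenotypes
    of the selected phases.  When a tidy elementary-effect sample table
    is supplied, per-record-time correlations are added as well: for
    each output and record time, the recorded post-perturbation value is
    correlated against the base genotype, and the per-pair time
    stability |rho(t) - rho(t_last)| is summarised in ``stability``.
    """
    sub = pop.alive_only().select_phases(phases)
    params = sub.params()
    outputs = sub.vars()
    parameters = tuple(parameters) if parameters is not None else tuple(params.columns)
    variables = tuple(variables) if variables is not None else tuple(outputs.columns)

    rows = []
    for parameter in parameters:
        xs = params[parameter].to_numpy()
        for variable in variables:
            rows.append(
                {
                    "parameter": parameter,
                    "variable": variable,
                    "time_min": np.nan,
                    "stratum": stratum,
                    "rho": spearman(xs, outputs[variable].to_numpy()),
                    "n": len(sub),
                }
            )

    stability = None
    if samples is not None:
        genotypes = pop.params()
        time_rows = []
        for (variable, t), group in samples[samples["status"] == "ok"].groupby(
            ["output", "time_min"]
        ):
            if variable not in variables:
                continue
            geno = genotypes.loc[group["pre_id"]]
            values = group["value"].to_numpy()
            for parameter in parameters:
                time_rows.append(
                    {
                        "parameter": parameter,
                        "variable": variable,
                        "time_min": float(t),
                        "stratum": stratum,
                        "rho": spearman(geno[parameter].to_numpy(), values),
                        "n": len(group),
                    }
                )
        time_frame = pd.DataFrame(time_rows)
        rows_frame = pd.DataFrame(rows, columns=TABLE_COLUMNS)
        frame = pd.concat([rows_frame, time_frame], ignore_index=True)
        t_last = time_frame["time_min"].max()
        last = time_frame[time_frame["time_min"] == t_last].set_index(["parameter", "variable"])[
            "rho"
        ]
        devs = (
            time_frame.set_index(["parameter", "variable"])
            .groupby(level=[0, 1])
            .apply(lambda g: float(np.nanmax(np.abs(g["rho"] - last.loc[g.name]))))
        )
        stability = devs.rename("max_dev").reset_index()
        return CorrelationTable(frame, stability)

    return CorrelationTable(pd.DataFrame(rows, columns=TABLE_COLUMNS), None)


def screen_interactions(
    samples: pd.DataFrame,
    pop: Population,
    parameter: str,
    output: str,
    time_min: float | None = None,
    min_samples: int = 10,
) -> pd.Series:
    """Correlate one elementary effect with the other co-sampled parameters.

    For the chosen (parameter, output) pair — at the latest record time
    unless ``time_min`` is given — the signed elementary-effect samples
    are Spearman-correlated against each *other* parameter's base value
    across the sampled genotypes.  A large |rho| flags that parameter as
    modulating the elementary effect, making the pair a candidate for a
    joint multi-parameter perturbation.

    Returns a Series indexed by co-parameter name; empty when fewer than
    ``min_samples`` valid samples exist.
    """
    sel = samples[
        (samples["parameter"] == parameter)
        & (samples["output"] == output)
        & (samples["status"] == "ok")
    ]
    if time_min is None:
        time_min = sel["time_min"].max()
    sel = sel[sel["time_min"] == time_min]
    if len(sel) < min_samples:
        return pd.Series(dtype=float, name="rho")
    genotypes = pop.params().loc[sel["pre_id"]]
    ee = sel["ee"].to_numpy()
    out = {}
    for other in genotypes.columns:
        if other == parameter:
            continue
        out[other] = spearman(genotypes[other].to_numpy(), ee)
    return pd.Series(out, name="rho")


def compare_strata(
    norm: CorrelationTable,
    hyper: CorrelationTable,
    display_threshold: float = 0.1,
) -> pd.DataFrame:
    """Categorise how correlations change between sub-populations.

    Per (parameter, variable), comparing steady-state rows only:

    * ``sign-flip``  — opposite signs, both above the display threshold
      in magnitude;
    * ``increased`` / ``decreased`` — |rho| grew / shrank in the
      hypertensive stratum (both above threshold);
    * ``unchanged`` — either correlation below the display threshold in
      magnitude (or exactly equal magnitudes).
    """
    a = norm.frame[norm.frame["time_min"].isna()].set_index(["parameter", "variable"])["rho"]
    b = hyper.frame[hyper.frame["time_min"].isna()].set_index(["parameter", "variable"])["rho"]
    if set(a.index) != set(b.index):
        raise ValueError("strata tables cover different (parameter, variable) sets")
    rows = []
    for key in a.index:
        rn, rh = float(a.loc[key]), float(b.loc[key])
        if abs(rn) < display_threshold or abs(rh) < display_threshold:
            category = "unchanged"
        elif rn * rh < 0:
            category = "sign-flip"
        elif abs(rh) > abs(rn):
            category = "increased"
        elif abs(rh) < abs(rn):
            category = "decreased"
        else:
            category = "unchanged"
        rows.append(
            {
                "parameter": key[0],
                "variable": key[1],
                "rho_norm": rn,
                "rho_hyper": rh,
                "category": category,
            }
        )
    return pd.DataFrame(rows)
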