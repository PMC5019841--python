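"""Seeded generator of event-level flow-cytometry datasets.

Emulates the statistical structure the downstream processing assumes: a
log-normally distributed cell-size channel (FSC-A), per-cell fluorescence
proportional to size × intracellular reporter concentration (the size
correlation that FSC normalization removes), an additive autofluorescence
floor, small multiplicative measurement noise, and the two instrument
dialects — a zero-floored Accuri-style machine and a baseline-subtracted
VYB-style machine whose values can go negative.

Populations, dose series (driven by a steady-state response model) and
time courses (driven by the kinetic model) are all pure functions of their
spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _fcs
from .kinetics import KineticParams, Scenario, simulate
from .response_models import (
    HillParams,
    IFFLParams,
    hill_response,
    iffl_response,
)

__all__ = [
    "PopulationSpec",
    "EventTable",
    "generate_population",
    "generate_dose_series",
    "generate_timecourse",
    "write_events",
]

EVENT_COLUMNS = ("fsc_a", "fl1_a", "mcherry_a", "t_acquire")


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical description of one cytometry read.

    ``size_cv`` and ``conc_cv`` are linear-scale coefficients of variation
    of the log-normal size and concentration marginals (converted
    internally to log-space sigma).  ``autofluorescence`` is an additive
    fluorescence floor; ``noise_sd_frac`` the multiplicative measurement
    noise (SD as a fraction of the noiseless signal).  The VYB dialect
    subtracts ``vyb_baseline`` from fluorescence, producing the negative
    values that the cleaning step later offsets away.
    """

    n_events: int = 10_000
    size_median: float = 1.0e5     # FSC-A units
    size_cv: float = 0.4
    conc_median: float = 0.02      # fluorescence per FSC unit
    conc_cv: float = 0.25
    autofluorescence: float = 50.0
    instrument_dialect: Literal["accuri", "vyb"] = "accuri"
    seed: int = 0
    noise_sd_frac: float = 0.01
    read_duration_s: float = 60.0
    vyb_baseline: float = 30.0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.size_median <= 0 or self.conc_median <= 0:
            raise ValueError("size_median and conc_median must be positive")
        if self.size_cv < 0 or self.conc_cv < 0:
            raise ValueError("CVs must be non-negative")
        if self.autofluorescence < 0:
            raise ValueError("autofluorescence must be non-negative")
        if self.instrument_dialect not in ("accuri", "vyb"):
            raise ValueError(
                f"unknown instrument dialect {self.instrument_dialect!r}"
            )
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be non-negative")


@dataclass
class EventTable:
    """Per-event measurements for one population plus shared metadata.

    ``data`` columns: ``fsc_a``, one or more fluorescence channels
    (``fl1_a``[, ``mcherry_a``]) and ``t_acquire`` (seconds from read
    start).  ``metadata`` applies to every row (strain, treatment doses,
    timepoint, instrument dialect, ...).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "fsc_a" not in self.data.columns:
            raise ValueError("EventTable requires an fsc_a column")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def dialect(self) -> str:
        return self.metadata.get("dialect", "accuri")

    def fl_channels(self) -> list[str]:
        return [
            c for c in self.data.columns if c not in ("fsc_a", "t_acquire")
        ]

    def copy(self) -> "EventTable":
        return EventTable(self.data.copy(), dict(self.metadata))


def _lognormal(
    rng: np.random.Generator, median: float, cv: float, n: int
) -> np.ndarray:
    """Log-normal sample parameterized by its median and linear-scale CV."""
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=n)


def _generate(
    spec: PopulationSpec,
    response_scale: float,
    rng: np.random.Generator,
    metadata: dict,
) -> EventTable:
    n = spec.n_events
    size = _lognormal(rng, spec.size_median, spec.size_cv, n)
    if response_scale > 0:
        conc = _lognormal(
            rng, spec.conc_median * response_scale, spec.conc_cv, n
        )
    else:
        conc = np.zeros(n)
    signal = size * conc + spec.autofluorescence
    noise = rng.normal(0.0, 1.0, n) * spec.noise_sd_frac * signal
    fl = signal + noise
    if spec.instrument_dialect == "accuri":
        fl = np.clip(fl, 0.0, None)
    else:  # vyb: baseline subtraction can push dim events below zero
        fl = fl - spec.vyb_baseline
    t_acquire = np.sort(rng.uniform(0.0, spec.read_duration_s, n))
    df = pd.DataFrame({"fsc_a": size, "fl1_a": fl, "t_acquire": t_acquire})
    meta = {"dialect": spec.instrument_dialect, **metadata}
    return EventTable(df, meta)


def generate_population(
    spec: PopulationSpec,
    response_scale: float = 1.0,
    *,
    metadata: Mapping | None = None,
) -> EventTable:
    """Generate one seeded population of ``spec.n_events`` events.

    ``response_scale`` multiplies the concentration median (1.0 = the
    untreated steady state; a functional-degron strain after induction has
    a scale < 1).  Identical (spec, response_scale) → bit-identical output.
    """
    if response_scale < 0:
        raise ValueError("response_scale must be non-negative")
    rng = np.random.default_rng(spec.seed)
    return _generate(spec, response_scale, rng, dict(metadata or {}))


ResponseModel = (
    HillParams | IFFLParams | Callable[[float], float] | tuple
)


def _as_model_fn(model: ResponseModel) -> Callable[[float], float]:
    if isinstance(model, HillParams):
        return lambda x: hill_response(x, model)
    if isinstance(model, IFFLParams):
        return lambda x: iffl_response(x, model)
    if isinstance(model, tuple):
        name, params = model
        if name == "hill":
            return lambda x: hill_response(x, params)
        if name == "iffl":
            return lambda x: iffl_response(x, params)
        raise ValueError(f"unknown model name {name!r}")
    if callable(model):
        return model
    raise TypeError(f"cannot interpret response model {model!r}")


def generate_dose_series(
    spec: PopulationSpec,
    doses: Sequence[float],
    model: ResponseModel,
    *,
    dose_key: str = "alpha_uM",
    metadata: Mapping | None = None,
) -> dict[float, EventTable]:
    """Generate one population per dose, scaled by a response model.

    The concentration scale at dose ``d`` is ``model(d)/model(0)`` —
    normalization to the untreated condition — so the zero-dose population
    sits at the spec's ``conc_median``.  Per-dose random streams are
    derived deterministically from ``spec.seed``, independent of the model.
    """
    doses = [float(d) for d in doses]
    if any(d < 0 for d in doses):
        raise ValueError("doses must be non-negative")
    fn = _as_model_fn(model)
    y0 = fn(0.0)
    if y0 == 0:
        raise ZeroDivisionError(
            "model(0) = 0: cannot normalize the dose series to the "
            "untreated condition"
        )
    children = np.random.SeedSequence(spec.seed).spawn(len(doses))
    out: dict[float, EventTable] = {}
    for child, d in zip(children, doses):
        scale = fn(d) / y0
        meta = {dose_key: d, **dict(metadata or {})}
        rng = np.random.default_rng(child)
        out[d] = _generate(spec, scale, rng, meta)
    return out


def generate_timecourse(
    spec: PopulationSpec,
    kinetics: KineticParams,
    times: Sequence[float],
    *,
    scenario: Scenario | None = None,
    inputs: Mapping | None = None,
    metadata: Mapping | None = None,
) -> dict[float, EventTable]:
    """Generate one population per timepoint along a kinetic trajectory.

    The reporter-concentration median at each time follows the kinetic
    model's total-reporter trajectory, normalized to its value at time 0
    (induction).  Default inputs: 10 µM α-factor at time zero.
    """
    times = [float(t) for t in times]
    if any(t < 0 for t in times) or any(
        b <= a for a, b in zip(times, times[1:])
    ):
        raise ValueError("times must be non-negative and strictly increasing")
    scenario = scenario or Scenario()
    inputs = dict(inputs or {"alpha": 10.0, "aba": 0.0})
    sim_times = times if times[0] == 0 else [0.0, *times]
    traj = simulate(kinetics, scenario, inputs, sim_times)
    total = traj.total_reporter
    if total[0] <= 0:
        raise ZeroDivisionError("reporter level at time 0 is zero")
    scales = total / total[0]
    if times[0] != 0:
        scales = scales[1:]
    children = np.random.SeedSequence(spec.seed).spawn(len(times))
    out: dict[float, EventTable] = {}
    for child, t, scale in zip(children, times, scales):
        meta = {"timepoint_min": t, **dict(metadata or {})}
        rng = np.random.default_rng(child)
        out[t] = _generate(spec, float(scale), rng, meta)
    return out


# ---------------------------------------------------------------------------
# event-table serialization


def write_events(
    table: EventTable, path, format: Literal["csv", "fcs"] = "csv"
) -> None:
    """Write an event table to CSV (with metadata header comments) or FCS.

    The CSV form round-trips losslessly through ``cytometry.read_events``;
    the FCS form is a minimal FCS 3.0 float dataset whose numeric fields
    round-trip within 32-bit float precision.
    """
    if table.n_events == 0:
        raise ValueError("refusing to write an empty event table")
    path = Path(path)
    if format == "csv":
        lines = [
            f"# {k}={json.dumps(v)}" for k, v in sorted(table.metadata.items())
        ]
        body = table.data.to_csv(index=False, float_format="%.17g")
        path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
    elif format == "fcs":
        cols = {c: table.data[c].to_numpy() for c in table.data.columns}
        _fcs.write_fcs(path, cols, table.metadata)
    else:
        raise ValueError(f"unsupported format {format!r}")
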