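"""End-to-end orchestration: generate or ingest events, process,
summarize, fit, classify, and report.

A single YAML-able configuration drives the whole run.  In simulate mode
every random stream is derived deterministically from the global seed
(condition ``i`` uses ``SeedSequence([seed, i])``), so any stage can be
rerun in isolation and two runs with the same config are byte-identical.
Reports are plain CSV/JSON.
"""

from __future__ import annotations

import glob as _glob
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cytometry import (
    clean_events,
    gate_anomalies,
    read_events,
    size_normalize,
    summarize,
)
from .fitting import DoseResponseCurve, fit_hill, fit_hill_joint, fit_iffl
from .kinetics import KineticParams, Scenario, simulate
from .response_models import HillParams, IFFLParams, classify_response
from .synthetic_data import (
    EventTable,
    PopulationSpec,
    generate_dose_series,
    write_events,
)

__all__ = ["RunConfig", "ConditionSpec", "ConfigError", "run"]

logger = logging.getLogger("mapk_rewire")


class ConfigError(ValueError):
    """Configuration schema violation, reported with the offending field
    path before any work starts."""


@dataclass
class ConditionSpec:
    """One experimental condition: a driver model plus a dose series."""

    label: str
    driver: str  # "hill" | "iffl" | "kinetics"
    doses: list[float]
    params: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    read_time_min: float = 180.0
    inputs: dict = field(default_factory=dict)  # extra doses, e.g. aba


@dataclass
class RunConfig:
    """Validated run configuration (see :func:`RunConfig.from_dict`)."""

    mode: str
    output_dir: str
    seed: int | None = None
    conditions: list[ConditionSpec] = field(default_factory=list)
    input_globs: list[str] = field(default_factory=list)
    population: dict = field(default_factory=dict)
    dialect: str = "accuri"
    channel: str = "fl1_a"
    gating: bool = False
    gate_window_s: float = 5.0
    gate_mad_threshold: float = 5.0
    fit_model: str = "hill"  # "hill" | "iffl" | "none"
    shared: list[str] = field(default_factory=list)
    classify_rel_tol: float = 0.05
    write_event_files: bool = False

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        def fail(path: str, msg: str):
            raise ConfigError(f"{path}: {msg}")

        mode = d.get("mode")
        if mode not in ("simulate", "ingest"):
            fail("mode", f"must be 'simulate' or 'ingest', got {mode!r}")
        if "output_dir" not in d:
            fail("output_dir", "is required")
        cfg = cls(mode=mode, output_dir=str(d["output_dir"]))
        if mode == "simulate":
            if d.get("seed") is None:
                fail("seed", "is required in simulate mode")
            cfg.seed = int(d["seed"])
            raw_conditions = d.get("conditions")
            if not raw_conditions:
                fail("conditions", "at least one condition is required")
            for i, rc in enumerate(raw_conditions):
                path = f"conditions[{i}]"
                for key in ("label", "driver", "doses"):
                    if key not in rc:
                        fail(f"{path}.{key}", "is required")
                if rc["driver"] not in ("hill", "iffl", "kinetics"):
                    fail(f"{path}.driver", f"unknown driver {rc['driver']!r}")
                doses = [float(x) for x in rc["doses"]]
                if any(x < 0 for x in doses):
                    fail(f"{path}.doses", "doses must be non-negative")
                cfg.conditions.append(
                    ConditionSpec(
                        label=str(rc["label"]),
                        driver=rc["driver"],
                        doses=doses,
                        params=dict(rc.get("params", {})),
                        scenario=dict(rc.get("scenario", {})),
                        read_time_min=float(rc.get("read_time_min", 180.0)),
                        inputs=dict(rc.get("inputs", {})),
                    )
                )
            cfg.population = dict(d.get("population", {}))
        else:
            globs = d.get("inputs") or d.get("input_globs")
            if not globs:
                fail("inputs", "ingest mode requires input file globs")
            cfg.input_globs = [str(g) for g in globs]
            matched = [f for g in cfg.input_globs for f in _glob.glob(g)]
            if not matched:
                fail("inputs", f"no files match {cfg.input_globs}")
        proc = d.get("processing", {})
        cfg.dialect = proc.get("dialect", "accuri")
        if cfg.dialect not in ("accuri", "vyb"):
            fail("processing.dialect", f"unknown dialect {cfg.dialect!r}")
        cfg.channel = proc.get("channel", "fl1_a")
        cfg.gating = bool(proc.get("gating", False))
        cfg.gate_window_s = float(proc.get("window_s", 5.0))
        cfg.gate_mad_threshold = float(proc.get("mad_threshold", 5.0))
        ana = d.get("analysis", {})
        cfg.fit_model = ana.get("model", "hill")
        if cfg.fit_model not in ("hill", "iffl", "none"):
            fail("analysis.model", f"unknown model {cfg.fit_model!r}")
        cfg.shared = [str(s) for s in ana.get("shared", [])]
        cfg.classify_rel_tol = float(ana.get("classify_rel_tol", 0.05))
        cfg.write_event_files = bool(d.get("write_event_files", False))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _condition_seed(global_seed: int, index: int) -> int:
    """Deterministic per-condition seed derivation (documented scheme)."""
    return int(
        np.random.SeedSequence([global_seed, index]).generate_state(1)[0]
        % (2**31)
    )


def _kinetics_dose_model(cond: ConditionSpec):
    """Reporter level at the read time as a function of α-factor dose."""
    params = KineticParams(**cond.params)
    scenario = Scenario(**cond.scenario)
    times = [0.0, cond.read_time_min]
    cache: dict[float, float] = {}

    def model(alpha: float) -> float:
        if alpha not in cache:
            traj = simulate(
                params,
                scenario,
                {"alpha": alpha, **cond.inputs},
                times,
            )
            cache[alpha] = float(traj.total_reporter[-1])
        return cache[alpha]

    return model


def _simulate_condition(
    cond: ConditionSpec, cfg: RunConfig, seed: int
) -> dict[float, EventTable]:
    pop = PopulationSpec(
        **{**cfg.population, "seed": seed, "instrument_dialect": cfg.dialect}
    )
    if cond.driver == "hill":
        model = HillParams(**cond.params)
    elif cond.driver == "iffl":
        model = IFFLParams(**cond.params)
    else:
        model = _kinetics_dose_model(cond)
    return generate_dose_series(
        pop, cond.doses, model, metadata={"condition": cond.label}
    )


def _process_table(table: EventTable, cfg: RunConfig) -> EventTable:
    t = clean_events(table)
    if cfg.gating:
        t = gate_anomalies(t, cfg.gate_window_s, cfg.gate_mad_threshold)
    return size_normalize(t, cfg.channel)


def run(config: RunConfig | Mapping | str | Path) -> dict:
    """Execute a full pipeline run and write the report bundle.

    Writes ``summaries.csv``, ``fits.json``, ``classification.json`` and
    ``run_log.json`` into the configured output directory and returns the
    in-memory results.  Stage failures are reported per condition without
    corrupting outputs already written.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    cfg = config
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: obtain event tables grouped by condition and dose
    grouped: dict[str, dict[float, EventTable]] = {}
    if cfg.mode == "simulate":
        for i, cond in enumerate(cfg.conditions):
            seed = _condition_seed(cfg.seed, i)
            grouped[cond.label] = _simulate_condition(cond, cfg, seed)
            if cfg.write_event_files:
                for dose, tab in grouped[cond.label].items():
                    write_events(
                        tab, outdir / f"events_{cond.label}_{dose:g}.csv"
                    )
    else:
        for g in cfg.input_globs:
            for f in sorted(_glob.glob(g)):
                tab = read_events(f)
                label = str(
                    tab.metadata.get("condition")
                    or tab.metadata.get("strain")
                    or "default"
                )
                dose = float(tab.metadata.get("alpha_uM", 0.0))
                grouped.setdefault(label, {})[dose] = tab

    # ---- stage 2: process + summarize
    rows = []
    curves: dict[str, DoseResponseCurve] = {}
    errors: dict[str, str] = {}
    for label, by_dose in grouped.items():
        try:
            doses = sorted(by_dose)
            summaries = []
            for dose in doses:
                s = summarize(
                    _process_table(by_dose[dose], cfg), f"{cfg.channel}_norm"
                )
                summaries.append(s)
                rows.append(
                    {
                        "condition": label,
                        "dose": dose,
                        "median": s.median,
                        "q1": s.iqr[0],
                        "q3": s.iqr[1],
                        "cv": s.cv,
                        "n_events": s.n_events,
                    }
                )
            curves[label] = DoseResponseCurve(
                doses=tuple(doses),
                medians=tuple(s.median for s in summaries),
                iqr=tuple(s.iqr for s in summaries),
                n_events=tuple(s.n_events for s in summaries),
                condition=label,
            )
        except Exception as exc:  # keep other conditions alive
            logger.exception("processing failed for condition %r", label)
            errors[label] = f"processing: {exc}"
    summaries_df = pd.DataFrame(rows)
    summaries_df.to_csv(outdir / "summaries.csv", index=False)

    # ---- stage 3: fits
    fits: dict[str, dict] = {}
    if cfg.fit_model != "none":
        if cfg.shared and len(curves) >= 2:
            try:
                res = fit_hill_joint(
                    list(curves.values()), set(cfg.shared)
                )
                fits["joint"] = res.to_dict()
            except Exception as exc:
                logger.exception("joint fit failed")
                errors["joint_fit"] = str(exc)
        for label, curve in curves.items():
            try:
                fit_fn = fit_hill if cfg.fit_model == "hill" else fit_iffl
                fits[label] = fit_fn(curve).to_dict()
            except Exception as exc:
                logger.exception("fit failed for condition %r", label)
                errors[label] = f"fit: {exc}"
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2, default=float))

    # ---- stage 4: classification
    classification: dict[str, str] = {}
    for label, curve in curves.items():
        try:
            classification[label] = classify_response(
                curve.doses, curve.medians, cfg.classify_rel_tol
            )
        except Exception as exc:
            logger.exception("classification failed for %r", label)
            errors[label] = f"classify: {exc}"
    (outdir / "classification.json").write_text(
        json.dumps(classification, indent=2)
    )

    # ---- run log
    log = {
        "package_version": _pkg_version,
        "seed": cfg.seed,
        "config": {
            **{
                f.name: getattr(cfg, f.name)
                for f in fields(cfg)
                if f.name != "conditions"
            },
            "conditions": [asdict(c) for c in cfg.conditions],
        },
        "condition_seeds": (
            {
                c.label: _condition_seed(cfg.seed, i)
                for i, c in enumerate(cfg.conditions)
            }
            if cfg.mode == "simulate"
            else {}
        ),
        "errors": errors,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "summaries": summaries_df,
        "curves": curves,
        "fits": fits,
        "classification": classification,
        "errors": errors,
    }
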