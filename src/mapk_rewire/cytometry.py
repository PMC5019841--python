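"""Event-level cytometry processing and population summaries.

The processing chain mirrors how pooled single-cell fluorescence reads are
prepared before dose-response analysis:

1. optional anomaly gating — events (bubbles, clogs) whose FSC-A deviates
   wildly from the local time-window median are dropped;
2. dialect-specific cleaning — Accuri-style zero floors are converted to 1
   (so later log transforms are defined); VYB-style baseline-subtracted
   values are shifted by |batch minimum| + 1 so everything is positive;
3. size normalization — each event's fluorescence is divided by its FSC-A
   value, removing the cell-size component of fluorescence variation;
4. summarization — median, interquartile range and CV (sd/mean, linear
   scale) of the normalized signal per population.

Fold changes are oriented untreated/treated, so degradation of the
reporter gives values > 1 ("x-fold drop").
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import _fcs
from .synthetic_data import EventTable

__all__ = [
    "PopulationSummary",
    "read_events",
    "clean_events",
    "gate_anomalies",
    "size_normalize",
    "summarize",
    "fold_change",
    "cv_reduction",
]

logger = logging.getLogger("mapk_rewire")

_DIALECTS = ("accuri", "vyb")


@dataclass(frozen=True)
class PopulationSummary:
    """Median / IQR / CV of one population's (normalized) signal."""

    median: float
    iqr: tuple[float, float]  # (q1, q3)
    cv: float
    n_events: int
    channel: str = "fl1_a_norm"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q1, q3 = self.iqr
        if not (q1 <= self.median <= q3):
            raise ValueError("IQR must bracket the median")
        if self.cv < 0:
            raise ValueError("CV must be non-negative")
        if self.n_events < 1:
            raise ValueError("summary needs at least one event")


def read_events(path, format: str | None = None) -> EventTable:
    """Read an event table from CSV (with ``# key=value`` metadata header
    comments) or minimal FCS 3.x.  Format inferred from the extension when
    not given."""
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "fcs":
        columns, meta = _fcs.read_fcs(path)
        return EventTable(pd.DataFrame(columns), meta)
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    meta: dict = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            pos += len(line)
            k, _, v = line[1:].strip().partition("=")
            try:
                meta[k.strip()] = json.loads(v)
            except json.JSONDecodeError:
                meta[k.strip()] = v
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    return EventTable(df, meta)


def clean_events(
    table: EventTable, *, batch_tables: Iterable[EventTable] | None = None
) -> EventTable:
    """Apply the dialect-specific raw-value correction.

    Accuri dialect: measurement values equal to 0 are converted to 1 (a
    zero here is an instrument floor, and would become NA under a log
    transform).  VYB dialect: every measurement column is shifted by the
    absolute value of the lowest value in its acquisition batch, plus 1,
    making all values strictly positive; pass the other tables acquired in
    the same batch ("that day") via ``batch_tables`` so the offset is
    shared.  Row count is never changed.

    Accuri cleaning is idempotent (no zeros remain after one pass).
    """
    dialect = table.dialect
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown instrument dialect {dialect!r}")
    out = table.copy()
    cols = [c for c in out.data.columns if c != "t_acquire"]
    if dialect == "accuri":
        for c in cols:
            vals = out.data[c].to_numpy(dtype=float, copy=True)
            vals[vals == 0] = 1.0
            out.data[c] = vals
    else:
        group = list(batch_tables) if batch_tables is not None else []
        for c in cols:
            batch_min = min(
                [float(np.min(out.data[c]))]
                + [
                    float(np.min(t.data[c]))
                    for t in group
                    if c in t.data.columns
                ]
            )
            out.data[c] = out.data[c] + abs(batch_min) + 1.0
    out.metadata["cleaned"] = True
    return out


def gate_anomalies(
    table: EventTable,
    window: float = 5.0,
    mad_threshold: float = 5.0,
) -> EventTable:
    """Remove acquisition anomalies (bubbles, clogs) from a read.

    An event is anomalous when its FSC-A deviates from the sliding
    time-window median by more than ``mad_threshold`` robust standard
    deviations (1.4826·MAD of the per-event deviations).  The removed
    count is recorded in the output metadata.
    """
    if "t_acquire" not in table.data.columns:
        raise ValueError("gate_anomalies requires a t_acquire column")
    df = table.data.sort_values("t_acquire", kind="mergesort")
    duration = float(df["t_acquire"].iloc[-1] - df["t_acquire"].iloc[0])
    if window >= duration:
        logger.warning(
            "gating window %.3gs >= read duration %.3gs; using one global "
            "window",
            window,
            duration,
        )
        local_median = np.full(len(df), float(df["fsc_a"].median()))
    else:
        ts = pd.Series(
            df["fsc_a"].to_numpy(),
            index=pd.to_timedelta(df["t_acquire"], unit="s"),
        )
        local_median = (
            ts.rolling(pd.Timedelta(seconds=window), center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    dev = np.abs(df["fsc_a"].to_numpy() - local_median)
    mad = np.median(dev)
    robust_sd = 1.4826 * mad
    if not np.isfinite(mad_threshold):
        keep = np.ones(len(df), dtype=bool)
    elif robust_sd == 0:
        keep = dev == 0
    else:
        keep = dev <= mad_threshold * robust_sd
    out = EventTable(
        df.loc[keep].reset_index(drop=True), dict(table.metadata)
    )
    out.metadata["n_gated_out"] = int((~keep).sum())
    return out


def size_normalize(table: EventTable, channel: str = "fl1_a") -> EventTable:
    """Divide a fluorescence channel by per-event FSC-A.

    Adds ``<channel>_norm``; the original columns are retained.  Requires
    strictly positive FSC-A (run :func:`clean_events` / gating first).
    """
    if channel not in table.data.columns:
        raise KeyError(f"channel {channel!r} not in table")
    fsc = table.data["fsc_a"].to_numpy(dtype=float)
    if np.any(fsc <= 0):
        raise ValueError(
            "FSC-A must be strictly positive; apply clean_events (and "
            "gating) before size normalization"
        )
    out = table.copy()
    out.data[f"{channel}_norm"] = out.data[channel].to_numpy(dtype=float) / fsc
    return out


def summarize(table: EventTable, channel: str = "fl1_a_norm") -> PopulationSummary:
    """Median, IQR and CV of one population's signal.

    Quantiles use linear interpolation (numpy default, type 7); the CV is
    sd/mean on the linear scale.
    """
    if table.n_events == 0:
        raise ValueError("cannot summarize an empty table")
    if channel not in table.data.columns:
        raise KeyError(f"channel {channel!r} not in table")
    # sorting makes the summary exactly invariant to event order (float
    # summation is otherwise order-dependent at the last ulp)
    x = np.sort(table.data[channel].to_numpy(dtype=float))
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    mean = x.mean()
    cv = float(x.std(ddof=1) / mean) if len(x) > 1 and mean != 0 else 0.0
    return PopulationSummary(
        median=float(med),
        iqr=(float(q1), float(q3)),
        cv=abs(cv),
        n_events=len(x),
        channel=channel,
        metadata=dict(table.metadata),
    )


def fold_change(
    untreated: PopulationSummary, treated: PopulationSummary
) -> tuple[float, float]:
    """Fold drop of the treated population: untreated/treated medians.

    Returns ``(ratio, log10(ratio))``; degradation of the reporter gives
    ratios > 1.
    """
    if treated.median <= 0:
        raise ValueError("treated median must be positive")
    ratio = untreated.median / treated.median
    return float(ratio), float(np.log10(ratio))


def cv_reduction(
    raw: PopulationSummary, normalized: PopulationSummary
) -> float:
    """Percent CV reduction achieved by size normalization.

    ``100·(1 − cv_norm/cv_raw)`` on the same underlying events (raw
    summary on the fluorescence channel, normalized summary on the
    size-normalized channel).
    """
    if raw.cv == 0:
        raise ZeroDivisionError("raw CV is zero")
    return 100.0 * (1.0 - normalized.cv / raw.cv)
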