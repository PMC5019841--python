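"""Constrained least-squares fitting of the dose-response models.

Fits are to per-dose population medians (optionally weighted by 1/IQR
width), with box bounds (A, B ≥ 0; C > 0; 0 < n ≤ 10; D, E ≥ 0) and a
deterministic multistart grid so the reported optimum is the best of
several basins.  Joint fits tie any subset of {A, B, C, n} across
conditions — sharing the saturation coefficient C across a feedback and a
control curve is the scheme used for the negative-feedback comparisons.
Uncertainty comes from a seeded within-dose event bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import lmfit
import numpy as np

from .response_models import HillParams, IFFLParams, hill_response, iffl_response

__all__ = [
    "DoseResponseCurve",
    "FitResult",
    "fit_hill",
    "fit_hill_joint",
    "fit_iffl",
    "bootstrap_uncertainty",
]

_N_MAX = 10.0
_C_MIN = 1e-12


@dataclass(frozen=True)
class DoseResponseCurve:
    """Per-dose medians of normalized reporter signal for one condition."""

    doses: tuple[float, ...]
    medians: tuple[float, ...]
    iqr: tuple[tuple[float, float], ...] | None = None
    n_events: tuple[int, ...] | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        if len(set(self.doses)) != len(self.doses):
            raise ValueError("doses must be unique")
        if len(self.medians) != len(self.doses):
            raise ValueError("one median per dose required")
        if self.iqr is not None and len(self.iqr) != len(self.doses):
            raise ValueError("one IQR per dose required")

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.doses, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.medians, dtype=float)

    def weights(self, scheme: Literal["none", "inv_iqr"]) -> np.ndarray:
        if scheme == "none" or self.iqr is None:
            return np.ones(len(self.doses))
        widths = np.array([q3 - q1 for q1, q3 in self.iqr], dtype=float)
        widths[widths <= 0] = np.nanmin(widths[widths > 0]) if np.any(widths > 0) else 1.0
        return 1.0 / widths


@dataclass
class FitResult:
    """Outcome of a (possibly joint) dose-response fit."""

    model: Literal["hill", "iffl"]
    params: dict[str, HillParams | IFFLParams]  # per condition label
    shared: frozenset[str] = frozenset()
    rss: float = np.nan
    converged: bool = False
    unidentifiable: bool = False
    warnings: tuple[str, ...] = ()
    uncertainty: dict[str, dict[str, tuple[float, float]]] | None = None
    n_boot: int = 0
    n_boot_failed: int = 0
    seed: int | None = None

    def single(self) -> HillParams | IFFLParams:
        """The parameter set of a single-condition fit."""
        (p,) = self.params.values()
        return p

    def to_dict(self) -> dict:
        from dataclasses import asdict as _asdict

        return {
            "model": self.model,
            "params": {
                k: _asdict(v) for k, v in self.params.items()
            },
            "shared": sorted(self.shared),
            "rss": self.rss,
            "converged": self.converged,
            "unidentifiable": self.unidentifiable,
            "warnings": list(self.warnings),
            "uncertainty": self.uncertainty,
            "n_boot": self.n_boot,
        }


def _is_flat(y: np.ndarray, rel_tol: float = 1e-9) -> bool:
    scale = max(np.abs(y).max(), np.finfo(float).tiny)
    return (y.max() - y.min()) <= rel_tol * scale


def _hill_starts(curve: DoseResponseCurve) -> list[dict[str, float]]:
    """Deterministic multistart grid: A from the curve minimum, B/C from
    its span, C over decades, n over {1, 2, 4}."""
    y = curve.y
    a0 = max(float(y.min()), 0.0)
    span = max(float(y.max() - y.min()), 1e-12)
    starts = []
    for c0 in (0.1, 1.0, 10.0):
        for n0 in (1.0, 2.0, 4.0):
            starts.append(
                {"A": a0, "B": span * c0, "C": c0, "n": n0}
            )
    return starts


def _make_params(
    start: Mapping[str, float], model: str, suffix: str = ""
) -> lmfit.Parameters:
    ps = lmfit.Parameters()
    ps.add(f"A{suffix}", value=start["A"], min=0.0)
    ps.add(f"B{suffix}", value=max(start["B"], 1e-9), min=0.0)
    ps.add(f"C{suffix}", value=max(start["C"], _C_MIN), min=_C_MIN)
    ps.add(f"n{suffix}", value=start["n"], min=1e-3, max=_N_MAX)
    if model == "iffl":
        ps.add(f"D{suffix}", value=start.get("D", 0.1), min=0.0)
        ps.add(f"E{suffix}", value=start.get("E", 0.01), min=0.0)
    return ps


def _eval(model: str, x: np.ndarray, v: Mapping[str, float], suffix: str = ""):
    if model == "hill":
        p = HillParams(
            v[f"A{suffix}"], v[f"B{suffix}"], v[f"C{suffix}"], v[f"n{suffix}"]
        )
        return hill_response(x, p)
    p = IFFLParams(
        v[f"A{suffix}"],
        v[f"B{suffix}"],
        v[f"C{suffix}"],
        v[f"n{suffix}"],
        v[f"D{suffix}"],
        v[f"E{suffix}"],
    )
    return iffl_response(x, p)


def _minimize(params, resid_fn) -> lmfit.minimizer.MinimizerResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lmfit.minimize(
            resid_fn,
            params,
            method="least_squares",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )


def fit_hill(
    curve: DoseResponseCurve,
    weights: Literal["none", "inv_iqr"] = "none",
    *,
    starts: Sequence[Mapping[str, float]] | None = None,
) -> FitResult:
    """Fit the Hill amplifier model to one dose-response curve.

    Multistart bounded least squares on the per-dose medians; pass
    ``starts`` to override the default deterministic start grid (e.g. a
    single warm start when refitting bootstrap replicates).  A flat curve
    is flagged unidentifiable (the Hill coefficient is then unconstrained)
    rather than silently returned as a success.
    """
    if len(curve.doses) < 4:
        raise ValueError("need at least 4 distinct doses for 4 parameters")
    x, y = curve.x, curve.y
    w = curve.weights(weights)
    if _is_flat(y):
        flat = HillParams(max(float(y.mean()), 0.0), 0.0, 1.0, 1.0)
        return FitResult(
            model="hill",
            params={curve.condition or "curve": flat},
            converged=False,
            unidentifiable=True,
            warnings=("flat curve: B ≈ 0, n unconstrained",),
        )

    best = None
    for start in starts if starts is not None else _hill_starts(curve):
        params = _make_params(start, "hill")
        res = _minimize(params, lambda ps: w * (_eval("hill", x, ps.valuesdict()) - y))
        if best is None or res.chisqr < best.chisqr:
            best = res
    v = best.params.valuesdict()
    fitted = HillParams(v["A"], v["B"], v["C"], v["n"])
    return FitResult(
        model="hill",
        params={curve.condition or "curve": fitted},
        rss=float(best.chisqr),
        converged=bool(best.success),
    )


def fit_hill_joint(
    curves: Sequence[DoseResponseCurve],
    shared: set[str] | frozenset[str],
    weights: Literal["none", "inv_iqr"] = "none",
) -> FitResult:
    """Jointly fit Hill curves with parameters tied across conditions.

    One optimization over the concatenated residuals; each name in
    ``shared`` (⊆ {A, B, C, n}) is a single parameter common to all
    conditions — sharing {"C"} fixes the saturation coefficient between a
    feedback curve and its control.  The joint RSS is never below the sum
    of the independent-fit RSS values (nested models).
    """
    shared = frozenset(shared)
    if not shared <= {"A", "B", "C", "n"}:
        raise ValueError("shared must be a subset of {A, B, C, n}")
    if len(curves) < 2:
        raise ValueError("joint fit needs at least 2 curves")
    labels = [c.condition or f"curve{i}" for i, c in enumerate(curves)]
    if len(set(labels)) != len(labels):
        raise ValueError("curve condition labels must be unique")

    starts_per_curve = [_hill_starts(c) for c in curves]
    n_starts = len(starts_per_curve[0])
    ws = [c.weights(weights) for c in curves]

    best = None
    for k in range(n_starts):
        params = lmfit.Parameters()
        for i, c in enumerate(curves):
            sp = _make_params(starts_per_curve[i][k], "hill", suffix=f"_{i}")
            for pname in sp:
                params[pname] = sp[pname]
        for name in shared:
            for i in range(1, len(curves)):
                params[f"{name}_{i}"].expr = f"{name}_0"

        def resid(ps):
            v = ps.valuesdict()
            return np.concatenate(
                [
                    ws[i] * (_eval("hill", c.x, v, suffix=f"_{i}") - c.y)
                    for i, c in enumerate(curves)
                ]
            )

        res = _minimize(params, resid)
        if best is None or res.chisqr < best.chisqr:
            best = res
    v = best.params.valuesdict()
    out_params = {
        label: HillParams(
            v[f"A_{i}"], v[f"B_{i}"], v[f"C_{i}"], v[f"n_{i}"]
        )
        for i, label in enumerate(labels)
    }
    return FitResult(
        model="hill",
        params=out_params,
        shared=shared,
        rss=float(best.chisqr),
        converged=bool(best.success),
    )


def fit_iffl(
    curve: DoseResponseCurve,
    weights: Literal["none", "inv_iqr"] = "none",
    *,
    normalize_to_untreated: bool = False,
    degeneracy_rtol: float = 0.05,
    starts: Sequence[Mapping[str, float]] | None = None,
) -> FitResult:
    """Fit the band-pass (incoherent feed-forward) model to one curve.

    Six free parameters; with ``normalize_to_untreated=True`` the medians
    are first divided by the zero-dose median.  When the fitted D̂ ≈ Ê the
    inhibitory factor is ≈ 1 and the two arms are unidentifiable from
    monotone data — flagged with a warning rather than hidden.
    """
    if len(curve.doses) < 6:
        raise ValueError("need at least 6 distinct doses for 6 parameters")
    x, y = curve.x, curve.y
    if normalize_to_untreated:
        if 0.0 not in curve.doses:
            raise ValueError("normalization requires a zero-dose point")
        y0 = y[curve.x == 0.0][0]
        if y0 <= 0:
            raise ZeroDivisionError("untreated median must be positive")
        y = y / y0
    w = curve.weights(weights)
    if _is_flat(y):
        flat = IFFLParams(max(float(y.mean()), 0.0), 0.0, 1.0, 1.0, 0.0, 0.0)
        return FitResult(
            model="iffl",
            params={curve.condition or "curve": flat},
            converged=False,
            unidentifiable=True,
            warnings=("flat curve: B ≈ 0, n unconstrained",),
        )
    if starts is not None:
        start_list = list(starts)
    else:
        start_list = [
            {**start, "D": d0, "E": e0}
            for start in _hill_starts(curve)
            for d0, e0 in ((0.01, 0.01), (0.1, 0.01), (1.0, 0.01), (1.0, 1.0))
        ]
    best = None
    for start in start_list:
        params = _make_params(start, "iffl")
        res = _minimize(
            params, lambda ps: w * (_eval("iffl", x, ps.valuesdict()) - y)
        )
        if best is None or res.chisqr < best.chisqr:
            best = res
    v = best.params.valuesdict()
    fitted = IFFLParams(v["A"], v["B"], v["C"], v["n"], v["D"], v["E"])
    warns = []
    scale = max(fitted.D, fitted.E, 1e-12)
    if abs(fitted.D - fitted.E) <= degeneracy_rtol * scale:
        warns.append(
            "D ≈ E: inhibitory factor ≈ 1; curve is effectively Hill-shaped "
            "and (D, E) are unidentifiable"
        )
    return FitResult(
        model="iffl",
        params={curve.condition or "curve": fitted},
        rss=float(best.chisqr),
        converged=bool(best.success),
        warnings=tuple(warns),
    )


def bootstrap_uncertainty(
    events_by_dose: Mapping[float, np.ndarray],
    fit_op: Callable[[DoseResponseCurve], FitResult],
    n_boot: int = 200,
    seed: int = 0,
    *,
    condition: str = "curve",
    max_failure_frac: float = 0.2,
    refit_from_base: bool = True,
) -> FitResult:
    """Percentile bootstrap intervals from within-dose event resampling.

    For each replicate, events are resampled with replacement within every
    dose, per-dose medians recomputed, and the model refit; the 2.5/97.5
    percentiles of each parameter across replicates form the nominal 95%
    interval.  Fully seeded.  With ``refit_from_base`` (default) the
    replicates are refit from a single warm start at the base estimate —
    bootstrap perturbations are small, so the full multistart grid is
    unnecessary.  Refit failures are counted; more than
    ``max_failure_frac`` of them is an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    doses = sorted(events_by_dose)
    arrays = [np.asarray(events_by_dose[d], dtype=float) for d in doses]
    base_curve = DoseResponseCurve(
        doses=tuple(doses),
        medians=tuple(float(np.median(a)) for a in arrays),
        condition=condition,
    )
    base = fit_op(base_curve)
    pnames = list(vars(base.single()))
    if refit_from_base and base.converged:
        warm = [{k: getattr(base.single(), k) for k in pnames}]
        if base.model == "hill":
            refit = lambda c: fit_hill(c, starts=warm)  # noqa: E731
        else:
            refit = lambda c: fit_iffl(c, starts=warm)  # noqa: E731
    else:
        refit = fit_op

    rng = np.random.default_rng(seed)
    draws: list[dict[str, float]] = []
    failures = 0
    for _ in range(n_boot):
        medians = tuple(
            float(np.median(a[rng.integers(0, len(a), len(a))]))
            for a in arrays
        )
        curve = DoseResponseCurve(
            doses=tuple(doses), medians=medians, condition=condition
        )
        try:
            res = refit(curve)
            if not res.converged:
                failures += 1
                continue
            p = res.single()
            draws.append({k: getattr(p, k) for k in pnames})
        except Exception:
            failures += 1
    if failures > max_failure_frac * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap refits failed "
            f"(> {max_failure_frac:.0%} allowed)"
        )
    intervals = {
        k: tuple(
            np.percentile([d[k] for d in draws], [2.5, 97.5]).tolist()
        )
        for k in pnames
    }
    base.uncertainty = {condition: intervals}
    base.n_boot = n_boot
    base.n_boot_failed = failures
    base.seed = seed
    return base
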