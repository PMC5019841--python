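"""Steady-state dose-response models for the rewired mating pathway.

Two phenomenological models describe the median reporter output as a
function of the pheromone (α-factor) dose ``x`` in µM:

* a saturating Hill-type *amplifier*,

  .. math:: Y(x) = A + \\frac{B x^n}{1 + C x^n}

  where ``A`` is the baseline (uninduced) signal, ``B/C`` the induced span,
  and ``n`` the apparent Hill coefficient;

* a *band-pass* form arising from a hybrid incoherent feed-forward loop in
  which the kinase both drives reporter transcription and degrades the
  reporter protein,

  .. math:: Y(x) = A + \\frac{B x^n}{1 + C x^n}\\cdot\\frac{1 + E x}{1 + D x}

  which reduces exactly to the Hill form when ``D = E`` and exhibits an
  interior maximum when the inhibitory arm dominates at high dose
  (``D > E``).

The degradation factor multiplies only the induced term, not the baseline
``A``: ``A`` represents background/autofluorescence, which the degradation
arm does not act on.  (The alternative grouping, with the factor applied to
the whole expression, is available via ``apply_factor_to_baseline=True`` on
:func:`iffl_response`.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HillParams",
    "IFFLParams",
    "hill_response",
    "iffl_response",
    "max_activation",
    "percent_reduction",
    "bandpass_peak",
    "classify_response",
]


@dataclass(frozen=True)
class HillParams:
    """Parameters of the Hill-type amplifier response.

    Attributes
    ----------
    A : baseline signal (normalized-fluorescence units), ≥ 0
    B : response numerator coefficient (signal · µM⁻ⁿ), ≥ 0
    C : saturation coefficient (µM⁻ⁿ), > 0
    n : apparent Hill coefficient (dimensionless), > 0
    """

    A: float
    B: float
    C: float
    n: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("A and B must be non-negative")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient n must be positive")

    def to_json(self) -> str:
        return json.dumps({"model": "hill", **asdict(self)})

    @classmethod
    def from_json(cls, s: str) -> "HillParams":
        d = json.loads(s)
        d.pop("model", None)
        return cls(**d)


@dataclass(frozen=True)
class IFFLParams:
    """Parameters of the incoherent-feed-forward band-pass response.

    Extends :class:`HillParams` with the inhibitory-arm coefficients
    ``D`` (saturation, µM⁻¹) and ``E`` (residual, µM⁻¹); ``D > E`` gives
    band-pass behaviour, ``D = E`` collapses to the Hill form.
    """

    A: float
    B: float
    C: float
    n: float
    D: float
    E: float

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("A and B must be non-negative")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient n must be positive")
        if self.D < 0 or self.E < 0:
            raise ValueError("D and E must be non-negative")

    @property
    def hill(self) -> HillParams:
        return HillParams(self.A, self.B, self.C, self.n)

    def to_json(self) -> str:
        return json.dumps({"model": "iffl", **asdict(self)})

    @classmethod
    def from_json(cls, s: str) -> "IFFLParams":
        d = json.loads(s)
        d.pop("model", None)
        return cls(**d)


def params_from_json(s: str) -> "HillParams | IFFLParams":
    """Load either parameter set from its JSON serialization."""
    d = json.loads(s)
    model = d.pop("model", None)
    if model == "iffl" or (model is None and "D" in d):
        return IFFLParams(**d)
    return HillParams(**d)


def _check_dose(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("doses must be non-negative")
    return x


def hill_response(x, p: HillParams):
    """Evaluate ``A + B·xⁿ / (1 + C·xⁿ)`` at dose(s) ``x`` (µM).

    Monotone non-decreasing in ``x``; equals ``A`` at ``x = 0`` and
    approaches ``A + B/C`` as ``x → ∞``.
    """
    x = _check_dose(x)
    xn = np.power(x, p.n)
    out = p.A + p.B * xn / (1.0 + p.C * xn)
    return out if out.ndim else float(out)


def iffl_response(x, p: IFFLParams, *, apply_factor_to_baseline: bool = False):
    """Evaluate ``A + [B·xⁿ/(1+C·xⁿ)]·[(1+E·x)/(1+D·x)]`` at dose(s) ``x``.

    Reduces exactly to :func:`hill_response` when ``D == E``.  With
    ``apply_factor_to_baseline=True`` the degradation factor multiplies the
    baseline ``A`` as well (alternative reading of the closed form).
    """
    x = _check_dose(x)
    xn = np.power(x, p.n)
    induced = p.B * xn / (1.0 + p.C * xn)
    factor = (1.0 + p.E * x) / (1.0 + p.D * x)
    if apply_factor_to_baseline:
        out = (p.A + induced) * factor
    else:
        out = p.A + induced * factor
    return out if out.ndim else float(out)


def max_activation(p: HillParams) -> float:
    """Maximal pathway activation ``A + B/C`` (the x → ∞ limit)."""
    if p.C == 0:
        raise ZeroDivisionError("C must be nonzero for a finite maximum")
    return p.A + p.B / p.C


def percent_reduction(
    feedback: HillParams,
    control: HillParams,
    *,
    include_baseline: bool = False,
) -> float:
    """Percent reduction in maximal activation caused by negative feedback.

    Returns ``100·(1 − max_fb / max_ctrl)``.  By default the maxima are the
    induced spans ``B/C`` — baseline autofluorescence ``A`` is not pathway
    activation; pass ``include_baseline=True`` to compare ``A + B/C``
    instead.
    """
    if include_baseline:
        m_fb, m_ctrl = max_activation(feedback), max_activation(control)
    else:
        m_fb, m_ctrl = feedback.B / feedback.C, control.B / control.C
    if m_ctrl == 0:
        raise ZeroDivisionError("control maximal activation is zero")
    return 100.0 * (1.0 - m_fb / m_ctrl)


def _iffl_dlog(x: float, p: IFFLParams) -> float:
    # d/dx log of the induced term B x^n/(1+Cx^n) * (1+Ex)/(1+Dx);
    # zero-crossings locate interior extrema of the A=0 response.
    xn = x**p.n
    return (
        p.n / x
        - p.n * p.C * xn / (x * (1.0 + p.C * xn))
        + p.E / (1.0 + p.E * x)
        - p.D / (1.0 + p.D * x)
    )


def bandpass_peak(
    p: IFFLParams,
    *,
    x_range: tuple[float, float] = (1e-6, 1e6),
    n_grid: int = 4000,
) -> float | None:
    """Dose (µM) of the interior maximum of the band-pass response, if any.

    Scans a log-spaced grid for a sign change of the derivative of the
    induced term and polishes it with a bracketed root solve; returns
    ``None`` when the response is monotone (e.g. ``D ≤ E``), in which case
    no band-pass peak exists.

    The peak is defined on the dose-dependent (induced) part of the
    response; the additive baseline ``A`` does not shift it.
    """
    if p.D <= p.E:
        return None  # factor non-decreasing -> response monotone
    grid = np.geomspace(x_range[0], x_range[1], n_grid)
    d = np.array([_iffl_dlog(x, p) for x in grid])
    sign = np.sign(d)
    crossings = np.nonzero((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    if crossings.size == 0:
        return None
    i = crossings[0]
    x_star = brentq(_iffl_dlog, grid[i], grid[i + 1], args=(p,), xtol=1e-12)
    # local grid refinement confirms an interior maximum, not a saddle
    probe = x_star * np.array([0.99, 1.0, 1.01])
    y = iffl_response(probe, p)
    if not (y[1] >= y[0] and y[1] >= y[2]):
        return None
    return float(x_star)


def classify_response(
    doses: Sequence[float],
    signals: Sequence[float],
    rel_tol: float = 0.05,
) -> Literal["amplifier", "bandpass", "flat"]:
    """Classify a sampled dose-response curve.

    ``bandpass``  — some interior point exceeds both endpoints by more than
    ``rel_tol`` (relative); ``amplifier`` — the final point is the maximum
    and exceeds the zero-dose baseline by more than ``rel_tol``; ``flat``
    otherwise.  Requires at least five dose points including dose 0,
    sorted ascending.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(signals, dtype=float)
    if doses.size != y.size:
        raise ValueError("doses and signals must have the same length")
    if doses.size < 5:
        raise ValueError("need at least 5 dose points")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be sorted strictly ascending")
    if doses[0] != 0:
        raise ValueError("curve must include dose 0")

    scale = max(abs(y).max(), np.finfo(float).tiny)
    interior_max = y[1:-1].max() if y.size > 2 else -np.inf
    if (interior_max - y[0] > rel_tol * scale) and (
        interior_max - y[-1] > rel_tol * scale
    ):
        return "bandpass"
    if y[-1] >= y.max() - rel_tol * scale and (y[-1] - y[0] > rel_tol * scale):
        return "amplifier"
    return "flat"
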