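"""Kinetic summary metrics and derived risk-assessment quantities.

Cmax, windowed and extrapolated AUC, the steady-state (24 h average)
blood concentration, per-conjugate pathway fractions of the absorbed
dose, and the percent-of-reference / fold-ratio arithmetic used when
internal doses are compared against a tolerable-daily-intake anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import SimulationResult


class IncompleteAbsorptionError(RuntimeError):
    """Depot residual too large for pathway fractions; simulate longer."""


def cmax(result: SimulationResult, tissue: str) -> float:
    """Maximum concentration (µg/L) of a compartment on the output grid."""
    series = result.concentration(tissue)
    if series.size == 0:
        raise ValueError("empty concentration series")
    return float(series.max())


def auc(
    result: SimulationResult, tissue: str, window: tuple[float, float] | None = None
) -> float:
    """Trapezoidal AUC (µg/L x h) of a compartment over a time window."""
    t = result.time
    series = result.concentration(tissue)
    if window is not None:
        t0, t1 = window
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9 or t1 <= t0:
            raise ValueError(
                f"window {window} outside simulated span ({t[0]}, {t[-1]})"
            )
        mask = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
        t, series = t[mask], series[mask]
    if t.size < 2:
        raise ValueError("window contains fewer than two grid points")
    return float(np.trapezoid(series, t))


def auc_to_infinity(
    result: SimulationResult, tissue: str, tail_tol: float = 1e-3
) -> float:
    """AUC(0->inf): trapezoidal AUC plus a terminal log-linear tail.

    The terminal slope is fitted to the last tenth of the simulated span;
    the extrapolated tail must contribute less than ``tail_tol`` of the
    total, otherwise the simulation was too short to truncate.
    """
    t = result.time
    series = result.concentration(tissue)
    body = float(np.trapezoid(series, t))
    c_end = float(series[-1])
    if c_end <= 0 or body == 0:
        return body
    mask = (t >= t[-1] - 0.1 * (t[-1] - t[0])) & (series > 0)
    if mask.sum() < 3:
        raise ValueError("too few terminal points to fit a slope")
    slope = np.polyfit(t[mask], np.log(series[mask]), 1)[0]
    if slope >= 0:
        raise ValueError("terminal concentration not declining; simulate longer")
    tail = c_end / -slope
    total = body + tail
    if tail > tail_tol * total:
        raise ValueError(
            f"extrapolated tail is {tail / total:.2%} of AUC (> {tail_tol:.1%}); "
            "simulate a longer horizon"
        )
    return total


def steady_state_concentration(result: SimulationResult) -> float:
    """24 h time-average blood concentration of a converged periodic day."""
    if not result.periodic:
        raise ValueError(
            "steady-state concentration requires a run_to_steady_state result"
        )
    span = result.time[-1] - result.time[0]
    return auc(result, "blood") / span


def pathway_fractions(
    result: SimulationResult, residual_tol: float = 1e-3
) -> dict[str, float]:
    """Fraction of the absorbed dose excreted via each conjugate.

    For single-run results absorption must be essentially complete
    (residual depots below ``residual_tol`` of the input) so that the
    cumulative conjugate amounts partition the absorbed amount.  For
    periodic-day results the day increments are used directly.
    """
    led = result.ledgers
    absorbed = float(led["absorbed"][-1] - led["absorbed"][0])
    if absorbed <= 0:
        raise ValueError("no absorbed amount; cannot form pathway fractions")
    if not result.periodic:
        residual = float(led["residual_gut"][-1] + led["residual_skin"][-1])
        total_in = float(led["input_total"][-1])
        if residual > residual_tol * max(total_in, 1e-12):
            raise IncompleteAbsorptionError(
                f"depot residual is {residual / total_in:.2%} of the input "
                f"(> {residual_tol:.1%}); simulate longer before computing "
                "pathway fractions"
            )
    return {
        name.removeprefix("metabolized_"): float(series[-1] - series[0]) / absorbed
        for name, series in led.items()
        if name.startswith("metabolized_")
    }


def percent_of_reference(value: float, reference: float) -> float:
    """100 x value / reference (e.g. percent of the SSC at the TDI)."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return 100.0 * value / reference


def fold_ratio(a: float, b: float) -> float:
    """Fold difference a/b between two positive metrics."""
    if b <= 0:
        raise ValueError(f"denominator must be > 0, got {b}")
    return a / b


@dataclass(frozen=True)
class DoseMetrics:
    """Per-tissue Cmax and AUC plus blood average for one scenario run."""

    cmax: Mapping[str, float]  # µg/L
    auc: Mapping[str, float]  # µg/L x h
    window: tuple[float, float]
    blood_average: float  # µg/L

    @classmethod
    def from_result(
        cls, result: SimulationResult, tissues: tuple[str, ...] = ("blood", "liver", "kidney")
    ) -> "DoseMetrics":
        window = (float(result.time[0]), float(result.time[-1]))
        return cls(
            cmax={t: cmax(result, t) for t in tissues},
            auc={t: auc(result, t) for t in tissues},
            window=window,
            blood_average=auc(result, "blood") / (window[1] - window[0]),
        )
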