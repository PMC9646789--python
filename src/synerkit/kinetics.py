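"""Reaction velocities and percent inhibition from absorbance-time traces.

The assay behind these types is a coupled colorimetric DHODH test:
dihydroorotate oxidation is stoichiometric with DCIP reduction, read as a
linear decline in A600 over a short kinetic window. The reaction velocity
is the ordinary-least-squares slope of A600 on time (dA/min); inhibition
of the enzyme shows up as a shallower slope relative to the uninhibited
control, and

    inhibition% = (slope_control - slope_sample) / slope_control * 100.

Dividing by 100 gives the fraction affected fa consumed by the
median-effect stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import (
    DomainError,
    InsufficientDataError,
    MissingControlError,
    UndefinedControlError,
)

logger = logging.getLogger(__name__)

#: fa window, outside which points are flagged non-fittable by default.
DEFAULT_CLIP_BOUNDS = (0.005, 0.995)

# Tie tolerance when comparing r^2 between candidate windows.
_R2_TIE = 1e-12


@dataclass(frozen=True)
class AbsorbanceTrace:
    """One well's kinetic read: A600 versus time for a single (agent, dose, replicate)."""

    times: np.ndarray  # minutes, strictly increasing
    a600: np.ndarray  # absorbance units
    agent: str
    dose: float  # concentration in the agent's unit; 0 for controls
    dose_unit: str
    replicate: int = 1
    is_control: bool = False

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        a600 = np.asarray(self.a600, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "a600", a600)
        if times.ndim != 1 or a600.shape != times.shape:
            raise DomainError("times and a600 must be 1-D arrays of equal length")
        if len(times) < 3:
            raise DomainError(
                f"trace for agent {self.agent!r} has {len(times)} timepoints; need >= 3"
            )
        if not np.all(np.diff(times) > 0):
            raise DomainError(f"times must be strictly increasing (agent {self.agent!r})")
        if self.dose < 0:
            raise DomainError(f"dose must be >= 0, got {self.dose}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class VelocityEstimate:
    """OLS slope of A600 on time over a selected window (the assay's dA/min)."""

    slope: float  # absorbance units per minute
    intercept: float  # absorbance units
    r_squared: float
    window: tuple[int, int]  # [start, stop) index range used

    def __post_init__(self):
        if self.window[1] - self.window[0] < 3:
            raise DomainError("velocity window must span >= 3 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class DoseEffectPoint:
    """A (dose, fraction-affected) observation for one agent.

    ``fittable`` marks whether the point may enter a median-effect fit:
    the log transform is undefined at fa in {0, 1} and near-boundary
    points dominate it, so only points with
    clip_low <= fa <= clip_high (and dose > 0) are fittable. Flagged
    points are retained for reporting, never silently dropped.
    """

    agent: str
    dose: float
    dose_unit: str
    fa: float
    n_replicates: int = 1
    fittable: bool = True

    def __post_init__(self):
        if not math.isfinite(self.fa):
            raise DomainError(f"fa must be finite, got {self.fa}")
        if self.fittable and self.dose <= 0:
            raise DomainError(f"fittable point requires dose > 0, got {self.dose}")


def flag_point(
    agent: str,
    dose: float,
    dose_unit: str,
    fa: float,
    n_replicates: int = 1,
    clip_bounds: tuple[float, float] = DEFAULT_CLIP_BOUNDS,
) -> DoseEffectPoint:
    """Build a DoseEffectPoint, setting ``fittable`` from dose and clip bounds."""
    lo, hi = clip_bounds
    fittable = dose > 0 and lo <= fa <= hi
    if not fittable:
        logger.warning(
            "dose-effect point flagged non-fittable: agent=%s dose=%g fa=%g "
            "(clip bounds %g..%g)",
            agent, dose, fa, lo, hi,
        )
    return DoseEffectPoint(agent, dose, dose_unit, fa, n_replicates, fittable)


# ---------------------------------------------------------------------------
# velocity estimation
# ---------------------------------------------------------------------------

def _ols_window(times: np.ndarray, a600: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r^2 of an OLS line over one window.

    A flat (zero-variance) signal is a perfect fit of a zero-slope line,
    so r^2 is 1 when both total and residual sums of squares vanish.
    """
    slope, intercept = np.polyfit(times, a600, 1)
    fitted = slope * times + intercept
    ss_res = float(np.sum((a600 - fitted) ** 2))
    ss_tot = float(np.sum((a600 - a600.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return float(slope), float(intercept), r2


def fit_velocity(trace: AbsorbanceTrace, mode: str = "full") -> VelocityEstimate:
    """Estimate the reaction velocity (dA/min) of one trace.

    mode "full" regresses over all timepoints. mode "auto" picks, among all
    contiguous windows of length >= max(3, ceil(n/2)), the one maximising
    r^2 — ties broken by the earlier, then the longer, window — which
    drops leading/trailing curvature or an outlying read while keeping at
    least half of the trace.
    """
    n = len(trace)
    if mode == "full":
        slope, intercept, r2 = _ols_window(trace.times, trace.a600)
        return VelocityEstimate(slope, intercept, r2, (0, n))
    if mode != "auto":
        raise DomainError(f"unknown velocity window mode {mode!r}")

    min_len = max(3, math.ceil(n / 2))
    if n < min_len:
        raise InsufficientDataError(f"trace has {n} points; need >= {min_len}")
    best: tuple[float, float, float, tuple[int, int]] | None = None
    # iterate starts ascending, lengths descending so the first strict
    # improvement implements the (earlier, then longer) tie rule
    for start in range(0, n - min_len + 1):
        for stop in range(n, start + min_len - 1, -1):
            s, b, r2 = _ols_window(trace.times[start:stop], trace.a600[start:stop])
            if best is None or r2 > best[2] + _R2_TIE:
                best = (s, b, r2, (start, stop))
    assert best is not None
    return VelocityEstimate(best[0], best[1], best[2], best[3])


# ---------------------------------------------------------------------------
# percent inhibition and dose-effect assembly
# ---------------------------------------------------------------------------

def percent_inhibition(slope_control: float, slope_sample: float) -> float:
    """Percent inhibition of the enzyme from control and sample velocities.

    Values below 0 (apparent activation) or above 100 are returned as
    computed — clamping would hide assay problems — with a logged warning.
    """
    if slope_control == 0:
        raise UndefinedControlError("control slope is zero; inhibition undefined")
    value = (slope_control - slope_sample) / slope_control * 100.0
    if not (0.0 <= value <= 100.0):
        logger.warning("percent inhibition out of [0, 100]: %.4f", value)
    return value


def build_dose_effect(
    traces: Iterable[AbsorbanceTrace],
    *,
    clip_bounds: tuple[float, float] = DEFAULT_CLIP_BOUNDS,
    velocity_mode: str = "full",
) -> list[DoseEffectPoint]:
    """Convert kinetic traces into per-(agent, dose) dose-effect points.

    Replicate velocities are averaged first and the mean slope converted to
    inhibition against the mean control slope (not a mean of per-replicate
    inhibitions), matching a velocity estimated from the pooled linear
    region. Controls for an agent are its own ``is_control`` traces when
    present, otherwise the pooled controls of the batch.
    """
    traces = list(traces)
    controls = [t for t in traces if t.is_control]
    samples = [t for t in traces if not t.is_control]
    if samples and not controls:
        raise MissingControlError("no control trace in batch")

    control_slope_by_agent: dict[str, float] = {}
    pooled = (
        float(np.mean([fit_velocity(t, velocity_mode).slope for t in controls]))
        if controls
        else math.nan
    )
    points: list[DoseEffectPoint] = []
    by_agent: dict[str, list[AbsorbanceTrace]] = {}
    for t in samples:
        by_agent.setdefault(t.agent, []).append(t)

    for agent in sorted(by_agent):
        own = [t for t in controls if t.agent == agent]
        if own:
            c_slope = float(np.mean([fit_velocity(t, velocity_mode).slope for t in own]))
        else:
            c_slope = pooled
        control_slope_by_agent[agent] = c_slope
        group: dict[float, list[AbsorbanceTrace]] = {}
        for t in by_agent[agent]:
            group.setdefault(t.dose, []).append(t)
        unit = by_agent[agent][0].dose_unit
        for dose in sorted(group):
            reps = group[dose]
            mean_slope = float(np.mean([fit_velocity(t, velocity_mode).slope for t in reps]))
            fa = percent_inhibition(c_slope, mean_slope) / 100.0
            points.append(
                flag_point(agent, dose, unit, fa, n_replicates=len(reps), clip_bounds=clip_bounds)
            )
    logger.info(
        "build_dose_effect: %d traces in (%d controls), %d points out, %d fittable",
        len(traces), len(controls), len(points), sum(p.fittable for p in points),
    )
    return points
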