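"""Mass-action median-effect dose-effect model and its Hill alternative.

The median-effect equation relates dose D to the fraction affected fa:

    fa / fu = (D / Dm)^m,        fu = 1 - fa,

where Dm is the median-effect dose (the dose giving 50% effect, equivalent
to IC50/ED50) and m the sigmoidicity of the curve. Taking logs gives the
linear median-effect plot

    log(fa/fu) = m log(D) - m log(Dm),

so m is the plot's slope, log(Dm) its x-intercept, and the Pearson
correlation r of the transformed points measures conformity to mass
action. Dm, m and r are *defined* through this linearisation, so the fit
is ordinary least squares on the transformed coordinates, not nonlinear
least squares on fa; a separately fitted logistic (Hill) curve is provided
for the conventional IC50 route, and the two coincide on noiseless data
when the logistic floor/ceiling are fixed at 0/100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .errors import (
    ConvergenceError,
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
    UnitConsistencyError,
)
from .kinetics import DoseEffectPoint

#: log base used for median-effect plot coordinates (slope and r are
#: base-invariant; Dm via the x-intercept is base-consistent).
DEFAULT_LOG_BASE = 10.0


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters of one agent (or of a fixed-ratio mixture).

    Dm is in the agent's dose unit, m is dimensionless, r is the linear
    correlation coefficient of the median-effect plot.
    """

    agent: str
    Dm: float
    m: float
    r: float
    n_points: int
    dose_unit: str = ""

    def __post_init__(self):
        if not (self.Dm > 0 and math.isfinite(self.Dm)):
            raise DomainError(f"Dm must be positive and finite, got {self.Dm}")
        if not math.isfinite(self.m) or self.m == 0:
            raise DomainError(f"m must be finite and nonzero, got {self.m}")
        if not (-1.0 <= self.r <= 1.0 + 1e-12):
            raise DomainError(f"r out of [-1, 1]: {self.r}")
        if self.n_points < 2:
            raise DomainError("n_points must be >= 2")

    @classmethod
    def from_parameters(
        cls, agent: str, Dm: float, m: float, dose_unit: str = ""
    ) -> "MedianEffectFit":
        """An analytically specified curve (exactly determined, r = 1)."""
        return cls(agent=agent, Dm=Dm, m=m, r=1.0, n_points=2, dose_unit=dose_unit)


@dataclass(frozen=True)
class HillFit:
    """Logistic dose-response fit: inhibition% = bottom + (top-bottom)/(1+(ic50/D)^h)."""

    ic50: float
    hill_slope: float
    bottom: float
    top: float
    converged: bool
    rss: float

    def __post_init__(self):
        if self.ic50 <= 0:
            raise DomainError(f"ic50 must be > 0, got {self.ic50}")
        if not self.bottom < self.top:
            raise DomainError("bottom must be < top")


def _fittable(points: Iterable[DoseEffectPoint]) -> list[DoseEffectPoint]:
    return [p for p in points if p.fittable]


def _check_homogeneous(points: Sequence[DoseEffectPoint]) -> None:
    if len({p.agent for p in points}) > 1:
        raise UnitConsistencyError(
            f"points span several agents: {sorted({p.agent for p in points})}"
        )
    if len({p.dose_unit for p in points}) > 1:
        raise UnitConsistencyError(
            f"agent {points[0].agent!r} mixes units: {sorted({p.dose_unit for p in points})}"
        )


def median_effect_plot_points(
    points: Iterable[DoseEffectPoint], log_base: float = DEFAULT_LOG_BASE
) -> list[tuple[float, float]]:
    """(x, y) = (log D, log fa/fu) coordinates of the median-effect plot."""
    if log_base <= 1:
        raise DomainError(f"log_base must be > 1, got {log_base}")
    lb = math.log(log_base)
    out = []
    for p in _fittable(points):
        out.append((math.log(p.dose) / lb, math.log(p.fa / (1.0 - p.fa)) / lb))
    return out


def fit_median_effect(
    points: Iterable[DoseEffectPoint], log_base: float = DEFAULT_LOG_BASE
) -> MedianEffectFit:
    """OLS fit of the median-effect plot; returns (Dm, m, r).

    Only fittable points enter (fa strictly inside the clip window); they
    must belong to one agent and unit and contain at least two distinct
    doses.
    """
    pts = _fittable(list(points))
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need >= 2 fittable points, got {len(pts)}"
        )
    _check_homogeneous(pts)
    doses = [p.dose for p in pts]
    if len(set(doses)) < 2:
        raise DegenerateDesignError("all doses identical; slope undefined")
    xy = median_effect_plot_points(pts, log_base)
    x = np.array([c[0] for c in xy])
    y = np.array([c[1] for c in xy])
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m == 0 or not math.isfinite(m):
        raise DegenerateDesignError(f"median-effect slope degenerate: {m}")
    dm = float(log_base ** (-res.intercept / m))  # antilog of the x-intercept
    return MedianEffectFit(
        agent=pts[0].agent,
        Dm=dm,
        m=m,
        r=float(res.rvalue),
        n_points=len(pts),
        dose_unit=pts[0].dose_unit,
    )


def effect_at_dose(fit: MedianEffectFit, dose: float) -> float:
    """fa at a dose: (D/Dm)^m / (1 + (D/Dm)^m), computed via a logistic for stability."""
    if dose <= 0:
        raise DomainError(f"dose must be > 0, got {dose}")
    return float(expit(fit.m * math.log(dose / fit.Dm)))


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dx, the dose producing effect fa: Dm * (fa/(1-fa))^(1/m)."""
    if not 0.0 < fa < 1.0:
        raise DomainError(f"fa must be in (0, 1), got {fa}")
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


# ---------------------------------------------------------------------------
# logistic (Hill) alternative for the IC50 route
# ---------------------------------------------------------------------------

def _hill_model(d: np.ndarray, ic50: float, slope: float, bottom: float, top: float) -> np.ndarray:
    return bottom + (top - bottom) * expit(slope * np.log(d / ic50))


def fit_hill(
    points: Iterable[DoseEffectPoint],
    *,
    bottom: float | None = 0.0,
    top: float | None = 100.0,
) -> HillFit:
    """Least-squares logistic fit of inhibition% versus dose.

    ``bottom``/``top`` fix the floor and ceiling in percent (defaults 0 and
    100, the constrained two-parameter form); pass None to free either.
    Initialisation is multi-start: the ic50 grid spans the dose quartiles
    plus a linearised median-effect guess, crossed with slope starts 0.5,
    1 and 2. ``converged`` reports the optimiser's own status for the best
    start — it is never forced.
    """
    pts = _fittable(list(points))
    n_free = 2 + (bottom is None) + (top is None)
    n_min = 5 if n_free == 4 else 3
    if len(pts) < n_min:
        raise InsufficientDataError(
            f"need >= {n_min} fittable points for {n_free} free parameters, got {len(pts)}"
        )
    _check_homogeneous(pts)
    d = np.array([p.dose for p in pts])
    y = np.array([p.fa for p in pts]) * 100.0

    ic50_starts = set(np.quantile(d, [0.25, 0.5, 0.75]).tolist())
    try:
        ic50_starts.add(fit_median_effect(pts).Dm)
    except (InsufficientDataError, DegenerateDesignError):
        pass

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_ic50, slope = theta[0], theta[1]
        k = 2
        b = theta[k] if bottom is None else bottom
        t = theta[k + (bottom is None)] if top is None else top
        return _hill_model(d, math.exp(log_ic50), slope, b, t) - y

    best = None
    for ic0 in sorted(ic50_starts):
        for s0 in (0.5, 1.0, 2.0):
            theta0 = [math.log(ic0), s0]
            if bottom is None:
                theta0.append(float(y.min()))
            if top is None:
                theta0.append(float(y.max()))
            sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=2000)
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol)
    assert best is not None
    rss, sol = best
    if not sol.success:
        raise ConvergenceError("Hill fit failed to converge from all starts", best_rss=rss)
    theta = sol.x
    k = 2
    b = theta[k] if bottom is None else bottom
    t = theta[k + (bottom is None)] if top is None else top
    return HillFit(
        ic50=float(math.exp(theta[0])),
        hill_slope=float(theta[1]),
        bottom=float(b),
        top=float(t),
        converged=bool(sol.success),
        rss=rss,
    )
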