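"""Combination index, dose-reduction index and isobologram analysis.

At an effect level fa, let (Dx)a and (Dx)b be the single-agent doses that
alone produce fa (from each agent's median-effect curve), and Da, Db the
component doses of a combination producing the same fa. The combination
index in the mutually exclusive (two-term) form is

    CI = Da/(Dx)a + Db/(Dx)b,

with CI < 1 synergism, CI = 1 additivity (the Loewe line) and CI > 1
antagonism. The dose-reduction index of each agent is DRI = (Dx)/D(combo),
the fold by which its dose can be cut at equal effect, so CI = 1/DRI_a +
1/DRI_b identically. Normalised isobologram coordinates are
(Da/(Dx)a, Db/(Dx)b); points below the unit diagonal are synergistic.

Fixed-ratio profiles derive component doses from the *mixture's own*
median-effect fit: at each fa the total mixture dose is Dc =
dose_for_effect(fit_combo, fa), split by the design's ratio fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import optimize

from .errors import DomainError, SolverError
from .median_effect import MedianEffectFit, dose_for_effect

#: Half-width of the CI band labelled additive. Practice in the field labels
#: CI within a few percent of 1 "additive"; 0.05 reflects published usage
#: where 1.03 is called additive but 1.09 antagonistic.
DEFAULT_ADDITIVE_BAND = 0.05

SYNERGISM = "synergism"
ADDITIVE = "additive"
ANTAGONISM = "antagonism"

_BRACKET = (1e-9, 1.0 - 1e-9)
_FA_TOL = 1e-12


@dataclass(frozen=True)
class FixedRatioDesign:
    """A two-agent combination series mixed at a constant dose ratio.

    ``ec_doses`` maps each agent label to its single-agent ECx doses at the
    target ``levels``; ``ratio_fractions`` gives the share of the combined
    effect-equivalent dose assigned to (agent_a, agent_b).
    """

    agent_a: str
    agent_b: str
    levels: tuple[float, ...]
    ec_doses: dict[str, tuple[float, ...]]
    ratio_fractions: tuple[float, float]

    def __post_init__(self):
        lv = self.levels
        if not all(0.0 < f < 1.0 for f in lv):
            raise DomainError("levels must lie in (0, 1)")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise DomainError("levels must be strictly increasing")
        for agent in (self.agent_a, self.agent_b):
            ec = self.ec_doses.get(agent)
            if ec is None or len(ec) != len(lv):
                raise DomainError(f"ec_doses missing or mismatched for {agent!r}")
            if any(b <= a for a, b in zip(ec, ec[1:])):
                raise DomainError(f"ec_doses must increase with level for {agent!r}")
        p, q = self.ratio_fractions
        if p < 0 or q < 0 or not math.isclose(p + q, 1.0, rel_tol=0, abs_tol=1e-9):
            raise DomainError("ratio_fractions must be non-negative and sum to 1")


@dataclass(frozen=True)
class CombinationPoint:
    """CI/DRI assessment of one combination at one effect level."""

    fa: float
    dose_a: float
    dose_b: float
    dx_a: float
    dx_b: float
    ci: float
    dri_a: float
    dri_b: float
    label: str

    def __post_init__(self):
        if self.ci <= 0:
            raise DomainError(f"ci must be > 0, got {self.ci}")


@dataclass(frozen=True)
class CombinationAssessment:
    """Full interaction profile of one fixed-ratio combination."""

    fit_combo: MedianEffectFit
    points: tuple[CombinationPoint, ...]
    #: per level: normalised isobologram coordinates (dose_a/dx_a, dose_b/dx_b)
    isobologram: tuple[tuple[float, float, float], ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# core indices
# ---------------------------------------------------------------------------

def combination_index(
    dose_a: float,
    dose_b: float,
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fa: float,
) -> float:
    """Two-term combination index at effect level fa."""
    if dose_a < 0 or dose_b < 0 or (dose_a == 0 and dose_b == 0):
        raise DomainError("doses must be >= 0 and not both zero")
    if not 0.0 < fa < 1.0:
        raise DomainError(f"fa must be in (0, 1), got {fa}")
    return dose_a / dose_for_effect(fit_a, fa) + dose_b / dose_for_effect(fit_b, fa)


def dose_reduction_index(fit: MedianEffectFit, dose_in_combo: float, fa: float) -> float:
    """DRI = Dx(alone) / dose(in combination) at effect level fa."""
    if dose_in_combo <= 0:
        raise DomainError(f"dose_in_combo must be > 0, got {dose_in_combo}")
    if not 0.0 < fa < 1.0:
        raise DomainError(f"fa must be in (0, 1), got {fa}")
    return dose_for_effect(fit, fa) / dose_in_combo


def ci_from_dri(dri_a: float, dri_b: float) -> float:
    """CI from the two dose-reduction indices: 1/DRI_a + 1/DRI_b."""
    if dri_a <= 0 or dri_b <= 0:
        raise DomainError("DRI values must be > 0")
    return 1.0 / dri_a + 1.0 / dri_b


def classify_interaction(ci: float, additive_band: float = DEFAULT_ADDITIVE_BAND) -> str:
    """Label a CI value: synergism below, additive within, antagonism above the band."""
    if ci <= 0:
        raise DomainError(f"ci must be > 0, got {ci}")
    if additive_band < 0:
        raise DomainError("additive_band must be >= 0")
    # tiny slack so a CI sitting exactly on the band edge is not pushed
    # out by floating-point representation of the band
    if abs(ci - 1.0) <= additive_band + 1e-12:
        return ADDITIVE
    return SYNERGISM if ci < 1.0 else ANTAGONISM


def isobologram_point(
    dose_a: float,
    dose_b: float,
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fa: float,
    additive_band: float = DEFAULT_ADDITIVE_BAND,
) -> tuple[tuple[float, float], str]:
    """Normalised isobologram coordinates and side of the additivity line.

    Coordinates are (dose_a/dx_a, dose_b/dx_b); their sum is the CI, so
    "below"/"on"/"above" (using the same additive band) always agrees with
    classify_interaction on the same inputs.
    """
    if dose_a < 0 or dose_b < 0 or (dose_a == 0 and dose_b == 0):
        raise DomainError("doses must be >= 0 and not both zero")
    if not 0.0 < fa < 1.0:
        raise DomainError(f"fa must be in (0, 1), got {fa}")
    xa = dose_a / dose_for_effect(fit_a, fa)
    xb = dose_b / dose_for_effect(fit_b, fa)
    total = xa + xb
    if abs(total - 1.0) <= additive_band + 1e-12:
        side = "on"
    elif total < 1.0:
        side = "below"
    else:
        side = "above"
    return (xa, xb), side


# ---------------------------------------------------------------------------
# fixed-ratio profiles and the Loewe-additive null
# ---------------------------------------------------------------------------

def default_ratio_fractions(
    fit_a: MedianEffectFit, fit_b: MedianEffectFit
) -> tuple[float, float]:
    """IC50-equivalent fixed ratio: split the combined dose in Dm proportions."""
    total = fit_a.Dm + fit_b.Dm
    return (fit_a.Dm / total, fit_b.Dm / total)


def fa_ci_profile(
    fit_combo: MedianEffectFit,
    ratio_fractions: tuple[float, float],
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fa_grid: Sequence[float],
    additive_band: float = DEFAULT_ADDITIVE_BAND,
) -> list[CombinationPoint]:
    """CI/DRI at each grid effect level for a fixed-ratio combination.

    At each fa the total mixture dose Dc comes from the mixture's own
    median-effect fit and is split by the ratio fractions into component
    doses; a zero ratio fraction yields an infinite DRI for that agent
    (its dose in the combination is zero) and CI reduces to one term.
    """
    if len(fa_grid) == 0:
        raise DomainError("fa_grid must be non-empty")
    p, q = ratio_fractions
    if p < 0 or q < 0 or not math.isclose(p + q, 1.0, rel_tol=0, abs_tol=1e-9):
        raise DomainError("ratio_fractions must be non-negative and sum to 1")
    out: list[CombinationPoint] = []
    for fa in fa_grid:
        if not 0.0 < fa < 1.0:
            raise DomainError(f"fa grid value out of (0, 1): {fa}")
        dc = dose_for_effect(fit_combo, fa)
        da, db = p * dc, q * dc
        dx_a = dose_for_effect(fit_a, fa)
        dx_b = dose_for_effect(fit_b, fa)
        ci = da / dx_a + db / dx_b
        dri_a = dx_a / da if da > 0 else math.inf
        dri_b = dx_b / db if db > 0 else math.inf
        out.append(
            CombinationPoint(
                fa=fa, dose_a=da, dose_b=db, dx_a=dx_a, dx_b=dx_b,
                ci=ci, dri_a=dri_a, dri_b=dri_b,
                label=classify_interaction(ci, additive_band),
            )
        )
    return out


def solve_loewe_mixture(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    ratio_fractions: tuple[float, float],
    total_dose: float,
) -> float:
    """Effect of a Loewe-additive mixture at a given total dose.

    Solves p*Dc/Dx_a(fa) + q*Dc/Dx_b(fa) = 1 for fa by bisection on
    (1e-9, 1-1e-9). The left side is strictly decreasing in fa for m > 0,
    so the root is unique whenever the bracket straddles it.
    """
    if total_dose <= 0:
        raise DomainError(f"total_dose must be > 0, got {total_dose}")
    p, q = ratio_fractions
    if p < 0 or q < 0 or not math.isclose(p + q, 1.0, rel_tol=0, abs_tol=1e-9):
        raise DomainError("ratio_fractions must be non-negative and sum to 1")

    def g(fa: float) -> float:
        term_a = p * total_dose / dose_for_effect(fit_a, fa) if p > 0 else 0.0
        term_b = q * total_dose / dose_for_effect(fit_b, fa) if q > 0 else 0.0
        return term_a + term_b - 1.0

    lo, hi = _BRACKET
    g_lo, g_hi = g(lo), g(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if g_lo < 0.0 or g_hi > 0.0:
        raise SolverError(
            f"no sign change on bracket: g({lo}) = {g_lo:.3g}, g({hi}) = {g_hi:.3g}",
            bracket=((lo, g_lo), (hi, g_hi)),
        )
    return float(optimize.bisect(g, lo, hi, xtol=_FA_TOL, maxiter=200))


def assess_combination(
    fit_combo: MedianEffectFit,
    ratio_fractions: tuple[float, float],
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fa_grid: Sequence[float],
    additive_band: float = DEFAULT_ADDITIVE_BAND,
) -> CombinationAssessment:
    """fa-CI profile plus normalised isobologram coordinates for each level."""
    points = fa_ci_profile(fit_combo, ratio_fractions, fit_a, fit_b, fa_grid, additive_band)
    iso = tuple((p.fa, p.dose_a / p.dx_a, p.dose_b / p.dx_b) for p in points)
    return CombinationAssessment(fit_combo=fit_combo, points=tuple(points), isobologram=iso)


def ci_table(points: Iterable[CombinationPoint]) -> pd.DataFrame:
    """Flat CI/DRI table (the machine twin of a printed combination table)."""
    return pd.DataFrame(
        [
            {
                "fa": p.fa, "dose_a": p.dose_a, "dose_b": p.dose_b,
                "dx_a": p.dx_a, "dx_b": p.dx_b, "ci": p.ci,
                "dri_a": p.dri_a, "dri_b": p.dri_b, "label": p.label,
            }
            for p in points
        ]
    )
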