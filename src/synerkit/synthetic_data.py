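"""Synthetic assay generator plus the published reference dataset.

The generator emulates the measurement chain of a DCIP-type kinetic
inhibition assay: each well's absorbance declines linearly in time with
velocity

    v(dose) = control_velocity * (1 - fa(dose)),

where fa follows the agent's median-effect curve (fa = 0 at dose 0), and
Gaussian noise with standard deviation ``noise_sd`` is added to each
absorbance read — noise enters the *measured* quantity and propagates
through slope fitting exactly as it would on a plate. Combination series
are generated at a fixed dose ratio, with the mixture's effect either
Loewe-additive (solved numerically from the two single-agent curves) or
following an explicitly specified (Dm, m) departure.

Also bundled here, as plain data, is the published reference dataset of a
fixed-ratio hDHODH inhibition study of brequinar, Allium sativum extract,
silymarin and silibinin: single-agent dose-effect tables at five effect
levels, the corresponding published median-effect parameters, and the
published CI/DRI tables of the three binary combinations with brequinar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json

import numpy as np

from .errors import DomainError, ValidationError
from .kinetics import AbsorbanceTrace, DoseEffectPoint, flag_point
from .median_effect import MedianEffectFit, effect_at_dose
from .combination import solve_loewe_mixture

#: 0-5 min at one-minute intervals: the conventional short linear read.
DEFAULT_TIMEPOINTS = tuple(float(t) for t in range(6))

#: Nominal absorbance noise (AU); replicate-level scatter in published
#: kinetic reads of this assay type is unreported, so this is a plausible
#: plate-reader figure, not a calibrated one.
DEFAULT_NOISE_SD = 0.002

#: Two technical replicates, the usual duplicate-well design.
DEFAULT_REPLICATES = 2


@dataclass(frozen=True)
class SyntheticAgentSpec:
    """Generative parameters of one inhibitor."""

    agent: str
    Dm: float  # median-effect dose, agent units
    m: float  # sigmoidicity
    unit: str = "nM"
    control_velocity: float = -0.010  # dA/min of the uninhibited reaction
    a0: float = 1.0  # initial absorbance

    def __post_init__(self):
        if self.Dm <= 0:
            raise ValidationError(f"Dm must be > 0, got {self.Dm}")
        if self.m <= 0:
            raise ValidationError(f"m must be > 0, got {self.m}")
        if self.control_velocity >= 0:
            raise ValidationError("control_velocity must be negative (signal declines)")

    def to_fit(self) -> MedianEffectFit:
        return MedianEffectFit.from_parameters(self.agent, self.Dm, self.m, self.unit)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """A full synthetic study: agents, dose series, noise and replication."""

    agents: tuple[SyntheticAgentSpec, ...]
    doses_per_agent: dict[str, tuple[float, ...]]
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    noise_sd: float = DEFAULT_NOISE_SD
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    #: optional combination block: (ratio_fractions, interaction) where
    #: interaction is "loewe" or an explicit (Dm, m) pair for the mixture
    combination: tuple[tuple[float, float], object] | None = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        for spec in self.agents:
            if spec.agent not in self.doses_per_agent:
                raise ValidationError(f"no dose list for agent {spec.agent!r}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_trace(
    spec: SyntheticAgentSpec,
    dose: float,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    noise_sd: float = 0.0,
    seed=0,
    *,
    replicate: int = 1,
) -> AbsorbanceTrace:
    """One well: linear decline at the dose's median-effect velocity plus noise."""
    if dose < 0:
        raise DomainError(f"dose must be >= 0, got {dose}")
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd}")
    fa = 0.0 if dose == 0 else effect_at_dose(spec.to_fit(), dose)
    v = spec.control_velocity * (1.0 - fa)
    t = np.asarray(timepoints, dtype=float)
    a = spec.a0 + v * t
    if noise_sd > 0:
        a = a + _rng(seed).normal(0.0, noise_sd, size=t.shape)
    return AbsorbanceTrace(
        times=t, a600=a, agent=spec.agent, dose=float(dose), dose_unit=spec.unit,
        replicate=replicate, is_control=(dose == 0),
    )


def simulate_single_agent_study(
    spec: SyntheticAgentSpec,
    doses: Sequence[float],
    *,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    noise_sd: float = DEFAULT_NOISE_SD,
    replicates: int = DEFAULT_REPLICATES,
    seed=0,
) -> list[AbsorbanceTrace]:
    """Replicated dose series plus controls, all driven by one seed."""
    if any(d <= 0 for d in doses):
        raise DomainError("sample doses must be > 0 (controls are added automatically)")
    rng = _rng(seed)
    traces = []
    for rep in range(1, replicates + 1):
        traces.append(
            simulate_trace(spec, 0.0, timepoints, noise_sd, rng, replicate=rep)
        )
    for dose in doses:
        for rep in range(1, replicates + 1):
            traces.append(
                simulate_trace(spec, dose, timepoints, noise_sd, rng, replicate=rep)
            )
    return traces


def simulate_combination_study(
    spec_a: SyntheticAgentSpec,
    spec_b: SyntheticAgentSpec,
    ratio_fractions: tuple[float, float],
    interaction,
    total_doses: Sequence[float],
    *,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    noise_sd: float = DEFAULT_NOISE_SD,
    replicates: int = DEFAULT_REPLICATES,
    seed=0,
    agent_label: str | None = None,
) -> list[AbsorbanceTrace]:
    """Fixed-ratio mixture series.

    ``interaction`` is either the string "loewe" (the mixture effect at
    each total dose solves the Loewe additivity condition for the two
    single-agent curves) or an explicit (Dm, m) pair giving the mixture its
    own median-effect curve (a specified departure from additivity).
    Mixture traces carry the combined total dose on the dose axis and an
    "a+b" agent label; controls are included.
    """
    p, q = ratio_fractions
    if p < 0 or q < 0 or not math.isclose(p + q, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValidationError("ratio_fractions must be non-negative and sum to 1")
    if any(d <= 0 for d in total_doses):
        raise DomainError("total doses must be > 0")
    label = agent_label or f"{spec_a.agent}+{spec_b.agent}"
    unit = spec_a.unit if spec_a.unit == spec_b.unit else f"{spec_a.unit}+{spec_b.unit}"

    if interaction == "loewe":
        fit_a, fit_b = spec_a.to_fit(), spec_b.to_fit()

        def mixture_fa(total: float) -> float:
            return solve_loewe_mixture(fit_a, fit_b, (p, q), total)
    else:
        dm_c, m_c = interaction
        combo_fit = MedianEffectFit.from_parameters(label, float(dm_c), float(m_c), unit)

        def mixture_fa(total: float) -> float:
            return effect_at_dose(combo_fit, total)

    rng = _rng(seed)
    t = np.asarray(timepoints, dtype=float)
    traces = []
    for rep in range(1, replicates + 1):
        traces.append(simulate_trace(spec_a, 0.0, t, noise_sd, rng, replicate=rep))
    for total in total_doses:
        fa = mixture_fa(total)
        v = spec_a.control_velocity * (1.0 - fa)
        for rep in range(1, replicates + 1):
            a = spec_a.a0 + v * t
            if noise_sd > 0:
                a = a + rng.normal(0.0, noise_sd, size=t.shape)
            traces.append(
                AbsorbanceTrace(
                    times=t, a600=a, agent=label, dose=float(total), dose_unit=unit,
                    replicate=rep, is_control=False,
                )
            )
    return traces


def simulate_study(spec: SyntheticStudySpec) -> list[AbsorbanceTrace]:
    """Run a full SyntheticStudySpec (single agents, plus combination if set)."""
    rng = np.random.default_rng(spec.seed)
    traces: list[AbsorbanceTrace] = []
    for agent_spec in spec.agents:
        traces.extend(
            simulate_single_agent_study(
                agent_spec,
                spec.doses_per_agent[agent_spec.agent],
                timepoints=spec.timepoints,
                noise_sd=spec.noise_sd,
                replicates=spec.replicates,
                seed=rng,
            )
        )
    if spec.combination is not None:
        if len(spec.agents) < 2:
            raise ValidationError("combination block requires two agents")
        ratio, interaction = spec.combination
        a, b = spec.agents[0], spec.agents[1]
        totals = spec.doses_per_agent.get(
            f"{a.agent}+{b.agent}", spec.doses_per_agent[a.agent]
        )
        traces.extend(
            simulate_combination_study(
                a, b, tuple(ratio), interaction, totals,
                timepoints=spec.timepoints, noise_sd=spec.noise_sd,
                replicates=spec.replicates, seed=rng,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# published reference dataset (plain data, no instrument required)
# ---------------------------------------------------------------------------

#: Single-agent dose-effect tables: dose at effect levels 0.10..0.90.
REFERENCE_DOSE_EFFECT: dict[str, tuple[str, tuple[tuple[float, float], ...]]] = {
    "brequinar": ("nM", ((3.78, 0.10), (10.28, 0.30), (19.54, 0.50), (36.82, 0.70), (101.74, 0.90))),
    "allium_sativum": ("ug/ml", ((72.42, 0.10), (205.82, 0.30), (403.56, 0.50), (791.9, 0.70), (2314.24, 0.90))),
    "silymarin": ("ug/ml", ((65.58, 0.10), (155.38, 0.30), (267.26, 0.50), (459.28, 0.70), (1086.42, 0.90))),
    "silibinin": ("nM", ((27.12, 0.10), (105.84, 0.30), (243.76, 0.50), (567.62, 0.70), (2189.06, 0.90))),
}

#: Published median-effect parameters (Dm, m, r) of the four single agents.
REFERENCE_SINGLE_AGENT_FITS: dict[str, dict] = {
    "brequinar": {"Dm": 9.76713, "m": 1.33376, "r": 0.99999, "unit": "nM"},
    "allium_sativum": {"Dm": 202.972, "m": 1.26701, "r": 0.99998, "unit": "ug/ml"},
    "silymarin": {"Dm": 133.538, "m": 1.56510, "r": 1.00000, "unit": "ug/ml"},
    "silibinin": {"Dm": 122.127, "m": 1.00184, "r": 0.99999, "unit": "nM"},
}

#: Published mixture median-effect parameters of the binary combinations.
REFERENCE_COMBINATION_FITS: dict[str, dict] = {
    "allium_sativum+brequinar": {"Dm": 141.25, "m": 1.107, "r": 0.99889, "unit": "ug/ml"},
    "silymarin+brequinar": {"Dm": 135.453, "m": 1.027, "r": 0.99999, "unit": "ug/ml"},
    "silibinin+brequinar": {"Dm": 127.135, "m": 2.2, "r": 0.98999, "unit": "nM"},
}

#: Published CI/DRI tables: rows of (fa, printed CI, dose_a, dose_b,
#: DRI_a, DRI_b) where agent a is the natural agent and b is brequinar.
REFERENCE_DRI_TABLES: dict[str, tuple[tuple[float, float, float, float, float, float], ...]] = {
    "allium_sativum+brequinar": (
        (0.11, 1.84, 39.32, 2.05, 1.09, 1.09),
        (0.39, 1.46, 142.08, 6.96, 1.38, 1.35),
        (0.72, 0.95, 431.44, 19.99, 2.14, 2.05),
        (0.78, 1.46, 545.62, 24.99, 1.38, 1.36),
        (0.98, 0.47, 5062.94, 207.41, 4.38, 4.08),
    ),
    "silibinin+brequinar": (
        (0.06, 3.49, 7.23, 1.17, 0.53, 0.62),
        (0.44, 1.14, 97.72, 8.26, 1.85, 1.61),
        (0.61, 1.34, 191.74, 13.71, 1.57, 1.40),
        (0.78, 1.40, 426.52, 24.99, 1.50, 1.36),
        (0.99, 0.16, 21481.50, 474.52, 19.63, 9.33),
    ),
    "silymarin+brequinar": (
        (0.17, 1.33, 47.76, 2.92, 1.46, 1.55),
        (0.33, 1.79, 85.75, 5.81, 1.10, 1.13),
        (0.72, 1.03, 245.88, 19.99, 1.84, 2.05),
        (0.83, 1.14, 373.37, 32.64, 1.63, 1.77),
        (0.98, 0.55, 1805.11, 207.41, 3.32, 4.08),
    ),
}


def reference_dose_effect_points(
    agent: str | None = None,
    clip_bounds: tuple[float, float] = (0.005, 0.995),
) -> list[DoseEffectPoint]:
    """The reference dose-effect tables as in-memory points."""
    agents = [agent] if agent else sorted(REFERENCE_DOSE_EFFECT)
    points = []
    for name in agents:
        unit, rows = REFERENCE_DOSE_EFFECT[name]
        for dose, fa in rows:
            points.append(flag_point(name, dose, unit, fa, clip_bounds=clip_bounds))
    return points


def make_reference_fixture(outdir) -> dict[str, Path]:
    """Write the reference dataset as a CSV/JSON bundle.

    Produces ``dose_effect.csv`` (all four single agents, in the schema
    read_dose_effect_csv consumes) and ``reference_parameters.json``
    (published single-agent and mixture median-effect parameters plus the
    published CI/DRI tables).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["agent,dose,dose_unit,fa"]
    for name in sorted(REFERENCE_DOSE_EFFECT):
        unit, table = REFERENCE_DOSE_EFFECT[name]
        for dose, fa in table:
            rows.append(f"{name},{dose},{unit},{fa}")
    csv_path = outdir / "dose_effect.csv"
    csv_path.write_text("\n".join(rows) + "\n", encoding="utf-8")

    manifest = {
        "single_agent_fits": REFERENCE_SINGLE_AGENT_FITS,
        "combination_fits": REFERENCE_COMBINATION_FITS,
        "dri_tables": {
            name: [
                {"fa": fa, "ci": ci, "dose_a": da, "dose_b": db, "dri_a": ra, "dri_b": rb}
                for fa, ci, da, db, ra, rb in rows_
            ]
            for name, rows_ in REFERENCE_DRI_TABLES.items()
        },
    }
    json_path = outdir / "reference_parameters.json"
    json_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return {"dose_effect": csv_path, "parameters": json_path}
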