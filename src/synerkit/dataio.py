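"""CSV/JSON input-output and run configuration.

Three CSV kinds are read here and validated completely before any other
stage sees them: kinetic absorbance traces, dose-effect tables and docking
score tables (the latter live in :mod:`synerkit.screening_scores`). The
dialect is comma-separated UTF-8 with a required header and "." decimals.
Units are opaque labels carried through unchanged — a single agent must use
one unit everywhere, and the downstream indices (CI, DRI) are unitless
ratios so no conversion is ever needed.

Reports are JSON with full-precision numbers plus a formatted mirror at the
configured precision, and embed a provenance block (config, seed, input
digests) so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .combination import DEFAULT_ADDITIVE_BAND, CombinationAssessment, ci_table
from .errors import (
    DuplicateRecordError,
    ParseError,
    SchemaError,
    UnitConsistencyError,
    ValidationError,
)
from .kinetics import (
    DEFAULT_CLIP_BOUNDS,
    AbsorbanceTrace,
    DoseEffectPoint,
    flag_point,
)
from .median_effect import DEFAULT_LOG_BASE, HillFit, MedianEffectFit

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("time_min", "a600", "agent", "dose", "dose_unit", "replicate", "is_control")
DOSE_EFFECT_COLUMNS = ("agent", "dose", "dose_unit", "fa")

_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f"}


@dataclass(frozen=True)
class StudyConfig:
    """Run-wide knobs shared by all stages.

    clip_bounds: admissible fa window for fitting (the log transform is
        undefined at 0 and 1); additive_band: half-width of the CI band
        labelled additive; velocity_window: "full" or "auto" kinetic
        window policy; log_base: base of the median-effect plot;
        output_precision: decimals in the formatted report mirror.
    """

    clip_bounds: tuple[float, float] = DEFAULT_CLIP_BOUNDS
    additive_band: float = DEFAULT_ADDITIVE_BAND
    velocity_window: str = "full"
    log_base: float = DEFAULT_LOG_BASE
    seed: int = 0
    output_precision: int = 2

    def __post_init__(self):
        lo, hi = self.clip_bounds
        if not (0.0 < lo < 0.5 < hi < 1.0):
            raise ValidationError(f"clip_bounds must satisfy 0 < low < 0.5 < high < 1, got {self.clip_bounds}")
        if self.additive_band < 0:
            raise ValidationError("additive_band must be >= 0")
        if self.velocity_window not in ("full", "auto"):
            raise ValidationError(f"velocity_window must be 'full' or 'auto', got {self.velocity_window!r}")
        if self.log_base <= 1:
            raise ValidationError(f"log_base must be > 1, got {self.log_base}")
        if self.output_precision < 0:
            raise ValidationError("output_precision must be >= 0")

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if "clip_bounds" in raw:
            raw["clip_bounds"] = tuple(raw["clip_bounds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clip_bounds"] = list(self.clip_bounds)
        return d


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty (no header row)")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        idx = int(bad.idxmax())
        raise ParseError(
            f"{path}: non-numeric {col!r} value {df[col].iloc[idx]!r} at file row {idx + 2}",
            row=idx + 2,
        )
    if vals.isna().any():
        idx = int(vals.isna().idxmax())
        raise ParseError(f"{path}: missing {col!r} at file row {idx + 2}", row=idx + 2)
    return vals.to_numpy(dtype=float)


def _check_units(df: pd.DataFrame, path) -> None:
    units = df.groupby("agent")["dose_unit"].nunique()
    mixed = units[units > 1]
    if len(mixed):
        agent = mixed.index[0]
        found = sorted(df.loc[df["agent"] == agent, "dose_unit"].unique())
        raise UnitConsistencyError(f"{path}: agent {agent!r} mixes dose units {found}")


def read_trace_csv(path) -> list[AbsorbanceTrace]:
    """Read kinetic traces; one trace per (agent, dose, replicate) group.

    Required columns: time_min, a600, agent, dose, dose_unit, replicate,
    is_control. Control rows must carry dose 0. Rows are sorted by time
    within each trace; duplicated (agent, dose, replicate, time) keys are
    rejected.
    """
    path = Path(path)
    df = _read_csv(path, TRACE_COLUMNS)
    if df.empty:
        logger.warning("%s: header only, no trace rows", path)
        return []
    df = df.reset_index(drop=True)
    df["time_min"] = _numeric(df, "time_min", path)
    df["a600"] = _numeric(df, "a600", path)
    df["dose"] = _numeric(df, "dose", path)
    df["replicate"] = _numeric(df, "replicate", path).astype(int)

    flags = []
    for i, raw in enumerate(df["is_control"].astype(str).str.strip().str.lower()):
        if raw in _TRUTHY:
            flags.append(True)
        elif raw in _FALSY:
            flags.append(False)
        else:
            raise ParseError(
                f"{path}: unrecognised is_control value {raw!r} at file row {i + 2}", row=i + 2
            )
    df["is_control"] = flags

    dup = df.duplicated(subset=["agent", "dose", "replicate", "time_min"])
    if dup.any():
        i = int(dup.idxmax())
        key = df.loc[i, ["agent", "dose", "replicate", "time_min"]].tolist()
        raise DuplicateRecordError(f"{path}: duplicate record {key} at file row {i + 2}")
    _check_units(df, path)
    bad_ctrl = df["is_control"] & (df["dose"] != 0)
    if bad_ctrl.any():
        i = int(bad_ctrl.idxmax())
        raise ValidationError(
            f"{path}: control row with nonzero dose {df['dose'].iloc[i]} at file row {i + 2}"
        )

    traces = []
    for (agent, dose, rep), grp in df.groupby(["agent", "dose", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            AbsorbanceTrace(
                times=grp["time_min"].to_numpy(),
                a600=grp["a600"].to_numpy(),
                agent=str(agent),
                dose=float(dose),
                dose_unit=str(grp["dose_unit"].iloc[0]),
                replicate=int(rep),
                is_control=bool(grp["is_control"].iloc[0]),
            )
        )
    logger.info("%s: read %d traces", path, len(traces))
    return traces


def read_dose_effect_csv(path, config: StudyConfig | None = None) -> list[DoseEffectPoint]:
    """Read a dose-effect table into points, flagging non-fittable fa values.

    Required columns: agent, dose, dose_unit, fa (optional n_replicates).
    dose <= 0 and fa outside [0, 1] are hard errors; fa outside the clip
    bounds only flags the point (it stays in reports).
    """
    path = Path(path)
    clip = config.clip_bounds if config else DEFAULT_CLIP_BOUNDS
    df = _read_csv(path, DOSE_EFFECT_COLUMNS)
    if df.empty:
        logger.warning("%s: header only, no dose-effect rows", path)
        return []
    df = df.reset_index(drop=True)
    df["dose"] = _numeric(df, "dose", path)
    df["fa"] = _numeric(df, "fa", path)
    _check_units(df, path)
    n_rep = (
        _numeric(df, "n_replicates", path).astype(int)
        if "n_replicates" in df.columns
        else np.ones(len(df), dtype=int)
    )

    points = []
    for i, row in df.iterrows():
        if row["dose"] <= 0:
            raise ValidationError(f"{path}: dose must be > 0, got {row['dose']} at file row {i + 2}")
        if not 0.0 <= row["fa"] <= 1.0:
            raise ValidationError(f"{path}: fa must be in [0, 1], got {row['fa']} at file row {i + 2}")
        points.append(
            flag_point(
                str(row["agent"]), float(row["dose"]), str(row["dose_unit"]),
                float(row["fa"]), n_replicates=int(n_rep[i]), clip_bounds=clip,
            )
        )
    return points


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dose_effect_csv(points: Iterable[DoseEffectPoint], path) -> None:
    """Write points in the same schema read_dose_effect_csv consumes."""
    pd.DataFrame(
        [
            {
                "agent": p.agent, "dose": p.dose, "dose_unit": p.dose_unit,
                "fa": p.fa, "n_replicates": p.n_replicates,
            }
            for p in points
        ]
    ).to_csv(path, index=False)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _fmt(value: float, precision: int) -> str:
    if value is None or not math.isfinite(value):
        return str(value)
    return f"{value:.{precision}f}"


def _fit_dict(fit: MedianEffectFit, precision: int) -> dict:
    return {
        "agent": fit.agent,
        "Dm": fit.Dm,
        "m": fit.m,
        "r": fit.r,
        "n_points": fit.n_points,
        "dose_unit": fit.dose_unit,
        "formatted": {
            "Dm": _fmt(fit.Dm, precision),
            "m": _fmt(fit.m, precision),
            "r": _fmt(fit.r, precision),
        },
    }


def _hill_dict(fit: HillFit, precision: int) -> dict:
    return {
        "ic50": fit.ic50, "hill_slope": fit.hill_slope,
        "bottom": fit.bottom, "top": fit.top,
        "converged": fit.converged, "rss": fit.rss,
        "formatted": {"ic50": _fmt(fit.ic50, precision), "hill_slope": _fmt(fit.hill_slope, precision)},
    }


def _assessment_dict(name: str, a: CombinationAssessment, precision: int) -> dict:
    table = ci_table(a.points)
    return {
        "name": name,
        "fit": _fit_dict(a.fit_combo, precision),
        "points": table.to_dict(orient="records"),
        "isobologram": [
            {"fa": fa, "x_a": xa, "x_b": xb} for fa, xa, xb in a.isobologram
        ],
        "formatted_ci": [_fmt(p.ci, precision) for p in a.points],
    }


def write_report(
    results: dict,
    path,
    *,
    config: StudyConfig | None = None,
    seed: int | None = None,
    input_hashes: dict[str, str] | None = None,
    manifest: dict | None = None,
) -> dict:
    """Serialise an analysis bundle to JSON and return the document.

    ``results`` maps "fits" to MedianEffectFit objects, optionally
    "hill_fits" to HillFit, "combinations" to {name: CombinationAssessment}
    and "points" to DoseEffectPoint collections. At least one fitted curve
    is required. Numeric values are stored at full precision with a
    formatted mirror at the configured precision; the payload is
    deterministic for identical inputs (keys sorted, no timestamps).
    """
    config = config or StudyConfig()
    fits = list(results.get("fits", []))
    combos = dict(results.get("combinations", {}))
    if not fits and not combos:
        raise ValidationError("report requires at least one fitted curve")
    prec = config.output_precision
    doc = {
        "provenance": {
            "package": "synerkit",
            "version": __version__,
            "config": config.to_dict(),
            "seed": config.seed if seed is None else seed,
            "input_hashes": dict(input_hashes or {}),
        },
        "agents": [_fit_dict(f, prec) for f in fits],
        "hill_fits": [_hill_dict(h, prec) for h in results.get("hill_fits", [])],
        "combinations": [_assessment_dict(n, a, prec) for n, a in combos.items()],
        "points": [
            {
                "agent": p.agent, "dose": p.dose, "dose_unit": p.dose_unit,
                "fa": p.fa, "n_replicates": p.n_replicates, "fittable": p.fittable,
            }
            for p in results.get("points", [])
        ],
    }
    if manifest is not None:
        doc["manifest"] = manifest
    payload = json.dumps(doc, indent=2, sort_keys=True)
    try:
        Path(path).write_text(payload + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return doc


def read_report(path) -> dict:
    """Re-read a report; fit parameters come back as MedianEffectFit objects."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    doc["fits"] = [
        MedianEffectFit(
            agent=d["agent"], Dm=d["Dm"], m=d["m"], r=d["r"],
            n_points=d["n_points"], dose_unit=d["dose_unit"],
        )
        for d in doc.get("agents", [])
    ]
    return doc
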