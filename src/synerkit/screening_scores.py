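"""Per-plant aggregation of virtual-screening docking scores.

Docking scores (e.g. Glide XP GScores, kcal/mol) are more negative for
better predicted binding. A compound is an "active hit" when its score is
at or below a user-chosen cutoff. Because plants contribute different
numbers of compounds to the screened database, the plant-level activity
statistic weights the summed hit scores by the hit fraction:

    plant score = (sum of hit scores) * (n_hits / total compounds in database),

so a plant with many strong hits out of few database entries outranks one
whose few hits came from a large roster. Ranking is ascending in the score
(most negative = most active first). No docking is performed here; scores
are consumed from tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import DomainError, SchemaError, ValidationError


@dataclass(frozen=True)
class DockingHitTable:
    """Scored compounds of one plant plus its database roster size."""

    plant: str
    compound_scores: tuple[tuple[str, float], ...]  # (compound id, kcal/mol)
    total_in_database: int
    hit_threshold: float  # score cutoff; hits have score <= threshold

    def __post_init__(self):
        if self.total_in_database < len(self.compound_scores):
            raise DomainError(
                f"{self.plant!r}: total_in_database ({self.total_in_database}) < "
                f"scored compounds ({len(self.compound_scores)})"
            )
        for cid, s in self.compound_scores:
            if not math.isfinite(s):
                raise DomainError(f"{self.plant!r}/{cid!r}: non-finite score {s}")


@dataclass(frozen=True)
class PlantScore:
    plant: str
    n_hits: int
    sum_hit_scores: float
    score: float


def select_hits(table: DockingHitTable) -> list[tuple[str, float]]:
    """Compounds at or below the hit threshold, ordered (score ascending, id)."""
    hits = [(cid, s) for cid, s in table.compound_scores if s <= table.hit_threshold]
    return sorted(hits, key=lambda cs: (cs[1], cs[0]))


def plant_score(table: DockingHitTable) -> PlantScore:
    """Hit-fraction-weighted sum of hit scores for one plant."""
    if table.total_in_database <= 0:
        raise DomainError(f"{table.plant!r}: total_in_database must be > 0")
    hits = select_hits(table)
    total = sum(s for _, s in hits)
    return PlantScore(
        plant=table.plant,
        n_hits=len(hits),
        sum_hit_scores=total,
        score=total * (len(hits) / table.total_in_database),
    )


def rank_plants(scores: Iterable[PlantScore]) -> list[PlantScore]:
    """Most active (most negative score) first; ties broken alphabetically."""
    scores = list(scores)
    if not scores:
        raise DomainError("no plant scores to rank")
    return sorted(scores, key=lambda s: (s.score, s.plant))


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def read_docking_tables(
    scores_path, totals_path, hit_threshold: float
) -> list[DockingHitTable]:
    """Load per-compound scores and per-plant roster sizes from two CSVs.

    ``scores_path`` needs columns plant, compound_id, xp_gscore;
    ``totals_path`` needs plant, total_in_database. Every scored plant must
    appear in the totals table.
    """
    scores = pd.read_csv(scores_path)
    for col in ("plant", "compound_id", "xp_gscore"):
        if col not in scores.columns:
            raise SchemaError(f"{scores_path}: missing column {col!r}")
    totals = pd.read_csv(totals_path)
    for col in ("plant", "total_in_database"):
        if col not in totals.columns:
            raise SchemaError(f"{totals_path}: missing column {col!r}")
    totals_map = dict(zip(totals["plant"].astype(str), totals["total_in_database"].astype(int)))

    tables = []
    for plant, grp in scores.groupby("plant", sort=True):
        plant = str(plant)
        if plant not in totals_map:
            raise ValidationError(f"plant {plant!r} has scores but no database total")
        tables.append(
            DockingHitTable(
                plant=plant,
                compound_scores=tuple(
                    (str(c), float(s)) for c, s in zip(grp["compound_id"], grp["xp_gscore"])
                ),
                total_in_database=totals_map[plant],
                hit_threshold=hit_threshold,
            )
        )
    # plants present only in the totals table score zero hits
    for plant, total in sorted(totals_map.items()):
        if plant not in {t.plant for t in tables}:
            tables.append(
                DockingHitTable(
                    plant=plant, compound_scores=(), total_in_database=total,
                    hit_threshold=hit_threshold,
                )
            )
    return tables


def ranking_frame(scores: Sequence[PlantScore]) -> pd.DataFrame:
    """Ranked plant-score table ready for CSV export."""
    ranked = rank_plants(scores)
    return pd.DataFrame(
        [
            {
                "rank": i + 1, "plant": s.plant, "score": s.score,
                "n_hits": s.n_hits, "sum_hit_scores": s.sum_hit_scores,
            }
            for i, s in enumerate(ranked)
        ]
    )
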