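"""Fusion of the three evidence streams into the final candidate score.

score = w_full * max(0, ceiling - avg_rank_full)
      + w_final * max(0, ceiling - avg_rank_final)
      + w_en * en_selected
      + w_corr * |corr_class|

with default weights (1, 1, 3, 1) and rank ceiling 7.  A missing rank
contributes 0, as does a rank at or beyond the ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScoreWeights", "final_score", "build_candidate_table"]


@dataclass(frozen=True)
class ScoreWeights:
    w_full: float = 1.0
    w_final: float = 1.0
    w_en: float = 3.0
    w_corr: float = 1.0
    rank_ceiling: float = 7.0
    min_score: float = 2.0

    def __post_init__(self) -> None:
        if min(self.w_full, self.w_final, self.w_en, self.w_corr) < 0:
            raise ValueError("score weights must be nonnegative")


def _is_missing(rank) -> bool:
    return rank is None or (isinstance(rank, float) and math.isnan(rank))


def _rank_term(rank, ceiling: float) -> float:
    if _is_missing(rank):
        return 0.0
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    return max(0.0, ceiling - float(rank))


def final_score(
    rank_full,
    rank_final,
    en_selected: int,
    corr_class: float,
    weights: ScoreWeights = ScoreWeights(),
) -> float:
    """Evidence score for one taxon; missing ranks (None/NaN) contribute 0."""
    if en_selected not in (0, 1):
        raise ValueError(f"en_selected must be 0 or 1, got {en_selected}")
    return (
        weights.w_full * _rank_term(rank_full, weights.rank_ceiling)
        + weights.w_final * _rank_term(rank_final, weights.rank_ceiling)
        + weights.w_en * en_selected
        + weights.w_corr * abs(corr_class)
    )


def build_candidate_table(
    rank_summary: pd.DataFrame,
    en_candidates,
    corr_records: pd.DataFrame,
    weights: ScoreWeights = ScoreWeights(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every taxon appearing in any evidence stream.

    ``rank_summary`` has columns avg_rank_full/avg_rank_final indexed by (or
    with a column) taxon_id; ``en_candidates`` is any iterable of selected
    taxon IDs; ``corr_records`` has taxon_id and corr_class columns.

    Returns ``(full, report)``: the full scored table sorted by score
    descending, and the report restricted to scores >= ``weights.min_score``.
    """
    if "taxon_id" in rank_summary.columns:
        rank_summary = rank_summary.set_index("taxon_id")
    if rank_summary.index.has_duplicates:
        raise ValueError("duplicate taxon entries in rank summary")
    corr = corr_records.set_index("taxon_id")["corr_class"]
    if corr.index.has_duplicates:
        raise ValueError("duplicate taxon entries in correlation records")
    en_set = set(en_candidates)

    universe = sorted(set(rank_summary.index) | en_set | set(corr.index))
    rows = []
    for taxon in universe:
        rank_full = rank_summary["avg_rank_full"].get(taxon, np.nan)
        rank_final = rank_summary["avg_rank_final"].get(taxon, np.nan)
        en = int(taxon in en_set)
        cls = float(corr.get(taxon, 0.0))
        rows.append(
            {
                "taxon_id": taxon,
                "avg_rank_full": rank_full,
                "avg_rank_final": rank_final,
                "en_selected": en,
                "corr_class": cls,
                "score": final_score(rank_full, rank_final, en, cls, weights),
            }
        )
    full = (
        pd.DataFrame(rows)
        .sort_values(["score", "taxon_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    report = full[full["score"] >= weights.min_score].reset_index(drop=True)
    return full, report
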