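"""Filtering rules for external viral-prediction and AMG output tables.

Two rule sets, applied verbatim with strict inequalities:

* viral prediction: a contig >= ``min_len`` bp is accepted when its
  machine-learning viral score is > 0.9 with p < 0.05, or when its
  hallmark-gene category is one of the high-confidence categories
  {1, 2, 4, 5}; the provenance of each acceptance (both predictors, score
  only, category only) is recorded for recovery-breakdown reporting.
* auxiliary metabolic gene (AMG) candidates: retained when the auxiliary
  confidence score is < 4, none of the flags F (viral), T (transposon),
  P (viral-like peptidase) or A (attachment) is set, and both gene id
  and description are present.

Both filters are pure functions of their input rows: order-independent
and idempotent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

HIGH_CONFIDENCE_CATEGORIES = frozenset({1, 2, 4, 5})
DISALLOWED_AMG_FLAGS = frozenset("FTPA")
DEFAULT_MIN_LEN = 10_000


@dataclass(frozen=True)
class PredictionRow:
    """Per-contig output of the two viral predictors (either may be absent)."""

    contig_id: str
    length: int
    dvf_score: float | None = None
    dvf_p: float | None = None
    vs_category: int | None = None


@dataclass(frozen=True)
class AmgRow:
    """One putative auxiliary metabolic gene with its confidence metadata."""

    gene_id: str
    gene_description: str
    auxiliary_score: int
    flags: frozenset[str] = frozenset()


def _score_passes(row: PredictionRow) -> bool:
    return (
        row.dvf_score is not None
        and row.dvf_p is not None
        and row.dvf_score > 0.9
        and row.dvf_p < 0.05
    )


def _category_passes(row: PredictionRow) -> bool:
    return row.vs_category in HIGH_CONFIDENCE_CATEGORIES


def filter_viral_predictions(
    rows: list[PredictionRow], min_len: int = DEFAULT_MIN_LEN
) -> dict[str, str]:
    """Accepted contigs with provenance in {both, score_only, category_only}.

    The length cut is applied first, mirroring the assembly's >= 10 kbp
    convention; absent predictor fields simply do not pass.
    """
    accepted: dict[str, str] = {}
    for row in rows:
        if row.length < min_len:
            continue
        s, c = _score_passes(row), _category_passes(row)
        if s and c:
            accepted[row.contig_id] = "both"
        elif s:
            accepted[row.contig_id] = "score_only"
        elif c:
            accepted[row.contig_id] = "category_only"
    return accepted


def provenance_fractions(accepted: dict[str, str]) -> dict[str, float]:
    """Fraction of accepted contigs per provenance class (sums to 1)."""
    n = len(accepted)
    out = {"both": 0.0, "score_only": 0.0, "category_only": 0.0}
    for prov in accepted.values():
        out[prov] += 1
    return {k: v / n if n else 0.0 for k, v in out.items()}


def filter_amg_candidates(rows: list[AmgRow]) -> list[AmgRow]:
    """Retain confidently viral AMG candidates."""
    return [
        row
        for row in rows
        if row.auxiliary_score < 4
        and not (set(row.flags) & DISALLOWED_AMG_FLAGS)
        and row.gene_id
        and row.gene_description
    ]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def prediction_rows_from_table(df: pd.DataFrame) -> list[PredictionRow]:
    """Build rows from a TSV table with columns contig_id, length and any
    of dvf_score, dvf_p, vs_category."""
    rows = []
    for rec in df.to_dict("records"):
        cat = _opt_float(rec.get("vs_category"))
        rows.append(
            PredictionRow(
                contig_id=str(rec["contig_id"]),
                length=int(rec["length"]),
                dvf_score=_opt_float(rec.get("dvf_score")),
                dvf_p=_opt_float(rec.get("dvf_p")),
                vs_category=int(cat) if cat is not None else None,
            )
        )
    return rows


def amg_rows_from_table(df: pd.DataFrame) -> list[AmgRow]:
    """Build rows from a TSV with columns gene_id, gene_description,
    auxiliary_score, flags (flags as a bare string such as 'MT')."""
    rows = []
    for rec in df.to_dict("records"):
        raw = rec.get("flags")
        flags = frozenset() if pd.isna(raw) else frozenset(str(raw))
        gid = "" if pd.isna(rec.get("gene_id")) else str(rec["gene_id"])
        desc = "" if pd.isna(rec.get("gene_description")) else str(rec["gene_description"])
        rows.append(AmgRow(gid, desc, int(rec["auxiliary_score"]), flags))
    return rows
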