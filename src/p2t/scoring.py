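"""Weighted target prioritization.

Each target's score is a linear combination of ten attributes:

    score = w_pathways * n_pathways
          + w_tractability * tractability_count
          + w_approved * n_approved
          + w_safety * n_safety_liabilities
          + w_unique_drugs * n_unique_drugs
          + w_diseases * n_associated_diseases
          + w_phase1 * n_phase1 + w_phase2 * n_phase2
          + w_phase3 * n_phase3 + w_phase4 * n_phase4

``n_pathways`` is the number of *significant input pathways* containing
the target, recomputed per run from the enrichment table and the pathway
membership backend — it is a property of the analysis, not of the target.
Safety liabilities carry a negative default weight; no normalization or
capping is applied to any attribute.

Two built-in presets: ``default`` favors late-stage, heavily-drugged
targets (repurposing); ``novel`` damps disease-association and phase-4
counts and boosts phase-1/2 counts to surface earlier-stage targets.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel

from .backends import get_drugs_for_target, get_pathway_members
from .types import PathwayRecord, Snapshot, TargetRecord

__all__ = [
    "WeightScheme",
    "ScoredTarget",
    "PRESETS",
    "get_preset",
    "compute_pathway_counts",
    "score_target",
    "rank_targets",
    "build_drug_table",
    "targets_table",
]


class WeightScheme(BaseModel):
    """The ten attribute weights of the prioritization score."""

    w_pathways: float
    w_tractability: float
    w_approved: float
    w_safety: float
    w_unique_drugs: float
    w_diseases: float
    w_phase1: float
    w_phase2: float
    w_phase3: float
    w_phase4: float

    model_config = {"extra": "forbid"}


#: repurposing preset: reward approval, late clinical phases, broad
#: disease association; penalize safety liabilities.
DEFAULT_WEIGHTS = WeightScheme(
    w_pathways=1,
    w_tractability=1,
    w_approved=1,
    w_safety=-2,
    w_unique_drugs=1,
    w_diseases=1,
    w_phase1=0.5,
    w_phase2=1,
    w_phase3=1.5,
    w_phase4=2,
)

#: early/novel-target preset: damp everything late-stage, boost phase 1-2.
NOVEL_WEIGHTS = WeightScheme(
    w_pathways=0.5,
    w_tractability=0.5,
    w_approved=0.5,
    w_safety=-2,
    w_unique_drugs=0.5,
    w_diseases=0.01,
    w_phase1=10,
    w_phase2=4,
    w_phase3=0.5,
    w_phase4=0.01,
)

PRESETS: dict[str, WeightScheme] = {
    "default": DEFAULT_WEIGHTS,
    "novel": NOVEL_WEIGHTS,
}


def get_preset(name: str) -> WeightScheme:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown weight preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


class ScoredTarget(BaseModel):
    """A target with its per-run pathway count, score and 1-based rank."""

    record: TargetRecord
    n_pathways_with_target: int
    score: float
    rank: int


def compute_pathway_counts(
    significant_pathways: Sequence[PathwayRecord],
    snapshot: Snapshot,
) -> dict[str, int]:
    """Number of distinct significant pathways containing each gene.

    Genes appearing in no significant pathway are absent from the result.
    """
    counts: dict[str, int] = {}
    for pathway in significant_pathways:
        for gene in set(get_pathway_members(snapshot, pathway)):
            counts[gene] = counts.get(gene, 0) + 1
    return counts


def score_target(
    record: TargetRecord, n_pathways: int, weights: WeightScheme
) -> float:
    """The weighted linear score of one target."""
    return (
        weights.w_pathways * n_pathways
        + weights.w_tractability * record.tractability_count
        + weights.w_approved * record.n_approved
        + weights.w_safety * record.n_safety_liabilities
        + weights.w_unique_drugs * record.n_unique_drugs
        + weights.w_diseases * record.n_associated_diseases
        + weights.w_phase1 * record.n_phase1
        + weights.w_phase2 * record.n_phase2
        + weights.w_phase3 * record.n_phase3
        + weights.w_phase4 * record.n_phase4
    )


def rank_targets(
    records: Iterable[tuple[TargetRecord, int]],
    weights: WeightScheme,
) -> list[ScoredTarget]:
    """Score and rank targets.

    Sorted by score descending; ties broken by approved-therapeutic count
    descending, then unique-drug count descending, then symbol ascending,
    so the ranking is a deterministic function of the input *set*.
    """
    records = list(records)
    seen: set[str] = set()
    for rec, _ in records:
        if rec.ensembl_id in seen:
            raise ValueError(f"duplicate ensembl_id: {rec.ensembl_id}")
        seen.add(rec.ensembl_id)
    scored = [
        (score_target(rec, n_pathways, weights), rec, n_pathways)
        for rec, n_pathways in records
    ]
    scored.sort(
        key=lambda t: (-t[0], -t[1].n_approved, -t[1].n_unique_drugs, t[1].symbol)
    )
    return [
        ScoredTarget(
            record=rec, n_pathways_with_target=n_pathways, score=s, rank=i + 1
        )
        for i, (s, rec, n_pathways) in enumerate(scored)
    ]


def build_drug_table(
    scored: Sequence[ScoredTarget], snapshot: Snapshot
) -> pd.DataFrame:
    """Prioritized-therapeutics table.

    One row per unique drug across all scored targets' links; each drug
    inherits the maximum score among its linked scored targets (a drug is
    as promising as its best target). Sorted by inherited score
    descending, then drug id.
    """
    by_drug: dict[str, dict] = {}
    for st in scored:
        for link in get_drugs_for_target(snapshot, st.record.ensembl_id):
            row = by_drug.get(link.drug_id)
            if row is None or st.score > row["score"]:
                by_drug[link.drug_id] = {
                    "drug_id": link.drug_id,
                    "drug_name": link.drug_name,
                    "drug_type": link.drug_type,
                    "action": link.action,
                    "max_phase": link.max_phase,
                    "is_approved": link.is_approved,
                    "target_symbol": st.record.symbol,
                    "score": st.score,
                }
    rows = sorted(by_drug.values(), key=lambda r: (-r["score"], r["drug_id"]))
    columns = [
        "drug_id",
        "drug_name",
        "drug_type",
        "action",
        "max_phase",
        "is_approved",
        "target_symbol",
        "score",
    ]
    return pd.DataFrame(rows, columns=columns)


def targets_table(scored: Sequence[ScoredTarget]) -> pd.DataFrame:
    """Prioritized-targets table, one row per target in rank order."""
    rows = []
    for st in scored:
        r = st.record
        rows.append(
            {
                "rank": st.rank,
                "symbol": r.symbol,
                "ensembl_id": r.ensembl_id,
                "name": r.name,
                "n_associated_diseases": r.n_associated_diseases,
                "tractability_count": r.tractability_count,
                "subcellular_location": r.subcellular_location,
                "n_safety_liabilities": r.n_safety_liabilities,
                "n_unique_drugs": r.n_unique_drugs,
                "n_pathways_with_target": st.n_pathways_with_target,
                "n_approved": r.n_approved,
                "n_phase3": r.n_phase3,
                "n_phase2": r.n_phase2,
                "n_phase1": r.n_phase1,
                "n_phase4": r.n_phase4,
                "score": st.score,
            }
        )
    columns = [
        "rank",
        "symbol",
        "ensembl_id",
        "name",
        "n_associated_diseases",
        "tractability_count",
        "subcellular_location",
        "n_safety_liabilities",
        "n_unique_drugs",
        "n_pathways_with_target",
        "n_approved",
        "n_phase3",
        "n_phase2",
        "n_phase1",
        "n_phase4",
        "score",
    ]
    return pd.DataFrame(rows, columns=columns)
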