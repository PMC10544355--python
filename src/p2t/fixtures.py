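"""Deterministic synthetic fixtures.

Everything the pipeline consumes — the target-data snapshot, the pathway
enrichment table, the gold set — can be generated offline with a seed, so
every stage is testable without network access.

The generator emulates the regime of a real target-database pull for a
cancer transcriptomics study: a few dozen significant pathways over a few
hundred genes, disease-association counts up to the low thousands,
unique-drug counts up to ~100, clinical-phase counts up to ~15, and a
designated *gold* subset of targets whose approved / phase-4 / unique-drug
counts are inflated by a common factor. The gold subset plays the role of
the indication's approved targets: a correct ranking should concentrate
them near the top, which is what the enrichment test measures.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .types import (
    DrugLink,
    GeneMapEntry,
    PathwayEntry,
    Snapshot,
    SourceDB,
    TargetRecord,
    TRACTABILITY_KEYS,
)

__all__ = [
    "FixtureParams",
    "FixtureTruth",
    "generate_snapshot",
    "write_pathway_table",
    "write_gold_set",
]

#: inclusive integer draw ranges per attribute, calibrated to the
#: magnitudes seen in real target-annotation pulls
DEFAULT_ATTRIBUTE_RANGES: dict[str, tuple[int, int]] = {
    "n_associated_diseases": (0, 2500),
    "tractability_count": (0, 12),
    "n_safety_liabilities": (0, 25),
    "n_unique_drugs": (0, 100),
    "n_approved": (0, 15),
    "n_phase1": (0, 15),
    "n_phase2": (0, 15),
    "n_phase3": (0, 15),
}


class FixtureParams(BaseModel):
    """Knobs of the synthetic-data generator."""

    n_pathways: int = Field(default=10, ge=0)
    n_genes: int = Field(default=50, ge=1)
    genes_per_pathway: tuple[int, int] = (3, 15)
    n_gold: int = Field(default=5, ge=0)
    gold_attribute_inflation: float = Field(default=10.0, gt=0)
    attribute_ranges: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: dict(DEFAULT_ATTRIBUTE_RANGES)
    )
    drug_links_per_target: tuple[int, int] = (0, 4)
    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self) -> "FixtureParams":
        if self.n_gold > self.n_genes:
            raise ValueError("n_gold must not exceed n_genes")
        for label, (lo, hi) in [
            ("genes_per_pathway", self.genes_per_pathway),
            ("drug_links_per_target", self.drug_links_per_target),
            *self.attribute_ranges.items(),
        ]:
            if lo > hi or lo < 0:
                raise ValueError(f"empty or negative range for {label}: ({lo}, {hi})")
        unknown = set(self.attribute_ranges) - set(DEFAULT_ATTRIBUTE_RANGES)
        if unknown:
            raise ValueError(f"unknown attribute_ranges keys: {sorted(unknown)}")
        return self


class FixtureTruth(BaseModel):
    """Ground truth recorded while generating a snapshot."""

    gold_symbols: list[str]
    pathway_counts: dict[str, int]  # ensembl_id -> # pathways containing it


def _draw(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    return int(rng.integers(lo, hi + 1))


def _draw_attr(rng: np.random.Generator, name: str, bounds: tuple[int, int]) -> int:
    """Draw one attribute value inside ``bounds``.

    Disease-association counts are heavy-tailed in real annotation data —
    the median target has a few hundred associations while only the most
    studied genes reach the thousands — so they are drawn lognormal
    (median at ~6% of the upper bound, sigma 1) and clipped. Safety
    liabilities are similarly skewed toward zero (exponential). Drug,
    phase and tractability counts are drawn uniformly.
    """
    lo, hi = bounds
    span = hi - lo
    if span == 0:
        return lo
    if name == "n_associated_diseases":
        return lo + min(span, round(float(rng.lognormal(np.log(0.06 * span), 1.0))))
    if name == "n_safety_liabilities":
        return lo + min(span, int(rng.exponential(span / 8)))
    return _draw(rng, bounds)


def generate_snapshot(params: FixtureParams) -> tuple[Snapshot, FixtureTruth]:
    """Generate a schema-valid snapshot plus its ground truth.

    Identical params (including seed) give identical output. Gold targets
    receive ``round(background_draw * inflation)`` on the approved,
    phase-4 and unique-drug counts; every other attribute is drawn from
    the background ranges.
    """
    rng = np.random.default_rng(params.seed)
    ranges = {**DEFAULT_ATTRIBUTE_RANGES, **params.attribute_ranges}

    symbols = [f"GENE{i + 1:04d}" for i in range(params.n_genes)]
    ensembl_ids = [f"ENSG{9 * 10**10 + i:011d}" for i in range(params.n_genes)]
    gene_map = [
        GeneMapEntry(
            symbol=symbols[i],
            ensembl_id=ensembl_ids[i],
            entrez_id=str(100000 + i),
            uniprot_ids=[f"P{90000 + i:05d}"],
        )
        for i in range(params.n_genes)
    ]

    gold_idx = sorted(
        int(i) for i in rng.choice(params.n_genes, size=params.n_gold, replace=False)
    )
    gold_set = set(gold_idx)

    pathways: dict[str, PathwayEntry] = {}
    for p in range(params.n_pathways):
        size = min(_draw(rng, params.genes_per_pathway), params.n_genes)
        members = sorted(
            int(i) for i in rng.choice(params.n_genes, size=size, replace=False)
        )
        pid = f"R-HSA-9{p + 1:06d}"
        pathways[pid] = PathwayEntry(
            name=f"Synthetic signaling pathway {p + 1}",
            source_db=SourceDB.Reactome,
            member_ensembl_ids=[ensembl_ids[i] for i in members],
        )

    pathway_counts: dict[str, int] = {}
    for entry in pathways.values():
        for gene in entry.member_ensembl_ids:
            pathway_counts[gene] = pathway_counts.get(gene, 0) + 1

    targets: dict[str, TargetRecord] = {}
    drugs: list[DrugLink] = []
    drug_serial = 0
    drug_pool: list[str] = []
    for i in range(params.n_genes):
        attrs = {name: _draw_attr(rng, name, bounds) for name, bounds in ranges.items()}
        if i in gold_set:
            # a gold (approved-indication) target has, by definition, at
            # least one approved therapeutic before inflation
            attrs["n_approved"] = max(attrs["n_approved"], 1)
        # a target's unique-drug count can never be below its approved count
        attrs["n_unique_drugs"] = max(attrs["n_unique_drugs"], attrs["n_approved"])
        # approved therapeutics are, by definition, post-approval (phase 4)
        attrs["n_phase4"] = attrs["n_approved"]
        if i in gold_set:
            for key in ("n_approved", "n_phase4", "n_unique_drugs"):
                attrs[key] = round(attrs[key] * params.gold_attribute_inflation)
        flags = {k: bool(rng.integers(0, 2)) for k in TRACTABILITY_KEYS}
        targets[ensembl_ids[i]] = TargetRecord(
            symbol=symbols[i],
            ensembl_id=ensembl_ids[i],
            uniprot_ids=gene_map[i].uniprot_ids,
            name=f"Synthetic gene product {i + 1}",
            tractability_flags=flags,
            subcellular_location="Cytoplasm",
            **attrs,
        )
        n_links = _draw(rng, params.drug_links_per_target)
        for _ in range(n_links):
            # ~20% of links reuse an existing drug so the drug table has
            # genuine duplicates to deduplicate
            if drug_pool and rng.random() < 0.2:
                drug_id = drug_pool[int(rng.integers(0, len(drug_pool)))]
            else:
                drug_serial += 1
                drug_id = f"CHEMBL{drug_serial:07d}"
                drug_pool.append(drug_id)
            phase = int(rng.integers(0, 5))
            drugs.append(
                DrugLink(
                    drug_id=drug_id,
                    drug_name=f"compound-{drug_id[-7:]}",
                    drug_type=str(rng.choice(["small molecule", "antibody"])),
                    action=str(rng.choice(["inhibitor", "agonist", "antagonist"])),
                    max_phase=phase,
                    is_approved=phase == 4,
                    target_ensembl_id=ensembl_ids[i],
                )
            )

    snapshot = Snapshot(
        schema_version="1",
        pathways=pathways,
        gene_map=gene_map,
        targets=targets,
        drugs=drugs,
    )
    truth = FixtureTruth(
        gold_symbols=[symbols[i] for i in gold_idx],
        pathway_counts=pathway_counts,
    )
    return snapshot, truth


def write_pathway_table(
    snapshot: Snapshot,
    dialect: str,
    path: Union[str, Path],
    p_values: Optional[Sequence[float]] = None,
) -> None:
    """Write the snapshot's pathway inventory as an enrichment table.

    ``p_values`` are attached verbatim, one per pathway in snapshot order;
    by default every pathway gets 1e-4 (comfortably significant). The
    written file parses back with the matching :mod:`p2t.io_pathways`
    parser.
    """
    if dialect not in ("spia", "enrichr"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'spia' or 'enrichr'")
    entries = list(snapshot.pathways.items())
    if p_values is None:
        p_values = [1e-4] * len(entries)
    if len(p_values) != len(entries):
        raise ValueError(
            f"got {len(p_values)} p-values for {len(entries)} pathways"
        )
    lines: list[str] = []
    if dialect == "spia":
        lines.append(
            "Name\tID\tpSize\tNDE\tpGFWER\tStatus\tSource database"
        )
        for (pid, entry), p in zip(entries, p_values):
            n = len(entry.member_ensembl_ids)
            lines.append(
                f"{entry.name}\t{pid}\t{n}\t{n}\t{p:.6g}\tActivated\t"
                f"{entry.source_db.value}"
            )
    else:
        lines.append("Term\tOverlap\tAdjusted P-value")
        for (pid, entry), p in zip(entries, p_values):
            n = len(entry.member_ensembl_ids)
            lines.append(f"{entry.name} {pid}\t{n}/{n}\t{p:.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_gold_set(symbols: Sequence[str], path: Union[str, Path]) -> None:
    """Write a gold set, one symbol per line."""
    body = "# synthetic gold target set\n" + "\n".join(symbols) + "\n"
    Path(path).write_text(body, encoding="utf-8")
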