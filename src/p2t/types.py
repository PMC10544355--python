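"""Core domain types.

The pipeline moves four kinds of records around:

* :class:`PathwayRecord` — one significant signaling pathway from an
  upstream enrichment run (SPIA- or enrichr-style).
* :class:`TargetRecord` — one gene product with the attributes that enter
  the weighted prioritization score (disease associations, tractability,
  safety liabilities, drug and clinical-phase counts).
* :class:`DrugLink` — one therapeutic linked to a target, with clinical
  phase and approval annotations.
* :class:`Snapshot` — a self-contained offline bundle of pathway
  membership, gene-identifier maps, target attributes and drug links;
  the offline stand-in for a live target-database query.

All models are pydantic so that snapshot loading doubles as schema
validation.
"""

from __future__ import annotations

import enum
import re
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

ENSG_PATTERN = re.compile(r"^ENSG\d{11}$")

#: tractability modalities: small molecule, antibody, PROTAC, other clinical
TRACTABILITY_MODALITIES = ("sm", "ab", "pr", "oc")
#: clinical maturity stages of tractability evidence
TRACTABILITY_STAGES = ("approved", "advanced_trial", "phase1")
#: the 12 modality x stage keys, e.g. ``"sm:approved"``
TRACTABILITY_KEYS = tuple(
    f"{m}:{s}" for m in TRACTABILITY_MODALITIES for s in TRACTABILITY_STAGES
)


class SourceDB(str, enum.Enum):
    """Pathway source database."""

    KEGG = "KEGG"
    Reactome = "Reactome"
    PID = "PID"
    BioCarta = "BioCarta"
    Panther = "Panther"
    other = "other"


class PathwayStatus(str, enum.Enum):
    """Predicted perturbation direction of a pathway."""

    Activated = "Activated"
    Inhibited = "Inhibited"
    unknown = "unknown"


class PathwayRecord(BaseModel):
    """One significant pathway from an upstream enrichment table."""

    name: str
    pathway_id: Optional[str] = None
    source_db: SourceDB = SourceDB.other
    n_proteins: Optional[int] = Field(default=None, ge=0)
    n_degs: Optional[int] = Field(default=None, ge=0)
    p_adjusted: float = Field(ge=0.0, le=1.0)
    status: PathwayStatus = PathwayStatus.unknown

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("pathway name must be nonempty")
        return v

    @model_validator(mode="after")
    def _degs_le_proteins(self) -> "PathwayRecord":
        if (
            self.n_proteins is not None
            and self.n_degs is not None
            and self.n_degs > self.n_proteins
        ):
            raise ValueError(
                f"n_degs ({self.n_degs}) exceeds n_proteins ({self.n_proteins})"
            )
        return self


class TargetRecord(BaseModel):
    """One gene product with its scoreable attributes.

    The per-run pathway count is deliberately *not* stored here: it depends
    on which pathways were significant in a given input and is computed at
    scoring time.
    """

    symbol: str
    ensembl_id: str
    uniprot_ids: list[str] = Field(default_factory=list)
    name: str = ""
    n_associated_diseases: int = Field(default=0, ge=0)
    tractability_count: int = Field(default=0, ge=0)
    tractability_flags: Optional[dict[str, bool]] = None
    subcellular_location: str = "No data"
    n_safety_liabilities: int = Field(default=0, ge=0)
    n_unique_drugs: int = Field(default=0, ge=0)
    n_approved: int = Field(default=0, ge=0)
    n_phase1: int = Field(default=0, ge=0)
    n_phase2: int = Field(default=0, ge=0)
    n_phase3: int = Field(default=0, ge=0)
    n_phase4: int = Field(default=0, ge=0)

    @field_validator("ensembl_id")
    @classmethod
    def _ensembl_pattern(cls, v: str) -> str:
        if not ENSG_PATTERN.match(v):
            raise ValueError(f"not an Ensembl gene accession: {v!r}")
        return v

    @field_validator("tractability_flags")
    @classmethod
    def _exactly_twelve_keys(
        cls, v: Optional[dict[str, bool]]
    ) -> Optional[dict[str, bool]]:
        if v is not None and set(v) != set(TRACTABILITY_KEYS):
            raise ValueError(
                "tractability_flags must have exactly the 12 modality:stage keys"
            )
        return v


class DrugLink(BaseModel):
    """One therapeutic linked to a target.

    ``is_approved`` and ``max_phase`` are reported as the source supplies
    them; no cross-field constraint is enforced because real source data
    occasionally disagree.
    """

    drug_id: str
    drug_name: str = ""
    drug_type: str = ""
    action: str = ""
    max_phase: int = Field(default=0, ge=0, le=4)
    is_approved: bool = False
    target_ensembl_id: str

    @field_validator("target_ensembl_id")
    @classmethod
    def _ensembl_pattern(cls, v: str) -> str:
        if not ENSG_PATTERN.match(v):
            raise ValueError(f"not an Ensembl gene accession: {v!r}")
        return v


class PathwayEntry(BaseModel):
    """Snapshot-side pathway definition: name, provenance, membership."""

    name: str
    source_db: SourceDB = SourceDB.other
    member_ensembl_ids: list[str] = Field(default_factory=list)

    @field_validator("member_ensembl_ids")
    @classmethod
    def _members_ensg(cls, v: list[str]) -> list[str]:
        for m in v:
            if not ENSG_PATTERN.match(m):
                raise ValueError(f"pathway member is not ENSG-patterned: {m!r}")
        return v


class GeneMapEntry(BaseModel):
    """One row of the gene-identifier crosswalk."""

    symbol: str
    ensembl_id: str
    entrez_id: Optional[str] = None
    uniprot_ids: list[str] = Field(default_factory=list)

    @field_validator("ensembl_id")
    @classmethod
    def _ensembl_pattern(cls, v: str) -> str:
        if not ENSG_PATTERN.match(v):
            raise ValueError(f"not an Ensembl gene accession: {v!r}")
        return v


class SnapshotIntegrityError(ValueError):
    """Referential-integrity violation inside a snapshot."""


class Snapshot(BaseModel):
    """Offline bundle of pathways, identifier maps, targets and drug links."""

    schema_version: str = "1"
    pathways: dict[str, PathwayEntry] = Field(default_factory=dict)
    gene_map: list[GeneMapEntry] = Field(default_factory=list)
    targets: dict[str, TargetRecord] = Field(default_factory=dict)
    drugs: list[DrugLink] = Field(default_factory=list)

    @model_validator(mode="after")
    def _referential_integrity(self) -> "Snapshot":
        for drug in self.drugs:
            if drug.target_ensembl_id not in self.targets:
                raise SnapshotIntegrityError(
                    f"drug {drug.drug_id!r} references unknown target "
                    f"{drug.target_ensembl_id!r}"
                )
        seen: set[str] = set()
        for entry in self.gene_map:
            if entry.ensembl_id in seen:
                raise SnapshotIntegrityError(
                    f"duplicate ensembl_id in gene_map: {entry.ensembl_id!r}"
                )
            seen.add(entry.ensembl_id)
        return self
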