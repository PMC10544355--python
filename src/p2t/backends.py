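"""Target-data backends.

The pipeline needs four lookups: pathway membership, gene-identifier
mapping, per-target attributes, and drug links. The reference backend is
an offline JSON :class:`~p2t.types.Snapshot`, validated on load; an
optional live client can populate an equivalent snapshot from an Open
Targets-style GraphQL endpoint, so the rest of the pipeline never knows
whether its data came from a file or the network.
"""

from __future__ import annotations

import json
import logging
import math
import time
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from pydantic import ValidationError

from .types import DrugLink, PathwayRecord, Snapshot, TargetRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SnapshotLoadError",
    "TargetNotFoundError",
    "load_snapshot",
    "save_snapshot",
    "snapshot_to_canonical_json",
    "get_pathway_members",
    "map_gene_ids",
    "get_target_record",
    "get_drugs_for_target",
    "LiveQueryPlan",
    "build_live_query",
    "parse_live_response",
    "fetch_live_snapshot",
]

ID_SPACES = ("symbol", "ensembl", "entrez", "uniprot")


class SnapshotLoadError(ValueError):
    """Snapshot file failed schema or integrity validation."""


class TargetNotFoundError(KeyError):
    """Requested target accession absent from the snapshot."""


def load_snapshot(path: Union[str, Path]) -> Snapshot:
    """Load and validate a snapshot JSON file.

    Schema violations and referential-integrity violations (for example a
    drug link pointing at a missing target) are both reported as
    :class:`SnapshotLoadError` with the offending location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"snapshot not found: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SnapshotLoadError(f"{path}: not valid JSON: {exc}") from exc
    try:
        return Snapshot.model_validate(raw)
    except ValidationError as exc:
        locations = "; ".join(
            "/".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise SnapshotLoadError(f"{path}: schema violation at {locations}") from exc


def snapshot_to_canonical_json(snapshot: Snapshot) -> str:
    """Serialize with sorted keys and fixed formatting (byte-reproducible)."""
    payload = snapshot.model_dump(mode="json")
    return json.dumps(payload, sort_keys=True, indent=1, ensure_ascii=False) + "\n"


def save_snapshot(snapshot: Snapshot, path: Union[str, Path]) -> None:
    Path(path).write_text(snapshot_to_canonical_json(snapshot), encoding="utf-8")


def get_pathway_members(snapshot: Snapshot, pathway: PathwayRecord) -> list[str]:
    """Member Ensembl accessions of a pathway.

    Lookup tries the pathway accession first, then an exact name match.
    Input pathway lists routinely outnumber snapshot coverage, so a miss
    is a logged warning and an empty list, not an error.
    """
    if pathway.pathway_id and pathway.pathway_id in snapshot.pathways:
        return list(snapshot.pathways[pathway.pathway_id].member_ensembl_ids)
    for entry in snapshot.pathways.values():
        if entry.name == pathway.name:
            return list(entry.member_ensembl_ids)
    logger.warning("pathway not in snapshot: %s (%s)", pathway.name, pathway.pathway_id)
    return []


def _gene_entry_ids(entry, space: str) -> list[str]:
    if space == "symbol":
        return [entry.symbol]
    if space == "ensembl":
        return [entry.ensembl_id]
    if space == "entrez":
        return [entry.entrez_id] if entry.entrez_id else []
    if space == "uniprot":
        return list(entry.uniprot_ids)
    raise ValueError(f"unknown id-space {space!r}; expected one of {ID_SPACES}")


def map_gene_ids(
    snapshot: Snapshot,
    ids: list[str],
    from_space: str,
    to_space: str,
) -> dict[str, str]:
    """Map identifiers between id-spaces via the snapshot's gene map.

    Returns a partial map: inputs with no mapping are absent from the
    result (and logged). When a gene carries several identifiers in the
    target space (UniProt, typically) the first stored one is returned.
    """
    for space in (from_space, to_space):
        if space not in ID_SPACES:
            raise ValueError(f"unknown id-space {space!r}; expected one of {ID_SPACES}")
    index: dict[str, str] = {}
    for entry in snapshot.gene_map:
        targets = _gene_entry_ids(entry, to_space)
        if not targets:
            continue
        for key in _gene_entry_ids(entry, from_space):
            index.setdefault(key, targets[0])
    result: dict[str, str] = {}
    for ident in ids:
        if ident in index:
            result[ident] = index[ident]
        else:
            logger.info("unmapped %s id: %s", from_space, ident)
    return result


def get_target_record(snapshot: Snapshot, ensembl_id: str) -> TargetRecord:
    """The stored record for ``ensembl_id``, verbatim."""
    try:
        return snapshot.targets[ensembl_id]
    except KeyError:
        raise TargetNotFoundError(ensembl_id) from None


def get_drugs_for_target(snapshot: Snapshot, ensembl_id: str) -> list[DrugLink]:
    """All drug links for a target, sorted by drug id; unknown target -> []."""
    links = [d for d in snapshot.drugs if d.target_ensembl_id == ensembl_id]
    return sorted(links, key=lambda d: d.drug_id)


# --------------------------------------------------------------------------
# Optional live GraphQL client.
#
# build_live_query constructs text only and is fully testable offline;
# fetch_live_snapshot is the thin network wrapper and is never exercised by
# the test suite.

_TARGET_QUERY_TEMPLATE = """\
query targetAnnotation($ensemblIds: [String!]!) {
  targets(ensemblIds: $ensemblIds) {
    id
    approvedSymbol
    approvedName
    proteinIds { id source }
    associatedDiseases { count }
    tractability { modality label value }
    subcellularLocations { location }
    safetyLiabilities { event }
    knownDrugs {
      uniqueDrugs
      rows {
        drugId
        prefName
        drugType
        mechanismOfAction
        phase
        status
      }
    }
  }
}
"""


@dataclass
class LiveQueryPlan:
    """A GraphQL query document plus the id batches to submit it with."""

    query: str
    batches: list[list[str]] = field(default_factory=list)

    @property
    def n_batches(self) -> int:
        return len(self.batches)


def build_live_query(ensembl_ids: list[str], page_size: int = 100) -> LiveQueryPlan:
    """Build the target-annotation query and its pagination plan.

    Batches are ceiling-divided at ``page_size`` ids per request. This
    constructs text only; network execution lives in
    :func:`fetch_live_snapshot`.
    """
    if not ensembl_ids:
        raise ValueError("ensembl_ids must be nonempty")
    if page_size < 1:
        raise ValueError("page_size must be >= 1")
    n = math.ceil(len(ensembl_ids) / page_size)
    batches = [
        list(ensembl_ids[i * page_size : (i + 1) * page_size]) for i in range(n)
    ]
    return LiveQueryPlan(query=_TARGET_QUERY_TEMPLATE, batches=batches)


def _phase_counts(rows: list[dict]) -> dict[str, int]:
    counts = {"n_approved": 0, "n_phase1": 0, "n_phase2": 0, "n_phase3": 0, "n_phase4": 0}
    # one therapeutic may occur in several rows (one per indication); count
    # each drug once at its maximum phase
    best: dict[str, int] = {}
    approved: set[str] = set()
    for row in rows:
        did = row.get("drugId", "")
        phase = int(row.get("phase") or 0)
        best[did] = max(best.get(did, 0), phase)
        if str(row.get("status", "")).lower() == "approved" or phase == 4:
            approved.add(did)
    for did, phase in best.items():
        if 1 <= phase <= 4:
            counts[f"n_phase{phase}"] += 1
    counts["n_approved"] = len(approved)
    return counts


def parse_live_response(payload: dict) -> Snapshot:
    """Convert a GraphQL response body into a Snapshot.

    Accepts the ``{"data": {"targets": [...]}}`` envelope or the bare
    target list. Pathway membership and the gene map are not part of the
    target-annotation query; the resulting snapshot carries targets and
    drug links only and is merged with pathway data elsewhere.
    """
    targets_json = payload.get("data", payload).get("targets", [])
    targets: dict[str, TargetRecord] = {}
    drugs: list[DrugLink] = []
    for t in targets_json:
        ensembl_id = t["id"]
        known = t.get("knownDrugs") or {}
        rows = known.get("rows") or []
        counts = _phase_counts(rows)
        locations = t.get("subcellularLocations") or []
        targets[ensembl_id] = TargetRecord(
            symbol=t.get("approvedSymbol", ensembl_id),
            ensembl_id=ensembl_id,
            uniprot_ids=[
                p["id"]
                for p in (t.get("proteinIds") or [])
                if p.get("source") == "uniprot_swissprot"
            ],
            name=t.get("approvedName", ""),
            n_associated_diseases=int(
                (t.get("associatedDiseases") or {}).get("count", 0)
            ),
            tractability_count=sum(
                1 for b in (t.get("tractability") or []) if b.get("value")
            ),
            subcellular_location=(
                locations[0]["location"] if locations else "No data"
            ),
            n_safety_liabilities=len(t.get("safetyLiabilities") or []),
            n_unique_drugs=int(known.get("uniqueDrugs", 0)),
            **counts,
        )
        seen: set[str] = set()
        for row in rows:
            did = row.get("drugId", "")
            if did in seen:
                continue
            seen.add(did)
            drugs.append(
                DrugLink(
                    drug_id=did,
                    drug_name=row.get("prefName", ""),
                    drug_type=row.get("drugType", ""),
                    action=row.get("mechanismOfAction", ""),
                    max_phase=max(
                        int(r.get("phase") or 0)
                        for r in rows
                        if r.get("drugId") == did
                    ),
                    is_approved=str(row.get("status", "")).lower() == "approved",
                    target_ensembl_id=ensembl_id,
                )
            )
    return Snapshot(targets=targets, drugs=drugs)


def fetch_live_snapshot(
    ensembl_ids: list[str],
    endpoint: str = "https://api.platform.opentargets.org/api/v4/graphql",
    page_size: int = 100,
    retries: int = 3,
    timeout: float = 30.0,
    backoff: float = 2.0,
) -> Snapshot:
    """Execute the live query with retry/backoff and merge the pages.

    Network access only; everything downstream consumes the returned
    Snapshot exactly as it would a file-loaded one.
    """
    plan = build_live_query(ensembl_ids, page_size=page_size)
    merged = Snapshot()
    for batch in plan.batches:
        body = json.dumps(
            {"query": plan.query, "variables": {"ensemblIds": batch}}
        ).encode()
        req = urllib.request.Request(
            endpoint, data=body, headers={"Content-Type": "application/json"}
        )
        last_err: Optional[Exception] = None
        for attempt in range(retries):
            try:
                with urllib.request.urlopen(req, timeout=timeout) as resp:
                    payload = json.load(resp)
                break
            except Exception as exc:  # pragma: no cover - network only
                last_err = exc
                time.sleep(backoff * (2**attempt))
        else:  # pragma: no cover - network only
            raise RuntimeError(f"live query failed after {retries} tries: {last_err}")
        page = parse_live_response(payload)
        merged.targets.update(page.targets)
        merged.drugs.extend(page.drugs)
    return merged
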