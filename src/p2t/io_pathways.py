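"""Parse pathway-enrichment result tables into :class:`PathwayRecord` lists.

Two dialects are supported:

* **SPIA** — the tabular output of a Signaling Pathway Impact Analysis run
  (one row per pathway, with pathway size, DEG count, a family of adjusted
  global p-value columns, and an Activated/Inhibited status).
* **enrichr** — the export of an over-representation analysis (one row per
  term, with an ``n/m`` overlap fraction and an adjusted p-value).

Both parsers keep rows in file order and never apply their own
multiple-testing correction: the p-values consumed here are already
adjusted upstream, and :func:`filter_significant` just applies the strict
``p < alpha`` cut.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .types import PathwayRecord, PathwayStatus, SourceDB

__all__ = [
    "PathwayTableFormatError",
    "parse_spia_table",
    "parse_enrichr_table",
    "filter_significant",
]


class PathwayTableFormatError(ValueError):
    """The input table does not conform to the expected dialect."""


#: canonical field -> candidate column names, first match wins.
#: The p-value fallback order prefers the most conservative adjustment
#: (FWER, then FDR, then the uncorrected global p).
_SPIA_DEFAULT_MAP: dict[str, Sequence[str]] = {
    "name": ("Name",),
    "pathway_id": ("ID",),
    "n_proteins": ("pSize",),
    "n_degs": ("NDE",),
    "p_adjusted": ("pGFWER", "pGFdr", "pG"),
    "status": ("Status",),
    "source_db": ("Source database", "SourceDB", "source_db", "Database", "DB"),
}

_REQUIRED_SPIA_FIELDS = ("name", "p_adjusted")

_ENRICHR_TERM_COLS = ("Term",)
_ENRICHR_OVERLAP_COLS = ("Overlap",)
_ENRICHR_P_COLS = ("Adjusted P-value", "Adj.P", "Adjusted P value")

_REACTOME_ID = re.compile(r"R-[A-Z]{3}-\d+")
_KEGG_ID = re.compile(r"\bhsa\d{5}\b")


def _parse_status(raw: object) -> PathwayStatus:
    text = str(raw).strip().lower()
    if text == "activated":
        return PathwayStatus.Activated
    if text == "inhibited":
        return PathwayStatus.Inhibited
    return PathwayStatus.unknown


def _parse_source_db(raw: object) -> SourceDB:
    text = str(raw).strip().lower()
    for member in SourceDB:
        if member.value.lower() == text:
            return member
    return SourceDB.other


def _read_table(path: Union[str, Path], delimiter: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pathway table not found: {path}")
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def _resolve_columns(
    columns: Sequence[str],
    column_map: Optional[dict[str, str]],
) -> dict[str, str]:
    """Resolve canonical field names to actual column names.

    ``column_map`` entries (field -> column name) take precedence over the
    built-in candidates; a mapped column that is absent from the file is a
    format error.
    """
    resolved: dict[str, str] = {}
    colset = set(columns)
    for field, candidates in _SPIA_DEFAULT_MAP.items():
        if column_map and field in column_map:
            wanted = column_map[field]
            if wanted not in colset:
                raise PathwayTableFormatError(
                    f"mapped column {wanted!r} for field {field!r} not in table"
                )
            resolved[field] = wanted
            continue
        for cand in candidates:
            if cand in colset:
                resolved[field] = cand
                break
    for field in _REQUIRED_SPIA_FIELDS:
        if field not in resolved:
            raise PathwayTableFormatError(
                f"required column for field {field!r} missing "
                f"(tried {list(_SPIA_DEFAULT_MAP[field])})"
            )
    return resolved


def _parse_p(raw: str, row_index: int) -> float:
    try:
        p = float(str(raw).replace("−", "-"))  # tolerate unicode minus
    except (TypeError, ValueError) as exc:
        raise PathwayTableFormatError(
            f"row {row_index}: unparseable p-value {raw!r}"
        ) from exc
    if not 0.0 <= p <= 1.0:
        raise PathwayTableFormatError(
            f"row {row_index}: p-value {p} outside [0, 1]"
        )
    return p


def _parse_count(raw: str) -> Optional[int]:
    text = str(raw).replace(",", "").strip()
    if not text:
        return None
    return int(float(text))


def parse_spia_table(
    path: Union[str, Path],
    column_map: Optional[dict[str, str]] = None,
    delimiter: str = "\t",
) -> list[PathwayRecord]:
    """Parse a SPIA-dialect enrichment table.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Optional mapping of canonical field name (``name``, ``pathway_id``,
        ``n_proteins``, ``n_degs``, ``p_adjusted``, ``status``,
        ``source_db``) to the column holding it; overrides the built-in
        SPIA column names.
    delimiter
        Field delimiter; pass ``","`` for CSV exports.

    Returns
    -------
    list of PathwayRecord, one per data row, in file order.
    """
    df = _read_table(path, delimiter)
    resolved = _resolve_columns(list(df.columns), column_map)
    records: list[PathwayRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowmap = dict(zip(df.columns, row))
        kwargs: dict[str, object] = {
            "name": str(rowmap[resolved["name"]]),
            "p_adjusted": _parse_p(rowmap[resolved["p_adjusted"]], i),
        }
        if "pathway_id" in resolved:
            pid = str(rowmap[resolved["pathway_id"]]).strip()
            kwargs["pathway_id"] = pid or None
        if "n_proteins" in resolved:
            kwargs["n_proteins"] = _parse_count(rowmap[resolved["n_proteins"]])
        if "n_degs" in resolved:
            kwargs["n_degs"] = _parse_count(rowmap[resolved["n_degs"]])
        if "status" in resolved:
            kwargs["status"] = _parse_status(rowmap[resolved["status"]])
        if "source_db" in resolved:
            kwargs["source_db"] = _parse_source_db(rowmap[resolved["source_db"]])
        records.append(PathwayRecord(**kwargs))
    return records


def _infer_source_from_term(term: str) -> tuple[SourceDB, Optional[str]]:
    m = _REACTOME_ID.search(term)
    if m:
        return SourceDB.Reactome, m.group(0)
    m = _KEGG_ID.search(term)
    if m:
        return SourceDB.KEGG, m.group(0)
    return SourceDB.other, None


def parse_enrichr_table(
    path: Union[str, Path],
    delimiter: str = "\t",
) -> list[PathwayRecord]:
    """Parse an enrichr-dialect export.

    The term string becomes the pathway name; the ``n/m`` overlap fraction
    supplies the DEG and pathway-size counts; a trailing Reactome or KEGG
    accession in the term, when present, fixes the source database and
    pathway id. Status is always unknown (over-representation analysis has
    no direction).
    """
    df = _read_table(path, delimiter)
    colset = set(df.columns)
    term_col = next((c for c in _ENRICHR_TERM_COLS if c in colset), None)
    overlap_col = next((c for c in _ENRICHR_OVERLAP_COLS if c in colset), None)
    p_col = next((c for c in _ENRICHR_P_COLS if c in colset), None)
    if term_col is None or p_col is None:
        raise PathwayTableFormatError(
            "enrichr table requires a 'Term' column and an adjusted p-value "
            f"column (one of {list(_ENRICHR_P_COLS)})"
        )
    records: list[PathwayRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowmap = dict(zip(df.columns, row))
        term = str(rowmap[term_col])
        source_db, pathway_id = _infer_source_from_term(term)
        n_degs = n_proteins = None
        if overlap_col is not None:
            overlap = str(rowmap[overlap_col]).strip()
            if overlap:
                parts = overlap.split("/")
                try:
                    n_degs, n_proteins = int(parts[0]), int(parts[1])
                except (IndexError, ValueError) as exc:
                    raise PathwayTableFormatError(
                        f"row {i}: malformed overlap field {overlap!r}"
                    ) from exc
        records.append(
            PathwayRecord(
                name=term,
                pathway_id=pathway_id,
                source_db=source_db,
                n_degs=n_degs,
                n_proteins=n_proteins,
                p_adjusted=_parse_p(rowmap[p_col], i),
                status=PathwayStatus.unknown,
            )
        )
    return records


def filter_significant(
    records: list[PathwayRecord], alpha: float = 0.05
) -> list[PathwayRecord]:
    """Retain pathways with adjusted p strictly below ``alpha``, in order."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    return [r for r in records if r.p_adjusted < alpha]
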