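"""Reading and writing BioRECIPE-style interaction tables.

One interaction per row, header required.  Tab- or comma-delimited text and
spreadsheets are accepted.  Column headers are mapped case-insensitively
through an extensible dialect table that understands both the
``Regulator*/Regulated*`` pairing used by BioRECIPE and the ``Source*/Target*``
pairing emitted by some converters.  Rows whose endpoints carry no usable
identity, or whose sign cannot be mapped onto {positive, negative}, are
rejected with a row-indexed report — never silently dropped.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    Element,
    Interaction,
    InteractionList,
    normalize_connection,
    normalize_identifier,
    normalize_sign,
)

__all__ = [
    "FormatError",
    "RowErrorsError",
    "read_interactions",
    "write_interactions",
    "write_classified",
    "unique_interactions",
    "register_column_alias",
    "interactions_to_frame",
]


class FormatError(ValueError):
    """The file's header does not describe a readable interaction table."""


class RowErrorsError(ValueError):
    """One or more data rows were rejected; ``row_errors`` lists (row, message)."""

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = row_errors
        lines = "; ".join(f"row {i}: {msg}" for i, msg in row_errors[:20])
        extra = "" if len(row_errors) <= 20 else f" (+{len(row_errors) - 20} more)"
        super().__init__(f"{len(row_errors)} row(s) rejected: {lines}{extra}")


def _norm_header(h: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(h).lower())


# canonical field -> set of normalized header aliases; user-extensible via
# register_column_alias.  Endpoint fields exist in a source and a target
# flavour, generated from both Regulator/Regulated and Source/Target prefixes.
_ENDPOINT_SUFFIXES = {
    "name": ("name", ""),
    "id": ("id", "databaseid", "identifier", "dbid"),
    "symbol": ("hgncsymbol", "symbol", "genesymbol"),
    "type": ("type", "elementtype"),
    "compartment": ("compartment", "location"),
    "compartment_id": ("compartmentid", "locationid"),
}
_SRC_PREFIXES = ("regulator", "source")
_TGT_PREFIXES = ("regulated", "target")

_SCALAR_ALIASES: dict[str, tuple[str, ...]] = {
    "sign": ("sign", "interactionsign", "regulationsign", "effect"),
    "connection": ("connectiontype", "connection", "direct", "directindirect"),
    "mechanism": ("mechanism", "interactionmechanism"),
    "cell_line": ("cellline",),
    "cell_type": ("celltype",),
    "tissue": ("tissuetype", "tissue"),
    "organism": ("organism", "species"),
    "context": ("context", "contextother"),
    "score": ("score", "readerscore", "beliefscore"),
    "paper_ids": ("paperids", "paperid", "pmid", "pmcid", "papers"),
    "evidence": ("evidence", "statements", "statement", "evidencestatement"),
    "source_db": ("database", "sourcedatabase"),
}

_ALIAS_TABLE: dict[str, str] = {}


def _rebuild_alias_table() -> None:
    _ALIAS_TABLE.clear()
    for field, suffixes in _ENDPOINT_SUFFIXES.items():
        for prefix in _SRC_PREFIXES:
            for suf in suffixes:
                _ALIAS_TABLE[prefix + suf] = "src_" + field
        for prefix in _TGT_PREFIXES:
            for suf in suffixes:
                _ALIAS_TABLE[prefix + suf] = "tgt_" + field
    for field, aliases in _SCALAR_ALIASES.items():
        for a in aliases:
            _ALIAS_TABLE[a] = field


_rebuild_alias_table()


def register_column_alias(header: str, canonical: str) -> None:
    """Extend the column dialect: map ``header`` onto a canonical field.

    ``canonical`` is one of the scalar fields (``sign``, ``mechanism``, ...)
    or an endpoint field such as ``src_id``/``tgt_compartment``.
    """
    _ALIAS_TABLE[_norm_header(header)] = canonical


def _map_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map actual headers onto canonical field names.

    A bare ``Source``/``Target`` column is an endpoint name only when no
    Regulator/Regulated identity column is present; otherwise ``Source`` is
    provenance (originating database) and left unmapped.
    """
    normed = {col: _norm_header(col) for col in columns}
    has_regulator = any(
        n.startswith("regulator") or n.startswith("regulated") for n in normed.values()
    )
    mapping: dict[str, str] = {}
    for col, n in normed.items():
        if has_regulator and n in ("source", "target"):
            continue  # provenance in the Regulator/Regulated dialect
        canon = _ALIAS_TABLE.get(n)
        if canon is not None and canon not in mapping.values():
            mapping[col] = canon
    return mapping


def _read_frame(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls", ".xlsm"):
        return pd.read_excel(path, dtype=str).fillna("")
    if suffix == ".csv":
        sep = ","
    elif suffix in (".tsv", ".tab", ".txt"):
        sep = "\t"
    else:
        with open(path, newline="") as fh:
            sample = fh.readline()
        try:
            sep = csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
        except csv.Error:
            sep = "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


_CONTEXT_ITEM = re.compile(r"\s*([^=;]+)=([^;]*)\s*")


def _parse_context(raw: str) -> dict[str, str]:
    """Parse a serialized context map: ``key=value; key=value``."""
    out: dict[str, str] = {}
    for m in _CONTEXT_ITEM.finditer(raw):
        key = m.group(1).strip().lower()
        if key:
            out[key] = m.group(2).strip()
    return out


def _format_context(ctx: dict[str, str]) -> str:
    return "; ".join(f"{k}={v}" for k, v in sorted(ctx.items()))


def _resolve_endpoint(row: pd.Series, mapping: dict[str, str], side: str) -> Element:
    """Build an Element from a row, applying identity precedence ID>symbol>name."""
    def get(field: str) -> str:
        for col, canon in mapping.items():
            if canon == f"{side}_{field}":
                return str(row[col]).strip()
        return ""

    db_id, symbol, name = get("id"), get("symbol"), get("name")
    if db_id:
        identifier, id_source = db_id, "database_id"
    elif symbol:
        identifier, id_source = symbol, "symbol"
    elif name:
        identifier, id_source = name, "name"
    else:
        raise ValueError(f"missing {side} identity (no ID, symbol or name)")
    return Element(
        name=name or symbol or db_id,
        identifier=identifier,
        element_type=get("type") or "other",
        id_source=id_source,
        compartment=get("compartment").strip().lower(),
        compartment_id=get("compartment_id").strip().lower(),
    )


def read_interactions(
    path, role: str = "new_list", strict: bool = True, label: Optional[str] = None
) -> InteractionList:
    """Read an interaction table into an :class:`InteractionList`.

    Parameters
    ----------
    path
        Delimited text (tab/comma) or spreadsheet with a header row.
    role
        ``"new_list"`` or ``"baseline"``; recorded on the list's label.
    strict
        If True (default), any rejected row raises :class:`RowErrorsError`
        with the full row-indexed report; if False, valid rows are kept and
        the report is attached as ``InteractionList.row_errors``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    frame = _read_frame(path)
    mapping = _map_columns(list(frame.columns))
    canon = set(mapping.values())
    if not any(c.startswith("src_") for c in canon):
        raise FormatError(
            "header lacks a recognized regulator/source identity column "
            "(expected e.g. 'Regulator Name' or 'Source ID')"
        )
    if not any(c.startswith("tgt_") for c in canon):
        raise FormatError(
            "header lacks a recognized regulated/target identity column "
            "(expected e.g. 'Regulated Name' or 'Target ID')"
        )
    if "sign" not in canon:
        raise FormatError("header lacks a recognized sign column")

    def scalar(row: pd.Series, field: str) -> str:
        for col, c in mapping.items():
            if c == field:
                return str(row[col]).strip()
        return ""

    interactions: list[Interaction] = []
    row_errors: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            source = _resolve_endpoint(row, mapping, "src")
            target = _resolve_endpoint(row, mapping, "tgt")
            sign = normalize_sign(scalar(row, "sign"))
            connection = normalize_connection(scalar(row, "connection"))
        except ValueError as exc:
            row_errors.append((i, str(exc)))
            continue
        provenance = {
            key: scalar(row, key)
            for key in ("score", "paper_ids", "evidence", "source_db")
            if scalar(row, key)
        }
        interactions.append(
            Interaction(
                source=source,
                target=target,
                sign=sign,
                connection=connection,
                mechanism=scalar(row, "mechanism").lower(),
                cell_line=scalar(row, "cell_line").lower(),
                cell_type=scalar(row, "cell_type").lower(),
                tissue=scalar(row, "tissue").lower(),
                organism=scalar(row, "organism").lower(),
                context_other=_parse_context(scalar(row, "context").lower()),
                provenance=provenance,
                index=i,
            )
        )
    if strict and row_errors:
        raise RowErrorsError(row_errors)
    return InteractionList(
        interactions=interactions,
        source_label=label or f"{role}:{path.name}",
        row_errors=row_errors,
    )


_OUT_COLUMNS = [
    "Regulator Name", "Regulator ID", "Regulator Type",
    "Regulator Compartment", "Regulator Compartment ID",
    "Regulated Name", "Regulated ID", "Regulated Type",
    "Regulated Compartment", "Regulated Compartment ID",
    "Sign", "Connection Type", "Mechanism", "Cell Line", "Cell Type",
    "Tissue Type", "Organism", "Context", "Score", "Paper IDs", "Evidence",
]


def _interaction_row(it: Interaction) -> dict[str, str]:
    return {
        "Regulator Name": it.source.name,
        "Regulator ID": it.source.identifier,
        "Regulator Type": it.source.element_type,
        "Regulator Compartment": it.source.compartment,
        "Regulator Compartment ID": it.source.compartment_id,
        "Regulated Name": it.target.name,
        "Regulated ID": it.target.identifier,
        "Regulated Type": it.target.element_type,
        "Regulated Compartment": it.target.compartment,
        "Regulated Compartment ID": it.target.compartment_id,
        "Sign": it.sign,
        "Connection Type": it.connection,
        "Mechanism": it.mechanism,
        "Cell Line": it.cell_line,
        "Cell Type": it.cell_type,
        "Tissue Type": it.tissue,
        "Organism": it.organism,
        "Context": _format_context(it.context_other),
        "Score": it.provenance.get("score", ""),
        "Paper IDs": it.provenance.get("paper_ids", ""),
        "Evidence": it.provenance.get("evidence", ""),
    }


def interactions_to_frame(interactions: Iterable[Interaction]) -> pd.DataFrame:
    rows = [_interaction_row(it) for it in interactions]
    return pd.DataFrame(rows, columns=_OUT_COLUMNS)


def _write_frame(path: Path, frame: pd.DataFrame) -> None:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        frame.to_excel(path, index=False)
    elif suffix == ".csv":
        frame.to_csv(path, index=False)
    else:
        frame.to_csv(path, sep="\t", index=False)


def write_interactions(path, interactions: Iterable[Interaction]) -> None:
    """Write interactions as a canonical BioRECIPE-style table."""
    _write_frame(Path(path), interactions_to_frame(interactions))


def write_classified(path, classified: Sequence) -> None:
    """Write classified interactions: input columns + Category, Subcategory,
    MatchedBaseline and Mismatches, in input row order."""
    frame = interactions_to_frame(c.interaction for c in classified)
    frame["Category"] = [c.category for c in classified]
    frame["Subcategory"] = [c.subcategory for c in classified]
    frame["MatchedBaseline"] = [c.describe_matched() for c in classified]
    frame["Mismatches"] = [c.mismatches.describe() if c.mismatches else "" for c in classified]
    _write_frame(Path(path), frame)


def unique_interactions(lst: InteractionList) -> tuple[int, InteractionList]:
    """Count and extract unique interactions.

    Uniqueness key = (source identity, target identity, sign, connection);
    the first occurrence of each key is retained, in input order.
    """
    seen: dict[tuple, Interaction] = {}
    for it in lst:
        seen.setdefault(it.dedup_key, it)
    unique = InteractionList(
        interactions=list(seen.values()),
        source_label=lst.source_label + ":unique" if lst.source_label else "unique",
    )
    return len(unique), unique
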