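"""Conversion between the odML tree and the flat row representation.

In the tabular dialect every value occupies one row; the section hierarchy
is encoded in a ``/``-delimited "path to section" column.  A property with
no values still yields one row with an empty value cell.  Sections that hold
no properties anywhere in their subtree produce no rows at all — they are
the declared loss of the tabular round trip.

``compact``/``expand`` implement the readability option of blanking cells
that repeat the cell above (and the inverse forward-fill on read).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .model import (
    DEFAULT_REGISTRY,
    Document,
    DtypeRegistry,
    PATH_DELIMITER,
    Property,
    Section,
    validate,
)

__all__ = [
    "FlatRow",
    "DocumentInfo",
    "DialectError",
    "flatten",
    "unflatten",
    "compact",
    "expand",
    "EMPTY_STRING_SENTINEL",
    "SECTION_COLUMNS",
    "PROPERTY_COLUMNS",
]

#: Cell text that denotes a value which IS the empty string (as opposed to an
#: empty cell, which denotes a missing value).
EMPTY_STRING_SENTINEL = '""'

#: Column groups for compaction: section-level cells reset together on a
#: path change; property-level cells reset on property or section change.
SECTION_COLUMNS = (
    "path_to_section",
    "section_name",
    "section_type",
    "section_definition",
)
PROPERTY_COLUMNS = (
    "property_name",
    "property_definition",
    "data_unit",
    "data_uncertainty",
    "odml_data_type",
    "value_origin",
    "property_reference",
)


class DialectError(ValueError):
    """Raised for row sequences that do not form a valid flat document."""


@dataclass
class FlatRow:
    """One value-level record of the flat dialect.

    All fields are cell text; empty string means an empty/absent cell.
    Rows of one property agree on every field except ``value``.
    """

    path_to_section: str = ""
    section_name: str = ""
    section_type: str = ""
    section_definition: str = ""
    property_name: str = ""
    property_definition: str = ""
    value: str = ""
    data_unit: str = ""
    data_uncertainty: str = ""
    odml_data_type: str = ""
    value_origin: str = ""
    property_reference: str = ""


@dataclass
class DocumentInfo:
    """The four document attributes carried in the table's top row."""

    author: str = ""
    date: str = ""
    version: str = ""
    repository: str = ""


def _render_value(value, dtype: str | None, reg: DtypeRegistry) -> str:
    text = reg.format(value, dtype)
    if text == "":
        # a genuine empty-string value must stay distinguishable from "no
        # value"; write the sentinel quote pair
        return EMPTY_STRING_SENTINEL
    return text


def _property_rows(
    path: str, sec: Section, prop: Property, reg: DtypeRegistry
) -> list[FlatRow]:
    base = dict(
        path_to_section=path,
        section_name=sec.name,
        section_type=sec.type or "",
        section_definition=sec.definition or "",
        property_name=prop.name,
        property_definition=prop.definition or "",
        data_unit=prop.unit or "",
        data_uncertainty="" if prop.uncertainty is None else repr(prop.uncertainty),
        odml_data_type=prop.dtype or "",
        value_origin=prop.value_origin or "",
        property_reference=prop.reference or "",
    )
    if not prop.values:
        return [FlatRow(value="", **base)]
    return [
        FlatRow(value=_render_value(v, prop.dtype, reg), **base)
        for v in prop.values
    ]


def flatten(
    document: Document, registry: DtypeRegistry | None = None
) -> tuple[DocumentInfo, list[FlatRow]]:
    """Flatten a validated document into (document info, one row per value)."""
    reg = registry or DEFAULT_REGISTRY
    info = DocumentInfo(
        author=document.author or "",
        date=document.date.isoformat() if document.date else "",
        version=document.version or "",
        repository=document.repository or "",
    )
    rows: list[FlatRow] = []
    for path, sec in document.itersections():
        for prop in sec.properties:
            rows.extend(_property_rows(path, sec, prop, reg))
    return info, rows


def _none_if_empty(text: str) -> str | None:
    return text if text else None


def unflatten(
    info: DocumentInfo,
    rows: Sequence[FlatRow],
    registry: DtypeRegistry | None = None,
) -> Document:
    """Rebuild a document from fully expanded rows.

    Consecutive rows sharing (path, property name) form one property whose
    value list preserves row order.  Intermediate sections implied by a path
    are created with empty attributes.  UUIDs are not part of the dialect,
    so every entity gets a fresh one.
    """
    reg = registry or DEFAULT_REGISTRY
    import datetime as _dt

    doc = Document(
        author=_none_if_empty(info.author),
        date=_dt.date.fromisoformat(info.date) if info.date else None,
        version=_none_if_empty(info.version),
        repository=_none_if_empty(info.repository),
    )
    sections: dict[str, Section] = {}
    seen_groups: set[tuple[str, str]] = set()
    group_key: tuple[str, str] | None = None
    current: Property | None = None

    for rownum, row in enumerate(rows, start=1):
        if not row.path_to_section.startswith(PATH_DELIMITER):
            raise DialectError(
                f"row {rownum}: path {row.path_to_section!r} must start "
                f"with {PATH_DELIMITER!r}"
            )
        if not row.property_name:
            raise DialectError(f"row {rownum}: missing property name")
        sec = _ensure_section(doc, sections, row)
        key = (row.path_to_section, row.property_name)
        if key != group_key:
            if key in seen_groups:
                raise DialectError(
                    f"row {rownum}: rows of property {row.property_name!r} in "
                    f"{row.path_to_section!r} are not consecutive"
                )
            seen_groups.add(key)
            group_key = key
            current = Property(
                name=row.property_name,
                definition=_none_if_empty(row.property_definition),
                dtype=_none_if_empty(row.odml_data_type),
                unit=_none_if_empty(row.data_unit),
                uncertainty=float(row.data_uncertainty)
                if row.data_uncertainty
                else None,
                value_origin=_none_if_empty(row.value_origin),
                reference=_none_if_empty(row.property_reference),
            )
            sec.properties.append(current)
        else:
            assert current is not None
            _check_group_consistency(rownum, row, current)
        value_text = row.value
        if value_text == "":
            continue  # empty cell = no value
        if value_text == EMPTY_STRING_SENTINEL:
            value_text = ""
        if current.dtype:
            current.values.append(reg.parse(value_text, current.dtype))
        else:
            current.values.append(value_text)
    return doc


def _ensure_section(
    doc: Document, sections: dict[str, Section], row: FlatRow
) -> Section:
    path = row.path_to_section
    if path in sections:
        sec = sections[path]
        if row.section_name and sec.name != row.section_name:
            raise DialectError(
                f"section name {row.section_name!r} does not match the last "
                f"component of path {path!r}"
            )
        return sec
    parts = path.strip(PATH_DELIMITER).split(PATH_DELIMITER)
    if row.section_name and parts[-1] != row.section_name:
        raise DialectError(
            f"section name {row.section_name!r} does not match the last "
            f"component of path {path!r}"
        )
    parent_children = doc.sections
    sofar = ""
    for part in parts:
        sofar += PATH_DELIMITER + part
        if sofar not in sections:
            sec = Section(name=part)
            sections[sofar] = sec
            parent_children.append(sec)
        parent_children = sections[sofar].sections
    sec = sections[path]
    sec.type = row.section_type or sec.type
    if row.section_definition:
        sec.definition = row.section_definition
    return sec


def _check_group_consistency(rownum: int, row: FlatRow, prop: Property) -> None:
    pairs = [
        ("property_definition", row.property_definition, prop.definition or ""),
        ("data_unit", row.data_unit, prop.unit or ""),
        (
            "data_uncertainty",
            row.data_uncertainty,
            "" if prop.uncertainty is None else repr(prop.uncertainty),
        ),
        ("odml_data_type", row.odml_data_type, prop.dtype or ""),
        ("value_origin", row.value_origin, prop.value_origin or ""),
        ("property_reference", row.property_reference, prop.reference or ""),
    ]
    for name, got, expected in pairs:
        if got != expected:
            raise DialectError(
                f"row {rownum}: {name} {got!r} conflicts with {expected!r} "
                f"in earlier rows of property {prop.name!r}"
            )


def compact(rows: Sequence[FlatRow]) -> list[FlatRow]:
    """Blank cells that repeat the cell above.

    Section-level cells are blanked while the path is unchanged; property
    level cells while both path and property name are unchanged.  Value
    cells are never blanked.  Inverted by :func:`expand`.
    """
    out: list[FlatRow] = []
    prev: FlatRow | None = None
    for row in rows:
        new = replace(row)
        if prev is not None:
            same_section = row.path_to_section == prev.path_to_section
            same_property = same_section and row.property_name == prev.property_name
            if same_section:
                for col in SECTION_COLUMNS:
                    if getattr(row, col) == getattr(prev, col):
                        setattr(new, col, "")
            if same_property:
                for col in PROPERTY_COLUMNS:
                    if getattr(row, col) == getattr(prev, col):
                        setattr(new, col, "")
        out.append(new)
        prev = row
    return out


def expand(rows: Sequence[FlatRow]) -> list[FlatRow]:
    """Forward-fill compacted rows back to full rows.

    A non-blank path cell starts a new section: section-level blanks are
    filled only within a section run, property-level blanks only within a
    property run.  The value column is never filled.
    """
    out: list[FlatRow] = []
    prev: FlatRow | None = None
    for rownum, row in enumerate(rows, start=1):
        new = replace(row)
        new_section = prev is None or bool(row.path_to_section)
        new_property = new_section or bool(row.property_name)
        if prev is None:
            if not row.path_to_section:
                raise DialectError("row 1: blank path-to-section cell")
            if not row.property_name:
                raise DialectError("row 1: blank property-name cell")
        else:
            if not new_section:
                for col in SECTION_COLUMNS:
                    if getattr(new, col) == "":
                        setattr(new, col, getattr(prev, col))
            if not new_property:
                for col in PROPERTY_COLUMNS:
                    if getattr(new, col) == "":
                        setattr(new, col, getattr(prev, col))
        out.append(new)
        prev = new
    return out


def row_count(document: Document) -> int:
    """Expected flatten row count: sum over properties of max(1, #values)."""
    total = 0
    for _, sec in document.itersections():
        for prop in sec.properties:
            total += max(1, len(prop.values))
    return total
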