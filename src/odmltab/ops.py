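"""Operations on metadata collections: templates, merge, filter, compare.

* ``create_template`` writes a table fixing the shape of future records;
  values present in the skeleton act as pre-filled defaults.
* ``merge`` reconciles two documents section by section; values of a
  property present in both are appended by default or replaced with
  ``overwrite_values=True``.
* ``filter_document`` narrows a collection to the properties matching a
  multi-step keep/reject specification (e.g. "all properties with no
  values"), keeping only the ancestor sections needed to house them.
* ``compare`` builds a presentation-only overview table of selected
  properties across sections (e.g. one column per recording day).
"""

from __future__ import annotations

import fnmatch
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

from .model import (
    DEFAULT_REGISTRY,
    Document,
    DtypeRegistry,
    PATH_DELIMITER,
    Property,
    Section,
    validate,
)
from . import table_io
from .table_io import StyleSpec, TableLayout

__all__ = [
    "MergeOptions",
    "MergeError",
    "FilterStep",
    "FilterSpec",
    "FilterSpecError",
    "CompareSpec",
    "CompareTable",
    "CompareSpecError",
    "create_template",
    "merge",
    "filter_document",
    "compare",
    "write_compare",
]


# ---------------------------------------------------------------------------
# templates

def create_template(
    path: str | Path,
    layout: TableLayout | None = None,
    skeleton: Document | None = None,
    registry: DtypeRegistry | None = None,
) -> None:
    """Write a template table (xlsx or csv by extension).

    With a skeleton document, its rows are written as-is: properties with
    empty value lists give empty value cells to be filled in later, while
    values present in the skeleton (e.g. a habitual experimenter name) act
    as pre-filled defaults.  Without a skeleton a single generic
    placeholder row is written.
    """
    path = Path(path)
    if skeleton is None:
        skeleton = Document(sections=[
            Section(name="Section", type="undefined", properties=[
                Property(name="Property", dtype="string"),
            ]),
        ])
    if path.suffix.lower() == ".csv":
        table_io.write_csv(skeleton, path, layout, registry)
    elif path.suffix.lower() == ".xlsx":
        table_io.write_xlsx(skeleton, path, layout, registry)
    else:
        raise ValueError(f"template path must end in .csv or .xlsx: {path}")


# ---------------------------------------------------------------------------
# merge

@dataclass
class MergeOptions:
    """``overwrite_values=False`` appends source values to coinciding
    properties; ``True`` replaces them (and lets source attributes win)."""

    overwrite_values: bool = False


class MergeError(ValueError):
    """Coinciding properties carry conflicting attributes in append mode."""


_PROP_ATTRS = ("definition", "dtype", "unit", "uncertainty",
               "value_origin", "reference")
_SEC_ATTRS = ("type", "definition", "reference", "link", "include", "repository")


def merge(
    target: Document,
    source: Document,
    options: MergeOptions | None = None,
) -> Document:
    """Merge *source* into a copy of *target*.

    Sections and properties of the source that are absent from the target
    are added (keeping their source UUIDs); entities already present keep
    the target's UUIDs.  Attributes absent in the target are filled from
    the source; conflicting scalar attributes resolve to the target in
    append mode and to the source in overwrite mode, except that a unit /
    uncertainty / dtype conflict on a value append is an error (silently
    mixing units would corrupt the value list).
    """
    options = options or MergeOptions()
    result = target.clone()
    _merge_section_lists(result.sections, source.sections, "", options)
    for attr in ("author", "date", "version", "repository"):
        if getattr(result, attr) is None and getattr(source, attr) is not None:
            setattr(result, attr, getattr(source, attr))
        elif options.overwrite_values and getattr(source, attr) is not None:
            setattr(result, attr, getattr(source, attr))
    return result


def _merge_section_lists(
    targets: list[Section], sources: Sequence[Section], path: str,
    options: MergeOptions,
) -> None:
    by_name = {sec.name: sec for sec in targets}
    for src in sources:
        if src.name not in by_name:
            targets.append(src.clone())
            continue
        tgt = by_name[src.name]
        spath = f"{path}{PATH_DELIMITER}{src.name}"
        for attr in _SEC_ATTRS:
            tval, sval = getattr(tgt, attr), getattr(src, attr)
            if attr == "type":
                blank = tval in (None, "", "undefined")
            else:
                blank = tval is None
            if sval not in (None, "", "undefined") and (
                blank or options.overwrite_values
            ):
                setattr(tgt, attr, sval)
        _merge_property_lists(tgt.properties, src.properties, spath, options)
        _merge_section_lists(tgt.sections, src.sections, spath, options)


def _merge_property_lists(
    targets: list[Property], sources: Sequence[Property], path: str,
    options: MergeOptions,
) -> None:
    by_name = {prop.name: prop for prop in targets}
    for src in sources:
        if src.name not in by_name:
            targets.append(src.clone())
            continue
        tgt = by_name[src.name]
        if options.overwrite_values:
            tgt.values = list(src.values)
            for attr in _PROP_ATTRS:
                if getattr(src, attr) is not None:
                    setattr(tgt, attr, getattr(src, attr))
        else:
            if src.values:
                for attr in ("dtype", "unit", "uncertainty"):
                    tval, sval = getattr(tgt, attr), getattr(src, attr)
                    if tval is not None and sval is not None and tval != sval \
                            and tgt.values:
                        raise MergeError(
                            f"property {path}:{src.name}: cannot append values "
                            f"with conflicting {attr} ({tval!r} vs {sval!r})"
                        )
                tgt.values.extend(src.values)
            for attr in _PROP_ATTRS:
                if getattr(tgt, attr) is None and getattr(src, attr) is not None:
                    setattr(tgt, attr, getattr(src, attr))


# ---------------------------------------------------------------------------
# filter

_FIELD_KEYS = ("path", "section_name", "section_type", "property_name",
               "value", "data_unit", "odml_data_type", "value_count")
_OPERATORS = ("equals", "contains", "matches", "is_empty")


class FilterSpecError(ValueError):
    """Malformed filter step (no comparisons, unknown field or operator)."""


@dataclass
class FilterStep:
    """One keep/reject pass over the property records of a document.

    ``comparisons`` are (field, operator, operand) triples combined with
    ``all`` or ``any``; a ``custom`` predicate over the property record dict
    participates in the same combination.
    """

    mode: str = "keep"
    comparisons: Sequence[tuple[str, str, Any]] = ()
    combine: str = "all"
    custom: Callable[[dict[str, Any]], bool] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("keep", "reject"):
            raise FilterSpecError(f"unknown mode {self.mode!r}")
        if self.combine not in ("all", "any"):
            raise FilterSpecError(f"unknown combine {self.combine!r}")
        if not self.comparisons and self.custom is None:
            raise FilterSpecError(
                "a filter step needs at least one comparison or a custom "
                "predicate"
            )
        for fieldkey, op, _ in self.comparisons:
            if fieldkey not in _FIELD_KEYS:
                raise FilterSpecError(
                    f"unknown field {fieldkey!r}; known: {_FIELD_KEYS}"
                )
            if op not in _OPERATORS:
                raise FilterSpecError(
                    f"unknown operator {op!r}; known: {_OPERATORS}"
                )

    def matches(self, record: dict[str, Any]) -> bool:
        results = [_compare(record, f, op, operand)
                   for f, op, operand in self.comparisons]
        if self.custom is not None:
            results.append(bool(self.custom(record)))
        return all(results) if self.combine == "all" else any(results)


@dataclass
class FilterSpec:
    """Ordered filter steps, applied left to right (keep intersects the
    survivors, reject subtracts from them)."""

    steps: Sequence[FilterStep] = ()

    def __post_init__(self) -> None:
        self.steps = tuple(self.steps)
        if not self.steps:
            raise FilterSpecError("a filter spec needs at least one step")


def _compare(record: dict[str, Any], fieldkey: str, op: str, operand: Any) -> bool:
    value = record[fieldkey]
    if fieldkey == "value":
        rendered = record["rendered_values"]
        if op == "is_empty":
            return not rendered
        return any(_scalar_compare(v, op, operand) for v in rendered)
    if fieldkey == "value_count":
        if op == "equals":
            return value == int(operand)
        if op == "is_empty":
            return value == 0
        raise FilterSpecError(f"operator {op!r} does not apply to value_count")
    return _scalar_compare(value, op, operand)


def _scalar_compare(value: Any, op: str, operand: Any) -> bool:
    text = "" if value is None else str(value)
    if op == "equals":
        return text == str(operand)
    if op == "contains":
        return str(operand) in text
    if op == "matches":
        return re.search(str(operand), text) is not None
    if op == "is_empty":
        return text == ""
    raise FilterSpecError(f"unknown operator {op!r}")


def property_record(path: str, sec: Section, prop: Property,
                    reg: DtypeRegistry) -> dict[str, Any]:
    """The flat record a filter predicate sees for one property."""
    return {
        "path": path,
        "section_name": sec.name,
        "section_type": sec.type or "",
        "property_name": prop.name,
        "value": prop.values,
        "rendered_values": [reg.format(v, prop.dtype) for v in prop.values],
        "data_unit": prop.unit or "",
        "odml_data_type": prop.dtype or "",
        "value_count": len(prop.values),
    }


def filter_document(
    document: Document,
    spec: FilterSpec,
    registry: DtypeRegistry | None = None,
) -> Document:
    """Extract the sub-document of properties surviving every filter step.

    Surviving properties are copied verbatim (UUIDs included) together with
    their ancestor sections; sections left without any kept property in
    their subtree are pruned.  The input document is not modified.
    """
    reg = registry or DEFAULT_REGISTRY
    kept: set[tuple[str, str]] = set()
    for path, sec in document.itersections():
        for prop in sec.properties:
            record = property_record(path, sec, prop, reg)
            surviving = True
            for step in spec.steps:
                hit = step.matches(record)
                if (step.mode == "keep" and not hit) or (
                    step.mode == "reject" and hit
                ):
                    surviving = False
                    break
            if surviving:
                kept.add((path, prop.name))

    out = Document(author=document.author, date=document.date,
                   version=document.version, repository=document.repository)
    out.sections = _prune_sections(document.sections, "", kept)
    return out


def _prune_sections(
    sections: Sequence[Section], prefix: str, kept: set[tuple[str, str]]
) -> list[Section]:
    result = []
    for sec in sections:
        path = f"{prefix}{PATH_DELIMITER}{sec.name}"
        subsections = _prune_sections(sec.sections, path, kept)
        properties = [p.clone() for p in sec.properties if (path, p.name) in kept]
        if properties or subsections:
            copy = sec.clone()
            copy.sections = subsections
            copy.properties = properties
            result.append(copy)
    return result


# ---------------------------------------------------------------------------
# compare

class CompareSpecError(ValueError):
    """Malformed compare specification."""


@dataclass
class CompareSpec:
    """Overview-table request: which properties, across which sections.

    ``section_selector`` is a glob pattern matched against section names
    anywhere in the tree (document order).  The resulting table is for
    visualization only and cannot be converted back to a document.
    """

    property_names: Sequence[str] = ()
    section_selector: str = "*"
    orientation: str = "sections-as-columns"

    def __post_init__(self) -> None:
        self.property_names = tuple(self.property_names)
        if not self.property_names:
            raise CompareSpecError("property_names must be non-empty")
        if len(set(self.property_names)) != len(self.property_names):
            raise CompareSpecError(
                f"duplicate property names in {self.property_names}"
            )
        if self.orientation not in ("sections-as-columns", "sections-as-rows"):
            raise CompareSpecError(f"unknown orientation {self.orientation!r}")


@dataclass
class CompareTable:
    """Rendered overview grid with row and column labels."""

    row_labels: list[str] = field(default_factory=list)
    column_labels: list[str] = field(default_factory=list)
    cells: list[list[str]] = field(default_factory=list)

    def as_grid(self) -> list[list[str]]:
        grid = [[""] + list(self.column_labels)]
        for label, row in zip(self.row_labels, self.cells):
            grid.append([label] + list(row))
        return grid


def render_cell(prop: Property, reg: DtypeRegistry) -> str:
    """Cell text: values joined by ", ", unit appended with no separator
    (e.g. ``5.0g``)."""
    text = ", ".join(reg.format(v, prop.dtype) for v in prop.values)
    if text and prop.unit:
        text += prop.unit
    return text


def compare(
    document: Document,
    spec: CompareSpec,
    registry: DtypeRegistry | None = None,
) -> CompareTable:
    """Build the overview table of *spec.property_names* across the sections
    whose name matches *spec.section_selector* (document order).  A property
    missing from a section gives an empty cell; a selector matching no
    section gives a zero-column table."""
    reg = registry or DEFAULT_REGISTRY
    matched = [sec for _, sec in document.itersections()
               if fnmatch.fnmatchcase(sec.name, spec.section_selector)]
    cells = []
    for name in spec.property_names:
        row = []
        for sec in matched:
            try:
                row.append(render_cell(sec.get_property(name), reg))
            except KeyError:
                row.append("")
        cells.append(row)
    table = CompareTable(
        row_labels=list(spec.property_names),
        column_labels=[sec.name for sec in matched],
        cells=cells,
    )
    if spec.orientation == "sections-as-rows":
        nrows, ncols = len(table.row_labels), len(table.column_labels)
        table = CompareTable(
            row_labels=list(table.column_labels),
            column_labels=list(table.row_labels),
            cells=[[table.cells[r][c] for r in range(nrows)]
                   for c in range(ncols)],
        )
    return table


def write_compare(
    table: CompareTable,
    path: str | Path,
    style: StyleSpec | None = None,
) -> None:
    """Save an overview table as csv or xlsx (by extension); xlsx carries
    header fills."""
    import csv as _csv

    import openpyxl
    from openpyxl.styles import Font, PatternFill

    path = Path(path)
    grid = table.as_grid()
    if path.suffix.lower() == ".csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            _csv.writer(fh, lineterminator="\n").writerows(grid)
    elif path.suffix.lower() == ".xlsx":
        style = style or StyleSpec()
        wb = openpyxl.Workbook()
        ws = wb.active
        ws.title = "comparison"
        for row in grid:
            ws.append(row)
        fill = PatternFill("solid", fgColor=style.header_fill)
        for cell in ws[1]:
            cell.fill = fill
            cell.font = Font(bold=True, color="FFFFFF")
        for i in range(2, len(grid) + 1):
            ws.cell(row=i, column=1).fill = fill
            ws.cell(row=i, column=1).font = Font(bold=True, color="FFFFFF")
        wb.save(path)
    else:
        raise ValueError(f"compare table path must end in .csv or .xlsx: {path}")
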