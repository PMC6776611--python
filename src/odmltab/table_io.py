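"""Tabular serialization of odML documents: csv (RFC 4180) and xlsx.

File grid layout:

* row 1 — document attributes, machine-parseable at fixed positions:
  ``Document Information, author, <author>, date, <date>, version,
  <version>, repository, <repository>``
* row 2 — display headers, customizable through a :class:`TableLayout`
  header map
* rows 3+ — one line per value (see :mod:`odmltab.flatten`), optionally
  compacted

Columns are associated with odML attributes by header *name*, never by
position, so users may reorder columns freely.  xlsx output additionally
carries fills: alternating colors per section/property block, red for
missing values, light yellow for cells holding the registry default of
their data type.  All styling is ignored when reading.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import openpyxl
from openpyxl.styles import Font, PatternFill

from .flatten import (
    DialectError,
    DocumentInfo,
    FlatRow,
    compact as _compact,
    expand as _expand,
    flatten,
    unflatten,
)
from .model import DEFAULT_REGISTRY, Document, DtypeRegistry, validate

__all__ = [
    "TableLayout",
    "StyleSpec",
    "LayoutError",
    "HeaderError",
    "CANONICAL_HEADERS",
    "MANDATORY_COLUMNS",
    "write_csv",
    "read_csv",
    "write_xlsx",
    "read_xlsx",
    "save_layout",
    "load_layout",
]

#: Canonical column keys and their default display headers.
CANONICAL_HEADERS = {
    "path_to_section": "Path to Section",
    "section_name": "Section Name",
    "section_type": "Section Type",
    "section_definition": "Section Definition",
    "property_name": "Property Name",
    "property_definition": "Property Definition",
    "value": "Value",
    "data_unit": "Data Unit",
    "data_uncertainty": "Data Uncertainty",
    "odml_data_type": "odML Data Type",
    "value_origin": "Value Origin",
    "property_reference": "Property Reference",
}

MANDATORY_COLUMNS = ("path_to_section", "property_name", "value")

#: Column selection used when no layout is given (value_origin and
#: property_reference are opt-in extras).
DEFAULT_COLUMNS = (
    "path_to_section",
    "section_name",
    "section_type",
    "section_definition",
    "property_name",
    "property_definition",
    "value",
    "data_unit",
    "data_uncertainty",
    "odml_data_type",
)

DOC_ROW_LABEL = "Document Information"


class LayoutError(ValueError):
    """Layout is missing mandatory columns or has a non-injective header map."""


class HeaderError(ValueError):
    """File headers cannot be resolved through the layout's header map."""


@dataclass
class StyleSpec:
    """Fill colors (RGB hex) for xlsx rendering."""

    section_row_colors: tuple[str, str] = ("DCE6F1", "B8CCE4")  # alternating blues
    property_row_colors: tuple[str, str] = ("F2F2F2", "D9D9D9")  # alternating grays
    missing_value_fill: str = "FF0000"  # red, the one color fixed by convention
    default_value_fill: str = "FFFF99"  # light yellow
    header_fill: str = "4F81BD"

    def __post_init__(self) -> None:
        for color in (*self.section_row_colors, *self.property_row_colors,
                      self.missing_value_fill, self.default_value_fill,
                      self.header_fill):
            int(color, 16)  # must be RGB hex


@dataclass
class TableLayout:
    """Column selection/order, display headers, compaction and style."""

    columns: tuple[str, ...] = DEFAULT_COLUMNS
    header_map: dict[str, str] = field(default_factory=dict)
    compaction: bool = True
    style: StyleSpec | None = None

    def __post_init__(self) -> None:
        self.columns = tuple(self.columns)
        unknown = [c for c in self.columns if c not in CANONICAL_HEADERS]
        if unknown:
            raise LayoutError(f"unknown column keys: {unknown}")
        missing = [c for c in MANDATORY_COLUMNS if c not in self.columns]
        if missing:
            raise LayoutError(f"layout is missing mandatory columns: {missing}")
        displays = [self.display_header(c) for c in self.columns]
        if len(set(displays)) != len(displays):
            raise LayoutError(f"header map is not injective: {displays}")

    def display_header(self, key: str) -> str:
        return self.header_map.get(key, CANONICAL_HEADERS[key])

    def key_for_header(self, header: str) -> str:
        for key in CANONICAL_HEADERS:
            if self.display_header(key) == header:
                return key
        raise HeaderError(f"unrecognized column header {header!r}")


def _grid(document: Document, layout: TableLayout,
          reg: DtypeRegistry) -> list[list[str]]:
    """Logical cell grid shared by the csv and xlsx writers."""
    report = validate(document, reg)
    if not report.ok:
        raise ValueError(f"invalid document: {report.violations}")
    info, rows = flatten(document, reg)
    if layout.compaction:
        rows = _compact(rows)
    grid = [_doc_row(info), [layout.display_header(c) for c in layout.columns]]
    for row in rows:
        grid.append([getattr(row, col) for col in layout.columns])
    return grid


def _doc_row(info: DocumentInfo) -> list[str]:
    return [DOC_ROW_LABEL, "author", info.author, "date", info.date,
            "version", info.version, "repository", info.repository]


def _parse_doc_row(cells: list[str]) -> DocumentInfo:
    if not cells or cells[0] != DOC_ROW_LABEL:
        raise DialectError(
            f"first row must start with {DOC_ROW_LABEL!r}, got {cells[:1]}"
        )
    cells = cells + [""] * (9 - len(cells))
    expected = ("author", "date", "version", "repository")
    labels = tuple(cells[1:9:2])
    if labels != expected:
        raise DialectError(
            f"malformed document row: labels {labels} != {expected}"
        )
    return DocumentInfo(author=cells[2], date=cells[4],
                        version=cells[6], repository=cells[8])


def _rows_from_grid(grid: list[list[str]], layout: TableLayout,
                    reg: DtypeRegistry) -> Document:
    if len(grid) < 2:
        raise DialectError("table needs a document row and a header row")
    info = _parse_doc_row(grid[0])
    positions = []
    unmatched = []
    for i, header in enumerate(grid[1]):
        if header == "":
            continue
        try:
            positions.append((i, layout.key_for_header(header)))
        except HeaderError:
            unmatched.append(header)
    if unmatched:
        raise HeaderError(
            f"unrecognized column headers {unmatched}; pass the layout that "
            f"maps them to the canonical columns"
        )
    keys = [k for _, k in positions]
    missing = [c for c in MANDATORY_COLUMNS if c not in keys]
    if missing:
        raise HeaderError(f"table is missing mandatory columns: {missing}")
    width = len(grid[1])
    rows = []
    for cells in grid[2:]:
        if all(c == "" for c in cells):
            continue
        cells = list(cells) + [""] * (width - len(cells))
        rows.append(FlatRow(**{k: cells[i] for i, k in positions}))
    return unflatten(info, _expand(rows), reg)


# ---------------------------------------------------------------------------
# csv

def write_csv(
    document: Document,
    path: str | Path,
    layout: TableLayout | None = None,
    registry: DtypeRegistry | None = None,
) -> None:
    """Write the flat representation as an RFC 4180 csv file (UTF-8, comma
    separated, LF line endings).  Style settings are ignored for csv."""
    layout = layout or TableLayout()
    reg = registry or DEFAULT_REGISTRY
    grid = _grid(document, layout, reg)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerows(grid)


def read_csv(
    path: str | Path,
    layout: TableLayout | None = None,
    registry: DtypeRegistry | None = None,
) -> Document:
    """Read a csv file in the flat dialect back into a document.

    The layout must supply the same header map used at write time; headers
    that cannot be resolved raise :class:`HeaderError`.
    """
    layout = layout or TableLayout()
    reg = registry or DEFAULT_REGISTRY
    with open(path, "r", encoding="utf-8", newline="") as fh:
        grid = [list(row) for row in csv.reader(fh)]
    return _rows_from_grid(grid, layout, reg)


# ---------------------------------------------------------------------------
# xlsx

def write_xlsx(
    document: Document,
    path: str | Path,
    layout: TableLayout | None = None,
    registry: DtypeRegistry | None = None,
) -> None:
    """Write the flat representation as a single-worksheet xlsx file.

    Cells are written as text (the logical grid equals the csv output);
    fills follow the layout's :class:`StyleSpec`: missing value cells red,
    registry-default values light yellow, alternating block colors keyed to
    section and property changes.
    """
    layout = layout or TableLayout()
    reg = registry or DEFAULT_REGISTRY
    style = layout.style or StyleSpec()
    grid = _grid(document, layout, reg)
    _, full_rows = flatten(document, reg)  # uncompacted, for block/fill logic

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "odML metadata"
    for cells in grid:
        ws.append(cells)

    header_fill = PatternFill("solid", fgColor=style.header_fill)
    for cell in ws[2]:
        cell.fill = header_fill
        cell.font = Font(bold=True, color="FFFFFF")

    col_of = {key: i for i, key in enumerate(layout.columns)}
    sec_idx = prop_idx = -1
    prev_path: object = object()
    prev_key: object = object()
    for i, row in enumerate(full_rows):
        if row.path_to_section != prev_path:
            sec_idx += 1
        group = (row.path_to_section, row.property_name)
        if group != prev_key:
            prop_idx += 1
        prev_path, prev_key = row.path_to_section, group
        sec_fill = PatternFill(
            "solid", fgColor=style.section_row_colors[sec_idx % 2])
        prop_fill = PatternFill(
            "solid", fgColor=style.property_row_colors[prop_idx % 2])
        for key, j in col_of.items():
            cell = ws.cell(row=i + 3, column=j + 1)
            if key in ("path_to_section", "section_name", "section_type",
                       "section_definition"):
                cell.fill = sec_fill
            elif key == "value":
                cell.fill = _value_fill(row, style, reg) or prop_fill
            else:
                cell.fill = prop_fill
    wb.save(path)


def _value_fill(row: FlatRow, style: StyleSpec,
                reg: DtypeRegistry) -> PatternFill | None:
    if row.value == "":
        return PatternFill("solid", fgColor=style.missing_value_fill)
    if row.odml_data_type and reg.is_known(row.odml_data_type):
        try:
            typed = reg.parse(row.value, row.odml_data_type)
        except Exception:
            return None
        if reg.is_default(typed, row.odml_data_type):
            return PatternFill("solid", fgColor=style.default_value_fill)
    return None


def read_xlsx(
    path: str | Path,
    layout: TableLayout | None = None,
    registry: DtypeRegistry | None = None,
) -> Document:
    """Read an xlsx file in the flat dialect; identical contract to
    :func:`read_csv`.  All cell styling is ignored."""
    layout = layout or TableLayout()
    reg = registry or DEFAULT_REGISTRY
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    ws = wb.active
    grid = [
        ["" if c is None else str(c) for c in cells]
        for cells in ws.iter_rows(values_only=True)
    ]
    wb.close()
    return _rows_from_grid(grid, layout, reg)


# ---------------------------------------------------------------------------
# layout persistence (plain-text config: key=value plus ordered column list)

def save_layout(layout: TableLayout, path: str | Path) -> None:
    """Persist a layout as a plain-text config file."""
    lines = [f"compaction={'on' if layout.compaction else 'off'}"]
    lines.append("columns=" + ",".join(layout.columns))
    for key, display in layout.header_map.items():
        lines.append(f"header.{key}={display}")
    if layout.style is not None:
        s = layout.style
        lines.append(f"style.section_row_colors={s.section_row_colors[0]},"
                     f"{s.section_row_colors[1]}")
        lines.append(f"style.property_row_colors={s.property_row_colors[0]},"
                     f"{s.property_row_colors[1]}")
        lines.append(f"style.missing_value_fill={s.missing_value_fill}")
        lines.append(f"style.default_value_fill={s.default_value_fill}")
        lines.append(f"style.header_fill={s.header_fill}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_layout(path: str | Path) -> TableLayout:
    """Load a layout config written by :func:`save_layout`."""
    columns = DEFAULT_COLUMNS
    header_map: dict[str, str] = {}
    compaction = True
    style_kwargs: dict[str, object] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise LayoutError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key == "compaction":
            compaction = value.lower() in ("on", "true", "1", "yes")
        elif key == "columns":
            columns = tuple(c.strip() for c in value.split(",") if c.strip())
        elif key.startswith("header."):
            header_map[key[len("header."):]] = value
        elif key in ("style.section_row_colors", "style.property_row_colors"):
            pair = tuple(v.strip() for v in value.split(","))
            style_kwargs[key[len("style."):]] = pair
        elif key.startswith("style."):
            style_kwargs[key[len("style."):]] = value
        else:
            raise LayoutError(f"{path}:{lineno}: unknown config key {key!r}")
    style = StyleSpec(**style_kwargs) if style_kwargs else None  # type: ignore[arg-type]
    return TableLayout(columns=columns, header_map=header_map,
                       compaction=compaction, style=style)
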