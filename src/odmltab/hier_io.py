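"""Hierarchical odML serialization: XML (canonical), JSON and YAML.

The XML dialect follows the odML reference schema: an ``<odML>`` root with a
mandatory ``version`` attribute, nested ``<section>`` elements and
``<property>`` elements holding one ``<value>`` element per value.  JSON and
YAML mirror that element tree one-to-one as a single mapping, so all three
formats carry identical content and read back to equal documents.

Legacy v1.3 files, in which each value was its own entity carrying ``dtype``
/ ``unit`` / ``uncertainty``, are upgraded transparently on read: the value
entities of a property collapse into one value list and the value-level
attributes move to the property.  Heterogeneous value attributes within one
property are an error in strict mode; lenient mode splits the property into
suffixed siblings instead.
"""

from __future__ import annotations

import datetime as _dt
import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Any

import yaml

from .model import (
    DEFAULT_REGISTRY,
    Document,
    DtypeRegistry,
    Property,
    Section,
    validate,
)

__all__ = [
    "read_odml",
    "write_odml",
    "upgrade_v13",
    "OdmlParseError",
    "OdmlVersionError",
    "UpgradeError",
    "FORMATS",
]

FORMATS = ("xml", "json", "yaml")
CURRENT_VERSION = "1.4"
LEGACY_VERSIONS = ("1.3", "1")

_EXTENSIONS = {
    ".odml": "xml",
    ".xml": "xml",
    ".json": "json",
    ".yaml": "yaml",
    ".yml": "yaml",
}

class OdmlParseError(ValueError):
    """Malformed odML file."""


class OdmlVersionError(OdmlParseError):
    """File declares an odML version this reader does not understand."""


class UpgradeError(ValueError):
    """v1.3 property whose value entities disagree on dtype/unit/uncertainty."""


class ValidationError(ValueError):
    """Document violates the model invariants."""


# ---------------------------------------------------------------------------
# format detection

def _detect_format(path: Path, fmt: str | None, *, sniff: bool = True) -> str:
    if fmt is not None and fmt != "auto":
        if fmt not in FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
        return fmt
    by_ext = _EXTENSIONS.get(path.suffix.lower())
    if by_ext:
        return by_ext
    if not sniff:
        return "xml"
    head = path.read_text(encoding="utf-8", errors="replace")[:200].lstrip()
    if head.startswith("<"):
        return "xml"
    if head.startswith("{"):
        return "json"
    return "yaml"


# ---------------------------------------------------------------------------
# plain-mapping <-> model (shared by JSON and YAML)

def _value_to_plain(value: Any) -> Any:
    if isinstance(value, (_dt.datetime, _dt.date, _dt.time)):
        return value.isoformat()
    return value


def _value_from_plain(plain: Any, dtype: str | None, reg: DtypeRegistry) -> Any:
    if dtype is None:
        return plain
    if isinstance(plain, str):
        return reg.parse(plain, dtype)
    if reg.conforms(plain, dtype):
        return plain
    return reg.parse(str(plain), dtype)


def _prop_to_plain(prop: Property) -> dict[str, Any]:
    out: dict[str, Any] = {"name": prop.name}
    for attr in ("definition", "unit", "value_origin", "reference"):
        if getattr(prop, attr) is not None:
            out[attr] = getattr(prop, attr)
    if prop.dtype is not None:
        out["type"] = prop.dtype
    if prop.uncertainty is not None:
        out["uncertainty"] = prop.uncertainty
    out["values"] = [_value_to_plain(v) for v in prop.values]
    out["id"] = prop.id
    return out


def _sec_to_plain(sec: Section) -> dict[str, Any]:
    out: dict[str, Any] = {"name": sec.name, "type": sec.type}
    for attr in ("definition", "reference", "link", "include", "repository"):
        if getattr(sec, attr) is not None:
            out[attr] = getattr(sec, attr)
    out["id"] = sec.id
    if sec.properties:
        out["properties"] = [_prop_to_plain(p) for p in sec.properties]
    if sec.sections:
        out["sections"] = [_sec_to_plain(s) for s in sec.sections]
    return out


def _doc_to_plain(doc: Document) -> dict[str, Any]:
    body: dict[str, Any] = {}
    if doc.author is not None:
        body["author"] = doc.author
    if doc.date is not None:
        body["date"] = doc.date.isoformat()
    if doc.version is not None:
        body["version"] = doc.version
    if doc.repository is not None:
        body["repository"] = doc.repository
    body["sections"] = [_sec_to_plain(s) for s in doc.sections]
    return {"odml-version": CURRENT_VERSION, "Document": body}


def _prop_from_plain(data: dict[str, Any], reg: DtypeRegistry) -> Property:
    dtype = data.get("type")
    kwargs: dict[str, Any] = {
        "name": data["name"],
        "dtype": dtype,
        "definition": data.get("definition"),
        "unit": data.get("unit"),
        "value_origin": data.get("value_origin"),
        "reference": data.get("reference"),
    }
    if data.get("uncertainty") is not None:
        kwargs["uncertainty"] = float(data["uncertainty"])
    if "id" in data:
        kwargs["id"] = data["id"]
    prop = Property(**kwargs)
    prop.values = [_value_from_plain(v, dtype, reg) for v in data.get("values", [])]
    return prop


def _sec_from_plain(data: dict[str, Any], reg: DtypeRegistry) -> Section:
    kwargs: dict[str, Any] = {
        "name": data["name"],
        "type": data.get("type", "undefined"),
    }
    for attr in ("definition", "reference", "link", "include", "repository"):
        if data.get(attr) is not None:
            kwargs[attr] = data[attr]
    if "id" in data:
        kwargs["id"] = data["id"]
    sec = Section(**kwargs)
    sec.properties = [_prop_from_plain(p, reg) for p in data.get("properties", [])]
    sec.sections = [_sec_from_plain(s, reg) for s in data.get("sections", [])]
    return sec


def _doc_from_plain(data: dict[str, Any], reg: DtypeRegistry) -> Document:
    if not isinstance(data, dict) or "Document" not in data:
        raise OdmlParseError("missing top-level 'Document' mapping")
    version = str(data.get("odml-version", ""))
    if version != CURRENT_VERSION:
        raise OdmlVersionError(
            f"unsupported odML version {version!r}; expected {CURRENT_VERSION!r}"
        )
    body = data["Document"]
    doc = Document(
        author=body.get("author"),
        date=_parse_doc_date(body.get("date")),
        version=_opt_str(body.get("version")),
        repository=body.get("repository"),
    )
    doc.sections = [_sec_from_plain(s, reg) for s in body.get("sections", [])]
    return doc


def _opt_str(value: Any) -> str | None:
    return None if value is None else str(value)


def _parse_doc_date(value: Any) -> _dt.date | None:
    if value is None:
        return None
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


# ---------------------------------------------------------------------------
# XML

def _sub(parent: ET.Element, tag: str, text: str) -> ET.Element:
    el = ET.SubElement(parent, tag)
    el.text = text
    return el


def _prop_to_xml(parent: ET.Element, prop: Property, reg: DtypeRegistry) -> None:
    el = ET.SubElement(parent, "property")
    _sub(el, "name", prop.name)
    for attr, tag in (("definition", "definition"), ("unit", "unit"),
                      ("value_origin", "value_origin"), ("reference", "reference")):
        if getattr(prop, attr) is not None:
            _sub(el, tag, getattr(prop, attr))
    if prop.dtype is not None:
        _sub(el, "type", prop.dtype)
    if prop.uncertainty is not None:
        _sub(el, "uncertainty", repr(prop.uncertainty))
    for value in prop.values:
        _sub(el, "value", reg.format(value, prop.dtype))
    _sub(el, "id", prop.id)


def _sec_to_xml(parent: ET.Element, sec: Section, reg: DtypeRegistry) -> None:
    el = ET.SubElement(parent, "section")
    _sub(el, "name", sec.name)
    _sub(el, "type", sec.type)
    for attr in ("definition", "reference", "link", "include", "repository"):
        if getattr(sec, attr) is not None:
            _sub(el, attr, getattr(sec, attr))
    _sub(el, "id", sec.id)
    for prop in sec.properties:
        _prop_to_xml(el, prop, reg)
    for sub in sec.sections:
        _sec_to_xml(el, sub, reg)


def _doc_to_xml(doc: Document, reg: DtypeRegistry) -> ET.ElementTree:
    root = ET.Element("odML", version=CURRENT_VERSION)
    if doc.author is not None:
        _sub(root, "author", doc.author)
    if doc.date is not None:
        _sub(root, "date", doc.date.isoformat())
    if doc.version is not None:
        _sub(root, "version", doc.version)
    if doc.repository is not None:
        _sub(root, "repository", doc.repository)
    for sec in doc.sections:
        _sec_to_xml(root, sec, reg)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    return tree


def _text(el: ET.Element | None) -> str | None:
    if el is None:
        return None
    return el.text or ""


def _prop_from_xml(el: ET.Element, reg: DtypeRegistry) -> Property:
    name = _text(el.find("name"))
    if not name:
        raise OdmlParseError("property element without a name")
    dtype = _text(el.find("type")) or None
    uncertainty = _text(el.find("uncertainty"))
    kwargs: dict[str, Any] = {
        "name": name,
        "dtype": dtype,
        "definition": _text(el.find("definition")),
        "unit": _text(el.find("unit")),
        "value_origin": _text(el.find("value_origin")),
        "reference": _text(el.find("reference")),
        "uncertainty": float(uncertainty) if uncertainty else None,
    }
    ident = _text(el.find("id"))
    if ident:
        kwargs["id"] = ident
    prop = Property(**kwargs)
    for vel in el.findall("value"):
        raw = vel.text or ""
        prop.values.append(reg.parse(raw, dtype) if dtype else raw)
    return prop


def _sec_from_xml(el: ET.Element, reg: DtypeRegistry) -> Section:
    name = _text(el.find("name"))
    if not name:
        raise OdmlParseError("section element without a name")
    kwargs: dict[str, Any] = {"name": name, "type": _text(el.find("type")) or "undefined"}
    for attr in ("definition", "reference", "link", "include", "repository"):
        value = _text(el.find(attr))
        if value is not None:
            kwargs[attr] = value
    ident = _text(el.find("id"))
    if ident:
        kwargs["id"] = ident
    sec = Section(**kwargs)
    sec.properties = [_prop_from_xml(p, reg) for p in el.findall("property")]
    sec.sections = [_sec_from_xml(s, reg) for s in el.findall("section")]
    return sec


def _doc_from_xml(root: ET.Element, reg: DtypeRegistry) -> Document:
    if root.tag != "odML":
        raise OdmlParseError(f"root element is {root.tag!r}, expected 'odML'")
    version = root.get("version")
    if version in LEGACY_VERSIONS:
        return upgrade_v13(root, reg=reg)
    if version != CURRENT_VERSION:
        raise OdmlVersionError(
            f"unsupported odML version {version!r}; expected {CURRENT_VERSION!r} "
            f"or legacy {LEGACY_VERSIONS}"
        )
    doc = Document(
        author=_text(root.find("author")),
        date=_parse_doc_date(_text(root.find("date")) or None),
        version=_text(root.find("version")),
        repository=_text(root.find("repository")),
    )
    doc.sections = [_sec_from_xml(s, reg) for s in root.findall("section")]
    return doc


# ---------------------------------------------------------------------------
# v1.3 upgrade

def upgrade_v13(
    root: ET.Element,
    *,
    strict: bool = True,
    reg: DtypeRegistry | None = None,
) -> Document:
    """Upgrade a parsed legacy v1.3 XML tree to a v1.4 document.

    In the legacy model each value is its own ``<value>`` entity carrying
    ``type``/``unit``/``uncertainty`` attributes.  Values of one property
    collapse into a single list; the shared attributes move to the property.
    Disagreeing attributes raise :class:`UpgradeError` in strict mode; with
    ``strict=False`` the property is split into ``name_1``, ``name_2``, ...
    one per attribute combination, conserving the total value count.
    """
    reg = reg or DEFAULT_REGISTRY
    doc = Document(
        author=_text(root.find("author")),
        date=_parse_doc_date(_text(root.find("date")) or None),
        version=_text(root.find("version")),
        repository=_text(root.find("repository")),
    )
    doc.sections = [
        _sec_from_xml_v13(s, "", strict, reg) for s in root.findall("section")
    ]
    return doc


def _sec_from_xml_v13(
    el: ET.Element, parent_path: str, strict: bool, reg: DtypeRegistry
) -> Section:
    name = _text(el.find("name"))
    if not name:
        raise OdmlParseError("section element without a name")
    path = f"{parent_path}/{name}"
    kwargs: dict[str, Any] = {"name": name, "type": _text(el.find("type")) or "undefined"}
    for attr in ("definition", "reference", "link", "include", "repository"):
        value = _text(el.find(attr))
        if value is not None:
            kwargs[attr] = value
    sec = Section(**kwargs)
    for pel in el.findall("property"):
        sec.properties.extend(_props_from_xml_v13(pel, path, strict, reg))
    sec.sections = [
        _sec_from_xml_v13(s, path, strict, reg) for s in el.findall("section")
    ]
    return sec


def _props_from_xml_v13(
    el: ET.Element, sec_path: str, strict: bool, reg: DtypeRegistry
) -> list[Property]:
    name = _text(el.find("name"))
    if not name:
        raise OdmlParseError("v1.3 property element without a name")
    # group values by their (dtype, unit, uncertainty) attribute combination,
    # preserving first-seen order
    groups: dict[tuple, list[Any]] = {}
    for vel in el.findall("value"):
        dtype = vel.get("type") or None
        unit = vel.get("unit") or None
        unc = vel.get("uncertainty")
        key = (dtype, unit, float(unc) if unc else None)
        raw = vel.text or ""
        groups.setdefault(key, []).append(reg.parse(raw, dtype) if dtype else raw)
    if not groups:
        groups[(None, None, None)] = []
    if len(groups) > 1 and strict:
        raise UpgradeError(
            f"property {sec_path}:{name} has value entities with conflicting "
            f"dtype/unit/uncertainty attributes; re-read with strict=False to "
            f"split it"
        )
    definition = _text(el.find("definition"))
    props = []
    for i, ((dtype, unit, unc), values) in enumerate(groups.items(), start=1):
        props.append(
            Property(
                name=name if len(groups) == 1 else f"{name}_{i}",
                definition=definition,
                dtype=dtype,
                unit=unit,
                uncertainty=unc,
                values=values,
            )
        )
    return props


# ---------------------------------------------------------------------------
# public API

def read_odml(
    path: str | Path,
    format: str | None = "auto",
    *,
    strict_upgrade: bool = True,
    registry: DtypeRegistry | None = None,
) -> Document:
    """Read an odML document from XML (canonical), JSON or YAML.

    ``format='auto'`` detects by extension, then by content sniffing.
    Legacy v1.3 XML is upgraded transparently (see :func:`upgrade_v13`).
    """
    reg = registry or DEFAULT_REGISTRY
    path = Path(path)
    fmt = _detect_format(path, format)
    text = path.read_text(encoding="utf-8")
    if fmt == "xml":
        try:
            root = ET.fromstring(text)
        except ET.ParseError as exc:
            raise OdmlParseError(f"{path}: malformed XML: {exc}") from exc
        if root.get("version") in LEGACY_VERSIONS:
            doc = upgrade_v13(root, strict=strict_upgrade, reg=reg)
        else:
            doc = _doc_from_xml(root, reg)
    elif fmt == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise OdmlParseError(
                f"{path}: malformed JSON at line {exc.lineno} col {exc.colno}: "
                f"{exc.msg}"
            ) from exc
        doc = _doc_from_plain(data, reg)
    else:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise OdmlParseError(f"{path}: malformed YAML: {exc}") from exc
        doc = _doc_from_plain(data, reg)
    report = validate(doc, reg)
    if not report.ok:
        raise ValidationError(
            f"{path}: document violates model invariants: {report.violations}"
        )
    return doc


def write_odml(
    document: Document,
    path: str | Path,
    format: str | None = "auto",
    *,
    registry: DtypeRegistry | None = None,
) -> None:
    """Write a validated document to disk; the file re-reads to an equal
    document, UUIDs and ordering included."""
    reg = registry or DEFAULT_REGISTRY
    path = Path(path)
    report = validate(document, reg)
    if not report.ok:
        raise ValidationError(
            f"refusing to write invalid document: {report.violations}"
        )
    fmt = _detect_format(path, format, sniff=False) if format else "xml"
    if fmt == "xml":
        tree = _doc_to_xml(document, reg)
        tree.write(path, encoding="utf-8", xml_declaration=True)
    elif fmt == "json":
        path.write_text(
            json.dumps(_doc_to_plain(document), indent=2, ensure_ascii=False) + "\n",
            encoding="utf-8",
        )
    else:
        path.write_text(
            yaml.safe_dump(_doc_to_plain(document), sort_keys=False,
                           allow_unicode=True),
            encoding="utf-8",
        )
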