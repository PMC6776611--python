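"""Entity model for hierarchical odML (v1.4) metadata documents.

An odML document is a tree of named, typed :class:`Section` nodes holding
:class:`Property` entries (extended key-value pairs).  A property carries a
*homogeneous* list of values: the data type, physical unit and uncertainty
are single attributes shared by every value in the list.  Each section and
property carries a UUID so entities remain identifiable across files.

The :class:`DtypeRegistry` defines the canonical odML data types, their
synonyms, per-type default values and the string<->typed conversions used by
the tabular serializers.
"""

from __future__ import annotations

import datetime as _dt
import re
import uuid as _uuid
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Iterator, NamedTuple

__all__ = [
    "Document",
    "Section",
    "Property",
    "DtypeRegistry",
    "ValidationReport",
    "Violation",
    "CoercionError",
    "UnknownDtypeError",
    "DEFAULT_REGISTRY",
    "validate",
    "coerce",
    "default_value",
    "documents_equal",
]

PATH_DELIMITER = "/"

#: Canonical odML data-type tokens.
CANONICAL_DTYPES = (
    "int",
    "float",
    "string",
    "text",
    "boolean",
    "date",
    "time",
    "datetime",
    "url",
    "person",
)

_SYNONYMS = {
    "integer": "int",
    "bool": "boolean",
    "str": "string",
    "txt": "text",
    "datefield": "date",
    "url": "url",
    "number": "float",
}

_TRUE_TOKENS = {"True", "true", "1"}
_FALSE_TOKENS = {"False", "false", "0"}


class CoercionError(ValueError):
    """Raised when a non-empty text cannot be parsed as the requested dtype."""


class UnknownDtypeError(KeyError):
    """Raised for a type token that is neither canonical nor a synonym."""


def _parse_bool(raw: str) -> bool:
    if raw in _TRUE_TOKENS:
        return True
    if raw in _FALSE_TOKENS:
        return False
    raise ValueError(raw)


def _parse_int(raw: str) -> int:
    # reject floats masquerading as ints ("5.5") but allow "+3", "-3"
    return int(raw)


def _format_bool(value: bool) -> str:
    return "True" if value else "False"


def _format_float(value: float) -> str:
    return repr(float(value))


def _format_time(value: _dt.time) -> str:
    return value.isoformat()


def _format_datetime(value: _dt.datetime) -> str:
    # isoformat pads the year to four digits, which strftime does not
    return value.isoformat(sep="T")


class Coerced(NamedTuple):
    """Result of a coercion: the typed value and whether the registry
    default was substituted for empty input."""

    value: Any
    is_default: bool


class DtypeRegistry:
    """Canonical data types, synonyms, defaults and string conversions.

    Defaults are user-overridable via :meth:`set_default`; the shipped table
    uses unambiguous, sortable sentinels (0, 0.0, empty text, ``False``,
    1900-01-01, midnight).
    """

    def __init__(self) -> None:
        self._synonyms = dict(_SYNONYMS)
        self._defaults: dict[str, Any] = {
            "int": 0,
            "float": 0.0,
            "string": "",
            "text": "",
            "url": "",
            "person": "",
            "boolean": False,
            "date": _dt.date(1900, 1, 1),
            "time": _dt.time(0, 0, 0),
            "datetime": _dt.datetime(1900, 1, 1, 0, 0, 0),
        }
        self._parsers: dict[str, Callable[[str], Any]] = {
            "int": _parse_int,
            "float": float,
            "string": str,
            "text": str,
            "url": str,
            "person": str,
            "boolean": _parse_bool,
            "date": _dt.date.fromisoformat,
            "time": _dt.time.fromisoformat,
            "datetime": _dt.datetime.fromisoformat,
        }
        self._formatters: dict[str, Callable[[Any], str]] = {
            "int": str,
            "float": _format_float,
            "string": str,
            "text": str,
            "url": str,
            "person": str,
            "boolean": _format_bool,
            "date": _dt.date.isoformat,
            "time": _format_time,
            "datetime": _format_datetime,
        }
        self._pytypes: dict[str, type | tuple[type, ...]] = {
            "int": int,
            "float": (int, float),
            "string": str,
            "text": str,
            "url": str,
            "person": str,
            "boolean": bool,
            "date": _dt.date,
            "time": _dt.time,
            "datetime": _dt.datetime,
        }

    @property
    def canonical_types(self) -> tuple[str, ...]:
        return CANONICAL_DTYPES

    def resolve(self, token: str) -> str:
        """Resolve a synonym to its canonical dtype token (idempotent)."""
        tok = token.strip().lower()
        tok = self._synonyms.get(tok, tok)
        if tok not in CANONICAL_DTYPES:
            raise UnknownDtypeError(
                f"unknown data type {token!r}; known types: "
                f"{', '.join(CANONICAL_DTYPES)}"
            )
        return tok

    def is_known(self, token: str) -> bool:
        try:
            self.resolve(token)
        except UnknownDtypeError:
            return False
        return True

    def default(self, dtype: str) -> Any:
        return self._defaults[self.resolve(dtype)]

    def set_default(self, dtype: str, value: Any) -> None:
        canon = self.resolve(dtype)
        self._defaults[canon] = self.parse(self.format(value, canon), canon)

    def parse(self, raw: str, dtype: str) -> Any:
        """Parse a non-empty string into a typed value."""
        canon = self.resolve(dtype)
        try:
            value = self._parsers[canon](raw)
        except (ValueError, TypeError) as exc:
            raise CoercionError(
                f"cannot interpret {raw!r} as odML type {canon!r}"
            ) from exc
        if canon == "datetime" and isinstance(value, _dt.datetime):
            return value
        if canon == "date" and isinstance(value, _dt.datetime):  # paranoia
            return value.date()
        return value

    def format(self, value: Any, dtype: str | None = None) -> str:
        """Render a typed value as the canonical cell text."""
        if value is None:
            return ""
        if dtype is None:
            dtype = self.infer_dtype(value)
        canon = self.resolve(dtype)
        return self._formatters[canon](value)

    def coerce(self, raw: str, dtype: str) -> Coerced:
        """Coerce cell text to a typed value.

        Empty text yields the registry default for *dtype*, flagged
        ``is_default=True``; unparseable non-empty text raises
        :class:`CoercionError`.
        """
        canon = self.resolve(dtype)
        if raw == "":
            return Coerced(self._defaults[canon], True)
        return Coerced(self.parse(raw, canon), False)

    def conforms(self, value: Any, dtype: str) -> bool:
        """True when *value* is an instance of the dtype's Python type."""
        canon = self.resolve(dtype)
        pytype = self._pytypes[canon]
        if canon == "date" and isinstance(value, _dt.datetime):
            return False  # datetime is a date subclass; keep types distinct
        if canon in ("int", "float") and isinstance(value, bool):
            return False
        return isinstance(value, pytype)

    def is_default(self, value: Any, dtype: str) -> bool:
        return value == self._defaults[self.resolve(dtype)]

    def infer_dtype(self, value: Any) -> str:
        """Best-effort canonical dtype for a Python value."""
        if isinstance(value, bool):
            return "boolean"
        if isinstance(value, int):
            return "int"
        if isinstance(value, float):
            return "float"
        if isinstance(value, _dt.datetime):
            return "datetime"
        if isinstance(value, _dt.date):
            return "date"
        if isinstance(value, _dt.time):
            return "time"
        return "string"


#: Shared registry used wherever no registry is passed explicitly.
DEFAULT_REGISTRY = DtypeRegistry()


def coerce(raw: str, dtype: str, registry: DtypeRegistry | None = None) -> Coerced:
    """Module-level shorthand for :meth:`DtypeRegistry.coerce`."""
    return (registry or DEFAULT_REGISTRY).coerce(raw, dtype)


def default_value(dtype: str, registry: DtypeRegistry | None = None) -> Any:
    """Module-level shorthand for :meth:`DtypeRegistry.default`."""
    return (registry or DEFAULT_REGISTRY).default(dtype)


def _new_id() -> str:
    return str(_uuid.uuid4())


_UUID_RE = re.compile(
    r"^[0-9a-fA-F]{8}-[0-9a-fA-F]{4}-[0-9a-fA-F]{4}"
    r"-[0-9a-fA-F]{4}-[0-9a-fA-F]{12}$"
)


@dataclass
class Property:
    """A named entry holding a homogeneous list of values.

    ``dtype``, ``unit`` and ``uncertainty`` apply to *all* values of the
    property; heterogeneous lists are a model violation.
    """

    name: str
    values: list[Any] = field(default_factory=list)
    dtype: str | None = None
    definition: str | None = None
    unit: str | None = None
    uncertainty: float | None = None
    value_origin: str | None = None
    reference: str | None = None
    id: str = field(default_factory=_new_id)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("property name must be non-empty")
        self.values = list(self.values)

    def clone(self, *, fresh_ids: bool = False) -> "Property":
        return Property(
            name=self.name,
            values=list(self.values),
            dtype=self.dtype,
            definition=self.definition,
            unit=self.unit,
            uncertainty=self.uncertainty,
            value_origin=self.value_origin,
            reference=self.reference,
            id=_new_id() if fresh_ids else self.id,
        )


@dataclass
class Section:
    """Named, typed grouping node; may nest subsections and hold properties."""

    name: str
    type: str = "undefined"
    definition: str | None = None
    reference: str | None = None
    link: str | None = None
    include: str | None = None
    repository: str | None = None
    sections: list["Section"] = field(default_factory=list)
    properties: list[Property] = field(default_factory=list)
    id: str = field(default_factory=_new_id)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("section name must be non-empty")
        if PATH_DELIMITER in self.name:
            raise ValueError(
                f"section name {self.name!r} may not contain the path "
                f"delimiter {PATH_DELIMITER!r}"
            )

    def __getitem__(self, name: str) -> "Section":
        for sec in self.sections:
            if sec.name == name:
                return sec
        raise KeyError(name)

    def get_property(self, name: str) -> Property:
        for prop in self.properties:
            if prop.name == name:
                return prop
        raise KeyError(name)

    def clone(self, *, fresh_ids: bool = False) -> "Section":
        return Section(
            name=self.name,
            type=self.type,
            definition=self.definition,
            reference=self.reference,
            link=self.link,
            include=self.include,
            repository=self.repository,
            sections=[s.clone(fresh_ids=fresh_ids) for s in self.sections],
            properties=[p.clone(fresh_ids=fresh_ids) for p in self.properties],
            id=_new_id() if fresh_ids else self.id,
        )


@dataclass
class Document:
    """Root of an odML metadata tree.

    Holds only sections (never properties directly) plus the four document
    attributes author, date, version and repository.
    """

    author: str | None = None
    date: _dt.date | None = None
    version: str | None = None
    repository: str | None = None
    sections: list[Section] = field(default_factory=list)

    def __getitem__(self, name: str) -> Section:
        for sec in self.sections:
            if sec.name == name:
                return sec
        raise KeyError(name)

    def itersections(self) -> Iterator[tuple[str, Section]]:
        """Depth-first (path, section) pairs; paths start with '/'."""
        yield from _walk(self.sections, "")

    def section_by_path(self, path: str) -> Section:
        node: Document | Section = self
        for part in path.strip(PATH_DELIMITER).split(PATH_DELIMITER):
            node = node[part]
        return node  # type: ignore[return-value]

    def clone(self, *, fresh_ids: bool = False) -> "Document":
        return Document(
            author=self.author,
            date=self.date,
            version=self.version,
            repository=self.repository,
            sections=[s.clone(fresh_ids=fresh_ids) for s in self.sections],
        )


def _walk(sections: Iterable[Section], prefix: str) -> Iterator[tuple[str, Section]]:
    for sec in sections:
        path = f"{prefix}{PATH_DELIMITER}{sec.name}"
        yield path, sec
        yield from _walk(sec.sections, path)


class Violation(NamedTuple):
    path: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def __bool__(self) -> bool:
        return not self.violations

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, path: str, rule: str, message: str) -> None:
        self.violations.append(Violation(path, rule, message))


def validate(
    document: Document, registry: DtypeRegistry | None = None
) -> ValidationReport:
    """Check a document against the model invariants.

    All problems are collected into the report; nothing is raised and the
    document is never modified.
    """
    reg = registry or DEFAULT_REGISTRY
    report = ValidationReport()
    _check_siblings(document.sections, "", report)
    for path, sec in document.itersections():
        if not sec.id or not _UUID_RE.match(sec.id):
            report.add(path, "uuid", f"section id {sec.id!r} is not a UUID")
        seen_props: set[str] = set()
        for prop in sec.properties:
            ppath = f"{path}:{prop.name}"
            if prop.name in seen_props:
                report.add(
                    path,
                    "unique-property-names",
                    f"duplicate property name {prop.name!r}",
                )
            seen_props.add(prop.name)
            if not prop.id or not _UUID_RE.match(prop.id):
                report.add(ppath, "uuid", f"property id {prop.id!r} is not a UUID")
            if prop.uncertainty is not None and prop.uncertainty < 0:
                report.add(
                    ppath,
                    "uncertainty-nonnegative",
                    f"uncertainty {prop.uncertainty} is negative",
                )
            if prop.dtype is not None:
                if not reg.is_known(prop.dtype):
                    report.add(
                        ppath, "known-dtype", f"unknown dtype {prop.dtype!r}"
                    )
                else:
                    for i, value in enumerate(prop.values):
                        if not reg.conforms(value, prop.dtype):
                            report.add(
                                ppath,
                                "value-conforms-dtype",
                                f"value #{i} {value!r} does not conform to "
                                f"dtype {prop.dtype!r}",
                            )
    return report


def _check_siblings(
    sections: Iterable[Section], prefix: str, report: ValidationReport
) -> None:
    seen: set[str] = set()
    for sec in sections:
        path = f"{prefix}{PATH_DELIMITER}{sec.name}"
        if sec.name in seen:
            report.add(
                prefix or PATH_DELIMITER,
                "unique-sibling-names",
                f"duplicate sibling section name {sec.name!r}",
            )
        seen.add(sec.name)
        _check_siblings(sec.sections, path, report)


def documents_equal(a: Document, b: Document, *, ignore_ids: bool = False) -> bool:
    """Structural equality; with ``ignore_ids`` UUIDs are not compared
    (tabular round trips mint fresh ones)."""
    if not ignore_ids:
        return a == b
    return _stripped(a) == _stripped(b)


def _stripped(doc: Document) -> Document:
    out = doc.clone()
    for _, sec in out.itersections():
        sec.id = "00000000-0000-0000-0000-000000000000"
        for prop in sec.properties:
            prop.id = "00000000-0000-0000-0000-000000000000"
    return out
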