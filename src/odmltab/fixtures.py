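"""Built-in example corpus and a seeded random-document generator.

The example corpus models a laboratory animal *score sheet* workflow: a
template fixing the measures recorded each day (date, body weight,
experimenter, comment), daily sheets filled in per recording day, and a
subject document aggregating the daily sheets under one ``/Subject``
section.  The corpus drives the worked examples in the documentation and
the test suite; no external data is needed.

``random_document`` generates arbitrary valid documents from a
:class:`GeneratorParams` seed, using Python's Mersenne-Twister ``random``
module so the output is reproducible across platforms for a fixed seed.
"""

from __future__ import annotations

import datetime as _dt
import random
import string as _string
import uuid as _uuid
from dataclasses import dataclass

from .model import CANONICAL_DTYPES, Document, Property, Section

__all__ = [
    "GeneratorParams",
    "build_scoresheet_template",
    "build_daily_scoresheet",
    "build_subject_document",
    "random_document",
]

DAY1 = _dt.date(2000, 1, 1)
DAY2 = _dt.date(2000, 1, 2)

DAY1_COMMENT = "Blood sample was taken [...]"
DAY2_COMMENT = "Small scratch at the right ear"


def _scoresheet_properties(
    date: _dt.date | None,
    weight: float | None,
    experimenter: str | None,
    comment: str | None,
) -> list[Property]:
    return [
        Property(name="Date", dtype="date",
                 values=[] if date is None else [date]),
        Property(name="Weight", dtype="float", unit="g",
                 values=[] if weight is None else [weight]),
        Property(name="Experimenter", dtype="string",
                 values=[] if experimenter is None else [experimenter]),
        Property(name="Comment", dtype="text",
                 values=[] if comment is None else [comment]),
    ]


def build_scoresheet_template() -> Document:
    """The daily score-sheet template.

    One ``Scores`` section under ``/Subject`` with properties Date (date),
    Weight (float, unit g), Experimenter (string) and Comment (text).
    Date, Weight and Comment are left empty to be filled in each day;
    Experimenter is pre-filled with the habitual default "Alice" and the
    Weight unit "g" is fixed by the template.
    """
    return Document(sections=[
        Section(name="Subject", type="subject", sections=[
            Section(
                name="Scores",
                type="scores",
                properties=_scoresheet_properties(None, None, "Alice", None),
            ),
        ]),
    ])


def build_daily_scoresheet(
    date: _dt.date,
    weight: float,
    experimenter: str,
    comment: str | None = None,
) -> Document:
    """A filled-in copy of the template for one measurement day.

    The section is renamed ``Scores_<ISO date>`` so each day occupies a
    unique path under ``/Subject``, which makes the daily merge into the
    subject document unambiguous.
    """
    return Document(sections=[
        Section(name="Subject", type="subject", sections=[
            Section(
                name=f"Scores_{date.isoformat()}",
                type="scores",
                properties=_scoresheet_properties(
                    date, weight, experimenter, comment),
            ),
        ]),
    ])


def build_subject_document(stage: str = "pre_enrichment") -> Document:
    """The two-day subject document of the worked example.

    ``/Subject`` holds ``Scores_2000-01-01`` (Date 2000-01-01, Weight 5.0 g,
    Experimenter Alice) and ``Scores_2000-01-02`` (Date 2000-01-02, Weight
    5.5 g, Experimenter Bob).

    ``stage='pre_enrichment'`` leaves both Comment properties empty — the
    document's only two empty-valued properties, as found right after the
    daily collection.  ``stage='enriched'`` carries the comments added
    during the later enrichment pass (day 1: blood sample note, day 2:
    "Small scratch at the right ear").

    The day-1 experimenter is the single value "Alice"; an overview table
    rendering of a genuine multi-value list is exercised separately in the
    tests.
    """
    if stage not in ("pre_enrichment", "enriched"):
        raise ValueError(f"unknown stage {stage!r}")
    enriched = stage == "enriched"
    day1 = build_daily_scoresheet(
        DAY1, 5.0, "Alice", DAY1_COMMENT if enriched else None)
    day2 = build_daily_scoresheet(
        DAY2, 5.5, "Bob", DAY2_COMMENT if enriched else None)
    doc = Document(author="Alice", date=DAY1, version="1.0")
    doc.sections = day1.sections
    doc["Subject"].sections.extend(day2["Subject"].sections)
    return doc


@dataclass
class GeneratorParams:
    """Knobs of the random-document generator; generation is a pure function
    of these parameters."""

    seed: int = 0
    max_depth: int = 3
    branching: int = 2
    properties_per_section: tuple[int, int] = (0, 3)
    values_per_property: tuple[int, int] = (0, 3)
    dtype_pool: tuple[str, ...] = CANONICAL_DTYPES

    def __post_init__(self) -> None:
        if self.max_depth < 1 or self.branching < 0:
            raise ValueError("max_depth must be >=1 and branching >=0")
        for lo, hi in (self.properties_per_section, self.values_per_property):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must be non-negative and ordered")


_WORDS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta",
          "theta", "iota", "kappa", "lambda", "mu")


def _seeded_uuid(rng: random.Random) -> str:
    """Version-4 UUID drawn from the generator's own stream, so identical
    seeds yield identical entity ids."""
    return str(_uuid.UUID(int=rng.getrandbits(128), version=4))


def _random_text(rng: random.Random) -> str:
    n = rng.randint(1, 3)
    return " ".join(rng.choice(_WORDS) for _ in range(n))


def _random_value(rng: random.Random, dtype: str):
    if dtype == "int":
        return rng.randint(-1000, 1000)
    if dtype == "float":
        return round(rng.uniform(-100, 100), 3)
    if dtype == "boolean":
        return rng.random() < 0.5
    if dtype == "date":
        return _dt.date(2000, 1, 1) + _dt.timedelta(days=rng.randint(0, 7000))
    if dtype == "time":
        return _dt.time(rng.randint(0, 23), rng.randint(0, 59),
                        rng.randint(0, 59))
    if dtype == "datetime":
        return _dt.datetime(2000 + rng.randint(0, 20), rng.randint(1, 12),
                            rng.randint(1, 28), rng.randint(0, 23),
                            rng.randint(0, 59), rng.randint(0, 59))
    if dtype == "url":
        return f"https://example.org/{rng.choice(_WORDS)}"
    if dtype == "person":
        return rng.choice(("Alice", "Bob", "Carol", "Dave"))
    return _random_text(rng)  # string / text


def _random_property(rng: random.Random, name: str,
                     params: GeneratorParams) -> Property:
    dtype = rng.choice(params.dtype_pool)
    nvalues = rng.randint(*params.values_per_property)
    return Property(
        name=name,
        dtype=dtype,
        values=[_random_value(rng, dtype) for _ in range(nvalues)],
        definition=_random_text(rng) if rng.random() < 0.3 else None,
        unit=rng.choice(("g", "mV", "ms", "um")) if rng.random() < 0.3 else None,
        uncertainty=round(rng.uniform(0, 1), 3) if rng.random() < 0.2 else None,
        id=_seeded_uuid(rng),
    )


def _random_section(rng: random.Random, name: str, depth: int,
                    params: GeneratorParams) -> Section:
    nprops = rng.randint(*params.properties_per_section)
    sec = Section(
        name=name,
        type=rng.choice(("undefined", "recording", "subject", "setup")),
        definition=_random_text(rng) if rng.random() < 0.3 else None,
        properties=[
            _random_property(rng, f"prop{_string.ascii_uppercase[i]}", params)
            for i in range(nprops)
        ],
        id=_seeded_uuid(rng),
    )
    if depth < params.max_depth:
        nsub = rng.randint(0, params.branching)
        sec.sections = [
            _random_section(rng, f"{name}_{i}", depth + 1, params)
            for i in range(nsub)
        ]
    return sec


def random_document(params: GeneratorParams) -> Document:
    """Generate a valid document; identical params (seed included) give
    identical documents."""
    rng = random.Random(params.seed)
    ntop = max(1, rng.randint(1, max(1, params.branching)))
    doc = Document(
        author=rng.choice(("Alice", "Bob", None)),
        date=_dt.date(2001, 1, 1) + _dt.timedelta(days=rng.randint(0, 1000)),
        version=f"{rng.randint(0, 3)}.{rng.randint(0, 9)}",
    )
    doc.sections = [
        _random_section(rng, f"sec{i}", 1, params) for i in range(ntop)
    ]
    return doc
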