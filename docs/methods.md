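# Methods and design notes

## Data model

A metadata collection is a tree. The `Document` root carries four optional
attributes (author, date, version, repository) and an ordered list of
`Section`s. Each section has a non-empty name (unique among siblings,
case-sensitive), a type, optional definition/reference/link/include/
repository attributes, subsections and `Property` entries. A property holds
an ordered, possibly empty list of values together with *single* shared
attributes: data type (`dtype`), physical `unit`, non-negative `uncertainty`,
plus optional definition, value origin and reference. Keeping the
value-level attributes on the property rather than on each value makes a
value list homogeneous by construction; a list whose members would need
different units must be split into separate properties. Every section and
property carries a version-4 UUID, minted automatically at construction, so
entities stay identifiable across files.

`validate()` collects all invariant violations (duplicate sibling names,
duplicate property names, non-UUID ids, values not conforming to the
declared dtype, negative uncertainty) into a report without raising or
modifying the document. Section names may not contain `/`, the path
delimiter of the tabular dialect; this is rejected at construction rather
than at validation time because a bad name would silently corrupt paths.

## Data types and defaults

The canonical types are `int, float, string, text, boolean, date, time,
datetime, url, person`, with common synonyms (`integer`, `bool`, `str`, …)
resolved idempotently. Dates and times use ISO 8601 text. Boolean cells
accept `True/true/1` and `False/false/0` because spreadsheet exports vary.

Each type has a registry default used when a tabular cell is empty but a
typed entry is required, and for default-value highlighting in xlsx output:
`int` → 0, `float` → 0.0, the four text-like types → empty text, `boolean` →
False, `date` → 1900-01-01, `time` → 00:00:00, `datetime` → their
combination. These are deliberate, sortable sentinels — no reference
defines this table, so it is a package choice and the registry is
user-overridable (`DtypeRegistry.set_default`). Parsing and formatting are
exact inverses for in-range values (floats use `repr`, which round-trips
IEEE doubles losslessly).

## Hierarchical serialization

XML is canonical: an `<odML version="1.4">` root, one element per entity
attribute, one `<value>` element per value. JSON and YAML mirror the same
element tree as a single mapping, so the three formats carry identical
content; a cross-format equality test enforces this. Files are UTF-8.
`link`/`include` references are stored and round-tripped verbatim, never
dereferenced.

Legacy v1.3 files — where each value was its own entity carrying
`type`/`unit`/`uncertainty` — are upgraded on read: the values of a property
collapse into one list and the shared attributes move up. If the value
entities of one property disagree, strict mode (default) raises naming the
property path, because silently merging different units would corrupt the
list; `strict=False` instead splits the property into `name_1`, `name_2`, …
per attribute combination, conserving the total value count. Attributes
outside the legacy model are not interpreted.

## The tabular dialect

`flatten` emits exactly one row per value, in depth-first document order; a
property without values emits one row with an empty value cell. Sections
holding no properties anywhere in their subtree emit no rows — the dialect
has no section-only row, so these sections (and the attributes of
intermediate sections that have no direct properties) are the dialect's
declared loss; hierarchical formats preserve them. UUIDs are likewise not
represented in tables: `unflatten` mints fresh ids.

An empty value cell means *no value*. A value that IS the empty string is
written as the sentinel quote pair `""` so the two cases stay
distinguishable; a string value consisting of exactly two double quotes
cannot be represented in a table (known limitation).

Compaction blanks a cell equal to the cell above within its column group —
section-level cells `{path, section name/type/definition}` while the path is
unchanged, property-level cells while path *and* property name are unchanged;
value cells are never blanked. Expansion forward-fills blanks under the same
reset rule, using the non-blank path/property-name cells as run boundaries.
Under the dialect's invariants (rows of one property agree on everything but
the value) the two functions are exact inverses, which a property test
checks on generated documents.

File grid: row 1 holds the document attributes at fixed positions
(`Document Information, author, <a>, date, <d>, version, <v>, repository,
<r>`) so the row is machine-parseable without a second header; row 2 holds
the display headers; data rows follow. The canonical headers are
"Path to Section", "Section Name", …, "odML Data Type"; a layout's header
map may rename them (injectively) and select/order any column subset that
keeps the three mandatory columns (path, property name, value).
"Value Origin" and "Property Reference" columns are opt-in extras. csv is
RFC 4180 (UTF-8, comma, double-quote quoting, LF); the spreadsheet target is
xlsx, which is lossless for the needed features, rather than legacy xls.
Layouts persist to a plain-text `key=value` config loadable by the CLI.

xlsx styling: alternating fills per section block and per property block,
red (`FF0000`, the conventional choice) for missing value cells, light
yellow for cells equal to the registry default of their type, a colored
bold header row. Styling is write-only decoration — readers ignore all
fills, which a fuzz test (random fills, re-read, compare) enforces.

## Operations

**Template** — writes the skeleton document's rows with its (usually empty)
value cells; values present in the skeleton act as pre-filled defaults, like
a habitual experimenter name. Without a skeleton, one generic placeholder
row shows the expected shape.

**Merge** — walks both trees by section name path. New sections/properties
are added keeping their source UUIDs; entities already in the target keep
the target's. For a property in both: append mode extends the target's value
list (a dtype/unit/uncertainty conflict raises, since mixing units silently
would corrupt data); overwrite mode replaces the values. Scalar attribute
conflicts resolve symmetrically: target wins in append mode, source wins in
overwrite mode; absent attributes are always filled from the other side.
Laws checked by tests: `merge(d, empty) == d`, idempotence under overwrite,
and value-multiset conservation per property path in append mode.

**Filter** — operates at property granularity. Each property is projected to
a flat record (path, section name/type, property name, values, unit, dtype,
value count); steps apply left to right, `keep` intersecting and `reject`
subtracting, each step combining its (field, operator, operand) comparisons
and optional custom predicate with `all` or `any`. Operators: `equals`,
`contains`, `matches` (regex), `is_empty`; comparisons on `value` hold if
any value matches. The output contains the surviving properties verbatim
plus exactly their ancestor sections — whether the reference behavior keeps
empty ancestors is unspecified, so pruning to ancestors-of-kept is the
declared choice here. A brute-force per-record evaluation serves as the
test oracle.

**Compare** — selects sections anywhere in the tree by a glob on the name
(document order) and renders one row per requested property, one column per
matched section (or transposed). Cell text joins the formatted values with
`", "` and appends the unit directly with no separator (`5.0g`), matching
established lab-book rendering. The table is presentation-only and cannot be
converted back. An empty selector match yields a zero-column table, not an
error.

## Fixture corpus and generator

The shipped corpus is a minimal two-day animal score-sheet workflow: a
template (`/Subject/Scores` with Date/Weight/Experimenter/Comment, weight in
grams, experimenter pre-filled "Alice"), per-day sheets named
`Scores_<ISO date>` so each day has a unique merge path, and a subject
document in two stages — `pre_enrichment` (the two Comment properties empty,
the document's only empty-valued entries) and `enriched` (comments filled
in). The day-1 experimenter is the single value "Alice"; multi-value
rendering is exercised by a separate explicit two-value test because the
corpus keeps one value per cell.

`random_document(GeneratorParams)` drives the property tests: seeded depth/
branching/value-count ranges over all canonical types, generated with
Python's Mersenne-Twister `random.Random`, whose sequence is stable across
platforms — identical parameters give identical documents, UUIDs included
(ids are drawn from the same stream). The generator produces structurally
valid documents with realistic features (empty and multi-valued properties,
nested sections, units, uncertainties) but not real-world scale or
vocabulary; green round-trip tests establish dialect fidelity, not
performance on thousand-value collections.

## Numerical and edge-case choices

- Floats render with `repr` (shortest exact form), so file round trips are
  bit-exact; times and datetimes keep microseconds via ISO format.
- Empty text attributes read back as absent (`None`); the model does not
  distinguish an attribute set to the empty string from an unset one across
  tabular round trips.
- Document equality is strict structural equality including UUIDs;
  `documents_equal(..., ignore_ids=True)` supports comparisons across
  tabular round trips, which mint fresh ids.
- The CLI is a thin shell: every subcommand delegates to the library
  functions, and a test asserts byte-identical output against direct API
  calls.

## Known limitations

- Section attributes of sections without direct properties, `link`/
  `include`/`repository`, and property `value_origin`/`reference` (unless
  their optional columns are enabled) survive only hierarchical round trips.
- Spreadsheets edited with non-text cell types (real Excel dates/numbers)
  are read via their string form; the dialect expects text cells as written
  by this package.
- Multi-worksheet workbooks and arbitrary third-party sheet layouts are out
  of scope; RDF export belongs to the odML core tooling, not here.
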