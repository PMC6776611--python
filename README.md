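# odmltab

Hierarchical metadata meets spreadsheet tables.

Neurophysiology experiments (and repetitive acquisition workflows in many
other fields) accumulate metadata — subject state, device settings, daily
health scores — that needs to live in a standardized, machine-readable
collection, but is most naturally *entered and inspected* in a spreadsheet.
The odML format stores such metadata as a tree: a **Document** holds named,
typed **Sections**, which hold **Properties** (extended key-value pairs,
each carrying a homogeneous list of values plus shared attributes such as
data type, physical unit and uncertainty).

`odmltab` bridges the two worlds. It converts odML documents (XML canonical,
JSON and YAML supported, legacy v1.3 XML upgraded transparently) to and from
a flat tabular dialect in csv or xlsx, and provides the operations a lab
needs to run a score-sheet workflow on top of it:

- **convert** — tree ↔ table, with customizable column sets, headers,
  repetitive-cell compaction and xlsx highlighting (missing values red,
  type-default values yellow);
- **template** — write an empty table that fixes the structure of future
  daily records, optionally with pre-filled default entries;
- **merge** — fold a daily record into the growing master document,
  appending values by default or overwriting on request;
- **filter** — extract a sub-document by multi-step keep/reject rules
  (e.g. *all properties that still have no value*);
- **compare** — a presentation-only overview grid of selected properties
  across sections (e.g. one column per recording day).

## The tabular dialect in one paragraph

Every value occupies one row. A `Path to Section` column encodes the
hierarchy as a `/`-delimited path (`/Subject/Scores_2000-01-01`); further
columns carry the section and property attributes, so rows of one property
agree everywhere except the `Value` cell. Document attributes (author, date,
version, repository) sit in a fixed-position top row. Columns are matched
by header *name*, never by position, so users may reorder or rename them —
renamed headers just need the same layout mapping at read time. Optional
compaction blanks any cell identical to the cell above (reset at section and
property boundaries) and is inverted by forward-filling on read.

## Worked example

The built-in fixture corpus models a two-day animal score sheet:

```python
from odmltab import CompareSpec, compare
from odmltab.fixtures import build_subject_document

doc = build_subject_document("enriched")
table = compare(doc, CompareSpec(
    property_names=("Date", "Weight", "Experimenter", "Comment"),
    section_selector="Scores_*"))
for row in table.as_grid():
    print(" | ".join(f"{c:<28}" for c in row).rstrip())
```

prints

```
                             | Scores_2000-01-01            | Scores_2000-01-02
Date                         | 2000-01-01                   | 2000-01-02
Weight                       | 5.0g                         | 5.5g
Experimenter                 | Alice                        | Bob
Comment                      | Blood sample was taken [...] | Small scratch at the right ear
```

one column per recording-day section, values rendered with the unit
appended directly (`5.0g`). The same workflow from the shell:

```sh
$ odmltab filter --empty-values subject.odml empty.odml --json-summary
{"written": ["empty.odml"], "sections": 3, "properties": 2, "values": 0}
```

finds the two properties still awaiting a value (the day comments); after
editing them in a spreadsheet, `odmltab merge --overwrite-values` folds the
enriched subset back into the master document. `odmltab convert`,
`odmltab template` and `odmltab compare` cover the remaining operations;
exit codes are 0 (success), 1 (processing error), 2 (usage error).

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch: template
generation and read-back, the filter → enrich → merge-back cycle, the
overview table, and a seeded batch of random documents round-tripped through
all five file formats (XML, JSON, YAML, csv, xlsx), asserting each stage.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the data model, dialect and design notes.
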