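"""Template, merge, filter and compare operations."""

import pytest

from odmltab import (
    CompareSpec,
    Document,
    FilterSpec,
    FilterStep,
    MergeOptions,
    Property,
    Section,
    compare,
    create_template,
    documents_equal,
    filter_document,
    merge,
    validate,
)
from odmltab.model import DEFAULT_REGISTRY as REG, PATH_DELIMITER
from odmltab.ops import (
    CompareSpecError,
    FilterSpecError,
    MergeError,
    property_record,
    write_compare,
)
from odmltab.table_io import read_csv, read_xlsx

from conftest import random_docs


# ---------------------------------------------------------------------------
# helpers / oracles

def _property_paths(doc):
    return {(path, p.name) for path, sec in doc.itersections()
            for p in sec.properties}


def _value_multisets(doc):
    out = {}
    for path, sec in doc.itersections():
        for p in sec.properties:
            out[(path, p.name)] = sorted(map(repr, p.values))
    return out


def _brute_force_filter(doc, spec):
    """Independent oracle: evaluate the composed predicate per property
    record and return the surviving (path, name) set."""
    survivors = set()
    for path, sec in doc.itersections():
        for prop in sec.properties:
            record = property_record(path, sec, prop, REG)
            alive = True
            for step in spec.steps:
                hit = step.matches(record)
                if step.mode == "keep":
                    alive = alive and hit
                else:
                    alive = alive and not hit
                if not alive:
                    break
            if alive:
                survivors.add((path, prop.name))
    return survivors


# ---------------------------------------------------------------------------
# template

class TestTemplate:
    def test_skeleton_template_read_back(self, template_doc, tmp_path):
        path = tmp_path / "template.csv"
        create_template(path, skeleton=template_doc)
        doc = read_csv(path)
        scores = doc["Subject"]["Scores"]
        assert [p.name for p in scores.properties] == \
               ["Date", "Weight", "Experimenter", "Comment"]
        # pre-filled defaults survive; everything else is empty
        assert scores.get_property("Experimenter").values == ["Alice"]
        assert scores.get_property("Weight").unit == "g"
        for name in ("Date", "Weight", "Comment"):
            assert scores.get_property(name).values == []

    def test_generic_placeholder_without_skeleton(self, tmp_path):
        path = tmp_path / "generic.xlsx"
        create_template(path)
        doc = read_xlsx(path)
        props = [(p, pr) for p, s in doc.itersections() for pr in s.properties]
        assert len(props) == 1
        assert props[0][1].values == []

    def test_xlsx_and_csv_templates_agree(self, template_doc, tmp_path):
        create_template(tmp_path / "t.csv", skeleton=template_doc)
        create_template(tmp_path / "t.xlsx", skeleton=template_doc)
        assert documents_equal(read_csv(tmp_path / "t.csv"),
                               read_xlsx(tmp_path / "t.xlsx"),
                               ignore_ids=True)


# ---------------------------------------------------------------------------
# merge

class TestMerge:
    def test_day2_sheet_extends_subject(self, subject_pre):
        from odmltab.fixtures import DAY2, build_daily_scoresheet

        day1_only = subject_pre.clone()
        day1_only["Subject"].sections = \
            [day1_only["Subject"]["Scores_2000-01-01"]]
        day2 = build_daily_scoresheet(DAY2, 5.5, "Bob")
        merged = merge(day1_only, day2)
        names = [s.name for s in merged["Subject"].sections]
        assert names == ["Scores_2000-01-01", "Scores_2000-01-02"]
        assert validate(merged).ok

    def test_merge_with_empty_is_identity(self, subject_enriched):
        assert merge(subject_enriched, Document()) == subject_enriched
        assert documents_equal(merge(Document(), subject_enriched),
                               subject_enriched, ignore_ids=True)

    def test_idempotent_under_overwrite(self):
        for doc in random_docs(10):
            assert merge(doc, doc, MergeOptions(overwrite_values=True)) == doc

    def test_append_mode_conserves_values(self):
        docs = random_docs(10)
        for a, b in zip(docs[::2], docs[1::2]):
            try:
                merged = merge(a, b)
            except MergeError:
                continue  # conflicting units are a legitimate refusal
            ma, mb, mm = (_value_multisets(d) for d in (a, b, merged))
            for key in set(ma) | set(mb):
                assert sorted(ma.get(key, []) + mb.get(key, [])) == mm[key]

    def test_append_mode_appends_values(self):
        a = Document(sections=[Section(name="S", properties=[
            Property("w", dtype="float", unit="g", values=[5.0])])])
        b = Document(sections=[Section(name="S", properties=[
            Property("w", dtype="float", unit="g", values=[5.5])])])
        merged = merge(a, b)
        assert merged["S"].get_property("w").values == [5.0, 5.5]

    def test_unit_conflict_in_append_mode_names_property(self):
        a = Document(sections=[Section(name="S", properties=[
            Property("w", dtype="float", unit="g", values=[5.0])])])
        b = Document(sections=[Section(name="S", properties=[
            Property("w", dtype="float", unit="kg", values=[0.005])])])
        with pytest.raises(MergeError, match="/S:w"):
            merge(a, b)

    def test_overwrite_replaces_values(self):
        a = Document(sections=[Section(name="S", properties=[
            Property("c", dtype="text", values=[])])])
        b = Document(sections=[Section(name="S", properties=[
            Property("c", dtype="text", values=["edited text"])])])
        merged = merge(a, b, MergeOptions(overwrite_values=True))
        assert merged["S"].get_property("c").values == ["edited text"]

    def test_target_uuids_preserved(self, subject_pre):
        source = subject_pre.clone(fresh_ids=True)
        merged = merge(subject_pre, source)
        for (p1, s1), (p2, s2) in zip(subject_pre.itersections(),
                                      merged.itersections()):
            assert s1.id == s2.id
            for q1, q2 in zip(s1.properties, s2.properties):
                assert q1.id == q2.id

    def test_absent_attributes_filled_from_source(self):
        a = Document(sections=[Section(name="S", properties=[
            Property("p", values=["x"], dtype="string")])])
        b = Document(sections=[Section(name="S", definition="a section",
                                       properties=[
            Property("p", definition="a prop", dtype="string")])])
        merged = merge(a, b)
        assert merged["S"].definition == "a section"
        assert merged["S"].get_property("p").definition == "a prop"


# ---------------------------------------------------------------------------
# filter

EMPTY_VALUES = FilterSpec(steps=[
    FilterStep(mode="keep", comparisons=[("value_count", "equals", 0)])])


class TestFilter:
    def test_keep_empty_value_properties(self, subject_pre):
        out = filter_document(subject_pre, EMPTY_VALUES)
        assert _property_paths(out) == {
            ("/Subject/Scores_2000-01-01", "Comment"),
            ("/Subject/Scores_2000-01-02", "Comment"),
        }
        assert validate(out).ok

    def test_always_true_keep_is_identity_up_to_empty_sections(
            self, subject_enriched):
        spec = FilterSpec(steps=[
            FilterStep(mode="keep", comparisons=[("property_name",
                                                  "matches", "")])])
        out = filter_document(subject_enriched, spec)
        assert documents_equal(out, subject_enriched)

    def test_input_not_modified(self, subject_pre):
        before = subject_pre.clone()
        filter_document(subject_pre, EMPTY_VALUES)
        assert subject_pre == before

    def test_ancestor_sections_survive_attributes_verbatim(self, subject_pre):
        out = filter_document(subject_pre, EMPTY_VALUES)
        assert out["Subject"].type == "subject"
        assert out["Subject"].id == subject_pre["Subject"].id

    def test_matches_brute_force_oracle_on_random_specs(self):
        """Declarative filtering equals per-record predicate evaluation."""
        import random

        rng = random.Random(42)
        fields = ("path", "section_name", "property_name", "odml_data_type",
                  "data_unit", "value")
        for doc in random_docs(20):
            steps = []
            for _ in range(rng.randint(1, 3)):
                comparisons = []
                for _ in range(rng.randint(1, 2)):
                    f = rng.choice(fields)
                    op = rng.choice(("equals", "contains", "matches",
                                     "is_empty"))
                    operand = rng.choice(("a", "e", "prop", "sec", "g", "1",
                                          "/sec0", "float"))
                    comparisons.append((f, op, operand))
                steps.append(FilterStep(
                    mode=rng.choice(("keep", "reject")),
                    comparisons=comparisons,
                    combine=rng.choice(("all", "any")),
                ))
            spec = FilterSpec(steps=steps)
            assert _property_paths(filter_document(doc, spec)) == \
                _brute_force_filter(doc, spec)

    def test_step_composition_equals_single_pass(self):
        step1 = FilterStep(mode="keep",
                           comparisons=[("odml_data_type", "equals", "float")])
        step2 = FilterStep(mode="reject",
                           comparisons=[("value_count", "equals", 0)])
        for doc in random_docs(10):
            chained = filter_document(
                filter_document(doc, FilterSpec(steps=[step1])),
                FilterSpec(steps=[step2]))
            direct = filter_document(doc, FilterSpec(steps=[step1, step2]))
            assert documents_equal(chained, direct)

    def test_custom_predicate(self, subject_enriched):
        spec = FilterSpec(steps=[FilterStep(
            mode="keep",
            custom=lambda rec: rec["data_unit"] == "g",
        )])
        out = filter_document(subject_enriched, spec)
        assert {name for _, name in _property_paths(out)} == {"Weight"}

    def test_malformed_steps_rejected(self):
        with pytest.raises(FilterSpecError):
            FilterStep(mode="keep", comparisons=[])
        with pytest.raises(FilterSpecError):
            FilterStep(mode="keep", comparisons=[("no_such_field",
                                                  "equals", "x")])
        with pytest.raises(FilterSpecError):
            FilterSpec(steps=[])

    def test_filter_edit_merge_cycle_restores_full_document(
            self, subject_pre, subject_enriched):
        """Extract the empty properties, fill them in, merge back with
        overwrite: the untouched content is unchanged and nothing is empty."""
        from odmltab.fixtures import DAY1_COMMENT, DAY2_COMMENT

        subset = filter_document(subject_pre, EMPTY_VALUES)
        subset["Subject"]["Scores_2000-01-01"].get_property(
            "Comment").values = [DAY1_COMMENT]
        subset["Subject"]["Scores_2000-01-02"].get_property(
            "Comment").values = [DAY2_COMMENT]
        merged = merge(subject_pre, subset,
                       MergeOptions(overwrite_values=True))
        assert documents_equal(merged, subject_enriched, ignore_ids=True)
        assert all(p.values for _, s in merged.itersections()
                   for p in s.properties)


# ---------------------------------------------------------------------------
# compare

class TestCompare:
    SPEC = CompareSpec(property_names=("Date", "Weight", "Experimenter",
                                       "Comment"),
                       section_selector="Scores_*")

    def test_worked_example_cells(self, subject_enriched):
        table = compare(subject_enriched, self.SPEC)
        assert table.column_labels == ["Scores_2000-01-01",
                                       "Scores_2000-01-02"]
        assert table.cells[1] == ["5.0g", "5.5g"]
        assert table.cells[3][1] == "Small scratch at the right ear"

    def test_cells_match_direct_tree_lookup(self):
        for doc in random_docs(10):
            names = sorted({p.name for _, s in doc.itersections()
                            for p in s.properties})
            if not names:
                continue
            spec = CompareSpec(property_names=names[:3],
                               section_selector="*")
            table = compare(doc, spec)
            sections = [s for _, s in doc.itersections()]
            for i, name in enumerate(spec.property_names):
                for j, sec in enumerate(sections):
                    try:
                        prop = sec.get_property(name)
                        expected = ", ".join(
                            REG.format(v, prop.dtype) for v in prop.values)
                        if expected and prop.unit:
                            expected += prop.unit
                    except KeyError:
                        expected = ""
                    assert table.cells[i][j] == expected

    def test_multi_value_cell_joined_with_comma(self):
        doc = Document(sections=[Section(name="S", properties=[
            Property("Experimenter", dtype="string",
                     values=["Alice", "Bob"])])])
        table = compare(doc, CompareSpec(property_names=("Experimenter",),
                                         section_selector="S"))
        assert table.cells == [["Alice, Bob"]]

    def test_selector_matching_nothing_gives_zero_columns(self,
                                                          subject_enriched):
        table = compare(subject_enriched,
                        CompareSpec(property_names=("Date",),
                                    section_selector="NoSuch*"))
        assert table.column_labels == [] and table.cells == [[]]

    def test_missing_property_gives_empty_cell(self, subject_enriched):
        table = compare(subject_enriched,
                        CompareSpec(property_names=("NotThere",),
                                    section_selector="Scores_*"))
        assert table.cells == [["", ""]]

    def test_duplicate_property_names_rejected(self):
        with pytest.raises(CompareSpecError):
            CompareSpec(property_names=("Date", "Date"))
        with pytest.raises(CompareSpecError):
            CompareSpec(property_names=())

    def test_sections_as_rows_transposes(self, subject_enriched):
        cols = compare(subject_enriched, self.SPEC)
        rows = compare(subject_enriched, CompareSpec(
            property_names=self.SPEC.property_names,
            section_selector=self.SPEC.section_selector,
            orientation="sections-as-rows"))
        assert rows.row_labels == cols.column_labels
        assert rows.cells[0][1] == cols.cells[1][0] == "5.0g"

    def test_write_compare_csv_and_xlsx_grids_agree(self, subject_enriched,
                                                    tmp_path):
        import csv as _csv

        import openpyxl

        table = compare(subject_enriched, self.SPEC)
        write_compare(table, tmp_path / "c.csv")
        write_compare(table, tmp_path / "c.xlsx")
        with open(tmp_path / "c.csv", newline="", encoding="utf-8") as fh:
            csv_grid = [row for row in _csv.reader(fh)]
        ws = openpyxl.load_workbook(tmp_path / "c.xlsx").active
        xlsx_grid = [["" if c is None else str(c) for c in row]
                     for row in ws.iter_rows(values_only=True)]
        assert csv_grid == xlsx_grid
        # 5 x 3 grid: label row/column + 4 properties x 2 days
        assert len(csv_grid) == 5 and all(len(r) == 3 for r in csv_grid)
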