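"""Exclusive set intersections against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from misset import (
    ConfigError,
    IntersectionTable,
    MissingnessMatrix,
    PatternKey,
    SelectionError,
    compute_intersections,
    compute_sets,
    project_fields,
    record_ids_for,
    select_intersections,
    sort_intersections,
)
from conftest import brute_force_intersections, key_of, mask_of, table_as_sets

FIELDS = ["A", "B", "C"]


class TestComputeSets:
    def test_counts_are_column_sums(self):
        mask = mask_of([{"A"}, {"A"}, set()], FIELDS)
        sets_ = compute_sets(mask)
        assert [s.missing_count for s in sets_] == [2, 0, 0]
        assert sets_[0].missing_fraction == pytest.approx(2 / 3)

    def test_all_present_mask_gives_zero_counts(self):
        mask = mask_of([set(), set()], FIELDS)
        assert all(s.missing_count == 0 for s in compute_sets(mask))

    def test_empty_matrix_is_flagged_degenerate(self):
        mask = mask_of([], FIELDS)
        sets_ = compute_sets(mask)
        assert all(s.degenerate and s.missing_fraction == 0.0 for s in sets_)

    def test_random_mask_matches_cellwise_tally(self, random_mask):
        mask = random_mask(n_records=50, n_fields=8, seed=7)
        expected = [
            sum(bool(mask.mask[i, j]) for i in range(mask.n_records))
            for j in range(mask.n_fields)
        ]
        assert [s.missing_count for s in compute_sets(mask)] == expected


class TestComputeIntersections:
    def test_three_fields_admit_four_multifield_patterns(self):
        """With fields A, B, C the only degree>=2 combinations are
        AB, AC, BC and ABC."""
        all_subsets = [
            set(s) for s in ([], ["A"], ["B"], ["C"], ["A", "B"],
                             ["A", "C"], ["B", "C"], ["A", "B", "C"])
        ]
        table = compute_intersections(mask_of(all_subsets, FIELDS))
        multi = {k for k in table.entries if k.degree >= 2}
        assert len(multi) == 4
        assert {tuple(k.fields) for k in multi} == {
            ("A", "B"), ("A", "C"), ("B", "C"), ("A", "B", "C")
        }

    def test_direct_grouping_example(self):
        table = compute_intersections(
            mask_of([{"A", "B"}, {"A", "B"}, {"C"}, set()], FIELDS)
        )
        assert table_as_sets(table) == {
            frozenset({"A", "B"}): 2, frozenset({"C"}): 1
        }
        assert table.complete_record_count == 1

    def test_random_mask_matches_grouping_oracle(self, random_mask):
        mask = random_mask(n_records=200, n_fields=10, seed=11)
        table = compute_intersections(mask)
        groups, complete = brute_force_intersections(mask)
        assert table_as_sets(table) == groups
        assert table.complete_record_count == complete

    def test_keys_are_in_dataset_order(self):
        mask = mask_of([{"C", "A"}], FIELDS)
        (key,) = compute_intersections(mask).entries
        assert key.fields == ("A", "C")

    def test_empty_matrix(self):
        table = compute_intersections(mask_of([], FIELDS))
        assert table.entries == {} and table.complete_record_count == 0


class TestProjection:
    def test_column_restriction_example(self):
        mask = mask_of([{"A", "B"}, {"A", "C"}], FIELDS)
        table = project_fields(mask, ["A", "B"])
        assert table_as_sets(table) == {
            frozenset({"A", "B"}): 1, frozenset({"A"}): 1
        }

    def test_projection_to_full_universe_is_identity(self, random_mask):
        mask = random_mask(seed=3)
        assert project_fields(mask, mask.field_names).entries == \
            compute_intersections(mask).entries

    def test_records_complete_within_subset_count_as_complete(self):
        mask = mask_of([{"C"}], FIELDS)
        table = project_fields(mask, ["A", "B"])
        assert table.entries == {} and table.complete_record_count == 1

    def test_unknown_field_rejected(self, random_mask):
        with pytest.raises(ConfigError):
            project_fields(random_mask(), ["NOPE"])

    @pytest.mark.parametrize("seed", range(5))
    def test_projection_matches_reaggregation_oracle(self, random_mask, seed):
        """Projecting the mask first must equal computing on the full mask
        and then dropping non-selected fields from every key."""
        r = np.random.default_rng(seed)
        mask = random_mask(n_records=120, n_fields=9, seed=100 + seed)
        chosen = sorted(
            r.choice(mask.field_names, size=4, replace=False).tolist()
        )
        direct = project_fields(mask, chosen)

        full = compute_intersections(mask)
        reagg: dict[frozenset, int] = {}
        complete = full.complete_record_count
        for key, card in full.entries.items():
            reduced = frozenset(f for f in key.fields if f in chosen)
            if reduced:
                reagg[reduced] = reagg.get(reduced, 0) + card
            else:
                complete += card
        assert table_as_sets(direct) == reagg
        assert direct.complete_record_count == complete


class TestSelection:
    def table(self):
        return compute_intersections(
            mask_of([{"A", "B"}, {"A", "B"}, {"C"}, set()], FIELDS)
        )

    def test_degree_filter(self):
        sel = select_intersections(self.table(), degree_range=(2, 2))
        assert {tuple(k.fields) for k in sel.selected_keys} == {("A", "B")}

    def test_cardinality_floor_of_one_selects_everything(self):
        table = self.table()
        sel = select_intersections(table, cardinality_range=(1, 10**9))
        assert sel.selected_keys == frozenset(table.entries)

    def test_provenance_records_the_predicate(self):
        sel = select_intersections(self.table(), degree_range=(2, 3))
        assert "degree" in sel.provenance

    def test_unknown_explicit_key_is_a_lookup_error(self):
        table = self.table()
        ghost = key_of({"B", "C"}, FIELDS)
        with pytest.raises(SelectionError):
            select_intersections(table, keys=[ghost])

    def test_malformed_range_rejected(self):
        with pytest.raises(ConfigError):
            select_intersections(self.table(), degree_range=(3, 1))

    def test_conjunction_matches_linear_scan(self, random_mask):
        mask = random_mask(n_records=400, n_fields=10, seed=5)
        table = compute_intersections(mask)
        n = mask.n_records
        sel = select_intersections(
            table, degree_range=(3, 10**9),
            cardinality_range=(0, max(0, int(n * 0.001))),
        )
        expected = {
            k for k, c in table.entries.items()
            if k.degree >= 3 and c <= n * 0.001
        }
        assert sel.selected_keys == expected


class TestSorting:
    def test_two_element_sort_by_cardinality(self):
        table = compute_intersections(
            mask_of([{"A", "B"}, {"A", "B"}, {"C"}] + [{"C"}] * 4, FIELDS)
        )
        ordered = sort_intersections(table, by="cardinality", descending=True)
        assert [tuple(k.fields) for k, _ in ordered] == [("C",), ("A", "B")]

    def test_ties_break_on_canonical_key_order(self):
        table = compute_intersections(
            mask_of([{"A", "B"}, {"A", "B"}, {"A", "C"}, {"A", "C"}], FIELDS)
        )
        ordered = sort_intersections(table, by="cardinality")
        assert [tuple(k.fields) for k, _ in ordered] == \
            [("A", "B"), ("A", "C")]

    @pytest.mark.parametrize("by", ["degree", "cardinality"])
    def test_random_entries_match_reference_sort(self, random_mask, by):
        table = compute_intersections(random_mask(n_records=300, n_fields=8,
                                                  seed=13))
        ordered = sort_intersections(table, by=by, descending=True)
        metric = (lambda kv: kv[0].degree) if by == "degree" \
            else (lambda kv: kv[1])
        reference = sorted(
            table.entries.items(),
            key=lambda kv: (-metric(kv), kv[0].indices),
        )
        assert ordered == reference


class TestRecordIds:
    def test_direct_match(self):
        mask = mask_of([{"A", "B"}, {"A", "B"}, {"C"}], FIELDS)
        table = compute_intersections(mask)
        sel = select_intersections(table, keys=[key_of({"A", "B"}, FIELDS)])
        assert record_ids_for(sel, mask) == [0, 1]

    def test_empty_selection_gives_no_records(self):
        mask = mask_of([{"A"}], FIELDS)
        sel = select_intersections(compute_intersections(mask),
                                   degree_range=(5, 9))
        assert record_ids_for(sel, mask) == []

    def test_random_case_matches_rescan_oracle(self, random_mask):
        mask = random_mask(n_records=250, n_fields=7, seed=21)
        table = compute_intersections(mask)
        sel = select_intersections(table, degree_range=(2, 3))
        got = record_ids_for(sel, mask)
        wanted_sets = {frozenset(k.fields) for k in sel.selected_keys}
        expected = [
            i for i in range(mask.n_records)
            if frozenset(
                mask.field_names[j]
                for j in range(mask.n_fields) if mask.mask[i, j]
            ) in wanted_sets
        ]
        assert got == expected


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        mask_bits=arrays(bool, st.tuples(st.integers(0, 40),
                                         st.integers(1, 6))),
    )
    def test_conservation_and_bounds(self, mask_bits):
        fields = tuple(f"F{j}" for j in range(mask_bits.shape[1]))
        mask = MissingnessMatrix(field_names=fields, mask=mask_bits)
        table = compute_intersections(mask)
        n = mask.n_records
        assert sum(table.entries.values()) + table.complete_record_count == n
        assert table.total_missing_cells == int(mask.mask.sum())
        assert table.n_intersections <= n
        assert table.n_intersections <= 2 ** len(fields) - 1
        assert all(k.degree >= 1 for k in table.entries)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), perm_seed=st.integers(0, 1000))
    def test_record_order_never_changes_the_table(self, seed, perm_seed):
        r = np.random.default_rng(seed)
        mask_bits = r.random((30, 5)) < 0.4
        fields = ("A", "B", "C", "D", "E")
        m1 = MissingnessMatrix(field_names=fields, mask=mask_bits)
        perm = np.random.default_rng(perm_seed).permutation(30)
        m2 = MissingnessMatrix(field_names=fields, mask=mask_bits[perm])
        t1, t2 = compute_intersections(m1), compute_intersections(m2)
        assert t1.entries == t2.entries
        assert t1.complete_record_count == t2.complete_record_count

    def test_cell_conservation_equals_field_counts(self, random_mask):
        mask = random_mask(n_records=80, n_fields=6, seed=2)
        table = compute_intersections(mask)
        assert table.total_missing_cells == sum(
            s.missing_count for s in compute_sets(mask)
        )


class TestPersistence:
    def test_csv_round_trip_is_bit_exact(self, random_mask, tmp_path):
        table = compute_intersections(random_mask(seed=31))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        table.to_csv(p1)
        again = IntersectionTable.from_csv(p1)
        assert again == table
        again.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_json_round_trip(self, random_mask, tmp_path):
        table = compute_intersections(random_mask(seed=33))
        path = tmp_path / "t.json"
        table.to_json(path)
        assert IntersectionTable.from_json(path) == table


class TestPatternKey:
    def test_canonicalisation_and_degree(self):
        key = PatternKey.from_fields(["C", "A"], FIELDS)
        assert key.fields == ("A", "C") and key.degree == 2
        assert "A" in key and "B" not in key
        assert str(key) == "A|C"

    def test_empty_key_rejected(self):
        with pytest.raises(ConfigError):
            PatternKey.from_fields([], FIELDS)

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigError):
            PatternKey.from_fields(["Z"], FIELDS)
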