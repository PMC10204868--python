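from collections import Counter

import pytest

from ebdiff.eb_io import InteractionRecord, parse_breakdown
from ebdiff.fixtures import FixturePlan, make_mock_breakdown
from ebdiff.interaction_diff import (
    CategoryStateError,
    InteractionCategory,
    InteractionType,
    RenumberingMismatchError,
    classify_category,
    classify_type,
    diff_tables,
    is_interacting,
    significant_changes,
    summary_table,
    total_energy_changes,
)
from tests.conftest import PLANTED_COUNTS

A, B, C, D, E, F = (InteractionCategory(x) for x in "ABCDEF")


def _rec(terms, restypes=("LEU", "VAL")):
    full = {t: 0.0 for t in
            ("fa_atr", "hbond_sc", "hbond_bb_sc", "hbond_sr_bb",
             "hbond_lr_bb", "dslf_fa13")}
    full.update(terms)
    return InteractionRecord(1, restypes[0], 2, restypes[1], full,
                             sum(full.values()))


class TestIsInteracting:
    def test_absent_pair_is_not_interacting(self, tables):
        ref, _ = tables
        assert not is_interacting(ref, (1, 2)) or (1, 2) in ref.pair_index

    def test_presence_follows_total_magnitude(self):
        text = "\n".join([
            "SCORE: pose_id resi1 pdbid1 restype1 resi2 pdbid2 restype2"
            " fa_atr total description",
            "SCORE: 1 1 1A ALA 2 2A GLY -0.4 -0.4 r1",
            "SCORE: 1 1 1A ALA 3 3A GLY 0.0 0.0 r2",
        ])
        t = parse_breakdown(text)
        assert is_interacting(t, (1, 2))
        assert not is_interacting(t, (1, 3))  # present but exactly zero
        assert not is_interacting(t, (5, 9))  # absent


class TestClassifyCategory:
    @pytest.mark.parametrize(
        "in_ref,in_mut,mutated,delta,expected",
        [
            (True, True, False, -0.8, A),
            (True, True, True, -0.8, B),
            (True, False, False, 0.5, C),
            (True, False, True, 0.5, D),
            (False, True, False, -1.0, E),
            (False, True, True, -3.32, F),
        ],
    )
    def test_truth_table(self, in_ref, in_mut, mutated, delta, expected):
        assert classify_category(in_ref, in_mut, mutated, delta) is expected

    def test_unchanged_both_sides_returns_none(self):
        assert classify_category(True, True, False, 0.0) is None
        assert classify_category(True, True, True, 1e-9) is None

    def test_neither_side_is_an_impossible_state(self):
        with pytest.raises(CategoryStateError):
            classify_category(False, False, False, 0.0)


class TestClassifyType:
    def test_arg_asp_with_sidechain_hbond_is_salt_bridge(self):
        types = classify_type(_rec({"hbond_sc": -1.1}, ("ARG", "ASP")))
        assert types == {InteractionType.SALT_BRIDGE, InteractionType.HB_SC_SC,
                         InteractionType.ALL}

    def test_cys_cys_with_disulfide_term(self):
        types = classify_type(_rec({"dslf_fa13": -2.0}, ("CYS", "CYS")))
        assert types == {InteractionType.DISULFIDE, InteractionType.ALL}

    def test_generic_pair_is_only_all(self):
        assert classify_type(_rec({"fa_atr": -0.9})) == {InteractionType.ALL}

    def test_charged_pair_without_hbond_term_is_not_salt_bridge(self):
        types = classify_type(_rec({"fa_atr": -0.5}, ("LYS", "GLU")))
        assert InteractionType.SALT_BRIDGE not in types

    @pytest.mark.parametrize("term,expected", [
        ("hbond_bb_sc", InteractionType.HB_BB_SC),
        ("hbond_sr_bb", InteractionType.HB_BB_SR),
        ("hbond_lr_bb", InteractionType.HB_BB_LR),
    ])
    def test_hbond_classes_fire_on_negative_terms(self, term, expected):
        assert expected in classify_type(_rec({term: -0.3}))

    def test_strict_mode_excludes_histidine(self):
        rec = _rec({"hbond_sc": -0.8}, ("HIS", "GLU"))
        assert InteractionType.SALT_BRIDGE in classify_type(rec)
        assert InteractionType.SALT_BRIDGE not in classify_type(
            rec, strict_salt_bridge=True)


class TestDiffTables:
    def test_identical_tables_give_no_changes(self, tables, mock):
        ref, _ = tables
        d = diff_tables(ref, ref, [])
        assert d.changes == []
        assert d.onebody_changes == []

    def test_planted_category_counts_recovered_exactly(self, diff):
        recovered = Counter(str(ch.category) for ch in diff.changes)
        assert dict(recovered) == PLANTED_COUNTS

    def test_planted_labels_and_types_agree_pairwise(self, diff, mock):
        got = {ch.pair: ch for ch in diff.changes}
        truth = mock.planted_by_pair
        assert set(got) == set(truth)
        for pair, planted in truth.items():
            assert got[pair].category is planted.category
            assert got[pair].types == planted.types
            assert got[pair].delta_total == pytest.approx(
                planted.delta_total, abs=1e-9)

    def test_mutation_restype_contradiction_raises(self, tables, mock):
        ref, mut = tables
        bad = list(mock.mutations)
        m = bad[0]
        wrong = "W" if m.ref_restype != "W" else "Y"
        bad[0] = type(m)(m.position, wrong, m.mut_restype)
        with pytest.raises(RenumberingMismatchError):
            diff_tables(ref, mut, bad)

    def test_swap_antisymmetry(self, tables, mock):
        ref, mut = tables
        swapped_muts = [type(m)(m.position, m.mut_restype, m.ref_restype)
                        for m in mock.mutations]
        fwd = diff_tables(ref, mut, mock.mutations)
        rev = diff_tables(mut, ref, swapped_muts)
        swap = {A: A, B: B, C: E, D: F, E: C, F: D}
        fwd_map = {ch.pair: ch for ch in fwd.changes}
        rev_map = {ch.pair: ch for ch in rev.changes}
        assert set(fwd_map) == set(rev_map)
        for pair, ch in fwd_map.items():
            assert rev_map[pair].category is swap[ch.category]
            assert rev_map[pair].delta_total == -ch.delta_total

    def test_conservation_of_grand_total_difference(self, tables, mock):
        ref, mut = tables
        d = diff_tables(ref, mut, mock.mutations, change_eps=0.0)
        lhs = sum(ch.delta_total for ch in d.changes)
        lhs += sum(delta for _, delta in d.onebody_changes)
        assert lhs == pytest.approx(mut.grand_total - ref.grand_total, abs=1e-6)

    def test_category_partition_is_exclusive_and_exhaustive(self, tables, mock):
        # every pair key in the union is either unchanged or exactly one category
        ref, mut = tables
        d = diff_tables(ref, mut, mock.mutations)
        seen = [ch.pair for ch in d.changes]
        assert len(seen) == len(set(seen))
        union = set(ref.pair_index) | set(mut.pair_index)
        assert set(seen) <= union


class TestSums:
    def test_total_energy_changes_arithmetic(self, diff):
        total = total_energy_changes(diff)
        brute = sum(ch.delta_total for ch in diff.changes)
        assert total == pytest.approx(brute, abs=1e-12)

    def test_category_selection(self, diff):
        by_cat = sum(total_energy_changes(diff, [c]) for c in "ABCDEF")
        assert by_cat == pytest.approx(total_energy_changes(diff), abs=1e-9)

    def test_empty_category_selection_rejected(self, diff):
        with pytest.raises(ValueError):
            total_energy_changes(diff, [])

    def test_significant_strict_threshold(self):
        # hand-written boundary values around the ±1.0 REU rule
        from ebdiff.interaction_diff import DiffResult, PairChange
        deltas = [1.0, -1.0, 1.0000001, -1.0000001, 0.3, 1.5, -2.0]
        changes = [
            PairChange((i, i + 1), ("ALA", "ALA"), ("ALA", "ALA"), A, {}, v,
                       frozenset({InteractionType.ALL}), False)
            for i, v in enumerate(deltas, start=1)
        ]
        d = DiffResult(changes=changes)
        total, kept = significant_changes(d, threshold=1.0)
        assert [ch.delta_total for ch in kept] == [-2.0, -1.0000001, 1.0000001, 1.5]
        assert total == pytest.approx(-2.0 - 1.0000001 + 1.0000001 + 1.5)

    def test_threshold_zero_equals_total(self, diff):
        s, kept = significant_changes(diff, threshold=0.0)
        assert s == pytest.approx(total_energy_changes(diff), abs=1e-9)
        assert len(kept) == len(diff.changes)

    def test_significant_set_size_non_increasing_in_threshold(self, diff):
        sizes = [len(significant_changes(diff, threshold=t)[1])
                 for t in (0.0, 0.5, 1.0, 2.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_significance_matches_planted_flags(self, diff, mock):
        _, kept = significant_changes(diff, threshold=1.0)
        assert {ch.pair for ch in kept} == \
               {p.pair for p in mock.planted if p.significant}


class TestSummaryTable:
    def test_empty_diff_gives_all_zero_grid(self):
        from ebdiff.interaction_diff import DiffResult
        grid = summary_table(DiffResult())
        assert all(v == (0, 0.0) for v in grid.values())

    def test_single_salt_bridge_cell(self):
        from ebdiff.interaction_diff import DiffResult, PairChange
        ch = PairChange(
            (135, 153), ("ILE", "ASP"), ("ARG", "ASP"), F, {}, -3.32,
            frozenset({InteractionType.SALT_BRIDGE, InteractionType.HB_SC_SC,
                       InteractionType.ALL}),
            True,
        )
        grid = summary_table(DiffResult(changes=[ch]))
        assert grid[(F, InteractionType.SALT_BRIDGE)] == (1, pytest.approx(-3.32))
        assert grid[(F, InteractionType.ALL)] == (1, pytest.approx(-3.32))
        assert grid[(E, InteractionType.SALT_BRIDGE)] == (0, 0.0)

    def test_all_column_marginals_match_significant_list(self, diff):
        grid = summary_table(diff, threshold=1.0)
        _, kept = significant_changes(diff, threshold=1.0)
        per_cat = Counter(ch.category for ch in kept)
        for cat in (A, B, C, D, E, F):
            count, _total = grid[(cat, InteractionType.ALL)]
            assert count == per_cat.get(cat, 0)


class TestPlantedRecoveryAcrossSeeds:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_perfect_recovery_on_random_plans(self, seed):
        from ebdiff.fixtures import random_plan
        mock = make_mock_breakdown(random_plan(seed, n_pairs=60))
        ref = parse_breakdown(mock.ref_text)
        mut = parse_breakdown(mock.mut_text)
        d = diff_tables(ref, mut, mock.mutations)
        got = {ch.pair: (ch.category, ch.types) for ch in d.changes}
        want = {p.pair: (p.category, p.types) for p in mock.planted}
        assert got == want
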