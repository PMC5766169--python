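"""Tests of dot-bracket parsing, pair-range classification and statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from spetfold.counting import split_deciles
from spetfold.structure import (
    CATEGORY_LONG,
    CATEGORY_SHORT,
    CATEGORY_UNPAIRED,
    category_reactivity,
    classify_pairs,
    element_metaprofile,
    enrichment_test,
    hairpin_elements,
    parse_dotbracket,
    read_vienna,
    write_vienna,
)


class TestParseDotbracket:
    def test_nested_pairs(self):
        s = parse_dotbracket("((..))")
        assert s.partner(1) == 6 and s.partner(2) == 5
        assert s.partner(3) == 0 and s.partner(4) == 0
        assert s.pairs() == [(1, 6), (2, 5)]

    def test_all_unpaired(self):
        s = parse_dotbracket("....")
        assert all(s.partner(p) == 0 for p in range(1, 5))

    def test_unclosed_reports_offset(self):
        with pytest.raises(ValueError, match="offset 1"):
            parse_dotbracket("((.)")
        with pytest.raises(ValueError, match="unmatched"):
            parse_dotbracket(".))")

    def test_pseudoknot_layers_rejected(self):
        with pytest.raises(ValueError, match="invalid character"):
            parse_dotbracket("([.)]")

    def test_round_trip_symmetry(self):
        s = parse_dotbracket("(((...)))..((..))")
        pt = s.pair_table
        for p in range(1, s.length + 1):
            if pt[p]:
                assert pt[pt[p]] == p


class TestClassifyPairs:
    def make(self, pairs, L=100):
        db = ["."] * L
        for i, j in pairs:
            db[i - 1], db[j - 1] = "(", ")"
        return parse_dotbracket("".join(db))

    def test_same_decile_is_short_range(self):
        s = self.make([(12, 18)])
        table = classify_pairs(s, split_deciles(100), [12, 18])
        assert set(table["category"]) == {CATEGORY_SHORT}
        assert list(table["helix_side"]) == ["FIVE_PRIME", "THREE_PRIME"]

    def test_distant_deciles_are_long_range(self):
        s = self.make([(5, 95)])
        table = classify_pairs(s, split_deciles(100), [5, 95]).set_index("position")
        assert table.loc[5, "category"] == CATEGORY_LONG
        assert table.loc[5, "helix_side"] == "FIVE_PRIME"

    def test_boundary_spanning_pair_is_long_range(self):
        s = self.make([(10, 11)])
        table = classify_pairs(s, split_deciles(100), [10, 11])
        assert set(table["category"]) == {CATEGORY_LONG}

    def test_partition_covers_every_ac_position(self):
        s = self.make([(12, 18), (5, 95), (40, 44)])
        ac = list(range(1, 101, 3))
        table = classify_pairs(s, split_deciles(100), ac)
        assert sorted(table["position"]) == sorted(ac)
        assert table["position"].is_unique


class TestEnrichment:
    def test_exact_summation_example(self):
        # N=100, K=30, n=20, k=12 upper tail
        from math import comb

        want = sum(comb(30, j) * comb(70, 20 - j) for j in range(12, 21)) / comb(100, 20)
        table = pd.DataFrame({
            "position": range(1, 101),
            "category": [CATEGORY_LONG] * 30 + [CATEGORY_UNPAIRED] * 70,
            "helix_side": ["FIVE_PRIME"] * 30 + ["NA"] * 70,
        })
        changed = list(range(1, 13)) + list(range(31, 39))   # 12 long-range of 20 draws
        res = enrichment_test(table, changed, range(1, 101))
        assert (res.population, res.successes, res.draws, res.observed) == (100, 30, 20, 12)
        assert res.p_value == pytest.approx(want, abs=1e-12)
        assert res.observed_fraction[CATEGORY_LONG] == pytest.approx(0.6)
        assert res.expected_fraction[CATEGORY_LONG] == pytest.approx(0.3)

    def test_inconsistent_inputs_error(self):
        table = pd.DataFrame({"position": [1, 2], "category": [CATEGORY_LONG] * 2,
                              "helix_side": ["FIVE_PRIME"] * 2})
        with pytest.raises(ValueError):
            enrichment_test(table, [1, 3], [1, 2])           # draws outside universe
        with pytest.raises(ValueError):
            enrichment_test(table, [1], [1, 2, 3])           # unlabeled universe position


class TestCategoryReactivity:
    def test_anova_matches_textbook_formula(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 40), rng.normal(0.3, 1, 35)
        f_scipy, p_scipy = scipy_stats.f_oneway(a, b)
        groups = [a, b]
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_direct = (ss_between / 1) / (ss_within / (len(a) + len(b) - 2))
        assert f_scipy == pytest.approx(f_direct, abs=1e-10)

    def test_identical_profiles_give_f_near_zero(self):
        L = 100
        db = ["."] * L
        for i, j in [(11, 17), (12, 16), (41, 49), (42, 48)]:
            db[i - 1], db[j - 1] = "(", ")"
        s = parse_dotbracket("".join(db))
        intervals = split_deciles(L)
        ac = list(range(1, L + 1, 2))
        table = classify_pairs(s, intervals, ac)
        rng = np.random.default_rng(13)
        profile = rng.uniform(0.05, 1.0, L)
        nascent = [profile.copy() for _ in range(10)]
        values, tests = category_reactivity(nascent, profile, table, intervals)
        assert not values.empty
        assert (tests["F"].abs() < 1e-20).all()
        assert (tests["p_value"] > 0.99).all()

    def test_three_prime_sides_excluded_from_paired_groups(self):
        L = 100
        db = ["."] * L
        db[4], db[94] = "(", ")"                      # pair (5, 95)
        s = parse_dotbracket("".join(db))
        intervals = split_deciles(L)
        table = classify_pairs(s, intervals, [5, 95])
        profile = np.full(L, 0.5)
        values, _ = category_reactivity([profile] * 10, profile, table, intervals)
        assert 95 not in set(values["position"])


class TestHairpinElements:
    def test_single_hairpin_with_stack_and_bulge(self):
        #        123456789012345678
        db = "..((.((...))..)).."
        s = parse_dotbracket(db)
        assert hairpin_elements(s) == [(3, 16)]

    def test_multiloop_splits_elements(self):
        db = "((..((...))..((...))..))"
        s = parse_dotbracket(db)
        assert hairpin_elements(s) == [(5, 11), (14, 20)]

    def test_metaprofile_identical_profiles_coincide(self):
        L = 60
        db = ["."] * L
        for i, j in [(11, 25), (12, 24), (13, 23)]:
            db[i - 1], db[j - 1] = "(", ")"
        s = parse_dotbracket("".join(db))
        intervals = [(1, L)]                # whole transcript in one segment
        ac = list(range(1, L + 1))
        rng = np.random.default_rng(14)
        profile = rng.uniform(0.0, 1.0, L)
        meta = element_metaprofile(s, [profile], profile, intervals, ac_positions=ac)
        covered = meta["n_nascent"] > 0
        assert covered.any()
        np.testing.assert_allclose(meta.loc[covered, "nascent_mean"],
                                   meta.loc[covered, "mature_mean"], atol=1e-12)

    def test_element_of_21_positions_bins_identically(self):
        L = 50
        db = ["."] * L
        # outermost pair spans 10..30: 21 positions
        for k in range(3):
            db[10 + k - 1], db[30 - k - 1] = "(", ")"
        s = parse_dotbracket("".join(db))
        intervals = [(1, L)]
        profile = np.arange(L, dtype=float) / L
        meta = element_metaprofile(s, [profile], profile, intervals,
                                   ac_positions=range(1, L + 1))
        got = meta["mature_mean"].to_numpy()
        np.testing.assert_allclose(got, profile[9:30], atol=1e-12)

    def test_no_qualifying_elements_gives_empty_bins(self):
        s = parse_dotbracket("." * 40)
        meta = element_metaprofile(s, [np.ones(40)] * 10, np.ones(40), split_deciles(40),
                                   ac_positions=range(1, 41))
        assert (meta["n_nascent"] == 0).all() and (meta["n_mature"] == 0).all()


def test_vienna_round_trip(tmp_path):
    structures = {
        "a": parse_dotbracket("((..))..", "a"),
        "b": parse_dotbracket(".....", "b"),
    }
    path = tmp_path / "s.db"
    write_vienna(structures, path, sequences={"a": "GGAACCGT", "b": "AAAAA"})
    again = read_vienna(path)
    assert {k: v.dotbracket for k, v in again.items()} == {"a": "((..))..", "b": "....."}
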