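import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloprof.core_io import SpeciesSet, ValidationError
from phyloprof.enrichment import (
    bh_adjust,
    enrichment_scan,
    enrichment_score,
    fraction_identical_overall,
    fraction_identical_within,
    permutation_pvalue,
)
from phyloprof.profiles import ProfileSet

from .oracles import bh_stepup, f_values_enumeration

# distinct 3-bit profiles used as letters in the toy examples
A, B, C = (1, 0, 0), (0, 1, 0), (0, 0, 1)


def _arr(profiles):
    return np.array(profiles, dtype=np.uint8)


class TestFractions:
    def test_toy_within(self):
        # {A,A,A,B}: oracle enumerates all 6 pairs -> 3 identical
        expected = f_values_enumeration([A, A, A, B], [])[0]
        assert expected == pytest.approx(0.5)
        assert fraction_identical_within(_arr([A, A, A, B])) == pytest.approx(expected)

    def test_all_identical_is_one(self):
        assert fraction_identical_within(_arr([A] * 9)) == pytest.approx(1.0)

    def test_all_distinct_is_zero(self):
        assert fraction_identical_within(_arr([A, B, C])) == pytest.approx(0.0)

    def test_undefined_below_two(self):
        assert fraction_identical_within(_arr([A])) is None
        assert fraction_identical_within(_arr([]).reshape(0, 3)) is None

    def test_toy_overall(self):
        # pathway {A,A,A,B}, outside {B,C} -> (3+1)/(6+8) = 2/7
        expected = f_values_enumeration([A, A, A, B], [B, C])[1]
        assert expected == pytest.approx(2 / 7)
        got = fraction_identical_overall(_arr([A, A, A, B]), _arr([B, C]))
        assert got == pytest.approx(expected)

    def test_empty_outside_reduces_to_within(self):
        inside = _arr([A, A, B])
        empty = _arr([]).reshape(0, 3)
        assert fraction_identical_overall(inside, empty) == pytest.approx(
            fraction_identical_within(inside)
        )

    def test_single_inside_with_outside(self):
        # pathway {A}, outside {A,B,C} -> (0+1)/(0+3) = 1/3
        got = fraction_identical_overall(_arr([A]), _arr([A, B, C]))
        assert got == pytest.approx(1 / 3)

    def test_fully_undefined(self):
        empty = _arr([]).reshape(0, 3)
        assert fraction_identical_overall(_arr([A]), empty) is None

    def test_oracle_equivalence_200_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_f = int(rng.integers(2, 21))
            n_out = int(rng.integers(0, 41))
            width = int(rng.integers(2, 6))
            inside = rng.integers(0, 2, size=(n_f, width))
            outside = rng.integers(0, 2, size=(n_out, width))
            exp_pw, exp_all = f_values_enumeration(
                [tuple(r) for r in inside], [tuple(r) for r in outside]
            )
            assert fraction_identical_within(inside) == pytest.approx(exp_pw, abs=1e-12)
            assert fraction_identical_overall(inside, outside) == pytest.approx(
                exp_all, abs=1e-12
            )

    def test_unique_profile_never_increases_f_pw(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            rows = rng.integers(0, 2, size=(int(rng.integers(2, 12)), 4))
            base = fraction_identical_within(rows)
            unique = np.full((1, 4), 9, dtype=int)  # matches nothing
            extended = fraction_identical_within(np.vstack([rows, unique]))
            assert extended <= base + 1e-12


class TestEnrichmentScore:
    def test_toy_arithmetic(self):
        assert enrichment_score(0.5, 2 / 7) == pytest.approx(1.75)

    def test_equal_fractions_give_one(self):
        assert enrichment_score(0.37, 0.37) == pytest.approx(1.0)

    def test_zero_numerator(self):
        assert enrichment_score(0.0, 0.3) == 0.0

    def test_zero_denominator_undefined(self):
        assert enrichment_score(0.5, 0.0) is None
        assert enrichment_score(None, 0.3) is None


class TestPermutationPvalue:
    def test_uniform_pool_all_draws_tie(self):
        pool = _arr([A] * 20)
        p, mean_er = permutation_pvalue(1.0, pool, n_f=5, n_draws=200, seed=0)
        assert p == pytest.approx(1.0)
        assert mean_er == pytest.approx(1.0)

    def test_planted_coherence_is_significant(self):
        rng = np.random.default_rng(0)
        # 200 objects over 50 distinct equifrequent profiles (4 objects each)
        distinct = np.eye(50, dtype=np.uint8)
        pool = np.repeat(distinct, 4, axis=0)
        pathway = np.repeat(distinct[:1], 10, axis=0)  # hypothetical: 10 sharing one profile
        # embed the pathway by taking 4 existing + 6 extra copies of profile 0
        pool = np.vstack([pool, np.repeat(distinct[:1], 6, axis=0)])
        inside = pool[np.r_[0:4, 200:206]]
        outside = np.delete(pool, np.r_[0:4, 200:206], axis=0)
        e = enrichment_score(
            fraction_identical_within(inside),
            fraction_identical_overall(inside, outside),
        )
        p, _ = permutation_pvalue(e, pool, n_f=10, n_draws=1000, seed=1)
        assert p < 0.05

    def test_undefined_observed_reported_missing(self):
        pool = _arr([A, B, C, A])
        p, mean_er = permutation_pvalue(None, pool, n_f=2, n_draws=50, seed=0)
        assert p is None

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        pool = rng.integers(0, 2, size=(60, 5)).astype(np.uint8)
        r1 = permutation_pvalue(1.2, pool, 8, n_draws=300, seed=9)
        r2 = permutation_pvalue(1.2, pool, 8, n_draws=300, seed=9)
        assert r1 == r2

    def test_n_f_exceeding_pool_is_error(self):
        with pytest.raises(ValidationError):
            permutation_pvalue(1.0, _arr([A, B]), n_f=3)


class TestBHAdjust:
    def test_hand_example(self):
        # step-up by hand: (0.01*3/1, 0.02*3/2, 0.03*3/3) -> monotone -> all 0.03
        got = bh_adjust([0.01, 0.02, 0.03])
        assert got == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    @settings(max_examples=80, deadline=None)
    def test_matches_stepup_oracle_and_dominates_input(self, pvals):
        got = bh_adjust(pvals)
        oracle = bh_stepup(pvals)
        assert got == pytest.approx(oracle, abs=1e-12)
        assert all(g >= p - 1e-12 for g, p in zip(got, pvals))

    def test_permutation_invariance_after_order_restoration(self):
        rng = np.random.default_rng(8)
        p = rng.random(15)
        perm = rng.permutation(15)
        adjusted = bh_adjust(p)
        adjusted_perm = bh_adjust(p[perm])
        assert adjusted[perm] == pytest.approx(adjusted_perm, abs=1e-12)


def _profile_set(matrix):
    matrix = np.asarray(matrix, dtype=np.uint8)
    ss = SpeciesSet(
        tuple(f"S{i}" for i in range(matrix.shape[1])),
        tuple(True for _ in range(matrix.shape[1])),
    )
    return ProfileSet([f"o{i}" for i in range(len(matrix))], matrix, ss)


class TestEnrichmentScan:
    def test_single_pathway_adjusted_equals_raw(self):
        rng = np.random.default_rng(0)
        pset = _profile_set(rng.integers(0, 2, size=(30, 4)))
        scan = enrichment_scan({"pw": {"o0", "o1", "o2"}}, pset, n_draws=200, seed=1)
        row = scan.iloc[0]
        assert row["p_adjusted"] == pytest.approx(row["p_empirical"])

    def test_untestable_pathway_flagged_not_dropped(self):
        pset = _profile_set([[1, 0], [0, 1], [1, 1]])
        scan = enrichment_scan({"small": {"o0"}, "ok": {"o0", "o1", "o2"}}, pset, n_draws=50, seed=2)
        small = scan[scan["pathway"] == "small"].iloc[0]
        assert not small["testable"]
        assert np.isnan(small["p_adjusted"])

    def test_result_independent_of_scan_composition(self):
        # per-pathway child seeds: p_empirical for a pathway must not depend
        # on which other pathways are scanned alongside it
        rng = np.random.default_rng(4)
        pset = _profile_set(rng.integers(0, 2, size=(40, 5)))
        members = {f"pw{k}": {f"o{i}" for i in rng.choice(40, 6, replace=False)} for k in range(4)}
        full = enrichment_scan(members, pset, n_draws=300, seed=7)
        solo = enrichment_scan({"pw2": members["pw2"]}, pset, n_draws=300, seed=7)
        got = full[full["pathway"] == "pw2"]["p_empirical"].iloc[0]
        assert got == pytest.approx(solo["p_empirical"].iloc[0])

    def test_fixture_scan_matches_oracle_values(self, loaded, fixture_expected, bundle):
        from phyloprof.families import build_families
        from phyloprof.pathways import PathwayDefinitions, build_memberships
        from phyloprof.pipeline import annotated_object_ids
        from phyloprof.profiles import build_profile_matrix

        part = build_families(loaded["edges"], loaded["genes"], min_identity=30)
        pset = build_profile_matrix(part, loaded["species"]).subset(
            annotated_object_ids(loaded["genes"], part)
        )
        defs = PathwayDefinitions(
            loaded["hierarchy"], frozenset(bundle.truth["secondary_classes"])
        )
        for level in ("map", "class"):
            memberships = build_memberships(loaded["genes"], part, defs, level)
            scan = enrichment_scan(memberships, pset, n_draws=50, seed=0)
            for row in scan.itertuples():
                exp = fixture_expected["enrichment"][f"{level}:{row.pathway}"]
                assert row.n_f == exp["n_f"]
                for mine, key in ((row.f_pw, "f_pw"), (row.f_all, "f_all"),
                                  (row.enrichment, "enrichment")):
                    if exp[key] is None:
                        assert np.isnan(mine)
                    else:
                        assert mine == pytest.approx(exp[key], abs=1e-12)
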