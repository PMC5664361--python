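import numpy as np
import pandas as pd
import pytest

from phyloprof.assoc import (
    coexpression_vs_profile,
    ppi_profile_comparison,
    preprocess_expression,
    quantile_normalize,
)
from phyloprof.core_io import PPITable, SpeciesSet, ValidationError
from phyloprof.profiles import ProfileSet


def _pset(rows):
    rows = np.asarray(rows, dtype=np.uint8)
    ss = SpeciesSet(
        tuple(f"S{i}" for i in range(rows.shape[1])),
        tuple(True for _ in range(rows.shape[1])),
    )
    return ProfileSet([f"o{i}" for i in range(len(rows))], rows, ss)


class TestQuantileNormalize:
    def test_columns_share_sorted_multiset(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(size=(50, 6)))
        qn = quantile_normalize(df)
        reference = np.sort(qn.iloc[:, 0].to_numpy())
        for j in range(qn.shape[1]):
            np.testing.assert_allclose(np.sort(qn.iloc[:, j].to_numpy()), reference)

    def test_idempotent_bitwise(self):
        # continuous (tie-free) data, as expression intensities are
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(size=(40, 5)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert (once.to_numpy() == twice.to_numpy()).all()

    def test_ties_get_mean_of_rank_slots(self):
        # column 0 has a tie spanning rank slots 1 and 2
        df = pd.DataFrame({"a": [5.0, 5.0, 1.0], "b": [30.0, 20.0, 10.0]})
        qn = quantile_normalize(df)
        mean_sorted = (np.sort(df["a"]) + np.sort(df["b"])) / 2  # [5.5, 12.5, 17.5]
        tied = (mean_sorted[1] + mean_sorted[2]) / 2
        np.testing.assert_allclose(qn["a"].to_numpy(), [tied, tied, mean_sorted[0]])
        np.testing.assert_allclose(qn["b"].to_numpy(), mean_sorted[::-1])

    def test_two_by_two_hand_computation(self):
        # values [[1,4],[3,2]], log then QN
        df = pd.DataFrame(np.log([[1.0, 4.0], [3.0, 2.0]]))
        qn = quantile_normalize(df)
        lo = (np.log(1) + np.log(2)) / 2
        hi = (np.log(3) + np.log(4)) / 2
        np.testing.assert_allclose(qn.to_numpy(), [[lo, hi], [hi, lo]], rtol=1e-12)


class TestPreprocessExpression:
    def test_nonpositive_rejected(self):
        df = pd.DataFrame([[1.0, 0.0], [2.0, 3.0]])
        with pytest.raises(ValidationError):
            preprocess_expression(df)

    def test_keep_prob_one_keeps_all_columns(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.lognormal(size=(10, 8)))
        out = preprocess_expression(df, sample_keep_prob=1.0)
        assert out.shape == df.shape

    def test_subsampling_drops_columns_deterministically(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.lognormal(size=(10, 100)))
        a = preprocess_expression(df, sample_keep_prob=0.1, seed=5)
        b = preprocess_expression(df, sample_keep_prob=0.1, seed=5)
        assert list(a.columns) == list(b.columns)
        assert 0 < a.shape[1] < 40


def _expression_for(genes, n_samples, maker, seed=0):
    rng = np.random.default_rng(seed)
    rows = [maker(g, rng, n_samples) for g in genes]
    return pd.DataFrame(
        np.exp(rows), index=genes, columns=[f"smp{j}" for j in range(n_samples)]
    )


class TestCoexpression:
    def test_two_genes_exactly_one_pair(self):
        pset = _pset([[1, 0], [0, 1]])
        expr = _expression_for(["g0", "g1"], 30, lambda g, r, n: r.normal(size=n))
        res = coexpression_vs_profile(
            expr, {"g0": "o0", "g1": "o1"}, pset, n_genes=2, seed=0
        )
        assert len(res.records) == 1

    def test_null_correlation_within_noise(self):
        rng = np.random.default_rng(4)
        n = 60
        pset = _pset(rng.integers(0, 2, size=(n, 8)) | np.eye(n, 8, dtype=int))
        genes = [f"g{i}" for i in range(n)]
        mapping = {g: f"o{i}" for i, g in enumerate(genes)}
        expr = _expression_for(genes, 50, lambda g, r, ns: r.normal(size=ns), seed=7)
        res = coexpression_vs_profile(expr, mapping, pset, n_genes=n, seed=1)
        se = 1 / np.sqrt(len(res.records))
        assert abs(res.pearson_r) < 4 * se + 0.02

    def test_planted_blocks_show_increasing_binned_medians(self):
        # two profile blocks; same-block gene pairs share a latent factor
        rng = np.random.default_rng(8)
        n_per = 15
        profiles = [[1, 1, 0, 0]] * n_per + [[0, 0, 1, 1]] * n_per
        pset = _pset(profiles)
        genes = [f"g{i}" for i in range(2 * n_per)]
        mapping = {g: f"o{i}" for i, g in enumerate(genes)}
        factors = {0: rng.normal(size=80), 1: rng.normal(size=80)}

        def maker(g, r, ns):
            block = 0 if int(g[1:]) < n_per else 1
            return 0.95 * factors[block] + 0.3 * r.normal(size=ns)

        expr = _expression_for(genes, 80, maker, seed=9)
        res = coexpression_vs_profile(expr, mapping, pset, n_genes=2 * n_per, seed=2)
        med = res.binned_medians.sort_values("bin_low")
        assert med["median_r_ge"].iloc[-1] > med["median_r_ge"].iloc[0]
        assert res.pearson_r > 0.5

    def test_too_few_eligible_is_error(self):
        pset = _pset([[1, 0]])
        expr = _expression_for(["gX"], 10, lambda g, r, n: r.normal(size=n))
        with pytest.raises(ValidationError):
            coexpression_vs_profile(expr, {}, pset, n_genes=5)


class TestPPIComparison:
    def test_single_interacting_pair_medians(self):
        # o0/o1 identical profiles (d_PP=1); o2, o3 disjoint from everything
        pset = _pset([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        mapping = {f"g{i}": f"o{i}" for i in range(4)}
        ppi = PPITable(pairs=[("g0", "g1")], evidence=["experimental"])
        comp = ppi_profile_comparison(ppi, mapping, pset)
        assert comp.median_interacting == 1.0
        assert comp.median_non_interacting == 0.0
        assert comp.n_non_interacting == 6 - 1

    def test_background_count_identity(self):
        rng = np.random.default_rng(0)
        pset = _pset(rng.integers(0, 2, size=(10, 5)) | np.eye(10, 5, dtype=int))
        mapping = {f"g{i}": f"o{i}" for i in range(10)}
        ppi = PPITable(
            pairs=[("g0", "g1"), ("g2", "g3")], evidence=["experimental"] * 2
        )
        comp = ppi_profile_comparison(ppi, mapping, pset)
        assert comp.n_non_interacting == 10 * 9 // 2 - comp.n_interacting

    def test_predicted_evidence_excluded_by_default(self):
        pset = _pset([[1, 0], [1, 0], [0, 1]])
        mapping = {f"g{i}": f"o{i}" for i in range(3)}
        ppi = PPITable(
            pairs=[("g0", "g1"), ("g0", "g2")],
            evidence=["experimental", "predicted"],
        )
        comp = ppi_profile_comparison(ppi, mapping, pset)
        assert comp.n_interacting == 1

    def test_pair_listing_order_invariant(self):
        rng = np.random.default_rng(1)
        pset = _pset(rng.integers(0, 2, size=(8, 4)) | np.eye(8, 4, dtype=int))
        mapping = {f"g{i}": f"o{i}" for i in range(8)}
        pairs = [("g0", "g3"), ("g1", "g2"), ("g4", "g5")]
        c1 = ppi_profile_comparison(
            PPITable(pairs=pairs, evidence=["experimental"] * 3), mapping, pset
        )
        c2 = ppi_profile_comparison(
            PPITable(pairs=pairs[::-1], evidence=["experimental"] * 3), mapping, pset
        )
        assert c1.median_interacting == c2.median_interacting
        assert c1.wilcoxon_p == c2.wilcoxon_p

    def test_no_mappable_pair_is_error(self):
        pset = _pset([[1, 0], [0, 1]])
        ppi = PPITable(pairs=[("x", "y")], evidence=["experimental"])
        with pytest.raises(ValidationError):
            ppi_profile_comparison(ppi, {"g0": "o0"}, pset)

    def test_planted_logistic_interactions_significant(self):
        # interaction probability logistic in d_PP with slope 6
        rng = np.random.default_rng(6)
        n = 120
        rows = rng.integers(0, 2, size=(n, 12))
        rows[rows.sum(axis=1) == 0, 0] = 1
        pset = _pset(rows)
        mapping = {f"g{i}": f"o{i}" for i in range(n)}
        from phyloprof.similarity import pairwise_similarity_matrix

        sim = pairwise_similarity_matrix(rows)
        pairs, evidence = [], []
        for i in range(n):
            for j in range(i + 1, n):
                p = 1 / (1 + np.exp(-6 * (sim[i, j] - 0.5)))
                if rng.random() < p * 0.15:
                    pairs.append((f"g{i}", f"g{j}"))
                    evidence.append("experimental")
        comp = ppi_profile_comparison(
            PPITable(pairs=pairs, evidence=evidence), mapping, pset
        )
        assert comp.median_interacting > comp.median_non_interacting
        assert comp.wilcoxon_p < 0.01
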