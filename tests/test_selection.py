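"""Operon ASE-similarity test and the gene-set sign test."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from hybrase import PipelineConfig, chi2_goodness, select_biased
from hybrase.ase import FAVORS_FIRST, FAVORS_SECOND
from hybrase.selection import (NON_OPERON, WITHIN_OPERON, OperonSimilarityTest,
                               SignTest, adjacent_gene_pairs)
from hybrase.data import CHROMOSOME, OrthologUnit, UnitLocus

from _oracles import signtest_exact_minp


class TestChi2Goodness:
    def test_perfect_balance_is_zero(self):
        chi2, p = chi2_goodness(10, 20)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_published_balance_example(self):
        # 453 vs 476 significant calls favoring either lineage
        chi2, p = chi2_goodness(453, 929)
        assert chi2 == pytest.approx(0.569, abs=5e-4)
        assert p == pytest.approx(0.451, abs=5e-3)

    def test_fifteen_of_nineteen(self):
        chi2, _ = chi2_goodness(15, 19)
        assert chi2 == pytest.approx(2 * 5.5**2 / 9.5)

    @pytest.mark.parametrize("k,n", [(0, 7), (3, 11), (15, 19), (453, 929)])
    def test_symmetric_in_label_swap_and_matches_scipy(self, k, n):
        a = chi2_goodness(k, n)
        b = chi2_goodness(n - k, n)
        assert a == b
        stat, p = scipy.stats.chisquare([k, n - k])
        assert a[0] == pytest.approx(stat)
        assert a[1] == pytest.approx(p)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chi2_goodness(5, 0)
        with pytest.raises(ValueError):
            chi2_goodness(8, 7)


def make_gene_row(oid, start, end, operon=None, members=None, coords=None):
    loci = {sp: UnitLocus(f"{sp}_chr", CHROMOSOME, start, end, "+",
                          member_coords=list(coords) if coords else None)
            for sp in ("v", "m")}
    if operon:
        return OrthologUnit(oid, "operon", members, loci)
    return OrthologUnit(oid, "gene", [oid], loci)


class TestAdjacency:
    def test_categories_and_skipped_mixed_pairs(self):
        units = [
            make_gene_row("g1", 0, 100),
            make_gene_row("g2", 120, 200),
            make_gene_row("op1", 220, 400, operon=True, members=["a", "b"],
                          coords=[(220, 300), (310, 400)]),
            make_gene_row("g3", 420, 500),
        ]
        pairs = adjacent_gene_pairs(units, "v")
        cats = {(r.gene_a, r.gene_b): r.category for r in pairs.itertuples()}
        assert cats[("g1", "g2")] == NON_OPERON
        assert cats[("a", "b")] == WITHIN_OPERON
        # g2-a and b-g3 straddle an operon boundary: dropped
        assert ("g2", "a") not in cats and ("b", "g3") not in cats


class TestOperonSimilarityTest:
    def _fit(self, within_vals, non_vals, rng_seed=0, n_samples=400, n_perm=400):
        genes, ratios, units, pos = [], {}, [], 0
        rows = []
        for i, (x, y) in enumerate(within_vals):
            a, b = f"op{i}.g1", f"op{i}.g2"
            ratios[a], ratios[b] = x, y
            rows.append((a, b, WITHIN_OPERON))
        for i, (x, y) in enumerate(non_vals):
            a, b = f"s{i}a", f"s{i}b"
            ratios[a], ratios[b] = x, y
            rows.append((a, b, NON_OPERON))
        pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "category"])
        series = pd.Series(ratios)
        cfg = PipelineConfig(rng_seed=rng_seed)
        test = OperonSimilarityTest({1: series}, pairs, cfg)
        return test.fit(n_samples=n_samples, n_permutations=n_perm).results.iloc[0]

    def test_complete_separation_gives_minimal_p(self):
        # within deltas all 0, non-operon deltas all 1
        within = [(0.5, 0.5)] * 4
        non = [(0.0, 1.0), (1.0, 2.0), (-1.0, 0.0), (2.0, 3.0)]
        r = self._fit(within, non)
        assert r.median_delta_within == 0.0
        assert r.median_delta_non == 1.0
        assert r.perm_p == pytest.approx(1 / 401, abs=1e-9)

    def test_identical_distributions_give_uniform_p(self):
        # same pair pool in both categories: p should be ~Uniform(0,1)
        rng = np.random.default_rng(0)
        ps = []
        for seed in range(40):
            vals = [(a, b) for a, b in rng.normal(size=(6, 2))]
            ps.append(self._fit(vals, list(vals), rng_seed=seed,
                                n_samples=150, n_perm=150).perm_p)
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_h_statistic_matches_scipy_kruskal(self):
        within = [(0.1, 0.15), (0.2, 0.3), (0.0, 0.05)]
        non = [(0.0, 1.0), (0.5, 2.0), (1.0, 0.2)]
        rng_seed = 5
        genes = {}
        rows = []
        for i, (x, y) in enumerate(within):
            genes[f"w{i}a"], genes[f"w{i}b"] = x, y
            rows.append((f"w{i}a", f"w{i}b", WITHIN_OPERON))
        for i, (x, y) in enumerate(non):
            genes[f"n{i}a"], genes[f"n{i}b"] = x, y
            rows.append((f"n{i}a", f"n{i}b", NON_OPERON))
        pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "category"])
        cfg = PipelineConfig(rng_seed=rng_seed)
        test = OperonSimilarityTest({1: pd.Series(genes)}, pairs, cfg)
        # reproduce the sampled deltas with the same stage stream
        from hybrase.config import stage_rng
        rng = stage_rng(cfg.rng_seed, "operon-test")
        deltas = {}
        for cat in (WITHIN_OPERON, NON_OPERON):
            sub = pairs[pairs["category"] == cat]
            idx = rng.integers(0, len(sub), size=200)
            a = pd.Series(genes)[sub["gene_a"].to_numpy()[idx]].to_numpy()
            b = pd.Series(genes)[sub["gene_b"].to_numpy()[idx]].to_numpy()
            deltas[cat] = np.abs(a - b)
        expected_h = scipy.stats.kruskal(deltas[WITHIN_OPERON],
                                         deltas[NON_OPERON]).statistic
        r = test.fit(n_samples=200, n_permutations=50).results.iloc[0]
        assert r.kruskal_h == pytest.approx(expected_h)

    def test_category_without_pairs_rejected(self):
        pairs = pd.DataFrame([("a", "b", NON_OPERON), ("a", "b", NON_OPERON)],
                             columns=["gene_a", "gene_b", "category"])
        with pytest.raises(ValueError, match=WITHIN_OPERON):
            OperonSimilarityTest({1: pd.Series({"a": 0.0, "b": 1.0})}, pairs)


class TestSelectBiased:
    def _calls(self):
        return pd.DataFrame({
            "ortholog_id": ["a", "b", "c", "d", "e"],
            "ratio_rep1": [2.0, -1.5, 1.0, 0.5, 3.0],
            "ratio_rep2": [2.0, -1.5, 1.0, 0.5, 3.0],
            "direction": [FAVORS_FIRST, FAVORS_SECOND, FAVORS_FIRST,
                          FAVORS_FIRST, FAVORS_FIRST],
            "significant": [True, True, True, True, False],
        })

    def test_top50_keeps_floor_half_by_magnitude(self):
        out = select_biased(self._calls(), "top50")
        assert list(out["ortholog_id"]) == ["a", "b"]

    def test_all_keeps_every_significant(self):
        out = select_biased(self._calls(), "all")
        assert list(out["ortholog_id"]) == ["a", "b", "c", "d"]
        assert "e" not in set(out["ortholog_id"])

    def test_ties_break_lexicographically(self):
        calls = self._calls()
        calls.loc[:, "ratio_rep1"] = 1.0
        calls.loc[:, "ratio_rep2"] = 1.0
        out = select_biased(calls, "all")
        assert list(out["ortholog_id"]) == ["a", "b", "c", "d"]


class TestSignTest:
    def _biased(self, directions):
        return pd.DataFrame({
            "ortholog_id": [f"og{i}" for i in range(len(directions))],
            "direction": directions,
            "abs_ratio": np.linspace(2, 1, len(directions)),
        })

    def _catalog(self, members_by_cat):
        rows = [(c, m) for c, ms in members_by_cat.items() for m in ms]
        return pd.DataFrame(rows, columns=["category_id", "ortholog_id"])

    def test_direction_counts_and_chi2(self):
        directions = [FAVORS_SECOND] * 15 + [FAVORS_FIRST] * 4 + [FAVORS_SECOND]
        biased = self._biased(directions)
        catalog = self._catalog({"kinase": [f"og{i}" for i in range(19)]})
        st = SignTest(biased, catalog, min_size=10,
                      config=PipelineConfig(rng_seed=1))
        res = st.fit(n_permutations=200).results
        row = res.iloc[0]
        assert (row.n, row.k) == (19, 15)
        assert row.chi2 == pytest.approx(2 * 5.5**2 / 9.5)

    def test_small_category_skipped(self):
        biased = self._biased([FAVORS_SECOND] * 12)
        catalog = self._catalog({"tiny": ["og0", "og1"]})
        st = SignTest(biased, catalog, min_size=10, config=PipelineConfig(rng_seed=1))
        assert st.fit(n_permutations=50).results.empty

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SignTest(self._biased([FAVORS_FIRST] * 4),
                     pd.DataFrame(columns=["category_id", "ortholog_id"]))

    def test_perm_p_matches_exact_enumeration(self):
        """Max-statistic permutation null vs. exhaustive label placement."""
        rng = np.random.default_rng(7)
        n, k_true = 12, 6
        labels = np.zeros(n, dtype=bool)
        labels[:k_true] = True
        labels = rng.permutation(labels)
        directions = [FAVORS_SECOND if x else FAVORS_FIRST for x in labels]
        biased = self._biased(directions)
        cats = {"c1": [f"og{i}" for i in range(8)],
                "c2": [f"og{i}" for i in range(4, 12)],
                "c3": [f"og{i}" for i in (0, 2, 4, 6, 8, 10, 1, 3)]}
        catalog = self._catalog(cats)
        st = SignTest(biased, catalog, min_size=8,
                      config=PipelineConfig(rng_seed=3))
        res = st.fit(n_permutations=4000).results.set_index("category_id")
        idx_by_cat = [np.array([int(m[2:]) for m in ms]) for ms in cats.values()]
        exact, obs_p = signtest_exact_minp(
            idx_by_cat, int(labels.sum()), labels,
            lambda k, nn: chi2_goodness(k, nn)[1])
        for (cat, idx), prob in zip(cats.items(), exact):
            expected = prob  # P(min nominal p <= observed p) under the null
            got = res.loc[cat, "perm_p"]
            se = np.sqrt(expected * (1 - expected) / 4000) + 1e-4
            assert got == pytest.approx((1 + 4000 * expected) / 4001, abs=5 * se)

    def test_null_calibration_super_uniform(self):
        """Under random directions the adjusted p is super-uniform."""
        rng = np.random.default_rng(11)
        hits_10 = 0
        n_runs = 120
        for run in range(n_runs):
            directions = [FAVORS_SECOND if rng.random() < 0.5 else FAVORS_FIRST
                          for _ in range(40)]
            biased = self._biased(directions)
            cats = {f"c{j}": [f"og{i}" for i in rng.choice(40, 12, replace=False)]
                    for j in range(4)}
            st = SignTest(biased, self._catalog(cats), min_size=10,
                          config=PipelineConfig(rng_seed=run))
            res = st.fit(n_permutations=150).results
            hits_10 += int((res["perm_p"] <= 0.1).any())
        # P(any category <= 0.1) <= 0.1 by the max-statistic construction
        # (familywise); allow 3 binomial SEs of slack
        se = np.sqrt(0.1 * 0.9 / n_runs)
        assert hits_10 / n_runs <= 0.1 + 3 * se
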