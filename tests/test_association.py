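import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zincsig import association as assoc
from zincsig.datasets_io import ExpressionDataset, GeneSetCollection


def _dataset(values, ds_id="D", log_scale=True):
    genes = [f"G{i:03d}" for i in range(values.shape[0])]
    samples = [f"{ds_id}s{j:02d}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=genes, columns=samples)
    half = len(samples) // 2
    groups = pd.Series(["disease"] * half + ["healthy"] * (len(samples) - half),
                       index=samples)
    return ExpressionDataset(dataset_id=ds_id, platform="intensity",
                             values=frame, groups=groups, log_scale=log_scale)


class TestMergeBatches:
    def test_constant_shift_removed(self):
        rng = np.random.default_rng(0)
        base = rng.normal(8, 1, size=(120, 10))
        d1 = _dataset(base, "B1")
        d2 = _dataset(base + 2.5, "B2")  # pure location batch effect
        merged = assoc.merge_batches([d1, d2], min_common_genes=100)
        arr = merged.values
        b = merged.batch
        for ds_id in ("B1", "B2"):
            cols = b.index[b == ds_id]
            means = arr[cols].mean(axis=1)
            # per-gene batch means agree with the pooled mean
            pooled = arr.mean(axis=1)
            assert np.allclose(means, pooled, atol=1e-8)

    def test_batch_mean_differences_vanish(self):
        rng = np.random.default_rng(1)
        d1 = _dataset(rng.normal(8, 1, size=(150, 8)), "B1")
        d2 = _dataset(rng.normal(6, 2, size=(150, 8)), "B2")
        merged = assoc.merge_batches([d1, d2], min_common_genes=100)
        b = merged.batch
        m1 = merged.values[b.index[b == "B1"]].mean(axis=1)
        m2 = merged.values[b.index[b == "B2"]].mean(axis=1)
        assert np.abs(m1 - m2).max() <= 1e-8

    def test_constant_gene_in_one_batch_location_only(self):
        rng = np.random.default_rng(2)
        v1 = rng.normal(8, 1, size=(120, 6))
        v1[0] = 5.0  # constant within batch 1
        d1 = _dataset(v1, "B1")
        d2 = _dataset(rng.normal(8, 1, size=(120, 6)), "B2")
        merged = assoc.merge_batches([d1, d2], min_common_genes=100)
        assert np.isfinite(merged.values.to_numpy()).all()

    def test_single_dataset_is_quantile_normalized_input(self):
        rng = np.random.default_rng(3)
        d1 = _dataset(rng.normal(size=(120, 6)), "B1")
        from zincsig.diffexpr import quantile_normalize
        merged = assoc.merge_batches([d1], min_common_genes=100)
        assert np.allclose(merged.values.to_numpy(),
                           quantile_normalize(d1.values).to_numpy())

    def test_too_few_common_genes_errors(self):
        d1 = _dataset(np.ones((10, 6)) + np.arange(6), "B1")
        d2 = _dataset(np.ones((10, 6)) + np.arange(6), "B2")
        with pytest.raises(ValueError, match="shared"):
            assoc.merge_batches([d1, d2], min_common_genes=100)


class TestGenomewideCorrelation:
    def test_score_itself_ranks_first(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(50, 20))
        ds = _dataset(vals, "D")
        scores = pd.Series(vals[7], index=ds.samples)  # gene G007 == score
        rk = assoc.correlate_score_genomewide(ds, scores)
        assert rk.table.loc["G007", "r"] == pytest.approx(1.0)
        assert rk.table.loc["G007", "rank"] == 1

    def test_anti_score_ranks_last(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(50, 20))
        vals[3] = -vals[7]
        ds = _dataset(vals, "D")
        scores = pd.Series(vals[7], index=ds.samples)
        rk = assoc.correlate_score_genomewide(ds, scores)
        assert rk.table.loc["G003", "r"] == pytest.approx(-1.0)
        assert rk.table.loc["G003", "rank"] == 50

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(20, 15))
        ds = _dataset(vals, "D")
        scores = pd.Series(rng.normal(size=15), index=ds.samples)
        rk = assoc.correlate_score_genomewide(ds, scores)
        for i, g in enumerate(ds.genes):
            r_ref, p_ref = stats.pearsonr(scores.values, vals[i])
            assert rk.table.loc[g, "r"] == pytest.approx(r_ref, abs=1e-10)
            assert rk.table.loc[g, "p"] == pytest.approx(p_ref, abs=1e-10)

    def test_independent_gene_bounded_correlation(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=(2, 200))
            ds = _dataset(vals, "D")
            scores = pd.Series(rng.normal(size=200), index=ds.samples)
            rk = assoc.correlate_score_genomewide(ds, scores)
            if abs(rk.table["r"].iloc[0]) < 0.2:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_zero_variance_gene_reported_missing(self):
        vals = np.random.default_rng(7).normal(size=(5, 10))
        vals[2] = 3.14
        ds = _dataset(vals, "D")
        scores = pd.Series(vals[0], index=ds.samples)
        rk = assoc.correlate_score_genomewide(ds, scores)
        assert np.isnan(rk.table.loc["G002", "r"])
        assert np.isnan(rk.table.loc["G002", "rank"])


def _ranking_from_r(r_by_gene, ds_id="R"):
    genes = sorted(r_by_gene, key=lambda g: (-r_by_gene[g], g))
    table = pd.DataFrame({
        "r": [r_by_gene[g] for g in genes],
        "p": 0.5,
        "rank": np.arange(1, len(genes) + 1),
    }, index=genes)
    return assoc.CorrelationRanking(dataset_id=ds_id, table=table)


class TestCrossDatasetTop:
    def test_identical_rankings_reproduce_top_k(self):
        rng = np.random.default_rng(8)
        rs = {f"G{i:03d}": float(rng.normal()) for i in range(100)}
        rk1 = _ranking_from_r(rs, "A")
        rk2 = _ranking_from_r(rs, "B")
        top = assoc.cross_dataset_top([rk1, rk2], k=10)
        assert list(top["gene"]) == rk1.ranked_genes()[:10]

    def test_mean_rank_matches_brute_force(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i:02d}" for i in range(30)]
        rankings = []
        for d in range(3):
            rs = {g: float(rng.normal()) for g in genes}
            rankings.append(_ranking_from_r(rs, f"D{d}"))
        top = assoc.cross_dataset_top(rankings, k=30)
        brute = {}
        for g in genes:
            brute[g] = np.mean([float(rk.table.loc[g, "rank"]) for rk in rankings])
        expect = sorted(genes, key=lambda g: (brute[g], g))
        assert list(top["gene"]) == expect

    def test_k_truncated_with_warning(self):
        rs = {f"G{i}": float(i) for i in range(5)}
        top = assoc.cross_dataset_top([_ranking_from_r(rs, "A"),
                                       _ranking_from_r(rs, "B")], k=50)
        assert len(top) == 5

    def test_exclude_removes_signature_genes(self):
        rs = {f"G{i:02d}": float(-i) for i in range(10)}
        top = assoc.cross_dataset_top([_ranking_from_r(rs, "A"),
                                       _ranking_from_r(rs, "B")],
                                      k=10, exclude=["G00", "G01"])
        assert "G00" not in set(top["gene"]) and "G01" not in set(top["gene"])


class TestPrerankedGsea:
    def _four_gene_ranking(self):
        return _ranking_from_r({"A": 0.9, "B": 0.8, "C": -0.1, "D": -0.7})

    def test_top_set_unweighted_es_one(self):
        rk = self._four_gene_ranking()
        sets = GeneSetCollection(sets={"TOP": ("d", ["A", "B"])})
        res = assoc.preranked_gsea(rk, sets, weight_p=0.0, n_perm=0, min_size=2)
        # walk: +1/2, +1/2 before any miss -> ES = 1.0
        assert res[0].es == pytest.approx(1.0, abs=1e-12)

    def test_bottom_set_unweighted_es_minus_one(self):
        rk = self._four_gene_ranking()
        sets = GeneSetCollection(sets={"BOT": ("d", ["C", "D"])})
        res = assoc.preranked_gsea(rk, sets, weight_p=0.0, n_perm=0, min_size=2)
        # misses first: -1/2, -1/2 at the same boundary -> ES = -1.0
        assert res[0].es == pytest.approx(-1.0, abs=1e-12)

    def test_es_invariant_under_monotone_transform_when_unweighted(self):
        rng = np.random.default_rng(10)
        rs = {f"G{i:03d}": float(rng.normal()) for i in range(100)}
        rk1 = _ranking_from_r(rs)
        rs2 = {g: float(np.tanh(3 * v) + 5) for g, v in rs.items()}  # monotone
        rk2 = _ranking_from_r(rs2)
        members = list(rs)[:20]
        sets = GeneSetCollection(sets={"S": ("d", members)})
        e1 = assoc.preranked_gsea(rk1, sets, weight_p=0.0, n_perm=0)
        e2 = assoc.preranked_gsea(rk2, sets, weight_p=0.0, n_perm=0)
        assert e1[0].es == pytest.approx(e2[0].es, abs=1e-12)

    def test_fixed_seed_bit_reproducible(self):
        rng = np.random.default_rng(11)
        rs = {f"G{i:03d}": float(rng.normal()) for i in range(200)}
        rk = _ranking_from_r(rs)
        sets = GeneSetCollection(sets={"S": ("d", list(rs)[:25])})
        r1 = assoc.preranked_gsea(rk, sets, n_perm=200, seed=42)
        r2 = assoc.preranked_gsea(rk, sets, n_perm=200, seed=42)
        assert (r1[0].es, r1[0].nes, r1[0].p_perm) == (r2[0].es, r2[0].nes, r2[0].p_perm)

    def test_sign_consistency_and_p_range(self):
        rng = np.random.default_rng(12)
        rs = {f"G{i:03d}": float(rng.normal()) for i in range(300)}
        rk = _ranking_from_r(rs)
        sets = GeneSetCollection(sets={
            f"S{j}": ("d", list(rng.choice(sorted(rs), 20, replace=False)))
            for j in range(5)})
        for e in assoc.preranked_gsea(rk, sets, n_perm=100, seed=0):
            assert 0 < e.p_perm <= 1
            if e.nes is not None and not np.isnan(e.nes):
                assert np.sign(e.nes) == np.sign(e.es)

    def test_n_perm_zero_gives_es_only(self):
        rk = self._four_gene_ranking()
        sets = GeneSetCollection(sets={"TOP": ("d", ["A", "B"])})
        res = assoc.preranked_gsea(rk, sets, n_perm=0, min_size=2)
        assert res[0].nes is None and res[0].p_perm is None

    def test_small_set_skipped(self):
        rk = self._four_gene_ranking()
        sets = GeneSetCollection(sets={"TINY": ("d", ["A"])})
        assert assoc.preranked_gsea(rk, sets, n_perm=0) == []

    def test_es_matches_independent_reference_implementation(self):
        """Weighted walking-sum ES agrees with the gseapy pre-ranked
        implementation on the same list and set."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(21)
        genes = [f"G{i:03d}" for i in range(200)]
        r = np.sort(rng.normal(size=200))[::-1]
        members = list(rng.choice(genes, 25, replace=False))
        rnk = pd.DataFrame({"gene": genes, "score": r})
        ref = gseapy.prerank(rnk=rnk, gene_sets={"S": members},
                             permutation_num=4, no_plot=True, outdir=None,
                             seed=1, min_size=5, max_size=100, weight=1.0)
        es_ref = float(ref.res2d["ES"].iloc[0])
        table = pd.DataFrame({"r": r, "p": 0.5,
                              "rank": np.arange(1, 201)}, index=genes)
        mine = assoc.preranked_gsea(
            assoc.CorrelationRanking("X", table),
            GeneSetCollection(sets={"S": ("d", members)}),
            weight_p=1.0, n_perm=0)
        assert mine[0].es == pytest.approx(es_ref, abs=1e-8)

    def test_null_pvalues_approximately_uniform(self):
        """Permutation p-values over random sets should not deviate from
        uniformity (KS at alpha=0.01)."""
        rng = np.random.default_rng(13)
        rs = {f"G{i:04d}": float(rng.normal()) for i in range(1000)}
        rk = _ranking_from_r(rs)
        names = sorted(rs)
        sets = GeneSetCollection(sets={
            f"S{j:03d}": ("d", list(rng.choice(names, 20, replace=False)))
            for j in range(200)})
        res = assoc.preranked_gsea(rk, sets, n_perm=500, seed=7)
        pvals = np.array([e.p_perm for e in res])
        stat = stats.kstest(pvals, "uniform").statistic
        crit = 1.63 / np.sqrt(len(pvals))  # alpha = 0.01
        assert stat < crit
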