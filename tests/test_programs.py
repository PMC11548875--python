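import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from icipipe import programs, qc
from icipipe.config import DegThresholds, NmfParams, PcaSigParams
from icipipe.programs import GeneSignature


def _norm(values, genes=None):
    v = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(v.shape[0])]
    return qc.NormalizedMatrix(v, pd.Index(genes), pd.RangeIndex(v.shape[1]))


def _exact_ranksum_p(a, b):
    """Brute-force two-tailed rank-sum p by enumerating all group splits."""
    pooled = np.r_[a, b]
    n = len(a)
    ranks = scipy.stats.rankdata(pooled)
    obs = ranks[:n].sum()
    mean = ranks.sum() * n / len(pooled)
    stats = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    stats = np.array(stats)
    return (np.abs(stats - mean) >= abs(obs - mean) - 1e-12).mean()


class TestWilcoxonDeg:
    def test_exact_p_matches_enumeration(self):
        # A=[1,2,3] vs B=[4,5,6]: exact two-tailed p = 2/20 = 0.1
        counts = np.tile([1, 2, 3, 4, 5, 6], (2, 1))
        vals = counts.astype(float)
        norm = _norm(vals)
        table = programs.wilcoxon_deg(
            norm, counts, np.arange(3), np.arange(3, 6),
            DegThresholds(min_pct=0.01),
        )
        assert table["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)
        assert table["p"].iloc[0] == pytest.approx(
            _exact_ranksum_p([1, 2, 3], [4, 5, 6]), abs=1e-12
        )

    def test_identical_groups_filtered_out(self, rng):
        counts = rng.integers(1, 10, (5, 20))
        counts[:, 10:] = counts[:, :10]
        norm = _norm(counts)
        t = programs.wilcoxon_deg(norm, counts, np.arange(10), np.arange(10, 20))
        assert not t["tested"].any()

    def test_group_overlap_and_small_groups_error(self, rng):
        counts = rng.integers(0, 5, (4, 10))
        norm = _norm(counts)
        with pytest.raises(ValueError, match="overlap"):
            programs.wilcoxon_deg(norm, counts, np.arange(5), np.arange(4, 10))
        with pytest.raises(ValueError, match="3 cells"):
            programs.wilcoxon_deg(norm, counts, np.arange(2), np.arange(5, 10))

    def test_swapping_groups_negates_logfc_and_swaps_sets(self, rng):
        counts = rng.poisson(4.0, (40, 60))
        counts[:5, :30] = rng.poisson(14.0, (5, 30))
        norm = _norm(np.log1p(counts))
        a = programs.wilcoxon_deg(norm, counts, np.arange(30), np.arange(30, 60))
        b = programs.wilcoxon_deg(norm, counts, np.arange(30, 60), np.arange(30))
        np.testing.assert_allclose(a["logfc"], -b["logfc"], atol=1e-12)
        up_a, down_a = programs.deg_sets(a)
        up_b, down_b = programs.deg_sets(b)
        assert up_a == down_b and down_a == up_b

    def test_planted_degs_recovered_without_false_positives(self):
        # 50 planted x2 genes among 2000, 200 vs 200 cells, 10 seeds
        n_genes, n_cells = 2000, 200
        total_fp = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            mu = np.full((n_genes, 1), 5.0)
            mu_b = mu.copy()
            mu_b[:50] *= 2.0
            shape = 1.0 / 0.05
            a = rng.poisson(rng.gamma(shape, mu * 0.05, (n_genes, n_cells)))
            b = rng.poisson(rng.gamma(shape, mu_b * 0.05, (n_genes, n_cells)))
            counts = np.hstack([b, a])  # group A = planted-up cells
            norm = _norm(np.log1p(counts / counts.sum(0) * 1e4))
            t = programs.wilcoxon_deg(
                norm, counts, np.arange(n_cells), np.arange(n_cells, 2 * n_cells)
            )
            up, down = programs.deg_sets(t)
            planted = {f"g{i}" for i in range(50)}
            assert len(up & planted) >= 45
            total_fp += len((up | down) - planted)
        assert total_fp == 0


class TestIntUnion:
    def _table(self, up, down):
        genes = sorted(up | down)
        return pd.DataFrame(
            {"logfc": [1.0 if g in up else -1.0 for g in genes],
             "pass_filter": True},
            index=pd.Index(genes, name="gene"),
        )

    def test_set_algebra(self):
        tables = [
            self._table({"a", "b"}, set()),
            self._table({"b", "c"}, set()),
            self._table({"b"}, set()),
        ]
        with pytest.warns(UserWarning):  # empty INT.down
            out = programs.build_int_union(tables)
        assert set(out["INT.up"].genes) == {"b"}
        assert set(out["UNION.up"].genes) == {"a", "b", "c"}

    def test_identical_tables_make_int_equal_union(self):
        t = self._table({"x", "y"}, {"z"})
        out = programs.build_int_union([t, t.copy(), t.copy()])
        assert set(out["INT.up"].genes) == set(out["UNION.up"].genes)
        assert set(out["INT.down"].genes) == set(out["UNION.down"].genes) == {"z"}

    def test_matches_bruteforce_set_oracle(self, rng):
        universe = [f"g{i}" for i in range(30)]
        ups, downs, tables = [], [], []
        for _ in range(3):
            up = set(rng.choice(universe, 8, replace=False))
            down = set(rng.choice(sorted(set(universe) - up), 5, replace=False))
            ups.append(up)
            downs.append(down)
            tables.append(self._table(up, down))
        out = programs.build_int_union(tables)
        assert set(out["UNION.up"].genes) == ups[0] | ups[1] | ups[2]
        assert set(out["UNION.down"].genes) == downs[0] | downs[1] | downs[2]
        int_up = ups[0] & ups[1] & ups[2]
        if int_up:
            assert set(out["INT.up"].genes) == int_up

    def test_fewer_than_three_tables_error(self):
        with pytest.raises(ValueError, match="three"):
            programs.build_int_union([self._table({"a"}, set())])


class TestNmf:
    def test_exact_rank_one_matrix_recovered(self, rng):
        u = rng.random(30) + 0.1
        v = rng.random(20) + 0.1
        model = programs.fit_nmf(np.outer(u, v), NmfParams(rank=1, max_iter=500, tol=0))
        assert model.errors[-1] < 1e-6

    def test_error_sequence_monotone_nonincreasing(self, rng):
        V = rng.random((40, 25))
        model = programs.fit_nmf(V, NmfParams(rank=5, max_iter=60, tol=0))
        diffs = np.diff(model.errors)
        assert (diffs <= 1e-12).all()
        assert (model.W >= 0).all() and (model.H >= 0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            programs.fit_nmf(np.array([[1.0, -1.0]]))

    def test_reconstruction_quality_matches_reference_nmf(self, rng):
        # independent cross-check: the multiplicative-update fit reaches a
        # reconstruction error comparable to sklearn's NMF on the same data
        from sklearn.decomposition import NMF as SkNMF

        V = rng.poisson(3.0, (60, 40)).astype(float)
        mine = programs.fit_nmf(V, NmfParams(rank=5, max_iter=400, tol=1e-7), seed=0)
        sk = SkNMF(n_components=5, solver="mu", init="random", random_state=0,
                   max_iter=400, tol=1e-7)
        W = sk.fit_transform(V)
        ref_err = np.linalg.norm(V - W @ sk.components_) / np.linalg.norm(V)
        assert mine.errors[-1] <= ref_err * 1.05

    def test_planted_block_structure_recovered(self, rng):
        blocks = np.zeros((80, 60))
        for k in range(4):
            blocks[k * 20 : (k + 1) * 20, k * 15 : (k + 1) * 15] = 5.0
        V = rng.poisson(blocks + 0.1)
        model = programs.fit_nmf(V, NmfParams(rank=4, max_iter=300), seed=1)
        for k in range(4):
            target = (blocks[:, k * 15] > 0).astype(float)
            cos = max(
                np.dot(model.W[:, f], target)
                / (np.linalg.norm(model.W[:, f]) * np.linalg.norm(target) + 1e-12)
                for f in range(4)
            )
            assert cos >= 0.9


class TestPrograms:
    def _model(self, W, H, genes=None):
        return programs.NmfModel(
            W=np.asarray(W, float), H=np.asarray(H, float), errors=[0.0],
            gene_ids=pd.Index(genes or [f"g{i}" for i in range(np.shape(W)[0])]),
            cell_barcodes=pd.RangeIndex(np.shape(H)[1]),
        )

    def test_uniform_loadings_assign_nothing(self):
        model = self._model(np.ones((10, 3)), np.ones((3, 9)))
        groups = np.repeat(["PR", "SD", "PD"], 3)
        shares, sigs = programs.derive_nmf_programs(model, groups)
        assert (shares["assigned_group"] == "").all()
        assert not sigs
        np.testing.assert_allclose(
            shares[["PD", "PR", "SD"]].sum(axis=1), 1.0, atol=1e-9
        )

    def test_group_exclusive_factor_assigned(self):
        H = np.zeros((2, 9))
        H[0, :3] = 5.0  # loads only on PR cells
        H[1] = 1.0
        model = self._model(np.ones((10, 2)), H)
        groups = np.repeat(["PR", "SD", "PD"], 3)
        shares, sigs = programs.derive_nmf_programs(model, groups)
        row = shares.loc[shares["assigned_group"] == "PR"]
        assert len(row) == 1 and row["PR"].iloc[0] == pytest.approx(1.0)
        assert "NMF.PR" in sigs

    def test_empty_group_is_error(self):
        model = self._model(np.ones((4, 2)), np.ones((2, 4)))
        labels = pd.Series(["PR"] * 2 + ["SD"] * 2).map({"PR": "PR", "SD": None})
        with pytest.raises(ValueError, match="no cells"):
            programs.derive_nmf_programs(model, labels)


class TestModules:
    def test_descending_coefficients_take_first_n(self):
        coefs = pd.Series(
            np.arange(200, 0, -1, dtype=float), index=[f"g{i}" for i in range(200)]
        )
        out = programs.refine_top_gene_modules({"m1": coefs}, {"m1": "PR"}, top_n=100)
        assert set(out["module.PR"].genes) == {f"g{i}" for i in range(100)}

    def test_identical_modules_union_is_either(self):
        coefs = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="only"):
            out = programs.refine_top_gene_modules(
                {"m1": coefs, "m2": coefs.copy()}, {"m1": "PD", "m2": "PD"}, top_n=100
            )
        assert set(out["module.PD"].genes) == {"a", "b", "c"}

    def test_matches_sort_oracle(self, rng):
        coefs = pd.Series(rng.random(300), index=[f"g{i}" for i in range(300)])
        out = programs.refine_top_gene_modules({"m": coefs}, {"m": "SD"}, top_n=50)
        oracle = set(coefs.sort_values(ascending=False).index[:50])
        assert set(out["module.SD"].genes) == oracle


class TestFisher:
    def test_corrected_or_on_degenerate_table(self):
        oratio, p = programs.fisher_odds_ratio([[10, 0], [0, 10]])
        assert oratio == pytest.approx(441.0)
        # exact hypergeometric tail: only the two extreme tables
        expected = 2 * scipy.stats.hypergeom.pmf(10, 20, 10, 10)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_balanced_table_is_null(self):
        oratio, p = programs.fisher_odds_ratio([[5, 5], [5, 5]])
        assert oratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_p_matches_hypergeom_tail_sum(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(0, 12, 4)
            table = np.array([[a, b], [c, d]])
            if table.sum() == 0:
                continue
            _, p = programs.fisher_odds_ratio(table)
            # brute-force two-sided Fisher: sum of all table probabilities
            # not exceeding the observed one (fixed margins)
            n, k1, k2 = table.sum(), a + b, a + c
            obs = scipy.stats.hypergeom.pmf(a, n, k1, k2)
            total = 0.0
            for x in range(max(0, k1 + k2 - n), min(k1, k2) + 1):
                px = scipy.stats.hypergeom.pmf(x, n, k1, k2)
                if px <= obs * (1 + 1e-7):
                    total += px
            assert p == pytest.approx(min(total, 1.0), abs=1e-10)

    def test_or_invariant_under_row_and_column_swap(self, rng):
        t = rng.integers(1, 20, (2, 2))
        a, _ = programs.fisher_odds_ratio(t)
        b, _ = programs.fisher_odds_ratio(t[::-1, ::-1])
        assert a == pytest.approx(b)


class TestEnrichment:
    def test_exclusive_programs_enriched(self):
        cells = pd.Index([f"c{i}" for i in range(60)])
        prog = pd.Series(np.repeat(["p1", "p2"], 30), index=cells)
        groups = np.repeat(["PR", "PD"], 30)
        out = programs.enrichment_odds_ratio(prog, groups)
        top = out.query("program=='p1' and group=='PR'")
        assert top["odds_ratio"].iloc[0] > 100
        assert out.query("program=='p1'")["z_or"].abs().max() > 0

    def test_single_group_is_error(self):
        prog = pd.Series(["p1", "p2"], index=["a", "b"])
        with pytest.raises(ValueError, match="two groups"):
            programs.enrichment_odds_ratio(prog, ["PR", "PR"])


class TestPcaSignatures:
    def _scaled(self, values, genes=None):
        v = np.asarray(values, float)
        return qc.ScaledMatrix(
            v, pd.Index(genes or [f"g{i}" for i in range(v.shape[0])]),
            pd.RangeIndex(v.shape[1]),
        )

    def test_planted_dominant_axis_recovered(self, rng):
        n_genes, n_cells = 200, 100
        axis = np.zeros(n_genes)
        axis[:30] = 1.0  # planted up-genes
        scores = rng.normal(0, 3, n_cells)
        v = np.outer(axis, scores) + rng.normal(0, 0.3, (n_genes, n_cells))
        sigs, _ = programs.pca_signatures(self._scaled(v), PcaSigParams(n_pcs=3))
        hits = len(set(sigs["PC1.pos"].genes) & {f"g{i}" for i in range(30)})
        assert hits >= 27

    def test_loadings_orthonormal(self, rng):
        v = rng.normal(0, 1, (80, 50))
        _, load = programs.pca_signatures(self._scaled(v), PcaSigParams(n_pcs=5))
        gram = load.T @ load
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_sign_convention_survives_cell_permutation(self, rng):
        v = rng.normal(0, 1, (80, 50)) + np.outer(
            rng.normal(0, 1, 80), rng.normal(0, 2, 50)
        )
        sigs_a, _ = programs.pca_signatures(self._scaled(v), PcaSigParams(n_pcs=2))
        perm = rng.permutation(50)
        sigs_b, _ = programs.pca_signatures(self._scaled(v[:, perm]), PcaSigParams(n_pcs=2))
        assert sigs_a["PC1.pos"].genes == sigs_b["PC1.pos"].genes
        assert sigs_a["PC1.neg"].genes == sigs_b["PC1.neg"].genes

    def test_too_few_genes_is_error(self, rng):
        with pytest.raises(ValueError, match="genes"):
            programs.pca_signatures(self._scaled(rng.normal(0, 1, (20, 30))))


class TestSampleScores:
    def test_single_sample_scores_one(self):
        norm = _norm([[1.0, 2.0], [3.0, 4.0]], genes=["a", "b"])
        sig = GeneSignature("s", ("a", "b"))
        out = programs.score_signature_per_sample(
            norm, sig, np.array([True, True]), np.array(["S1", "S1"])
        )
        assert out["S1"] == pytest.approx(1.0)

    def test_scale_invariance_of_max_normalization(self, rng):
        v = rng.random((5, 12)) + 0.1
        norm_a, norm_b = _norm(v), _norm(2.0 * v)
        sig = GeneSignature("s", ("g0", "g3"))
        samples = np.repeat(["S1", "S2", "S3"], 4)
        mask = np.ones(12, bool)
        a = programs.score_signature_per_sample(norm_a, sig, mask, samples)
        b = programs.score_signature_per_sample(norm_b, sig, mask, samples)
        pd.testing.assert_series_equal(a, b)

    def test_matches_bruteforce_double_loop(self, rng):
        v = rng.random((6, 9))
        norm = _norm(v)
        sig = GeneSignature("s", ("g1", "g4", "g5"))
        samples = np.repeat(["S1", "S2", "S3"], 3)
        mask = np.array([True, False, True] * 3)
        out = programs.score_signature_per_sample(norm, sig, mask, samples)
        raw = {}
        for s in ("S1", "S2", "S3"):
            cell_means = []
            for j in range(9):
                if samples[j] == s and mask[j]:
                    cell_means.append(np.mean([v[1, j], v[4, j], v[5, j]]))
            raw[s] = np.mean(cell_means)
        mx = max(raw.values())
        for s in raw:
            assert out[s] == pytest.approx(raw[s] / mx, abs=1e-12)

    def test_sample_without_malignant_cells_flagged(self, rng):
        v = rng.random((3, 4))
        norm = _norm(v)
        sig = GeneSignature("s", ("g0",))
        samples = np.array(["S1", "S1", "S2", "S2"])
        mask = np.array([True, True, False, False])
        with pytest.warns(UserWarning, match="without malignant"):
            out = programs.score_signature_per_sample(norm, sig, mask, samples)
        assert np.isnan(out["S2"]) and out["S1"] == pytest.approx(1.0)
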