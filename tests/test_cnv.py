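import numpy as np
import pandas as pd
import pytest

from icipipe import cnv, qc
from icipipe.cohort import GenePositionTable
from icipipe.config import CnvParams


def _positions(n, chrom="chr1"):
    return GenePositionTable(
        pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "chromosome": chrom,
             "start": np.arange(1, n + 1) * 100, "end": np.arange(1, n + 1) * 100 + 50}
        )
    )


class TestGenomicOrder:
    def test_sorted_by_chromosome_then_start(self):
        tab = pd.DataFrame(
            {"gene_id": ["b", "a", "c"], "chromosome": ["chr1", "chr1", "chr2"],
             "start": [200, 100, 50], "end": [250, 150, 90]}
        )
        pos = GenePositionTable(tab, chromosome_order=("chr1", "chr2"))
        order = cnv.build_genomic_order(pos, pd.Index(["a", "b", "c"]))
        assert list(order["gene_id"]) == ["a", "b", "c"]

    def test_gene_without_position_dropped(self):
        pos = _positions(3)
        order = cnv.build_genomic_order(pos, pd.Index(["g0", "g1", "g2", "mystery"]))
        assert list(order["gene_id"]) == ["g0", "g1", "g2"]

    def test_permutation_invariance(self, rng):
        pos = _positions(20)
        shuffled = GenePositionTable(
            pos.table.sample(frac=1, random_state=3).reset_index(drop=True),
            chromosome_order=pos.chromosome_order,
        )
        a = cnv.build_genomic_order(pos, pd.Index([f"g{i}" for i in range(20)]))
        b = cnv.build_genomic_order(shuffled, pd.Index([f"g{i}" for i in range(20)]))
        assert list(a["gene_id"]) == list(b["gene_id"])

    def test_excluded_chromosome_dropped(self):
        tab = pd.DataFrame(
            {"gene_id": ["a", "m"], "chromosome": ["chr1", "chrM"],
             "start": [1, 1], "end": [2, 2]}
        )
        pos = GenePositionTable(tab)
        order = cnv.build_genomic_order(pos, pd.Index(["a", "m"]))
        assert list(order["gene_id"]) == ["a"]

    def test_empty_overlap_is_error(self):
        with pytest.raises(ValueError, match="position"):
            cnv.build_genomic_order(_positions(3), pd.Index(["nope"]))


def _norm(values):
    v = np.asarray(values, dtype=float)
    return qc.NormalizedMatrix(
        v, pd.Index([f"g{i}" for i in range(v.shape[0])]), pd.RangeIndex(v.shape[1])
    )


class TestInferSignal:
    def test_query_equal_to_reference_mean_gives_zero_signal(self, rng):
        n_genes, n_ref = 60, 10
        base = rng.normal(2, 0.5, n_genes)
        vals = np.tile(base[:, None], (1, n_ref + 3))
        norm = _norm(vals)
        ref = np.r_[np.ones(n_ref, bool), np.zeros(3, bool)]
        order = cnv.build_genomic_order(_positions(n_genes), norm.gene_ids)
        prof = cnv.infer_cnv_signal(norm, ref, order, CnvParams(window_genes=5))
        assert np.abs(prof.signal).max() < 1e-10

    def test_planted_gain_raises_signal_inside_event(self, rng):
        n_genes, n_cells = 400, 60
        vals = rng.normal(2, 0.3, (n_genes, n_cells))
        mal = np.zeros(n_cells, bool)
        mal[40:] = True
        vals[100:250][:, mal] += np.log(1.5)
        norm = _norm(vals)
        ref = ~mal
        ref[30:40] = False  # some non-reference diploid cells
        order = cnv.build_genomic_order(_positions(n_genes), norm.gene_ids)
        prof = cnv.infer_cnv_signal(
            norm, ref, order, CnvParams(window_genes=31, denoise=False)
        )
        inside = prof.signal[120:230][:, mal].mean()
        outside = prof.signal[np.r_[0:80, 280:380]][:, mal].mean()
        assert inside > outside + 0.2

    def test_wider_window_never_increases_variance(self, rng):
        vals = rng.normal(0, 1, (300, 20))
        norm = _norm(vals)
        ref = np.zeros(20, bool)
        ref[:8] = True
        order = cnv.build_genomic_order(_positions(300), norm.gene_ids)
        var = []
        for w in (11, 23, 47):
            prof = cnv.infer_cnv_signal(
                norm, ref, order, CnvParams(window_genes=w, denoise=False)
            )
            var.append(prof.signal.var())
        assert var[0] >= var[1] >= var[2]

    def test_reference_mean_signal_is_zero(self, rng):
        vals = rng.normal(1, 0.5, (200, 30))
        norm = _norm(vals)
        ref = np.zeros(30, bool)
        ref[:12] = True
        order = cnv.build_genomic_order(_positions(200), norm.gene_ids)
        prof = cnv.infer_cnv_signal(norm, ref, order, CnvParams(denoise=False))
        np.testing.assert_allclose(
            prof.signal[:, ref].mean(axis=1), 0.0, atol=1e-8
        )

    def test_tiny_chromosome_skipped_with_warning(self, rng):
        tab = pd.concat([
            _positions(50).table,
            pd.DataFrame({"gene_id": ["t1", "t2"], "chromosome": "chr9",
                          "start": [1, 2], "end": [3, 4]}),
        ]).reset_index(drop=True)
        pos = GenePositionTable(tab)
        vals = rng.normal(1, 0.3, (52, 25))
        norm = qc.NormalizedMatrix(
            vals, pd.Index(list(pos.table["gene_id"])), pd.RangeIndex(25)
        )
        ref = np.zeros(25, bool)
        ref[:10] = True
        order = cnv.build_genomic_order(pos, norm.gene_ids)
        with pytest.warns(UserWarning, match="chr9"):
            prof = cnv.infer_cnv_signal(norm, ref, order, CnvParams(window_genes=5))
        assert "t1" not in prof.window_genes


class TestSummary:
    def _profile(self, signal, n_cand=None):
        n_cells = signal.shape[1]
        cand = np.ones(n_cells, bool) if n_cand is None else np.r_[
            np.ones(n_cand, bool), np.zeros(n_cells - n_cand, bool)
        ]
        return cnv.CnvProfileMatrix(
            signal=np.asarray(signal, float),
            window_genes=pd.Index([f"g{i}" for i in range(signal.shape[0])]),
            window_chromosomes=np.repeat("chr1", signal.shape[0]),
            cell_barcodes=pd.Index([f"c{i}" for i in range(n_cells)]),
            reference_mask=np.zeros(n_cells, bool),
            candidate_mask=cand,
        )

    def test_flat_cell_has_zero_sd(self, rng):
        sig = rng.normal(0, 1, (50, 25))
        sig[:, 0] = 0.7
        s = cnv.summarize_cnv_cells(self._profile(sig))
        assert s["sd"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_sd_matches_two_pass_oracle(self, rng):
        sig = rng.normal(0, 1, (40, 30))
        s = cnv.summarize_cnv_cells(self._profile(sig))
        for j in range(30):
            x = sig[:, j]
            mean = x.sum() / len(x)
            var = ((x - mean) ** 2).sum() / len(x)
            assert s["sd"].iloc[j] == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_top_cells_correlate_with_their_mean_profile(self, rng):
        event = np.r_[np.zeros(30), np.ones(20) * 0.5]
        sig = rng.normal(0, 0.05, (50, 40))
        sig[:, :10] += event[:, None]  # shared planted event in 10 cells
        s = cnv.summarize_cnv_cells(self._profile(sig))
        assert s.loc[s["is_top"], "cor"].min() > 0.5

    def test_scaling_scales_sd_not_cor(self, rng):
        sig = rng.normal(0, 0.3, (60, 30)) + np.outer(
            np.sin(np.arange(60)), rng.random(30)
        )
        a = cnv.summarize_cnv_cells(self._profile(sig))
        b = cnv.summarize_cnv_cells(self._profile(3.0 * sig))
        np.testing.assert_allclose(b["sd"], 3.0 * a["sd"], rtol=1e-10)
        np.testing.assert_allclose(b["cor"], a["cor"], atol=1e-10)

    def test_too_few_candidates_is_error(self, rng):
        with pytest.raises(ValueError, match="candidate"):
            cnv.summarize_cnv_cells(self._profile(rng.normal(0, 1, (30, 25)), n_cand=10))


class TestCalls:
    def test_threshold_rule(self):
        summary = pd.DataFrame(
            {"sd": [0.05, 0.01, 0.01, 0.05], "cor": [0.0, 0.1, 0.5, 0.5]}
        )
        cand = np.array([True, True, True, False])
        call = cnv.call_malignant_threshold(summary, cand)
        assert list(call) == [True, False, True, False]  # immune never called

    def test_aneuploid_degenerate_all_diploid(self):
        sig = np.ones((30, 25))
        prof = TestSummary()._profile(sig)
        with pytest.warns(UserWarning, match="diploid"):
            call = cnv.aneuploid_cluster_call(prof)
        assert not call.any()

    def test_aneuploid_bimodal_recovered_and_deterministic(self, rng):
        sig = rng.normal(0, 0.02, (100, 60))
        sig[:, :25] += rng.normal(0, 0.3, (100, 25))  # high-variance cells
        prof = TestSummary()._profile(sig)
        a = cnv.aneuploid_cluster_call(prof, seed=0)
        b = cnv.aneuploid_cluster_call(prof, seed=0)
        np.testing.assert_array_equal(a, b)
        truth = np.r_[np.ones(25, bool), np.zeros(35, bool)]
        assert (a == truth).mean() >= 0.9

    def test_consensus_union_truth_table(self):
        a = np.array([True, False, True, False])
        b = np.array([False, False, True, True])
        np.testing.assert_array_equal(
            cnv.consensus_union(a, b), [True, False, True, True]
        )
        with pytest.raises(ValueError, match="universe"):
            cnv.consensus_union(a, b[:2])


class TestSpikeReference:
    def test_no_spiking_below_cap(self, rng):
        # 10 epithelial among 100 analyzed cells: already under the 20% cap
        analysis = np.r_[np.ones(100, bool), np.zeros(50, bool)]
        epi = np.zeros(150, bool)
        epi[:10] = True
        out = cnv.spike_reference(analysis, epi, ~analysis, CnvParams(), rng)
        np.testing.assert_array_equal(out, analysis)

    def test_spiking_dilutes_epithelial_share(self, rng):
        # 40 epithelial of 60 analyzed -> normals added until <= 20%
        analysis = np.r_[np.ones(60, bool), np.zeros(300, bool)]
        epi = np.zeros(360, bool)
        epi[:40] = True
        out = cnv.spike_reference(analysis, epi, ~analysis, CnvParams(), rng)
        assert epi[out].mean() <= CnvParams().max_reference_epithelial_fraction
        assert (out & analysis).sum() == 60  # original cells retained


class TestCohortRecovery:
    def test_malignant_sensitivity_and_specificity(self, default_ctx):
        calls = default_ctx["cnv_profile"].calls
        truth = default_ctx["truth_filtered"]
        cand = calls["candidate"].to_numpy()
        mal = truth["malignant"].to_numpy()
        cons = calls["consensus_call"].to_numpy()
        assert cons[mal].mean() >= 0.90
        assert cons[cand & ~mal].mean() <= 0.05

    def test_consensus_at_least_as_sensitive_as_either_caller(self, default_ctx):
        calls = default_ctx["cnv_profile"].calls
        truth = default_ctx["truth_filtered"]
        mal = truth["malignant"].to_numpy()
        cons = calls["consensus_call"].to_numpy()[mal].mean()
        assert cons >= calls["threshold_call"].to_numpy()[mal].mean()
        assert cons >= calls["aneuploid_call"].to_numpy()[mal].mean()

    def test_calls_invariant_to_cell_permutation(self, rng):
        sig = rng.normal(0, 0.05, (80, 40))
        sig[:, :15] += rng.normal(0, 0.4, (80, 15))
        prof = TestSummary()._profile(sig)
        perm = rng.permutation(40)
        prof_p = TestSummary()._profile(sig[:, perm])
        a = cnv.call_malignant_threshold(
            cnv.summarize_cnv_cells(prof), prof.candidate_mask
        )
        b = cnv.call_malignant_threshold(
            cnv.summarize_cnv_cells(prof_p), prof_p.candidate_mask
        )
        np.testing.assert_array_equal(a[perm], b)
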