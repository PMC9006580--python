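"""QC metrics, threshold filtering, power markers and doublet flagging."""

import numpy as np
import pandas as pd
import pytest

from degentraj.io import CountMatrix
from degentraj.normalize import log_normalize
from degentraj.qc import (
    QCThresholds,
    apply_qc_filters,
    cell_metrics,
    find_power_markers,
    flag_coexpression_doublets,
    merge_clusters_into_types,
)
from helpers import make_counts


class TestCellMetrics:
    def test_direct_count_example(self):
        cm = make_counts([[2, 0], [2, 0]], symbols=["geneA", "mt-Nd1"])
        m = cell_metrics(cm)
        assert m["n_features"].iloc[0] == 2
        assert m["n_umi"].iloc[0] == 4
        assert m["pct_mito"].iloc[0] == 50.0

    def test_all_zero_cell(self):
        cm = make_counts([[2, 0], [2, 0]], symbols=["geneA", "mt-Nd1"])
        m = cell_metrics(cm)
        assert m.iloc[1].tolist() == [0, 0, 0.0]

    def test_no_mito_genes_warns_and_sets_zero(self):
        cm = make_counts([[1, 2]])
        with pytest.warns(UserWarning, match="mt-"):
            m = cell_metrics(cm)
        assert (m["pct_mito"] == 0).all()

    def test_lowq_cells_have_higher_mito_fraction(self, default_dataset):
        m = cell_metrics(default_dataset.counts)
        lowq = default_dataset.truth_lowq
        singlet = ~lowq & ~default_dataset.truth_doublet
        assert m["pct_mito"].to_numpy()[lowq].mean() > 2 * m["pct_mito"].to_numpy()[singlet].mean()


class TestFilters:
    def make_graded(self):
        # 30 genes; gene g expressed in the first g cells (50 cells)
        dense = np.zeros((30, 50), dtype=int)
        for g in range(30):
            dense[g, : g] = 5
        return make_counts(dense)

    def test_gene_in_two_cells_removed_in_three_kept(self):
        cm = self.make_graded()
        thr = QCThresholds(min_features=1, max_features=1000, min_umi=1, max_umi=10**6)
        out = apply_qc_filters(cm, thr=thr)
        kept = set(out.gene_symbols)
        assert "gene2" not in kept  # expressed in 2 cells
        assert "gene3" in kept      # expressed in 3 cells

    def test_feature_window_boundaries_inclusive(self):
        n_genes = 6500
        rng = np.random.default_rng(0)
        dense = np.zeros((n_genes, 4), dtype=int)
        dense[:150, 0] = 1            # 150 features -> removed
        dense[:200, 1] = 1            # 200 features, 200 UMI -> below min_umi
        dense[:6000, 2] = 3           # 6000 features, 18000 UMI -> kept
        dense[:6001, 3] = 3           # 6001 features -> removed
        dense[0, 1] = 801             # bring cell 1 to exactly 1000 UMI
        cm = make_counts(dense)
        out = apply_qc_filters(cm, thr=QCThresholds(min_cells_per_gene=1))
        kept = set(out.barcodes)
        assert kept == {"bc1", "bc2"}

    def test_filter_is_idempotent(self, default_dataset):
        once = apply_qc_filters(default_dataset.counts)
        twice = apply_qc_filters(once)
        assert once.equals(twice)

    def test_qc_removes_heavily_degraded_cells(self):
        from degentraj.simulate import SyntheticSpec, simulate_counts, inject_artifacts
        spec = SyntheticSpec(lowq_rate=0.05, lowq_factor_range=(0.05, 0.1),
                             coupled_population=None, seed=9)
        ds = inject_artifacts(simulate_counts(spec), spec)
        out = apply_qc_filters(ds.counts)
        lowq_bc = set(ds.counts.barcodes[ds.truth_lowq])
        surviving = lowq_bc & set(out.barcodes)
        assert len(surviving) <= 0.1 * len(lowq_bc)

    def test_removing_every_cell_raises(self):
        cm = make_counts(np.ones((10, 5), dtype=int))
        with pytest.raises(ValueError, match="threshold"):
            apply_qc_filters(cm)


class TestPowerMarkers:
    def make_two_cluster(self):
        rng = np.random.default_rng(1)
        n = 40
        x = rng.poisson(1.0, size=(20, n)).astype(float)
        x[0, :20] = 5.0   # gene0: perfect marker of cluster 0
        x[0, 20:] = 0.0
        x[1] = rng.poisson(2.0, n)  # gene1: identical everywhere
        clusters = np.array([0] * 20 + [1] * 20)
        return np.log1p(x), clusters

    def test_perfect_separator_has_auc_one_and_ranks_first(self):
        ln, cl = self.make_two_cluster()
        mk = find_power_markers(ln, np.array([f"g{i}" for i in range(20)]), cl)
        c0 = mk[mk["cluster"] == 0]
        assert c0.iloc[0]["gene"] == "g0"
        assert c0.iloc[0]["auc"] == pytest.approx(1.0)

    def test_uninformative_gene_excluded(self):
        ln, cl = self.make_two_cluster()
        mk = find_power_markers(ln, np.array([f"g{i}" for i in range(20)]), cl,
                                min_auc=0.8)
        assert "g1" not in set(mk["gene"])

    def test_planted_population_markers_recovered(self, default_dataset):
        from degentraj.qc import apply_qc_filters
        filt = apply_qc_filters(default_dataset.counts)
        ln = log_normalize(filt)
        cells = default_dataset.cells.set_index("barcode").loc[filt.barcodes]
        pops = cells["population"].to_numpy()
        mask = ~cells["doublet"].to_numpy() & ~cells["lowq"].to_numpy()
        mk = find_power_markers(ln.dense()[:, mask], ln.gene_symbols, pops[mask])
        for pop in ("cone_wt", "mueller", "bipolar"):
            found = set(mk[mk["cluster"] == pop]["gene"])
            planted = {g for g in ln.gene_symbols if g.startswith(f"Mk-{pop}-")}
            assert len(found & planted) / len(found) >= 0.95


class TestDoubletFlagging:
    def test_flags_constructed_doublet_not_singlets(self):
        rng = np.random.default_rng(0)
        n = 61
        x = np.zeros((20, n))
        x[:10, :30] = rng.poisson(4, (10, 30))   # cluster 0 markers
        x[10:, 30:60] = rng.poisson(4, (10, 30))  # cluster 1 markers
        x[:, 60] = rng.poisson(3, 20)             # doublet: both programs
        clusters = np.array([0] * 30 + [1] * 30 + [0])
        ln = np.log1p(x)
        sym = np.array([f"g{i}" for i in range(20)])
        mk = find_power_markers(ln[:, :60], sym, clusters[:60])
        flags = flag_coexpression_doublets(ln, sym, clusters, mk)
        assert flags[60]
        assert not flags[:60].any()

    def test_min_markers_zero_rejected(self):
        ln = np.zeros((5, 10))
        mk = pd.DataFrame({"cluster": [0], "gene": ["g0"]})
        with pytest.raises(ValueError, match="min_markers"):
            flag_coexpression_doublets(ln, np.array(["g%d" % i for i in range(5)]),
                                       np.zeros(10, int), mk, min_markers=0)

    def test_flagging_invariant_to_cell_order(self):
        rng = np.random.default_rng(3)
        n = 60
        x = np.zeros((20, n))
        x[:10, :30] = rng.poisson(4, (10, 30))
        x[10:, 30:] = rng.poisson(4, (10, 30))
        x[:, 0] = rng.poisson(3, 20)  # make cell 0 a doublet
        clusters = np.array([0] * 30 + [1] * 30)
        ln = np.log1p(x)
        sym = np.array([f"g{i}" for i in range(20)])
        mk = find_power_markers(ln, sym, clusters)
        flags = flag_coexpression_doublets(ln, sym, clusters, mk)
        perm = rng.permutation(n)
        flags_p = flag_coexpression_doublets(ln[:, perm], sym, clusters[perm], mk)
        assert (flags_p == flags[perm]).all()

    def test_sensitivity_and_false_flag_rate_on_synthetic_doublets(self, pipeline_run):
        res = pipeline_run
        cells = res.cells
        dbl = cells["doublet"].to_numpy()
        lowq = cells["lowq"].to_numpy()
        flags = res.doublet_flags
        assert flags[dbl].mean() >= 0.7
        assert flags[~dbl & ~lowq].mean() <= 0.05


def test_cluster_type_merging_joins_stage_clusters(pipeline_run):
    """Stage-clusters of the trajectory population merge into one cell type."""
    res = pipeline_run
    ln = log_normalize(res.counts_qc)
    types = merge_clusters_into_types(ln.dense(), res.clusters)
    tc = res.manifest["stages"]["trajectory"]["trajectory_clusters"]
    type_of = {c: types[res.clusters == c][0] for c in np.unique(res.clusters)}
    assert len({type_of[c] for c in tc}) == 1
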