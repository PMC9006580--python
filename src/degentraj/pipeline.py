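"""Staged pipeline runner: simulate/ingest → QC → normalize → cluster →
doublet removal → trajectory → DE → patterns → association → similarity.

Every stage derives a content key from its parameters plus its upstream
stage's key. Keys and outputs are recorded in ``manifest.json``; on a rerun
into the same output directory a stage whose key is unchanged and whose
output files exist is reloaded from disk instead of recomputed, so changing
one parameter re-executes exactly that stage and its dependents.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .cluster import build_snn, modularity_cluster, run_pca
from .comparative import group_mean_expression, spearman_similarity
from .config import PipelineConfig, params_hash, stage_seed
from .differential import wilcoxon_de
from .io import CountMatrix, read_10x_triplet, write_10x_triplet
from .normalize import log_normalize, scale_and_regress, select_variable_genes
from .patterns import binned_profiles, classify_patterns
from .qc import (QCThresholds, apply_qc_filters, cell_metrics, find_power_markers,
                 flag_coexpression_doublets, merge_clusters_into_types)
from .simulate import SyntheticSpec, simulate_dataset
from .trajectory import PseudotimeResult, bin_cells, fit_principal_curve, infer_lineage, association_test

_FLOAT_FMT = "%.17g"


@dataclass
class PipelineResult:
    config: PipelineConfig
    out_dir: str
    manifest: dict
    cells: pd.DataFrame | None = None            # per-cell metadata (genotype, truth)
    counts_qc: CountMatrix | None = None
    metrics: pd.DataFrame | None = None
    hvg: list = field(default_factory=list)
    pca_coords: np.ndarray | None = None
    clusters: np.ndarray | None = None
    modularity: float = 0.0
    doublet_flags: np.ndarray | None = None
    keep_mask: np.ndarray | None = None          # QC cells surviving doublet removal
    traj_mask: np.ndarray | None = None          # within kept cells
    traj_clusters: list = field(default_factory=list)
    lineage: list = field(default_factory=list)
    pseudotime: np.ndarray | None = None         # per trajectory cell
    binning: object = None
    de_tables: dict = field(default_factory=dict)
    de_union: list = field(default_factory=list)
    bin_profiles: object = None
    pattern_assignment: object = None
    association: pd.DataFrame | None = None
    similarity: pd.DataFrame | None = None


def _write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


class _Runner:
    def __init__(self, config: PipelineConfig):
        config.validate()
        self.cfg = config
        self.out = config.out_dir
        os.makedirs(self.out, exist_ok=True)
        prev_path = os.path.join(self.out, "manifest.json")
        self.prev = {}
        if os.path.exists(prev_path):
            try:
                with open(prev_path) as fh:
                    self.prev = json.load(fh).get("stages", {})
            except (json.JSONDecodeError, OSError):
                self.prev = {}
        self.manifest = {"version": __version__, "config": config.to_dict(), "stages": {}}
        self.res = PipelineResult(config, self.out, self.manifest)

    # -- stage framework -------------------------------------------------
    def stage(self, name, params, upstream_key, outputs, compute, load):
        key = params_hash(params, upstream_key)
        paths = [os.path.join(self.out, o) for o in outputs]
        prev = self.prev.get(name, {})
        info = {"hash": key, "outputs": outputs}
        if prev.get("hash") == key and all(os.path.exists(p) for p in paths):
            try:
                load(paths, prev)
                info["status"] = "reused"
                info.update({k: v for k, v in prev.items() if k not in ("hash", "outputs", "status")})
                self.manifest["stages"][name] = info
                return key
            except Exception:
                pass  # fall through to recompute
        extra = compute(paths) or {}
        info["status"] = "computed"
        info.update(extra)
        self.manifest["stages"][name] = info
        return key

    # -- stages ----------------------------------------------------------
    def run(self) -> PipelineResult:
        cfg, res = self.cfg, self.res

        # ingest / simulate ------------------------------------------------
        raw_dir = os.path.join(self.out, "raw")

        def compute_ingest(paths):
            if cfg.input_dir is not None:
                counts = read_10x_triplet(cfg.input_dir)
                meta_path = os.path.join(cfg.input_dir, "cells.tsv")
                cells = (pd.read_csv(meta_path, sep="\t") if os.path.exists(meta_path)
                         else pd.DataFrame({"barcode": counts.barcodes}))
            else:
                spec = replace(SyntheticSpec(), **cfg.synthetic,
                               seed=stage_seed(cfg.seed, "simulate"))
                ds = simulate_dataset(spec)
                counts, cells = ds.counts, ds.cells
            write_10x_triplet(counts, raw_dir)
            _write_tsv(cells, paths[0], index=False)
            self._raw, res.cells = counts, cells
            return {"n_cells": counts.n_cells, "n_genes": counts.n_genes}

        def load_ingest(paths, prev):
            self._raw = read_10x_triplet(raw_dir)
            res.cells = pd.read_csv(paths[0], sep="\t")

        k = self.stage(
            "ingest",
            {"input_dir": cfg.input_dir, "synthetic": cfg.synthetic,
             "seed": stage_seed(cfg.seed, "simulate")},
            "", ["cells.tsv"], compute_ingest, load_ingest,
        )

        # qc ---------------------------------------------------------------
        qc_dir = os.path.join(self.out, "filtered")
        thr = QCThresholds(cfg.min_cells_per_gene, cfg.min_features, cfg.max_features,
                           cfg.min_umi, cfg.max_umi)

        def compute_qc(paths):
            filtered = apply_qc_filters(self._raw, thr=thr, mito_prefix=cfg.mito_prefix)
            write_10x_triplet(filtered, qc_dir)
            metrics = cell_metrics(filtered, cfg.mito_prefix)
            _write_tsv(metrics, paths[0])
            res.counts_qc, res.metrics = filtered, metrics
            return {"n_cells": filtered.n_cells, "n_genes": filtered.n_genes,
                    "genes_dropped": filtered.log.get("genes_dropped"),
                    "cells_dropped": filtered.log.get("cells_dropped")}

        def load_qc(paths, prev):
            res.counts_qc = read_10x_triplet(qc_dir)
            res.metrics = pd.read_csv(paths[0], sep="\t", index_col=0)

        k = self.stage("qc", {"thr": thr.__dict__, "mito_prefix": cfg.mito_prefix}, k,
                       ["qc_metrics.tsv"], compute_qc, load_qc)

        # align cell metadata to QC'd barcodes
        if res.cells is not None and "barcode" in res.cells.columns:
            res.cells = (res.cells.set_index("barcode")
                         .reindex(res.counts_qc.barcodes).reset_index())
        self._lognorm = log_normalize(res.counts_qc, cfg.scale_factor)

        # normalize / variable genes --------------------------------------
        def compute_norm(paths):
            hvg_tab = select_variable_genes(
                self._lognorm, cfg.hvg_mean_lo, cfg.hvg_mean_hi, cfg.hvg_disp_min, cfg.n_hvg)
            _write_tsv(hvg_tab, paths[0])
            res.hvg = list(hvg_tab.index[hvg_tab["selected"]])
            return {"n_hvg": len(res.hvg)}

        def load_norm(paths, prev):
            tab = pd.read_csv(paths[0], sep="\t", index_col=0)
            res.hvg = list(tab.index[tab["selected"]])

        k = self.stage("normalize",
                       {"scale_factor": cfg.scale_factor, "n_hvg": cfg.n_hvg,
                        "window": [cfg.hvg_mean_lo, cfg.hvg_mean_hi, cfg.hvg_disp_min],
                        "clip": cfg.clip_max},
                       k, ["hvg.tsv"], compute_norm, load_norm)

        # cluster ----------------------------------------------------------
        def compute_cluster(paths):
            scaled, _ = scale_and_regress(self._lognorm, np.array(res.hvg), cfg.clip_max)
            n_pcs = min(cfg.n_pcs, min(scaled.shape) - 1)
            pcs = run_pca(scaled, n_pcs, seed=stage_seed(cfg.seed, "pca"))
            snn = build_snn(pcs, cfg.k_neighbors, cfg.snn_prune)
            assign = modularity_cluster(snn, cfg.resolution, seed=stage_seed(cfg.seed, "cluster"))
            res.pca_coords, res.clusters = pcs.coords, assign.labels
            res.modularity = assign.modularity
            _write_tsv(pd.DataFrame(pcs.coords, index=pd.Index(res.counts_qc.barcodes, name="barcode"),
                                    columns=[f"PC{i+1}" for i in range(pcs.coords.shape[1])]), paths[0])
            _write_tsv(pd.DataFrame({"cluster": assign.labels},
                                    index=pd.Index(res.counts_qc.barcodes, name="barcode")), paths[1])
            return {"n_clusters": int(len(np.unique(assign.labels))),
                    "modularity": assign.modularity}

        def load_cluster(paths, prev):
            res.pca_coords = pd.read_csv(paths[0], sep="\t", index_col=0).to_numpy()
            res.clusters = pd.read_csv(paths[1], sep="\t", index_col=0)["cluster"].to_numpy()
            res.modularity = prev.get("modularity", 0.0)

        k = self.stage("cluster",
                       {"n_pcs": cfg.n_pcs, "k": cfg.k_neighbors, "prune": cfg.snn_prune,
                        "resolution": cfg.resolution,
                        "seeds": [stage_seed(cfg.seed, "pca"), stage_seed(cfg.seed, "cluster")]},
                       k, ["pca.tsv", "clusters.tsv"], compute_cluster, load_cluster)

        # doublet removal --------------------------------------------------
        def compute_doublets(paths):
            lognorm_dense = self._lognorm.dense()
            sym_index = {s: i for i, s in enumerate(self._lognorm.gene_symbols)}
            hvg_rows = np.array([sym_index[g] for g in res.hvg])
            types = merge_clusters_into_types(lognorm_dense, res.clusters,
                                              cfg.doublet_type_corr, hvg_rows)
            markers = find_power_markers(lognorm_dense, self._lognorm.gene_symbols,
                                         types, cfg.marker_top_n, cfg.marker_min_auc)
            flags = flag_coexpression_doublets(lognorm_dense, self._lognorm.gene_symbols,
                                               types, markers, cfg.doublet_min_markers)
            res.doublet_flags = flags
            _write_tsv(markers, paths[0], index=False)
            _write_tsv(pd.DataFrame({"doublet": flags.astype(int)},
                                    index=pd.Index(res.counts_qc.barcodes, name="barcode")), paths[1])
            return {"n_flagged": int(flags.sum())}

        def load_doublets(paths, prev):
            res.doublet_flags = (pd.read_csv(paths[1], sep="\t", index_col=0)["doublet"]
                                 .to_numpy().astype(bool))

        k = self.stage("doublets",
                       {"top_n": cfg.marker_top_n, "min_auc": cfg.marker_min_auc,
                        "min_markers": cfg.doublet_min_markers,
                        "type_corr": cfg.doublet_type_corr},
                       k, ["markers.tsv", "doublet_flags.tsv"], compute_doublets, load_doublets)

        res.keep_mask = ~res.doublet_flags

        # trajectory -------------------------------------------------------
        def compute_traj(paths):
            keep = res.keep_mask
            kept_clusters = res.clusters[keep]
            lognorm_kept = self._lognorm.matrix[:, keep]
            # trajectory clusters: mean marker expression >= half the max cluster mean
            sym_index = {s: i for i, s in enumerate(self._lognorm.gene_symbols)}
            marker_rows = [sym_index[g] for g in cfg.trajectory_markers if g in sym_index]
            if not marker_rows:
                raise ValueError(f"trajectory markers {cfg.trajectory_markers} not in matrix")
            marker_expr = np.asarray(lognorm_kept[marker_rows].mean(axis=0)).ravel()
            labels = np.unique(kept_clusters)
            cluster_marker = np.array([marker_expr[kept_clusters == lab].mean() for lab in labels])
            traj_clusters = [int(lab) for lab, v in zip(labels, cluster_marker)
                             if v >= 0.5 * cluster_marker.max()]
            traj_mask = np.isin(kept_clusters, traj_clusters)
            tclust = kept_clusters[traj_mask]

            # start cluster: highest wild-type fraction when genotype is known,
            # else the lowest cluster label among trajectory clusters
            start = min(traj_clusters)
            if res.cells is not None and "genotype" in res.cells.columns:
                geno = res.cells["genotype"].to_numpy()[keep][traj_mask]
                fracs = {lab: float(np.mean(geno[tclust == lab] == "wt")) for lab in traj_clusters}
                start = max(fracs, key=lambda lab: (fracs[lab], -lab))

            # rod-subset re-analysis: fresh variable genes, scaling and PCA
            from .normalize import LogNormMatrix
            sub = LogNormMatrix(self._lognorm.matrix[:, keep][:, traj_mask].tocsr(),
                                self._lognorm.gene_symbols,
                                res.counts_qc.barcodes[keep][traj_mask],
                                self._lognorm.cell_totals[keep][traj_mask],
                                self._lognorm.scale_factor)
            hvg_tab = select_variable_genes(sub, cfg.hvg_mean_lo, cfg.hvg_mean_hi,
                                            cfg.hvg_disp_min, cfg.trajectory_n_hvg)
            hvg_sub = list(hvg_tab.index[hvg_tab["selected"]])
            if len(hvg_sub) < cfg.trajectory_n_pcs + 1:
                hvg_sub = list(hvg_tab.sort_values("dispersion_std").index[-(cfg.trajectory_n_pcs + 50):])
            scaled, _ = scale_and_regress(sub, np.array(hvg_sub), cfg.clip_max)
            pcs = run_pca(scaled, min(cfg.trajectory_n_pcs, min(scaled.shape) - 1),
                          seed=stage_seed(cfg.seed, "traj_pca"))
            init_lineage = infer_lineage(pcs, tclust, start)
            pt = fit_principal_curve(pcs, clusters=tclust, lineage=init_lineage,
                                     start_cluster=start)
            lineage = [int(x) for x in pt.lineage]
            binning = bin_cells(pt, cfg.n_bins, cfg.min_bin_cells)

            res.traj_mask, res.traj_clusters, res.lineage = traj_mask, traj_clusters, lineage
            res.pseudotime, res.binning = pt.pseudotime, binning
            self._pt_result = pt
            _write_tsv(pd.DataFrame(
                {"cluster": tclust, "pseudotime": pt.pseudotime, "bin": binning.bin_of_cell},
                index=pd.Index(res.counts_qc.barcodes[keep][traj_mask], name="barcode")), paths[0])
            return {"trajectory_clusters": traj_clusters, "lineage": [int(x) for x in lineage],
                    "start_cluster": int(start), "n_cells": int(traj_mask.sum()),
                    "n_bins": int(binning.n_bins), "converged": bool(pt.converged)}

        def load_traj(paths, prev):
            tab = pd.read_csv(paths[0], sep="\t", index_col=0)
            kept_bc = res.counts_qc.barcodes[res.keep_mask]
            res.traj_mask = np.isin(kept_bc, tab.index.to_numpy())
            res.traj_clusters = prev["trajectory_clusters"]
            res.lineage = prev["lineage"]
            res.pseudotime = tab["pseudotime"].to_numpy()
            res.binning = bin_cells(res.pseudotime, cfg.n_bins, cfg.min_bin_cells)
            self._pt_result = PseudotimeResult(res.pseudotime, res.lineage,
                                               np.zeros((0, 0)), 0, True)

        k = self.stage("trajectory",
                       {"markers": cfg.trajectory_markers, "n_hvg": cfg.trajectory_n_hvg,
                        "n_pcs": cfg.trajectory_n_pcs, "bins": cfg.n_bins,
                        "min_bin_cells": cfg.min_bin_cells,
                        "seed": stage_seed(cfg.seed, "traj_pca")},
                       k, ["pseudotime.tsv"], compute_traj, load_traj)

        keep = res.keep_mask
        kept_lognorm = self._lognorm.matrix[:, keep]
        kept_clusters = res.clusters[keep]

        # differential expression along the lineage ------------------------
        def compute_de(paths):
            union: list = []
            for i in range(len(res.lineage) - 1):
                a, b = res.lineage[i + 1], res.lineage[i]  # later vs earlier
                from .normalize import LogNormMatrix
                ln = LogNormMatrix(kept_lognorm.tocsr(), self._lognorm.gene_symbols,
                                   res.counts_qc.barcodes[keep],
                                   self._lognorm.cell_totals[keep], cfg.scale_factor)
                tab = wilcoxon_de(ln, np.flatnonzero(kept_clusters == a),
                                  np.flatnonzero(kept_clusters == b),
                                  cfg.min_pct, cfg.logfc_floor,
                                  exclude_prefixes=tuple(cfg.hemoglobin_prefixes))
                name = f"de_{a}_vs_{b}"
                res.de_tables[name] = tab
                _write_tsv(tab, os.path.join(self.out, f"{name}.tsv"))
                sig = tab.index[tab["p_adjusted"] < cfg.alpha]
                union.extend([g for g in sig if g not in union])
            res.de_union = union
            with open(paths[0], "w") as fh:
                fh.write("\n".join(map(str, union)) + ("\n" if union else ""))
            return {"pairs": len(res.lineage) - 1, "n_union": len(union)}

        def load_de(paths, prev):
            with open(paths[0]) as fh:
                res.de_union = [ln.strip() for ln in fh if ln.strip()]
            for i in range(len(res.lineage) - 1):
                name = f"de_{res.lineage[i + 1]}_vs_{res.lineage[i]}"
                p = os.path.join(self.out, f"{name}.tsv")
                if os.path.exists(p):
                    res.de_tables[name] = pd.read_csv(p, sep="\t", index_col=0)

        k = self.stage("de",
                       {"min_pct": cfg.min_pct, "logfc": cfg.logfc_floor, "alpha": cfg.alpha,
                        "hb": cfg.hemoglobin_prefixes},
                       k, ["de_union.txt"], compute_de, load_de)

        # pattern classification -------------------------------------------
        def compute_patterns(paths):
            if len(res.de_union) < cfg.k_patterns:
                _write_tsv(pd.DataFrame(), paths[0])
                _write_tsv(pd.DataFrame(), paths[1])
                return {"skipped": "too few DE genes"}
            from .normalize import LogNormMatrix
            traj_ln = LogNormMatrix(kept_lognorm[:, res.traj_mask].tocsr(),
                                    self._lognorm.gene_symbols,
                                    res.counts_qc.barcodes[keep][res.traj_mask],
                                    self._lognorm.cell_totals[keep][res.traj_mask],
                                    cfg.scale_factor)
            profiles = binned_profiles(traj_ln, res.binning, np.array(res.de_union))
            assign = classify_patterns(profiles, cfg.k_patterns,
                                       seed=stage_seed(cfg.seed, "patterns"))
            res.bin_profiles, res.pattern_assignment = profiles, assign
            _write_tsv(profiles.z, paths[0])
            _write_tsv(assign.assignments, paths[1])
            return {"centroid_labels": assign.centroid_labels}

        def load_patterns(paths, prev):
            z = pd.read_csv(paths[0], sep="\t", index_col=0)
            res.bin_profiles = type("BP", (), {"z": z, "means": None})()
            res.pattern_assignment = type("PA", (), {
                "assignments": pd.read_csv(paths[1], sep="\t", index_col=0),
                "centroid_labels": prev.get("centroid_labels", [])})()

        k = self.stage("patterns",
                       {"k": cfg.k_patterns, "seed": stage_seed(cfg.seed, "patterns")},
                       k, ["bin_profiles_z.tsv", "pattern_assignments.tsv"],
                       compute_patterns, load_patterns)

        # pseudotime association -------------------------------------------
        def compute_assoc(paths):
            from .normalize import LogNormMatrix
            traj_ln = LogNormMatrix(kept_lognorm[:, res.traj_mask].tocsr(),
                                    self._lognorm.gene_symbols,
                                    res.counts_qc.barcodes[keep][res.traj_mask],
                                    self._lognorm.cell_totals[keep][res.traj_mask],
                                    cfg.scale_factor)
            res.association = association_test(traj_ln, res.pseudotime, cfg.assoc_knots)
            _write_tsv(res.association, paths[0])
            return {"n_tested": len(res.association)}

        def load_assoc(paths, prev):
            res.association = pd.read_csv(paths[0], sep="\t", index_col=0)

        k = self.stage("association", {"knots": cfg.assoc_knots}, k,
                       ["association.tsv"], compute_assoc, load_assoc)

        # cross-group similarity -------------------------------------------
        def compute_sim(paths):
            from .normalize import LogNormMatrix
            ln = LogNormMatrix(kept_lognorm.tocsr(), self._lognorm.gene_symbols,
                               res.counts_qc.barcodes[keep],
                               self._lognorm.cell_totals[keep], cfg.scale_factor)
            geno = (res.cells["genotype"].to_numpy()[keep]
                    if res.cells is not None and "genotype" in res.cells.columns
                    else np.array(["na"] * int(keep.sum()), dtype=object))
            groups = np.array([f"C{c}:{g}" for c, g in zip(kept_clusters, geno)], dtype=object)
            lab, cnt = np.unique(groups, return_counts=True)
            ok = set(lab[cnt >= cfg.similarity_min_cells])
            groups = np.array([g if g in ok else None for g in groups], dtype=object)
            feats = np.array(res.hvg[: cfg.similarity_n_features])
            means = group_mean_expression(ln, groups, feats)
            res.similarity = spearman_similarity(means)
            _write_tsv(res.similarity, paths[0])
            return {"n_groups": res.similarity.shape[0]}

        def load_sim(paths, prev):
            res.similarity = pd.read_csv(paths[0], sep="\t", index_col=0)

        self.stage("similarity",
                   {"n_features": cfg.similarity_n_features,
                    "min_cells": cfg.similarity_min_cells},
                   k, ["similarity.tsv"], compute_sim, load_sim)

        # finalize ---------------------------------------------------------
        self.cfg.to_yaml(os.path.join(self.out, "config.yaml"))
        with open(os.path.join(self.out, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.res


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute (or resume) the full pipeline described by ``config``."""
    return _Runner(config).run()
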