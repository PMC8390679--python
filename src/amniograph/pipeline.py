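"""End-to-end orchestration: simulate/load -> QC -> ambient -> normalize ->
cluster/annotate -> signatures -> pseudotime -> regulons -> DE -> report.

Every stage draws its randomness from a named substream of one global seed,
so a config + seed pair reproduces the whole report bit-for-bit.  The report
is a JSON-serializable summary with three headline booleans mirroring the
biological phenotype the pipeline is designed to detect: mesoderm depletion
in the mutant, significant down-regulation of the BMP4-like regulon target
in mutant amnion, and an amnion-specific bimodal ISL1 regulon.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster_annotate as ca
from . import ingest_qc, normalize_de, pseudotime as pt_mod, regulons as reg_mod, syndata
from .signatures import GeneSignature, score_signature

__all__ = ["PipelineConfig", "PipelineReport", "derive_seed", "run_pipeline"]

log = logging.getLogger(__name__)


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (stable across processes)."""
    return (int(root_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed.

    ``mode`` is "simulate" (default; the generator provides the data and
    ground truth) or "load" (read a 10x triplet + truth annotations from
    ``input_dir``).  ``min_genes_per_cell`` defaults to 200: the synthetic
    atlas carries ~2000 genes, so the absolute cutoff is scaled to the panel
    rather than a whole transcriptome.
    """

    mode: str = "simulate"
    input_dir: str | None = None
    output_dir: str | None = None
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)
    max_mito_fraction: float = 0.075
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    n_dims: int = 30
    knn_k: int = 15
    cluster_resolution: float = 1.0
    de_fdr: float = 0.01
    de_percentile: float = 99.9
    de_n_partitions: int = 100
    regulon_alpha: float = 0.05
    regulon_min_active_frac: float = 0.01
    dip_n_boot: int = 1000
    moran_top_n: int = 100

    # stage toggles
    run_pseudotime: bool = True
    run_regulons: bool = True
    run_de: bool = True


@dataclass
class PipelineReport:
    """Machine-readable per-stage summaries and headline findings."""

    summary: dict
    composition: pd.DataFrame
    de_table: pd.DataFrame | None
    regulon_report: pd.DataFrame | None
    cluster_labels: pd.Series
    annotations: dict

    def to_json_dict(self) -> dict:
        return self.summary

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.summary, fh, indent=1, default=float)
        self.composition.to_csv(outdir / "composition.csv", index=False)
        if self.de_table is not None:
            self.de_table.to_csv(outdir / "de_amnion_mt_vs_wt.csv", index=False)
        if self.regulon_report is not None:
            self.regulon_report.to_csv(outdir / "regulon_binarization.csv")
        self.cluster_labels.to_frame().to_csv(outdir / "clusters.csv")
        return outdir / "report.json"


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _load_input(config: PipelineConfig):
    if config.input_dir is None:
        raise ValueError("load mode requires input_dir")
    path = Path(config.input_dir)
    if not path.exists():
        raise FileNotFoundError(f"input directory {path} does not exist")
    m = ingest_qc.read_tenx_triplet(path)
    truth = None
    truth_path = path / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    return m, truth


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all enabled stages in order; see module docstring."""
    summary: dict = {"seed": config.seed, "stages": {}}

    def _stage(name):
        def deco(fn):
            try:
                out = fn()
            except Exception as err:  # tag the failing stage
                raise StageError(name, err) from err
            return out

        return deco

    # ---- input ------------------------------------------------------
    @_stage("input")
    def _input():
        if config.mode == "simulate":
            sim_cfg = syndata.build_default_config(config.sim_overrides)
            m, truth = syndata.simulate_dataset(sim_cfg, seed=derive_seed(config.seed, "simulate"))
            return m, truth, sim_cfg
        elif config.mode == "load":
            m, truth = _load_input(config)
            return m, truth, None
        raise ValueError(f"unknown mode {config.mode!r}")

    m, truth, sim_cfg = _input
    is_sim = sim_cfg is not None
    summary["stages"]["input"] = {
        "mode": config.mode,
        "n_genes": m.n_genes,
        "n_cells": m.n_cells,
    }

    mito_genes = (
        truth.mito_genes if is_sim else [g for g in m.gene_ids if g.startswith("MT-")]
    )
    reporter_genes = (
        truth.reporter_genes if is_sim else [g for g in m.gene_ids if g.startswith("CGB")]
    )
    marker_sets = truth.marker_sets if is_sim else None
    regulon = truth.regulon if is_sim else None

    # ---- QC ---------------------------------------------------------
    @_stage("qc")
    def _qc():
        thr = ingest_qc.QcThresholds(
            max_mito_fraction=config.max_mito_fraction,
            min_cells_per_gene=config.min_cells_per_gene,
            min_genes_per_cell=config.min_genes_per_cell,
        )
        present_mito = [g for g in mito_genes if g in set(m.gene_ids)]
        return ingest_qc.apply_qc_filters(m, thr, present_mito)

    m_qc, qc_table = _qc
    summary["stages"]["qc"] = {
        "cells_in": int(qc_table.shape[0]),
        "cells_kept": int(qc_table["kept"].sum()),
        "genes_kept": int(m_qc.n_genes),
    }

    # ---- ambient ----------------------------------------------------
    @_stage("ambient")
    def _ambient():
        # reporter population: cells confidently positive for the epiblast
        # marker program (they never transcribe the CG reporters themselves)
        epi_markers = (
            marker_sets["Epi"]
            if marker_sets
            else [g for g in m_qc.gene_ids if g.startswith("MK-Epi")]
        )
        epi_sig = GeneSignature("Epi", tuple(g for g in epi_markers if g in set(m_qc.gene_ids)))
        scores = score_signature(m_qc, epi_sig)
        cutoff = np.percentile(scores, 75)
        pop = scores.index[scores > cutoff]
        est = ingest_qc.estimate_ambient_fraction(m_qc,
            [g for g in reporter_genes if g in set(m_qc.gene_ids)], pop)
        corrected = ingest_qc.correct_ambient(m_qc, est)
        return est, corrected

    est, m_corr = _ambient
    summary["stages"]["ambient"] = {
        "rho_hat": est.rho,
        "n_reporter_cells": len(est.reporter_population),
    }

    # ---- normalize --------------------------------------------------
    @_stage("normalize")
    def _normalize():
        fit = normalize_de.fit_nb_model(m_corr)
        res = normalize_de.pearson_residuals(m_corr, fit)
        return fit, res

    fit, res = _normalize
    summary["stages"]["normalize"] = {
        "median_theta": float(np.nanmedian(fit.theta)),
        "clip": fit.clip,
    }

    # ---- cluster & annotate ----------------------------------------
    @_stage("cluster")
    def _cluster():
        emb = ca.pca_knn_embed(res, n_dims=config.n_dims, k=config.knn_k,
                               seed=derive_seed(config.seed, "embed"))
        assign = ca.cluster_graph(emb, resolution=config.cluster_resolution,
                                  seed=derive_seed(config.seed, "cluster"))
        return emb, assign

    emb, assign = _cluster

    @_stage("annotate")
    def _annotate():
        sets = marker_sets or {}
        if not sets:
            raise ValueError("no marker sets available for annotation")
        mapping, info = ca.annotate_clusters(m_corr, assign, sets)
        type_labels = assign.labels.map(mapping).rename("cell_type")
        comp = ca.composition_by_condition(type_labels, m_corr.cell_meta)
        return mapping, info, type_labels, comp

    mapping, anno_info, type_labels, comp = _annotate
    comp_wide = ca.composition_difference(comp)
    summary["stages"]["cluster"] = {
        "n_clusters": int(assign.labels.nunique()),
        "annotation": mapping,
    }

    # headline 1: mutant mesoderm depleted, amnion over-represented
    def _frac(cond, types):
        sub = comp[(comp["condition"] == cond) & (comp["cell_type"].isin(types))]
        return float(sub["fraction"].sum()), int(sub["count"].sum())

    n_by_cond = comp.groupby("condition")["count"].sum().to_dict()
    meso_wt, _ = _frac("wt", syndata.MESODERM)
    meso_mt, _ = _frac("mt", syndata.MESODERM)
    am_wt, _ = _frac("wt", syndata.AMNION)
    am_mt, _ = _frac("mt", syndata.AMNION)

    def _se(p, n):
        return np.sqrt(max(p * (1 - p), 1e-12) / n)

    se_meso = np.hypot(_se(meso_wt, n_by_cond.get("wt", 1)), _se(meso_mt, n_by_cond.get("mt", 1)))
    se_am = np.hypot(_se(am_wt, n_by_cond.get("wt", 1)), _se(am_mt, n_by_cond.get("mt", 1)))
    mesoderm_depleted = (meso_wt - meso_mt) > 3 * se_meso
    amnion_overrepresented = (am_mt - am_wt) > 3 * se_am
    summary["composition"] = {
        "mesoderm_fraction_wt": meso_wt,
        "mesoderm_fraction_mt": meso_mt,
        "amnion_fraction_wt": am_wt,
        "amnion_fraction_mt": am_mt,
        "mesoderm_depleted_in_mutant": bool(mesoderm_depleted),
        "amnion_overrepresented_in_mutant": bool(amnion_overrepresented),
    }

    # ---- signatures / pseudotime ------------------------------------
    if config.run_pseudotime and is_sim:

        @_stage("pseudotime")
        def _pseudotime():
            naive = GeneSignature("naive", tuple(truth.naive_genes))
            primed = GeneSignature("primed", tuple(truth.primed_genes))
            naive_scores = score_signature(m_corr, naive)
            primed_scores = score_signature(m_corr, primed)
            epi_cells = type_labels.index[type_labels == "Epi"]
            if len(epi_cells) < 25:
                raise ValueError("too few epiblast cells for pseudotime")
            idx = m_corr.barcode_index(epi_cells)
            sub_res = normalize_de.ResidualMatrix(
                z=res.z[:, idx], gene_ids=res.gene_ids, barcodes=np.asarray(epi_cells), clip=res.clip
            )
            emb_epi = ca.pca_knn_embed(
                sub_res, n_dims=min(config.n_dims, len(epi_cells) - 1), k=config.knn_k,
                seed=derive_seed(config.seed, "embed-epi"),
            )
            root = naive_scores.loc[epi_cells].idxmax()
            ptr = pt_mod.graph_pseudotime(emb_epi, root)
            m_epi = m_corr.subset_cells(idx)
            moran, dyn = pt_mod.rank_and_cluster_dynamics(
                m_epi, ptr, emb_epi.adjacency, top_n=config.moran_top_n
            )
            return naive_scores, primed_scores, ptr, moran, dyn

        naive_scores, primed_scores, ptr, moran, dyn = _pseudotime
        top_genes = set(dyn["gene"])
        summary["stages"]["pseudotime"] = {
            "root": ptr.root,
            "n_top_genes": len(top_genes),
            "naive_in_top": len(top_genes & set(truth.naive_genes)),
            "primed_in_top": len(top_genes & set(truth.primed_genes)),
            "down_cluster_size": int((dyn["cluster"] == "down").sum()),
            "up_cluster_size": int((dyn["cluster"] == "up").sum()),
        }

    # ---- regulons ---------------------------------------------------
    regulon_report = None
    if config.run_regulons and regulon:

        @_stage("regulons")
        def _regulons():
            kept = reg_mod.prefilter_genes(m_corr)
            m_pre = m_corr.subset_genes(m_corr.gene_index(kept))
            auc = reg_mod.auc_score(
                m_pre, regulon, seed=derive_seed(config.seed, "auc")
            )
            report, bam = reg_mod.binarize_matrix(
                auc,
                alpha=config.regulon_alpha,
                min_active_frac=config.regulon_min_active_frac,
                n_boot=config.dip_n_boot,
                seed=derive_seed(config.seed, "dip"),
            )
            return kept, auc, report, bam

        kept_genes, auc, regulon_report, bam = _regulons
        tf = next(iter(regulon))
        isl1_retained = tf in bam.values.index
        isl1_bimodal = (
            bool(regulon_report.loc[tf, "modality"] == "bimodal") if tf in regulon_report.index else False
        )
        if isl1_retained:
            active_cells = bam.values.columns[bam.values.loc[tf].to_numpy()]
            labels_active = type_labels.reindex(active_cells)
            amnion_purity = float(labels_active.isin(syndata.AMNION).mean())
        else:
            amnion_purity = 0.0
        summary["stages"]["regulons"] = {
            "n_genes_prefiltered": len(kept_genes),
            "tf": tf,
            "retained": bool(isl1_retained),
            "bimodal": isl1_bimodal,
            "active_amnion_purity": amnion_purity,
        }

    # ---- differential expression ------------------------------------
    de_table = None
    if config.run_de:

        @_stage("de")
        def _de():
            am_cells = type_labels.index[type_labels.isin(syndata.AMNION)]
            cond = m_corr.cell_meta["condition"].reindex(am_cells)
            group_mt = list(am_cells[cond == "mt"])
            group_wt = list(am_cells[cond == "wt"])
            de_cfg = normalize_de.DeConfig(
                fdr=config.de_fdr,
                percentile=config.de_percentile,
                n_partitions=config.de_n_partitions,
                seed=derive_seed(config.seed, "de-band"),
            )
            return normalize_de.run_de(m_corr, group_mt, group_wt, de_cfg)

        de_table = _de
        sig_down = de_table[(de_table["significant"]) & (de_table["mean_diff"] < 0)]
        bmp4_row = de_table.index[de_table["gene"] == "BMP4"]
        bmp4_sig_down = bool(
            len(bmp4_row) and de_table.loc[bmp4_row[0], "significant"] and de_table.loc[bmp4_row[0], "mean_diff"] < 0
        )
        summary["stages"]["de"] = {
            "n_significant_down_in_mutant": int(sig_down.shape[0]),
            "band": float(de_table["band"].iloc[0]) if len(de_table) else np.nan,
            "bmp4_rank_by_p": int(bmp4_row[0]) + 1 if len(bmp4_row) else None,
            "bmp4_significantly_down": bmp4_sig_down,
        }

    # ---- headline booleans ------------------------------------------
    summary["headline"] = {
        "mesoderm_depleted_in_mutant": bool(mesoderm_depleted),
        "bmp4_down_in_mutant_amnion": bool(
            summary.get("stages", {}).get("de", {}).get("bmp4_significantly_down", False)
        ),
        "isl1_regulon_amnion_specific": bool(
            config.run_regulons
            and regulon
            and summary["stages"].get("regulons", {}).get("retained", False)
            and summary["stages"]["regulons"].get("bimodal", False)
            and summary["stages"]["regulons"].get("active_amnion_purity", 0.0) >= 0.9
        ),
    }

    report = PipelineReport(
        summary=summary,
        composition=comp,
        de_table=de_table,
        regulon_report=regulon_report,
        cluster_labels=assign.labels,
        annotations=mapping,
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report
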