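"""End-to-end pipeline: configuration, orchestration and artifacts.

The pipeline ties the stages together in the order the analysis
demands: preprocess -> (optional) soft-threshold selection -> iterative
density filter in the reference region -> rebuild the test-region
network on the surviving genes -> module metrics in both regions ->
label matching and overlap tables -> preservation, quality and ranking
-> trait correlations -> enrichment. Every artifact is plain text
(TSV/CSV/JSON) and every run writes its resolved configuration, seed
and a parameter hash next to the outputs, so a rerun with the same
inputs and seed is byte-identical.

A single master seed fans out to per-stage seeds by fixed offsets, so
each stage is individually reproducible when run on its own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .colors import GREY
from . import io as cio
from .crossregion import background_accounting, match_labels, overlap_table
from .density import iterative_filter
from .enrichment import (enrichment_table, export_enrichment, filter_terms,
                         term_significance)
from .metrics import (compute_kin, compute_kme, connectivity_table,
                      meta_modules, module_eigengenes)
from .network import build_network, cluster_and_cut, pick_soft_threshold
from .preprocess import collapse_probes, define_universe, drop_unannotated
from .preservation import (preservation_ranking, preservation_statistics,
                           quality_statistics)
from .traits import (diff_expression_vs_connectivity, me_trait_correlations,
                     trait_summary)

logger = logging.getLogger("coexnet")

# fixed offsets fanning the master seed out to stages
_SEED_DENSITY = 11
_SEED_PRESERVATION = 23
_SEED_QUALITY = 29
_SEED_BOOTSTRAP = 37


@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters of a full two-region run.

    ``beta=None`` selects the soft threshold automatically by the
    scale-free criterion (``r2_cut``); the default of 14 is the
    conventional signed-network choice for these data sizes.
    """

    expr_ref: str
    expr_test: str
    out_dir: str
    annotation: str | None = None
    traits: str | None = None
    gene_sets: str | None = None

    beta: int | None = 14
    r2_cut: float = 0.80
    min_module_size: int = 10
    cut_height_frac: float = 0.85
    n_perm_density: int = 10_000
    alpha_density: float = 0.01
    n_perm_preservation: int = 200
    match_p: float = 0.05
    fdr_max: float = 0.15
    min_term_genes: int = 3
    meta_module_k: int = 3
    n_boot: int = 2000
    seed: int = 1

    def validate(self) -> None:
        for name, path in [("expr_ref", self.expr_ref),
                           ("expr_test", self.expr_test),
                           ("annotation", self.annotation),
                           ("traits", self.traits),
                           ("gene_sets", self.gene_sets)]:
            if path is not None and not Path(path).is_file():
                raise FileNotFoundError(f"{name}: no such file: {path}")
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.alpha_density < 1:
            raise ValueError("alpha_density must be in (0, 1)")
        if not 0 < self.r2_cut <= 1:
            raise ValueError("r2_cut must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.n_perm_density < 1 or self.n_perm_preservation < 1:
            raise ValueError("permutation counts must be >= 1")
        if not 0 < self.match_p <= 1:
            raise ValueError("match_p must be in (0, 1]")
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def param_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns key results and artifact paths.

    All declared artifacts are written under ``config.out_dir``. The
    returned dict exposes the in-memory objects (assignments, reports)
    for programmatic use.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    cio.write_json({"version": __version__, "seed": seed,
                    "param_hash": config.param_hash(),
                    "config": config.to_dict()}, out / "run_meta.json")

    # ------------------------------------------------------------ preprocess
    logger.info("loading expression data")
    expr_ref = cio.read_expression(config.expr_ref)
    expr_test = cio.read_expression(config.expr_test)
    if config.annotation is not None:
        annotation = cio.read_annotation(config.annotation)
        expr_ref = drop_unannotated(expr_ref, annotation)
        expr_ref, probe_map = collapse_probes(expr_ref, annotation)
        expr_test = drop_unannotated(expr_test, annotation)
        expr_test, _ = collapse_probes(expr_test, annotation)
        probe_map.to_csv(out / "probe_map.tsv", sep="\t")
    shared = expr_ref.index.intersection(expr_test.index)
    expr_ref, expr_test = expr_ref.loc[shared], expr_test.loc[shared]
    universe = define_universe(expr_ref)
    pd.Series(universe, name="gene").to_csv(
        out / "universe.tsv", sep="\t", index=False)

    # -------------------------------------------------------- soft threshold
    if config.beta is None:
        logger.info("selecting soft threshold")
        st = pick_soft_threshold(expr_ref, r2_cut=config.r2_cut)
        beta = st.beta
        st.fit_table.to_csv(out / "soft_threshold.tsv", sep="\t")
    else:
        beta = config.beta
    logger.info("beta = %d", beta)

    # --------------------------------------------------------- density filter
    logger.info("iterative density filter (reference region)")
    filt = iterative_filter(
        expr_ref, beta,
        min_module_size=config.min_module_size,
        n_perm=config.n_perm_density,
        alpha=config.alpha_density,
        seed=seed + _SEED_DENSITY,
        cut_height_frac=config.cut_height_frac,
    )
    cio.write_jsonl(filt.log, out / "filter_log.jsonl")
    if filt.network is None or filt.assignment.empty:
        warnings.warn("empty network after filtering; nothing more to do")
        return {"out_dir": str(out), "assignment_ref": filt.assignment,
                "filter": filt}
    assign_ref = filt.assignment
    cio.write_assignment(assign_ref, out / "assignment_ref.tsv")
    filt.density.to_csv(out / "density_test.tsv", sep="\t")
    final_genes = assign_ref.index

    # --------------------------------------- rebuild test network, same genes
    logger.info("building test-region network on %d surviving genes",
                len(final_genes))
    expr_ref_f = expr_ref.loc[final_genes]
    expr_test_f = expr_test.loc[final_genes]
    net_test = build_network(expr_test_f, beta)
    det_test = cluster_and_cut(net_test.dissimilarity,
                               min_module_size=config.min_module_size,
                               cut_height_frac=config.cut_height_frac)
    assign_test = match_labels(assign_ref, det_test.labels,
                               p_threshold=config.match_p)
    cio.write_assignment(assign_test, out / "assignment_test.tsv")

    table = overlap_table(assign_ref, assign_test)
    table.counts.to_csv(out / "overlap_counts.csv")
    table.p_values.to_csv(out / "overlap_p.csv")
    background_accounting(assign_ref, assign_test).to_csv(
        out / "background_accounting.csv")

    # --------------------------------------------------------- module metrics
    logger.info("module eigengenes and connectivity")
    es_ref = module_eigengenes(expr_ref_f, assign_ref)
    es_ref.eigengenes.to_csv(out / "eigengenes_ref.tsv", sep="\t")
    conn_ref = connectivity_table(expr_ref_f, filt.network.adjacency
                                  .loc[final_genes, final_genes], assign_ref)
    conn_ref.to_csv(out / "connectivity_ref.tsv", sep="\t")
    conn_test = connectivity_table(expr_test_f, net_test.adjacency,
                                   assign_test)
    conn_test.to_csv(out / "connectivity_test.tsv", sep="\t")

    meta = None
    if es_ref.eigengenes.shape[0] >= 2:
        k = min(config.meta_module_k, es_ref.eigengenes.shape[0])
        meta = meta_modules(es_ref, k=k)
        meta.me_correlation.to_csv(out / "me_correlation.tsv", sep="\t")
        meta.labels.to_csv(out / "meta_modules.tsv", sep="\t")

    # ------------------------------------------------------------ preservation
    logger.info("preservation statistics (%d permutations)",
                config.n_perm_preservation)
    pres = preservation_statistics(
        expr_ref_f, expr_test_f, assign_ref, beta,
        n_perm=config.n_perm_preservation,
        seed=seed + _SEED_PRESERVATION,
    )
    pres.summary.to_csv(out / "preservation_summary.csv")
    pres.observed.to_csv(out / "preservation_observed.csv")
    pres.z.to_csv(out / "preservation_z.csv")
    ranking = preservation_ranking(pres)
    ranking.to_csv(out / "preservation_ranking.csv")

    qual = quality_statistics(
        expr_ref_f, assign_ref, beta,
        n_perm=config.n_perm_preservation,
        seed=seed + _SEED_QUALITY,
    )
    qual.summary.to_csv(out / "quality_summary.csv")

    # ------------------------------------------------------------------ traits
    trait_report = trait_means = None
    if config.traits is not None:
        logger.info("eigengene-trait correlations")
        traits = cio.read_traits(config.traits)
        trait_report = me_trait_correlations(es_ref.eigengenes, traits)
        trait_report.r.to_csv(out / "trait_correlations_r.csv")
        trait_report.p.to_csv(out / "trait_correlations_p.csv")
        trait_report.q.to_csv(out / "trait_correlations_q.csv")
        trait_means = trait_summary(trait_report, n_boot=config.n_boot,
                                    seed=seed + _SEED_BOOTSTRAP)
        trait_means.to_csv(out / "trait_summary.csv")

    # --------------------------------------- differential expr / connectivity
    diff = diff_expression_vs_connectivity(
        expr_ref_f, expr_test_f,
        compute_kin(filt.network.adjacency.loc[final_genes, final_genes],
                    assign_ref),
        compute_kin(net_test.adjacency, assign_ref.loc[final_genes]),
    )
    diff.table.to_csv(out / "differential.csv")

    # -------------------------------------------------------------- enrichment
    enriched = None
    if config.gene_sets is not None:
        logger.info("term enrichment")
        sets = cio.read_gmt(config.gene_sets)
        kme_ref = compute_kme(expr_ref_f, es_ref)
        raw = enrichment_table(assign_ref, sets, universe)
        enriched = term_significance(
            filter_terms(raw, fdr_max=config.fdr_max,
                         min_genes=config.min_term_genes),
            kme_ref,
        )
        export_enrichment(enriched).to_csv(out / "enrichment.csv",
                                           index=False)

    # ----------------------------------------------------------------- report
    report = {
        "beta": beta,
        "n_genes_input": int(len(shared)),
        "n_genes_final": int(len(final_genes)),
        "n_modules_ref": int(assign_ref[assign_ref != GREY].nunique()),
        "n_modules_test": int(assign_test[assign_test != GREY].nunique()),
        "n_grey_test": int((assign_test == GREY).sum()),
        "filter_iterations": len(filt.log),
        "z_summary": {m: float(v) for m, v in
                      pres.summary["z_summary"].items()},
        "quality_z_summary": {m: float(v) for m, v in
                              qual.summary["z_summary"].items()},
    }
    cio.write_json(report, out / "report.json")

    return {
        "out_dir": str(out),
        "beta": beta,
        "expr_ref": expr_ref_f,
        "expr_test": expr_test_f,
        "universe": universe,
        "filter": filt,
        "assignment_ref": assign_ref,
        "assignment_test": assign_test,
        "overlap": table,
        "eigengenes_ref": es_ref,
        "meta_modules": meta,
        "preservation": pres,
        "quality": qual,
        "ranking": ranking,
        "trait_report": trait_report,
        "trait_summary": trait_means,
        "differential": diff,
        "enrichment": enriched,
        "report": report,
    }


def simulate_to_dir(design, out_dir: str | Path, traits: bool = True,
                    gene_sets: bool = True) -> dict[str, str]:
    """Write a synthetic two-region dataset as pipeline-ready text files.

    Returns the path mapping suitable for building a PipelineConfig.
    """
    from .simulate import (generate_gene_sets, generate_traits,
                           generate_two_region_dataset)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = generate_two_region_dataset(design)
    paths = {
        "expr_ref": str(out / "expr_regionA.tsv"),
        "expr_test": str(out / "expr_regionB.tsv"),
    }
    cio.write_expression(data.expr_a, paths["expr_ref"])
    cio.write_expression(data.expr_b, paths["expr_test"])
    cio.write_assignment(data.truth_a, out / "truth_regionA.tsv")
    cio.write_assignment(data.truth_b, out / "truth_regionB.tsv")
    if traits:
        tr = generate_traits(data.factors_a, design.trait_specs,
                             seed=design.seed + 1)
        paths["traits"] = str(out / "traits.tsv")
        cio.write_traits(tr, paths["traits"])
    if gene_sets:
        gs = generate_gene_sets(data.truth_a, data.design.module_names[0],
                                seed=design.seed + 2)
        paths["gene_sets"] = str(out / "gene_sets.gmt")
        cio.write_gmt(gs, paths["gene_sets"])
    return paths
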