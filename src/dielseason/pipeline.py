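"""End-to-end pipeline orchestration and per-gene visualization export.

Stages run in a fixed order — normalize, screen, DEI, cluster, phase,
enrich, motifs, catalog — each writing TSV outputs into the run directory
and recording its parameters and output hashes in a JSON manifest, so any
stage can be audited or re-run from prior outputs.  The export stage
produces the long-format per-gene expression table and rDEI scatter data
behind gene-level visualization, plus mean +/- SD daily curves colored
blue (SD) / orange (EQ) / red (LD).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as catalog_mod
from . import cluster as cluster_mod
from . import dei as dei_mod
from . import enrich as enrich_mod
from . import motifs as motifs_mod
from . import phase as phase_mod
from .experiment import TimeCourseExperiment, mean_by_timepoint
from .normalize import cpm, tmm_factors
from .screen import screen

log = logging.getLogger("dielseason")

PHOTOPERIOD_COLORS = {"SD": "tab:blue", "EQ": "tab:orange", "LD": "tab:red"}


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; every threshold has the
    pipeline's standard default."""

    counts: str = ""
    design: str = ""
    spikeins: str | None = None
    gmt: str | None = None
    motifs: str | None = None
    motif_format: str = "jaspar"
    fasta: str | None = None
    gff3: str | None = None
    catalog: str | None = None
    outdir: str = "dielseason_run"

    alpha: float = 0.2
    use_fdr: bool = False
    fdr: float = 0.05
    cut: float = 0.82
    deep_splits: tuple[int, ...] = (2, 3)
    min_cluster_size: int = 20
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    motif_threshold: float = 8.0
    gsea_min_size: int = 20
    gsea_max_size: int = 500
    ora_min_size: int = 10
    ora_max_size: int = 500
    dei_exponent: float = 4.0
    n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for attr in ("counts", "design"):
            p = getattr(cfg, attr)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config {attr} file missing: {p!r}")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "config": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()}}

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"].append({
            "stage": stage, "params": params,
            "outputs": {f.name: _sha256(f) for f in files if f.exists()},
        })
        log.info("stage %s complete (%d outputs)", stage, len(files))

    exp = TimeCourseExperiment.from_files(config.counts, config.design,
                                          config.spikeins)

    # 1. normalize ----------------------------------------------------------
    factors = tmm_factors(exp)
    norm = cpm(exp, factors)
    f_factors = out / "tmm_factors.tsv"
    factors.to_frame().to_csv(f_factors, sep="\t")
    f_cpm = out / "cpm.tsv"
    norm.cpm.to_csv(f_cpm, sep="\t")
    record("normalize", {"n_genes": int(exp.counts.shape[0])},
           [f_factors, f_cpm])

    # 2. screen -------------------------------------------------------------
    gene_set, comparisons = screen(exp, alpha=config.alpha,
                                   use_fdr=config.use_fdr)
    comp_files = []
    for comp in comparisons:
        name = f"de_{comp.pair[0]}_vs_{comp.pair[1]}_ZT{int(comp.zt):02d}.tsv"
        path = out / name
        comp.table.to_csv(path, sep="\t")
        comp_files.append(path)
    f_union = out / "photoperiodic_genes.tsv"
    pd.Series(sorted(gene_set.genes), name="gene_id").to_csv(
        f_union, sep="\t", index=False)
    record("screen", {"alpha": config.alpha, "use_fdr": config.use_fdr,
                      "n_comparisons": len(comparisons),
                      "n_photoperiodic": len(gene_set.genes)},
           comp_files + [f_union])

    # 3. DEI ----------------------------------------------------------------
    mean_expr = mean_by_timepoint(norm.cpm.loc[~exp.spikein], exp.design)
    dei_table = dei_mod.build_dei_table(mean_expr, exponent=config.dei_exponent)
    f_dei = out / "dei.tsv"
    dei_table.to_csv(f_dei, sep="\t")
    record("dei", {"exponent": config.dei_exponent}, [f_dei])

    genes = [g for g in gene_set.genes if g in mean_expr.index]
    empty_downstream = len(genes) == 0

    # 4. cluster ------------------------------------------------------------
    f_members = out / "cluster_membership.tsv"
    f_newick = out / "exemplar_dendrogram.nwk"
    hierarchy = None
    if not empty_downstream:
        patterns = cluster_mod.pattern_matrix(mean_expr, genes)
        hierarchy = cluster_mod.cluster_genes(
            patterns, cut=config.cut, min_cluster_size=config.min_cluster_size,
            deep_splits=config.deep_splits)
        member = hierarchy.membership.copy()
        exset = set(hierarchy.exemplars.values())
        member["is_exemplar"] = member.index.isin(exset)
        member.to_csv(f_members, sep="\t")
        f_newick.write_text(hierarchy.dendrogram.to_newick())
    else:
        pd.DataFrame(columns=["ap_cluster", "major_cluster", "subgroup_d2",
                              "subgroup_d3", "is_exemplar"]).to_csv(
            f_members, sep="\t")
        f_newick.write_text(";")
    record("cluster", {"cut": config.cut,
                       "deep_splits": list(config.deep_splits),
                       "n_genes": len(genes)}, [f_members, f_newick])

    # 5. phase --------------------------------------------------------------
    f_phase = out / "phase.tsv"
    if not empty_downstream:
        ptab = phase_mod.phase_table(mean_expr.loc[genes])
    else:
        ptab = pd.DataFrame(columns=["gene_id", "photoperiod", "phase_ls",
                                     "phase_jtk", "phase_combined",
                                     "p_ls", "p_jtk", "antipodal"])
    ptab.to_csv(f_phase, sep="\t", index=False)
    record("phase", {"n_genes": len(genes)}, [f_phase])

    # 6. enrich -------------------------------------------------------------
    f_gsea = out / "gsea.tsv"
    f_ridge = out / "gsea_leading_edge.tsv"
    params: dict = {"configured": bool(config.gmt)}
    if config.gmt and not empty_downstream:
        sets = enrich_mod.read_gmt(config.gmt)
        ranking = dei_table.loc[genes, "log2_rDEI_SD_LD"].dropna()
        res = enrich_mod.gsea_preranked(
            ranking, sets, n_perm=config.n_perm, seed=config.seed,
            min_size=config.gsea_min_size, max_size=config.gsea_max_size)
        res.table.to_csv(f_gsea, sep="\t")
        ridge = [(term, g, float(ranking.get(g, np.nan)))
                 for term, lead in res.leading_edges.items() for g in lead]
        pd.DataFrame(ridge, columns=["term", "gene_id", "ranking_value"]
                     ).to_csv(f_ridge, sep="\t", index=False)
        params["n_sets_tested"] = int(len(res.table))
    else:
        pd.DataFrame(columns=["term", "size", "ES", "NES", "p", "fdr"]
                     ).to_csv(f_gsea, sep="\t", index=False)
        pd.DataFrame(columns=["term", "gene_id", "ranking_value"]
                     ).to_csv(f_ridge, sep="\t", index=False)
    record("enrich", params, [f_gsea, f_ridge])

    # 7. motifs -------------------------------------------------------------
    f_motif = out / "motif_enrichment.tsv"
    params = {"configured": bool(config.fasta and config.gff3 and config.motifs)}
    if params["configured"] and not empty_downstream and hierarchy is not None:
        promoters = motifs_mod.extract_promoters(
            config.fasta, config.gff3, config.promoter_upstream,
            config.promoter_downstream)
        pwms = motifs_mod.load_motifs(config.motifs, config.motif_format)
        universe = [g for g in mean_expr.index if g in promoters]
        blocks = []
        for sg, members in hierarchy.subgroups(depth=config.deep_splits[-1]).items():
            table = motifs_mod.motif_enrichment(
                members, universe, promoters, pwms, config.motif_threshold)
            table = table.assign(subgroup=sg)
            blocks.append(table.reset_index())
        res = (pd.concat(blocks, ignore_index=True) if blocks
               else pd.DataFrame())
        res.to_csv(f_motif, sep="\t", index=False)
    else:
        pd.DataFrame(columns=["motif", "k", "n", "K", "N", "fold", "p",
                              "fdr", "subgroup"]).to_csv(
            f_motif, sep="\t", index=False)
    record("motifs", params, [f_motif])

    # 8. catalog ------------------------------------------------------------
    f_groups = out / "catalog_group_scores.tsv"
    f_steps = out / "catalog_step_shading.tsv"
    params = {"configured": bool(config.catalog)}
    if config.catalog:
        cat = pd.read_csv(config.catalog, sep="\t")
        blocks = []
        for grouping in ("effect", "function", "branch"):
            if cat[grouping].notna().any():
                scores = catalog_mod.score_catalog(cat, dei_table, grouping)
                blocks.append(scores.groups.reset_index().rename(
                    columns={grouping: "group"}).assign(grouping=grouping))
        pd.concat(blocks, ignore_index=True).to_csv(f_groups, sep="\t",
                                                    index=False)
        catalog_mod.score_catalog(cat, dei_table, "branch").steps.to_csv(
            f_steps, sep="\t")
    else:
        pd.DataFrame(columns=["group", "n", "mean_log2_rdei",
                              "median_log2_rdei", "W", "p", "stars",
                              "grouping"]).to_csv(f_groups, sep="\t",
                                                  index=False)
        pd.DataFrame(columns=["step_label", "n_genes", "shading",
                              "consistent"]).to_csv(f_steps, sep="\t",
                                                    index=False)
    record("catalog", params, [f_groups, f_steps])

    f_manifest = out / "manifest.json"
    f_manifest.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# visualization export
# ---------------------------------------------------------------------------

def export_photograph(expression: pd.DataFrame, design: pd.DataFrame,
                      dei_table: pd.DataFrame,
                      gene_ids: list[str] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format expression plus an rDEI scatter table for plotting.

    Unknown gene ids are reported with a warning, not fatal; duplicates
    are dropped.  Returns ``(long_table, rdei_table)``.
    """
    import warnings as _warnings

    if gene_ids is None:
        gene_ids = list(expression.index)
    seen, ordered = set(), []
    for g in gene_ids:
        if g in seen:
            _warnings.warn(f"duplicate gene id {g!r}; deduplicated")
        else:
            seen.add(g)
            ordered.append(g)
    unknown = [g for g in ordered if g not in expression.index]
    if unknown:
        _warnings.warn(f"{len(unknown)} unknown gene ids skipped: "
                       f"{unknown[:5]}")
    ordered = [g for g in ordered if g in expression.index]

    rows = []
    for g in ordered:
        for lib, meta in design.iterrows():
            rows.append((g, meta["photoperiod"], float(meta["zt"]),
                         int(meta["replicate"]), float(expression.loc[g, lib])))
    long = pd.DataFrame(rows, columns=["gene_id", "photoperiod", "zt",
                                       "replicate", "expression"])
    cols = [c for c in ("rDEI_SD_LD", "log2_rDEI_SD_LD") if c in dei_table]
    scatter = dei_table.loc[[g for g in ordered if g in dei_table.index],
                            cols].copy()
    return long, scatter


def plot_gene(long_table: pd.DataFrame, gene_id: str, path: str | Path
              ) -> None:
    """Mean +/- SD daily expression curves, one line per photoperiod."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = long_table[long_table["gene_id"] == gene_id]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for pp, color in PHOTOPERIOD_COLORS.items():
        block = sub[sub["photoperiod"] == pp]
        if block.empty:
            continue
        agg = block.groupby("zt")["expression"].agg(["mean", "std"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["std"].fillna(0),
                    label=pp, color=color, marker="o", capsize=2)
    ax.set_xlabel("zeitgeber time (h)")
    ax.set_ylabel("expression (CPM)")
    ax.set_title(gene_id)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
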