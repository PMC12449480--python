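"""End-to-end synthetic study: simulate a cohort, train expression models,
run both association scans, fine-map, colocalize, estimate mediated
heritability, and tally the comparisons.

The default configuration is the package's standing study condition:
a 400-individual reference panel (within the tissue sample-size range of
large post-mortem expression resources), 100,000-individual GWAS, 20 genes
with 2 isoforms each on 2 chromosomes, moderate cis-heritability (0.25)
with 2 causal cis-SNPs per heritable isoform, block LD (rho = 0.8), ~30% of
genes trait-mediated through a single isoform (half of those with an
opposing second isoform that cancels the gene-level genetic signal), and a
polygenic direct-effect background.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .assoc import (
    burden_test,
    effective_sample_increase,
    fdr_adjust,
    harmonize_gwas,
    is_significant,
    permutation_test,
    two_stage_adjust,
)
from .expr_models import residualize_expression, train_models
from .finemap import compute_pips, group_overlapping, induced_correlation
from .mediation import compute_expression_scores, compute_ld_scores, lasso_eqtl_effects, mesc_fit
from .qtl_coloc import colocalize_feature, map_cis_qtl
from .report import define_gwas_loci, percent_increase, tag_loci
from .syndata import (
    GeneConfig,
    LDProfile,
    assign_trait_effects,
    estimate_ld,
    filter_variants,
    make_annotation,
    make_snp_map,
    simulate_genotypes,
    simulate_isoform_expression,
)
from .types import AssociationRecord

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    # cohort
    n_ref: int = 400
    n_gwas: int = 100_000
    n_chrom: int = 2
    snps_per_chrom: int = 150
    snp_spacing: int = 20_000
    block_size: int = 15
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    # transcriptome
    n_genes: int = 20
    isoforms_per_gene: int = 2
    n_causal: int = 2
    h2_cis: float = 0.25
    resid_cor: float = 0.3
    n_covariates: int = 5
    covariate_effect_sd: float = 0.3
    # trait architecture
    frac_mediated: float = 0.3
    opposing_frac: float = 0.5  # of mediated genes: second isoform cancels at gene level
    h2_med_target: float = 0.15
    h2_direct: float = 0.10
    # analysis settings
    k_folds: int = 10
    alpha: float = 0.05
    permutation_B: int = 10_000
    fine_prior_variance: float = 40.0
    fine_max_causal: int = 1
    coloc_max_causal: int = 2
    mediation_blocks: int = 20
    cis_window: int = 1_000_000


@dataclass
class PipelineResult:
    records_gene: list
    records_iso: list
    finemap_table: pd.DataFrame
    coloc_table: pd.DataFrame
    qtl_table: pd.DataFrame
    mediation: dict
    loci_table: pd.DataFrame
    tallies: dict
    truth: object
    manifest: dict


def _records_frame(records: list[AssociationRecord], alpha: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "level": [r.level for r in records],
            "z": [r.z_assoc for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_screen": [r.p_gene_screen for r in records],
            "p_fwer": [r.p_fwer_within for r in records],
            "p_fdr": [r.p_fdr for r in records],
            "p_perm": [r.p_perm for r in records],
            "chisq": [r.chisq for r in records],
            "significant": [is_significant(r, alpha) for r in records],
        }
    )


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic study; optionally write all outputs to outdir."""
    cfg = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2**31 - 1)]
    rng = np.random.default_rng(seeds[0])

    # --- simulate cohort -------------------------------------------------
    maps = [
        make_snp_map(cfg.snps_per_chrom, chrom=str(c + 1), spacing=cfg.snp_spacing)
        for c in range(cfg.n_chrom)
    ]
    snp_map_table = pd.concat([m.table for m in maps], ignore_index=True)
    from .types import SNPMap

    snp_map = SNPMap(snp_map_table)
    panel = simulate_genotypes(
        cfg.n_ref, snp_map, cfg.maf_range, LDProfile(cfg.block_size, cfg.rho), seed=seeds[1]
    )
    panel, _filter_report = filter_variants(panel, maf_min=cfg.maf_min, hwe_p_min=cfg.hwe_p_min)
    annotation = make_annotation(cfg.n_genes, panel.snp_map, cfg.isoforms_per_gene)

    n_med = round(cfg.frac_mediated * cfg.n_genes)
    med_genes = list(rng.choice(annotation.genes["gene_id"], size=n_med, replace=False))
    n_opp = round(cfg.opposing_frac * n_med)
    opp_genes = set(med_genes[:n_opp])
    gene_configs = {}
    for gid in annotation.genes["gene_id"]:
        gene_configs[gid] = GeneConfig(
            n_isoforms=cfg.isoforms_per_gene,
            n_causal=cfg.n_causal,
            h2_cis=cfg.h2_cis,
            resid_cor=cfg.resid_cor,
            opposing=gid in opp_genes,
        )
    expr_iso, expr_gene, truth = simulate_isoform_expression(
        panel, annotation, gene_configs, seed=seeds[2],
        n_covariates=cfg.n_covariates, covariate_effect_sd=cfg.covariate_effect_sd,
        cis_window=cfg.cis_window,
    )
    ld = estimate_ld(panel)

    # mediated architecture: first isoform of each mediated gene drives the trait
    alpha_mag = math.sqrt(cfg.h2_med_target / max(1, n_med) / max(cfg.h2_cis, 1e-9))
    alpha = {tid: 0.0 for tid in expr_iso.feature_ids}
    for gid in med_genes:
        tid = annotation.transcripts_of(gid)[0]
        alpha[tid] = alpha_mag * (1 if rng.random() < 0.5 else -1)
    direct = np.zeros(panel.m)
    n_direct = max(1, panel.m // 5)
    direct_idx = rng.choice(panel.m, size=n_direct, replace=False)
    direct[direct_idx] = rng.standard_normal(n_direct) * math.sqrt(cfg.h2_direct / n_direct)
    truth = assign_trait_effects(truth, ld, alpha, direct)

    from .syndata import simulate_gwas_summary

    gwas = simulate_gwas_summary(ld, truth, cfg.n_gwas, seed=seeds[3], snp_map=panel.snp_map)
    gwas = harmonize_gwas(gwas, panel.snp_map, drop_ambiguous=False)

    # --- expression models + association --------------------------------
    iso_resid = residualize_expression(expr_iso)
    gene_resid = residualize_expression(expr_gene)
    db = train_models(panel, iso_resid, gene_resid, annotation, cfg.k_folds, seed=seeds[4], cis_window=cfg.cis_window)

    from .assoc import DegenerateModelError

    records_gene, records_iso = [], []
    for out, level in ((records_gene, "gene"), (records_iso, "isoform")):
        for m in db.by_level(level, retained_only=True):
            try:
                out.append(burden_test(m, gwas, ld))
            except DegenerateModelError:
                continue  # all-zero refit weights: untestable feature
    fdr_adjust(records_gene)
    two_stage_adjust(records_iso, alpha=cfg.alpha)
    for rec, level in [(records_gene, "gene"), (records_iso, "isoform")]:
        for r in rec:
            if is_significant(r, cfg.alpha):
                r.p_perm = permutation_test(
                    db.get(r.feature_id, level), gwas, ld, B=cfg.permutation_B, seed=seeds[5]
                )
    sig_gene = [r for r in records_gene if is_significant(r, cfg.alpha)]
    sig_iso = [r for r in records_iso if is_significant(r, cfg.alpha)]

    # --- fine-mapping ----------------------------------------------------
    fm_rows = []
    for li, locus in enumerate(group_overlapping(sig_gene + sig_iso, annotation, cfg.cis_window)):
        models = [db.get(r.feature_id, r.level) for r in locus]
        try:
            omega = induced_correlation(models, ld)
        except ValueError:
            continue
        zmap = {r.feature_id: r.z_assoc for r in locus}
        z = np.array([zmap[f] for f in omega.feature_ids])
        res = compute_pips(
            z, omega, prior_variance=cfg.fine_prior_variance, max_causal=cfg.fine_max_causal
        )
        for fid, pip in zip(res.feature_ids, res.pip):
            fm_rows.append(
                {
                    "locus_id": f"fm_{li:03d}",
                    "feature_id": fid,
                    "pip": pip,
                    "in_credible_set": fid in res.credible_set,
                    "level": 0.90,
                }
            )
    finemap_table = pd.DataFrame(fm_rows, columns=["locus_id", "feature_id", "pip", "in_credible_set", "level"])

    # --- GWAS loci + tagging --------------------------------------------
    loci = define_gwas_loci(gwas, clump_distance=cfg.cis_window)
    tags = tag_loci(
        loci, {"twas": sig_gene, "isotwas": sig_iso}, annotation, window=cfg.cis_window
    )
    loci_table = pd.DataFrame(
        [
            {"locus_id": l.locus_id, "chrom": l.chrom, "start": l.start, "end": l.end,
             "lead_snp": l.lead_snp, "lead_p": l.lead_p}
            for l in loci
        ]
    )

    # --- QTL + colocalization -------------------------------------------
    qtl_iso = map_cis_qtl(panel, iso_resid, annotation, window=cfg.cis_window)
    qtl_gene = map_cis_qtl(panel, gene_resid, annotation, window=cfg.cis_window)
    qtl_table = pd.concat(
        [qtl_gene.assign(level="gene"), qtl_iso.assign(level="isoform")], ignore_index=True
    )
    gwas_t = gwas.table.set_index("snp_id")
    gwas_p = pd.Series(2.0 * stats.norm.sf(np.abs(gwas_t["z"])), index=gwas_t.index)
    ld_index = {s: i for i, s in enumerate(ld.snp_ids)}
    coloc_rows = []
    for recs, qtl in ((sig_gene, qtl_gene), (sig_iso, qtl_iso)):
        for r in recs:
            sub = qtl[qtl["feature_id"] == r.feature_id]
            snps = [s for s in sub["snp_id"] if s in ld_index]
            if len(snps) < 2:
                continue
            sub = sub.set_index("snp_id").loc[snps]
            qz = (sub["beta"] / sub["se"]).to_numpy()
            idx = [ld_index[s] for s in snps]
            res = colocalize_feature(
                r.feature_id,
                r.gene_id or r.feature_id,
                gwas_t.loc[snps, "z"].to_numpy(),
                gwas_p.loc[snps].to_numpy(),
                qz,
                sub["p"].to_numpy(),
                ld.r[np.ix_(idx, idx)],
                prior_variance=cfg.fine_prior_variance,
                max_causal=cfg.coloc_max_causal,
            )
            coloc_rows.append(
                {"locus_id": res.locus_id, "feature_id": res.feature_id, "level": r.level,
                 "clpp": res.clpp, "gwas_min_p": res.gwas_min_p, "qtl_min_p": res.qtl_min_p,
                 "colocalized": res.colocalized}
            )
    coloc_table = pd.DataFrame(
        coloc_rows,
        columns=["locus_id", "feature_id", "level", "clpp", "gwas_min_p", "qtl_min_p", "colocalized"],
    )

    # --- mediated heritability ------------------------------------------
    mediation = {}
    for level, resid in (("gene", gene_resid), ("isoform", iso_resid)):
        effects = lasso_eqtl_effects(panel, resid, annotation, window=cfg.cis_window, seed=seeds[6])
        expr_score, total_h2cis = compute_expression_scores(effects, ld)
        scores = pd.DataFrame(
            {"snp_id": ld.snp_ids, "ld_score": compute_ld_scores(ld), "expr_score": expr_score}
        )
        try:
            est = mesc_fit(gwas, scores, total_h2cis, n_jackknife_blocks=cfg.mediation_blocks)
        except ValueError as exc:  # too few SNPs at toy scale
            mediation[level] = {"error": str(exc)}
            continue
        mediation[level] = {
            "h2": est.h2_total, "h2_med": est.h2_med, "ratio": est.ratio,
            "se": est.se_ratio, "p": est.wald_p, "flagged": est.flagged,
        }

    # --- tallies ---------------------------------------------------------
    n_sig_gene_genes = len({r.feature_id for r in sig_gene})
    n_sig_iso_genes = len({r.gene_id for r in sig_iso})
    chis_by_gene = {}
    for r in records_gene:
        chis_by_gene.setdefault(r.feature_id, [None, None])[0] = r.chisq
    for r in records_iso:
        cur = chis_by_gene.setdefault(r.gene_id, [None, None])
        cur[1] = max(cur[1] or 0.0, r.chisq)
    pairs = [(g, i) for g, i in chis_by_gene.values() if g is not None and i is not None]
    ess = None
    if len(pairs) >= 3:
        try:
            rep = effective_sample_increase(
                np.array([i for _, i in pairs]), np.array([g for g, _ in pairs])
            )
            ess = {"pct_increase": rep.pct_increase, "se": rep.se_jackknife,
                   "ci95": list(rep.ci95), "n_genes": rep.n_features_used}
        except ValueError:
            ess = None
    tallies = {
        "n_loci": len(loci),
        "n_tagged_twas": int(tags["twas"].sum()) if len(tags) else 0,
        "n_tagged_isotwas": int(tags["isotwas"].sum()) if len(tags) else 0,
        "n_tagged_both": int((tags["twas"] & tags["isotwas"]).sum()) if len(tags) else 0,
        "n_sig_genes_twas": n_sig_gene_genes,
        "n_sig_genes_isotwas": n_sig_iso_genes,
        "pct_increase_genes": (
            percent_increase(n_sig_iso_genes, n_sig_gene_genes) if n_sig_gene_genes else None
        ),
        "effective_sample": ess,
        "n_colocalized": int(coloc_table["colocalized"].sum()) if len(coloc_table) else 0,
        "h2_med_true": truth.h2_med_true,
        "h2_trait_true": truth.h2_trait,
    }
    manifest = {
        "seed": seed,
        "stage_seeds": seeds,
        "version": __version__,
        "config": asdict(cfg),
    }

    result = PipelineResult(
        records_gene, records_iso, finemap_table, coloc_table, qtl_table,
        mediation, loci_table, tallies, truth, manifest,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _records_frame(records_gene, cfg.alpha).to_csv(outdir / "assoc_gene.tsv", sep="\t", index=False)
        _records_frame(records_iso, cfg.alpha).to_csv(outdir / "assoc_isoform.tsv", sep="\t", index=False)
        finemap_table.to_csv(outdir / "finemap.tsv", sep="\t", index=False)
        qtl_table.to_csv(outdir / "qtl.tsv", sep="\t", index=False)
        coloc_table.to_csv(outdir / "coloc.tsv", sep="\t", index=False)
        loci_table.to_csv(outdir / "loci.tsv", sep="\t", index=False)
        with open(outdir / "mediation.json", "w") as fh:
            json.dump(mediation, fh, indent=2)
        with open(outdir / "tallies.json", "w") as fh:
            json.dump(tallies, fh, indent=2)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return result
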