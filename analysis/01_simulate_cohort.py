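#!/usr/bin/env python
"""Simulate the study cohort: block-LD reference panel, isoform/gene
expression with planted cis architecture, and GWAS summary statistics under
an isoform-mediated trait.

Writes the cohort tables under results/study/ for the downstream drivers.
"""

import json
import math

import numpy as np
import pandas as pd

from _common import parse_args, study_dir, write_annotation, write_expression
from twaskit import PipelineConfig
from twaskit import io as tio
from twaskit.syndata import (
    GeneConfig,
    LDProfile,
    assign_trait_effects,
    estimate_ld,
    filter_variants,
    make_annotation,
    make_snp_map,
    simulate_genotypes,
    simulate_gwas_summary,
    simulate_isoform_expression,
)
from twaskit.types import SNPMap


def main() -> None:
    args = parse_args(__doc__)
    out = study_dir(args)
    cfg = PipelineConfig()
    ss = np.random.SeedSequence(args.seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2**31 - 1)]
    rng = np.random.default_rng(seeds[0])

    maps = [
        make_snp_map(cfg.snps_per_chrom, chrom=str(c + 1), spacing=cfg.snp_spacing)
        for c in range(cfg.n_chrom)
    ]
    snp_map = SNPMap(pd.concat([m.table for m in maps], ignore_index=True))
    panel = simulate_genotypes(
        cfg.n_ref, snp_map, cfg.maf_range, LDProfile(cfg.block_size, cfg.rho), seed=seeds[1]
    )
    panel, filt = filter_variants(panel, maf_min=cfg.maf_min, hwe_p_min=cfg.hwe_p_min)
    print(f"panel: {panel.n} individuals x {panel.m} SNPs ({(~filt['kept']).sum()} filtered)")

    anno = make_annotation(cfg.n_genes, panel.snp_map, cfg.isoforms_per_gene)
    n_med = round(cfg.frac_mediated * cfg.n_genes)
    med_genes = list(rng.choice(anno.genes["gene_id"], size=n_med, replace=False))
    opp = set(med_genes[: round(cfg.opposing_frac * n_med)])
    gene_configs = {
        g: GeneConfig(cfg.isoforms_per_gene, cfg.n_causal, cfg.h2_cis, cfg.resid_cor, g in opp)
        for g in anno.genes["gene_id"]
    }
    iso, gene, truth = simulate_isoform_expression(
        panel, anno, gene_configs, seed=seeds[2],
        n_covariates=cfg.n_covariates, covariate_effect_sd=cfg.covariate_effect_sd,
    )
    ld = estimate_ld(panel)
    alpha_mag = math.sqrt(cfg.h2_med_target / max(1, n_med) / cfg.h2_cis)
    alpha = {t: 0.0 for t in iso.feature_ids}
    for gid in med_genes:
        alpha[anno.transcripts_of(gid)[0]] = alpha_mag * (1 if rng.random() < 0.5 else -1)
    direct = np.zeros(panel.m)
    idx = rng.choice(panel.m, size=max(1, panel.m // 5), replace=False)
    direct[idx] = rng.standard_normal(len(idx)) * math.sqrt(cfg.h2_direct / len(idx))
    truth = assign_trait_effects(truth, ld, alpha, direct)
    gwas = simulate_gwas_summary(ld, truth, cfg.n_gwas, seed=seeds[3], snp_map=panel.snp_map)
    print(
        f"architecture: {n_med} mediated genes ({len(opp)} opposing), "
        f"h2_med = {truth.h2_med_true:.3f}, h2_trait = {truth.h2_trait:.3f}"
    )

    tio.write_genotype_tsv(panel, out / "genotypes.tsv", out / "snp_map.tsv")
    write_annotation(anno, out)
    write_expression(iso, out / "expression_isoform.tsv")
    write_expression(gene, out / "expression_gene.tsv")
    pd.DataFrame(
        iso.covariates, columns=[f"cov{i}" for i in range(iso.covariates.shape[1])]
    ).to_csv(out / "covariates.tsv", sep="\t", index=False)
    tio.write_gwas_tsv(gwas, out / "gwas.tsv")
    meta = {
        "seed": args.seed,
        "stage_seeds": seeds,
        "mediated_isoforms": {t: a for t, a in alpha.items() if a != 0.0},
        "h2_med_true": truth.h2_med_true,
        "h2_trait_true": truth.h2_trait,
    }
    (out / "cohort_meta.json").write_text(json.dumps(meta, indent=2))
    print(f"cohort written to {out}")


if __name__ == "__main__":
    main()
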