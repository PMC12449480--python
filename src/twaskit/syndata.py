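"""Synthetic genotypes, isoform/gene expression, and GWAS summary statistics.

The generator emulates the statistical structure the downstream analysis
assumes: a reference panel with block LD, isoform expression with a planted
cis-genetic component of specified heritability, gene expression as the sum
of its isoforms, and GWAS z-scores arising from an isoform-mediated trait
architecture. Every stochastic function takes an explicit seed.

LD model: haplotypes follow a first-order Markov allele-copy chain within
blocks — allele j copies allele j-1 with probability rho, otherwise is a
fresh Bernoulli draw at that SNP's allele frequency. At equal frequencies
the adjacent-allele Pearson correlation equals rho exactly, and the implied
LD decays geometrically (rho^|i-j|) within a block; blocks are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


from .types import (
    ExpressionSet,
    GenotypePanel,
    GWASSummary,
    LDMatrix,
    SimTruth,
    SNPMap,
    TranscriptomeAnnotation,
)

__all__ = [
    "LDProfile",
    "GeneConfig",
    "make_snp_map",
    "make_annotation",
    "simulate_genotypes",
    "estimate_ld",
    "hwe_exact_test",
    "filter_variants",
    "EmptyPanelError",
    "simulate_isoform_expression",
    "assign_trait_effects",
    "simulate_gwas_summary",
]


@dataclass
class LDProfile:
    """Block-LD specification: contiguous blocks of ``block_size`` SNPs with
    adjacent-locus allele correlation ``rho`` inside each block."""

    block_size: int = 20
    rho: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1); rho >= 1 implies a degenerate LD matrix")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


@dataclass
class GeneConfig:
    """Per-gene simulation settings.

    h2_cis may be a scalar (shared by all isoforms) or a sequence of length
    n_isoforms. resid_cor is the equicorrelation of the non-genetic residuals
    across the gene's isoforms.
    """

    n_isoforms: int = 2
    n_causal: int = 2
    h2_cis: float | list[float] = 0.2
    resid_cor: float = 0.3
    opposing: bool = False  # second isoform carries the negated effect vector

    def h2_list(self) -> list[float]:
        if np.isscalar(self.h2_cis):
            return [float(self.h2_cis)] * self.n_isoforms
        h2 = list(self.h2_cis)
        if len(h2) != self.n_isoforms:
            raise ValueError("h2_cis length must equal n_isoforms")
        return h2


def make_snp_map(
    m: int,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 5_000,
    prefix: str = "rs",
) -> SNPMap:
    """Evenly spaced biallelic SNP map on one chromosome."""
    table = pd.DataFrame(
        {
            "snp_id": [f"{prefix}{chrom}_{i}" for i in range(m)],
            "chrom": chrom,
            "pos": start + spacing * np.arange(m),
            "allele_ref": "A",
            "allele_alt": "G",
        }
    )
    return SNPMap(table)


def make_annotation(
    n_genes: int,
    snp_map: SNPMap,
    isoforms_per_gene: int | list[int] = 2,
    gene_length: int = 50_000,
) -> TranscriptomeAnnotation:
    """Tile genes evenly across each chromosome of ``snp_map``.

    Gene bodies are placed so that every gene has cis-SNPs; transcript TSS
    coincides with the gene TSS (gene_start on the plus strand).
    """
    if np.isscalar(isoforms_per_gene):
        iso_counts = [int(isoforms_per_gene)] * n_genes
    else:
        iso_counts = list(isoforms_per_gene)
        if len(iso_counts) != n_genes:
            raise ValueError("isoforms_per_gene length must equal n_genes")
    chroms = list(dict.fromkeys(snp_map.chrom))
    genes, transcripts = [], []
    per_chrom = math.ceil(n_genes / len(chroms))
    g = 0
    for chrom in chroms:
        pos = snp_map.pos[snp_map.chrom == chrom]
        lo, hi = int(pos.min()), int(pos.max())
        span = max(hi - lo, 1)
        k = min(per_chrom, n_genes - g)
        for j in range(k):
            center = lo + int(span * (j + 0.5) / k)
            start = max(1, center - gene_length // 2)
            end = start + gene_length
            gid = f"GENE{g:04d}"
            genes.append(
                {
                    "gene_id": gid,
                    "chrom": chrom,
                    "strand": "+",
                    "gene_start": start,
                    "gene_end": end,
                    "tss": start,
                }
            )
            for t in range(iso_counts[g]):
                transcripts.append(
                    {"transcript_id": f"{gid}.T{t + 1}", "gene_id": gid, "tss": start}
                )
            g += 1
    return TranscriptomeAnnotation(pd.DataFrame(genes), pd.DataFrame(transcripts))


def _block_bounds(m: int, block_size: int) -> list[tuple[int, int]]:
    return [(s, min(s + block_size, m)) for s in range(0, m, block_size)]


def simulate_genotypes(
    n: int,
    snp_map: SNPMap,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_profile: LDProfile | None = None,
    seed: int = 0,
) -> GenotypePanel:
    """Draw an unphased dosage panel from the block-Markov haplotype model.

    Each individual is the sum of two independent haplotypes. Blocks never
    span chromosome boundaries. Allele frequencies are drawn uniformly from
    ``maf_range`` per SNP (the alt allele is the minor allele).
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be contained in (0, 0.5]")
    ld_profile = ld_profile or LDProfile()
    rng = np.random.default_rng(seed)
    m = len(snp_map)
    freq = rng.uniform(lo, hi, size=m)
    haps = np.empty((2 * n, m), dtype=np.int8)
    chrom = snp_map.chrom
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        for s, e in _block_bounds(len(idx), ld_profile.block_size):
            cols = idx[s:e]
            block = np.empty((2 * n, len(cols)), dtype=np.int8)
            block[:, 0] = rng.random(2 * n) < freq[cols[0]]
            for j in range(1, len(cols)):
                copy = rng.random(2 * n) < ld_profile.rho
                fresh = (rng.random(2 * n) < freq[cols[j]]).astype(np.int8)
                block[:, j] = np.where(copy, block[:, j - 1], fresh)
            haps[:, cols] = block
    dosages = (haps[0::2] + haps[1::2]).astype(float)
    return GenotypePanel(dosages, snp_map)


def estimate_ld(panel: GenotypePanel, ridge: float = 0.0) -> LDMatrix:
    """Empirical SNP correlation matrix from a panel (monomorphic SNPs rejected)."""
    sd = panel.dosages.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("panel contains monomorphic SNPs; filter first")
    r = np.corrcoef(panel.dosages, rowvar=False)
    if ridge > 0:
        r = (1 - ridge) * r + ridge * np.eye(r.shape[0])
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return LDMatrix(panel.snp_map.snp_ids, r)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test P-value.

    Conditional on the observed allele counts, heterozygote counts with the
    correct parity are enumerated and those with probability not exceeding
    the observed configuration's are summed (two-sided exact test).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # log P(het = h | allele counts) up to a shared constant
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_common = 2 * n - n_rare
    logp = np.empty(len(hets), dtype=float)
    from scipy.special import gammaln

    for i, h in enumerate(hets):
        a = (n_rare - h) // 2  # rare homozygotes
        b = (n_common - h) // 2  # common homozygotes
        logp[i] = h * math.log(2.0) - gammaln(a + 1) - gammaln(b + 1) - gammaln(h + 1)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.searchsorted(hets, n_het)]
    return float(min(1.0, p[p <= p_obs + 1e-12].sum()))


class EmptyPanelError(ValueError):
    """Raised when variant filtering removes every SNP."""


def filter_variants(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-5,
    external_maf: np.ndarray | None = None,
    external_maf_min: float = 0.01,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Apply MAF, exact-HWE, and optional external-frequency filters.

    Returns the restricted panel and a per-SNP report with pass/fail reasons.
    Thresholds mirror standard QTL pre-processing: panel MAF >= maf_min,
    exact HWE P >= hwe_p_min, and (when an external reference frequency is
    supplied) external MAF >= external_maf_min.
    """
    if not (0.0 < maf_min < 0.5):
        raise ValueError("maf_min must lie in (0, 0.5)")
    maf = panel.maf
    D = panel.dosages
    n_hom_ref = (D == 0).sum(axis=0)
    n_het = (D == 1).sum(axis=0)
    n_hom_alt = (D == 2).sum(axis=0)
    hwe_p = np.array(
        [hwe_exact_test(int(a), int(h), int(b)) for a, h, b in zip(n_hom_ref, n_het, n_hom_alt)]
    )
    pass_maf = maf >= maf_min
    pass_hwe = hwe_p >= hwe_p_min
    report = pd.DataFrame(
        {
            "snp_id": panel.snp_map.snp_ids,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass_maf": pass_maf,
            "pass_hwe": pass_hwe,
        }
    )
    keep = pass_maf & pass_hwe
    if external_maf is not None:
        ext = np.asarray(external_maf, dtype=float)
        if len(ext) != panel.m:
            raise ValueError("external_maf length mismatch")
        pass_ext = ext >= external_maf_min
        report["pass_external_maf"] = pass_ext
        keep = keep & pass_ext
    report["kept"] = keep
    if not keep.any():
        raise EmptyPanelError("all SNPs removed by variant filters")
    return panel.subset(keep), report


def _cis_mask(snp_map: SNPMap, chrom: str, start: int, end: int, window: int = 1_000_000) -> np.ndarray:
    return (snp_map.chrom == chrom) & (snp_map.pos >= start - window) & (snp_map.pos <= end + window)


def simulate_isoform_expression(
    panel: GenotypePanel,
    annotation: TranscriptomeAnnotation,
    gene_configs: dict[str, GeneConfig] | GeneConfig,
    seed: int = 0,
    n_covariates: int = 5,
    covariate_effect_sd: float = 0.0,
    cis_window: int = 1_000_000,
) -> tuple[ExpressionSet, ExpressionSet, SimTruth]:
    """Simulate isoform expression with planted cis effects; aggregate to genes.

    For isoform k of a gene: y_k = X beta_k + eps_k, with X the standardized
    cis genotypes, beta_k supported on n_causal SNPs inside the gene-body
    +/- 1 Mb window and rescaled so the realized var(X beta_k)/var(y_k)
    equals h2_cis exactly; eps_k has variance 1 - h2_cis and equicorrelation
    resid_cor across the gene's isoforms. Gene expression is the row-sum of
    its isoform columns. Optional generic covariates (standard normal, with
    N(0, covariate_effect_sd^2) loadings) are added on top and returned so
    residualization can remove them.
    """
    rng = np.random.default_rng(seed)
    if isinstance(gene_configs, GeneConfig):
        gene_configs = {g: gene_configs for g in annotation.genes["gene_id"]}
    n = panel.n
    Xs = panel.standardized()
    snp_ids = panel.snp_map.snp_ids
    iso_cols, iso_ids = [], []
    gene_cols, gene_ids = [], []
    eqtl_effects: dict[str, np.ndarray] = {}
    h2_map: dict[str, float] = {}
    covariates = rng.standard_normal((n, n_covariates)) if n_covariates else None
    for _, grow in annotation.genes.iterrows():
        gid = grow["gene_id"]
        cfg = gene_configs.get(gid)
        if cfg is None:
            continue
        mask = _cis_mask(panel.snp_map, grow["chrom"], grow["gene_start"], grow["gene_end"], cis_window)
        cis_idx = np.flatnonzero(mask)
        if cfg.n_causal > len(cis_idx):
            raise ValueError(
                f"{gid}: requested {cfg.n_causal} causal SNPs but only {len(cis_idx)} cis-SNPs"
            )
        tids = annotation.transcripts_of(gid)
        if len(tids) != cfg.n_isoforms:
            raise ValueError(f"{gid}: annotation has {len(tids)} isoforms, config says {cfg.n_isoforms}")
        h2s = cfg.h2_list()
        # correlated residuals across the gene's isoforms
        k = cfg.n_isoforms
        C = np.full((k, k), cfg.resid_cor)
        np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C)
        eps = rng.standard_normal((n, k)) @ L.T
        eps = (eps - eps.mean(axis=0)) / eps.std(axis=0)
        gsum = np.zeros(n)
        prev_beta, prev_g = None, None
        for t, (tid, h2) in enumerate(zip(tids, h2s)):
            beta = np.zeros(len(snp_ids))
            if h2 > 0 and cfg.opposing and t == 1 and prev_beta is not None:
                # opposing-isoform architecture: the gene-level genetic
                # signal cancels while each isoform keeps its own
                beta = -prev_beta
                g = -prev_g
            elif h2 > 0:
                causal = rng.choice(cis_idx, size=cfg.n_causal, replace=False)
                raw = rng.standard_normal(cfg.n_causal)
                g = Xs[:, causal] @ raw
                vg = g.var()
                if vg <= 0:
                    raise ValueError("degenerate genetic value; increase panel size")
                scale = math.sqrt(h2 / vg)
                beta[causal] = raw * scale
                g = g * scale
                prev_beta, prev_g = beta, g
            else:
                g = np.zeros(n)
            y = g + math.sqrt(max(0.0, 1.0 - h2)) * eps[:, t]
            iso_cols.append(y)
            iso_ids.append(tid)
            eqtl_effects[tid] = beta
            h2_map[tid] = float(h2)
            gsum = gsum + y
        gene_cols.append(gsum)
        gene_ids.append(gid)
    iso_values = np.column_stack(iso_cols)
    gene_values = np.column_stack(gene_cols)
    if covariates is not None and covariate_effect_sd > 0:
        gamma = rng.normal(0.0, covariate_effect_sd, size=(n_covariates, iso_values.shape[1]))
        iso_values = iso_values + covariates @ gamma
        # gene aggregation applied after covariate effects: genes inherit
        # the summed isoform covariate loadings
        gene_values = np.column_stack(
            [
                iso_values[:, [iso_ids.index(t) for t in annotation.transcripts_of(g)]].sum(axis=1)
                for g in gene_ids
            ]
        )
    truth = SimTruth(
        eqtl_effects=eqtl_effects,
        h2_cis=h2_map,
        alpha={tid: 0.0 for tid in iso_ids},
        direct_snp_effects=np.zeros(len(snp_ids)),
        h2_trait=0.0,
        h2_med_true=0.0,
        seed=seed,
    )
    truth.snp_ids = snp_ids  # alignment of effect vectors
    iso = ExpressionSet(iso_values, iso_ids, "isoform", covariates)
    gene = ExpressionSet(gene_values, gene_ids, "gene", covariates)
    return iso, gene, truth


def assign_trait_effects(
    truth: SimTruth,
    ld: LDMatrix,
    alpha: dict[str, float],
    direct_snp_effects: np.ndarray | None = None,
) -> SimTruth:
    """Fill in the trait architecture of a SimTruth in place.

    The joint standardized SNP effect is b = sum_k alpha_k beta_k + d; trait
    variance is normalized to 1, so heritabilities are quadratic forms in the
    LD matrix: h2_trait = b' V b, h2_med = b_med' V b_med.
    """
    if not np.array_equal(np.asarray(ld.snp_ids), np.asarray(truth.snp_ids)):
        raise ValueError("LD matrix SNPs must match the truth's SNP ordering")
    m = len(ld.snp_ids)
    b_med = np.zeros(m)
    for tid, a in alpha.items():
        if a != 0.0:
            b_med += a * truth.eqtl_effects[tid]
    d = np.zeros(m) if direct_snp_effects is None else np.asarray(direct_snp_effects, dtype=float)
    b = b_med + d
    V = ld.r
    h2_trait = float(b @ V @ b)
    if h2_trait > 1.0:
        raise ValueError(f"genetic variance {h2_trait:.3f} exceeds trait variance 1; shrink effects")
    truth.alpha = dict(alpha)
    truth.direct_snp_effects = d
    truth.h2_trait = h2_trait
    truth.h2_med_true = float(b_med @ V @ b_med)
    return truth


def joint_effects(truth: SimTruth) -> np.ndarray:
    """Joint standardized SNP->trait effect vector b implied by the truth."""
    m = len(truth.snp_ids)
    b = np.array(truth.direct_snp_effects, dtype=float, copy=True)
    if b.shape != (m,):
        b = np.zeros(m)
    for tid, a in truth.alpha.items():
        if a != 0.0:
            b += a * truth.eqtl_effects[tid]
    return b


def simulate_gwas_summary(
    ld: LDMatrix,
    truth: SimTruth,
    n_gwas: int,
    mode: str = "analytic_summary",
    seed: int = 0,
    snp_map: SNPMap | None = None,
) -> GWASSummary:
    """Draw GWAS summary statistics under the truth's architecture.

    analytic_summary: z ~ MVN(sqrt(n) V b, V) where b is the joint
    standardized SNP effect and V the LD matrix. individual_level: draw
    standardized genotypes from N(0, V) for n_gwas individuals, form the
    phenotype y = X b + e with residual variance 1 - h2_trait, and compute
    each SNP's marginal z from its sample correlation with y. The two modes
    agree in distribution.
    """
    rng = np.random.default_rng(seed)
    V = ld.r
    m = V.shape[0]
    b = joint_effects(truth)
    if mode == "analytic_summary":
        w, Q = np.linalg.eigh((V + V.T) / 2.0)
        if w.min() < -1e-8:
            raise ValueError("LD matrix not PSD")
        w = np.clip(w, 0.0, None)
        mean = math.sqrt(n_gwas) * (V @ b)
        z = mean + Q @ (np.sqrt(w) * rng.standard_normal(m))
    elif mode == "individual_level":
        w, Q = np.linalg.eigh((V + V.T) / 2.0)
        if w.min() < -1e-8:
            raise ValueError("LD matrix not PSD")
        w = np.clip(w, 0.0, None)
        X = rng.standard_normal((n_gwas, m)) @ (Q * np.sqrt(w)).T
        resid_sd = math.sqrt(max(0.0, 1.0 - truth.h2_trait))
        y = X @ b + resid_sd * rng.standard_normal(n_gwas)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
        r = (Xc.T @ yc) / denom
        z = r * math.sqrt(n_gwas)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    se = np.full(m, 1.0 / math.sqrt(n_gwas))
    table = pd.DataFrame(
        {
            "snp_id": ld.snp_ids,
            "z": z,
            "beta": z * se,
            "se": se,
            "n": int(n_gwas),
        }
    )
    if snp_map is not None:
        anno = snp_map.table.set_index("snp_id")
        table["chrom"] = anno.loc[table["snp_id"], "chrom"].to_numpy()
        table["pos"] = anno.loc[table["snp_id"], "pos"].to_numpy()
        table["allele_ref"] = anno.loc[table["snp_id"], "allele_ref"].to_numpy()
        table["allele_alt"] = anno.loc[table["snp_id"], "allele_alt"].to_numpy()
    return GWASSummary(table)
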