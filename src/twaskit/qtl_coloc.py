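"""cis-QTL mapping by ordinary least squares and eCAVIAR-style colocalization.

QTL mapping regresses expression on each cis-SNP's allelic dosage (0/1/2)
jointly with covariates, reporting the Wald effect, SE and P per
(feature, SNP) pair. Colocalization computes per-SNP causal posteriors for
the GWAS and the QTL signal separately under the spike-and-slab enumeration
model and sums their product over SNPs (the colocalization posterior
probability, CLPP). A feature colocalizes when the locus shows a
genome-wide-significant GWAS SNP (P < 5e-8), a strong QTL (P < 1e-6), and
CLPP > 0.01.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import spike_slab_posterior
from .types import ColocResult, ExpressionSet, GenotypePanel, LDMatrix, TranscriptomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "map_cis_qtl",
    "snp_causal_posterior",
    "clpp_score",
    "coloc_call",
    "colocalize_feature",
    "prune_duplicate_snps",
]


def map_cis_qtl(
    panel: GenotypePanel,
    expr: ExpressionSet,
    annotation: TranscriptomeAnnotation,
    covariates: np.ndarray | None = None,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Marginal cis-QTL scan: one OLS fit per (feature, cis-SNP) pair.

    The cis set is all SNPs within ``window`` of the feature's TSS
    (transcript TSS for isoforms, gene TSS for genes). Covariates enter the
    fit as regressors jointly with the SNP; by Frisch-Waugh this equals the
    slope after projecting both SNP and expression off the covariates, which
    is how it is computed. Monomorphic SNPs are skipped and logged.
    Returns a DataFrame with columns feature_id, snp_id, beta, se, p.
    """
    C = covariates if covariates is not None else expr.covariates
    n = panel.n
    ones = np.ones((n, 1))
    C = ones if C is None else np.column_stack([ones, np.asarray(C, dtype=float)])
    Q, _ = np.linalg.qr(C, mode="reduced")
    c = Q.shape[1]
    dof = n - c - 1
    if dof <= 0:
        raise ValueError("not enough residual degrees of freedom")
    D = panel.dosages
    D_res = D - Q @ (Q.T @ D)
    Y_res = expr.values - Q @ (Q.T @ expr.values)
    snp_map = panel.snp_map
    tss_by_feature: dict[str, tuple[str, int]] = {}
    if expr.level == "isoform":
        for _, row in annotation.transcripts.iterrows():
            g = annotation.gene_row(row["gene_id"])
            tss_by_feature[row["transcript_id"]] = (str(g["chrom"]), int(row["tss"]))
    else:
        for _, row in annotation.genes.iterrows():
            tss_by_feature[row["gene_id"]] = (str(row["chrom"]), int(row["tss"]))
    sxx = (D_res**2).sum(axis=0)
    mono = D.std(axis=0) == 0
    rows = []
    for f_i, fid in enumerate(expr.feature_ids):
        chrom, tss = tss_by_feature[fid]
        cis = np.flatnonzero(
            (snp_map.chrom == chrom) & (np.abs(snp_map.pos - tss) <= window)
        )
        y = Y_res[:, f_i]
        syy = float(y @ y)
        for j in cis:
            if mono[j]:
                logger.info("skipping monomorphic SNP %s", snp_map.snp_ids[j])
                continue
            sxy = float(D_res[:, j] @ y)
            beta = sxy / sxx[j]
            rss = syy - beta * sxy
            sigma2 = max(rss, 0.0) / dof
            se = math.sqrt(sigma2 / sxx[j]) if sigma2 > 0 else 0.0
            if se == 0.0:
                p = 0.0 if beta != 0 else 1.0
            else:
                p = float(2.0 * stats.t.sf(abs(beta / se), dof))
            rows.append((fid, snp_map.snp_ids[j], beta, se, p))
    return pd.DataFrame(rows, columns=["feature_id", "snp_id", "beta", "se", "p"])


def snp_causal_posterior(
    z: np.ndarray,
    V: LDMatrix | np.ndarray,
    prior_p: float | None = None,
    prior_variance: float = 40.0,
    max_causal: int = 2,
) -> np.ndarray:
    """Per-SNP marginal posterior of causality at a locus (enumeration up to
    ``max_causal`` causal SNPs; loci capped at 100 SNPs)."""
    R = V.r if isinstance(V, LDMatrix) else np.asarray(V, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(z) > 100:
        raise ValueError("locus capped at 100 SNPs for enumeration; prune first")
    marginal, _, _, _ = spike_slab_posterior(
        z, R, prior_p=prior_p, prior_variance=prior_variance, max_causal=max_causal
    )
    return marginal


def clpp_score(gwas_posterior: np.ndarray, qtl_posterior: np.ndarray) -> float:
    """Colocalization posterior probability: sum over SNPs of the product of
    the two traits' per-SNP causal posteriors."""
    a = np.asarray(gwas_posterior, dtype=float)
    b = np.asarray(qtl_posterior, dtype=float)
    if a.shape != b.shape:
        raise ValueError("posteriors must be on identical SNP lists")
    return float(np.sum(a * b))


def coloc_call(
    result: ColocResult,
    gwas_p_max: float = 5e-8,
    qtl_p_max: float = 1e-6,
    clpp_min: float = 0.01,
) -> bool:
    """Three-condition colocalization rule, all strict: GWAS P < 5e-8,
    QTL P < 1e-6, CLPP > 0.01."""
    return bool(
        result.gwas_min_p < gwas_p_max
        and result.qtl_min_p < qtl_p_max
        and result.clpp > clpp_min
    )


def prune_duplicate_snps(V: np.ndarray, r_max: float = 0.99) -> np.ndarray:
    """Greedy index selection dropping SNPs with |r| > r_max to a kept SNP."""
    m = V.shape[0]
    keep: list[int] = []
    for j in range(m):
        if all(abs(V[j, i]) <= r_max for i in keep):
            keep.append(j)
    return np.asarray(keep, dtype=int)


def colocalize_feature(
    feature_id: str,
    locus_id: str,
    gwas_z: np.ndarray,
    gwas_p: np.ndarray,
    qtl_z: np.ndarray,
    qtl_p: np.ndarray,
    V: np.ndarray,
    prior_variance: float = 40.0,
    max_causal: int = 2,
    max_snps: int = 100,
) -> ColocResult:
    """End-to-end colocalization of one feature at one locus.

    Inputs must already be on a shared SNP list. Near-duplicate SNPs
    (|r| > 0.99) are greedily pruned; if more than ``max_snps`` remain, the
    strongest by combined |z| are kept for the quadratic enumeration.
    """
    gwas_z, qtl_z = np.asarray(gwas_z, float), np.asarray(qtl_z, float)
    if not (len(gwas_z) == len(qtl_z) == V.shape[0]):
        raise ValueError("SNP sets must match across GWAS, QTL, and LD")
    keep = prune_duplicate_snps(V)
    if len(keep) > max_snps:
        score = np.abs(gwas_z[keep]) + np.abs(qtl_z[keep])
        keep = keep[np.argsort(-score)[:max_snps]]
        keep = np.sort(keep)
    Vk = V[np.ix_(keep, keep)]
    gpost = snp_causal_posterior(gwas_z[keep], Vk, prior_variance=prior_variance, max_causal=max_causal)
    qpost = snp_causal_posterior(qtl_z[keep], Vk, prior_variance=prior_variance, max_causal=max_causal)
    res = ColocResult(
        feature_id=feature_id,
        locus_id=locus_id,
        clpp=clpp_score(gpost, qpost),
        gwas_min_p=float(np.min(gwas_p)),
        qtl_min_p=float(np.min(qtl_p)),
    )
    res.colocalized = coloc_call(res)
    return res
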