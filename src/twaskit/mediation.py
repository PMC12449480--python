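"""Expression-mediated SNP-heritability estimation by score regression.

The GWAS chi-square of SNP j has expectation
1 + n * (omega * expr_score_j + gamma * ld_score_j), where
ld_score_j = sum_i r2_ij and expr_score_j smears each feature's squared cis
eQTL effects across LD: sum_features sum_i r2_ij beta_i^2. The slope omega
is the average squared feature-to-trait effect, so the expression-mediated
heritability is h2_med = omega * sum_features h2_cis, the non-mediated part
is gamma * M, and h2 = h2_med + h2_nonmed. The ratio h2_med/h2 carries a
block-jackknife SE (contiguous SNP blocks) and a Wald test of ratio = 0.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV

from .types import ExpressionSet, GenotypePanel, GWASSummary, LDMatrix, MediationEstimate, TranscriptomeAnnotation

__all__ = [
    "compute_ld_scores",
    "compute_expression_scores",
    "lasso_eqtl_effects",
    "average_score_tables",
    "mesc_fit",
]


def compute_ld_scores(V: LDMatrix) -> np.ndarray:
    """Per-SNP LD score: sum of squared correlations over the window
    (self r2 = 1 included)."""
    return (V.r**2).sum(axis=1)


def compute_expression_scores(
    eqtl_effects: dict[str, np.ndarray], V: LDMatrix
) -> tuple[np.ndarray, float]:
    """LD-smeared squared cis effects, summed over features.

    ``eqtl_effects`` maps feature -> dense effect vector aligned to V's SNPs
    on the standardized-genotype scale. Returns (per-SNP expression score,
    total cis-genetic variance sum_f beta_f' V beta_f), the latter being the
    conversion factor from the regression slope to h2_med.
    """
    R2 = V.r**2
    m = R2.shape[0]
    beta_sq = np.zeros(m)
    total_h2cis = 0.0
    for beta in eqtl_effects.values():
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (m,):
            raise ValueError("effect vector not aligned to LD matrix")
        beta_sq += beta**2
        total_h2cis += float(beta @ V.r @ beta)
    return R2 @ beta_sq, total_h2cis


def lasso_eqtl_effects(
    panel: GenotypePanel,
    expr: ExpressionSet,
    annotation: TranscriptomeAnnotation,
    window: int = 1_000_000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """LASSO-estimated cis eQTL effect vectors per feature.

    Expression is regressed on standardized cis genotypes (TSS +/- window)
    with the penalty chosen by 3-fold cross-validation; effects are returned
    dense over the panel's SNPs (zeros off the cis window), standardized
    scale.
    """
    Xs = panel.standardized()
    snp_map = panel.snp_map
    tss: dict[str, tuple[str, int]] = {}
    if expr.level == "isoform":
        for _, row in annotation.transcripts.iterrows():
            g = annotation.gene_row(row["gene_id"])
            tss[row["transcript_id"]] = (str(g["chrom"]), int(row["tss"]))
    else:
        for _, row in annotation.genes.iterrows():
            tss[row["gene_id"]] = (str(row["chrom"]), int(row["tss"]))
    out: dict[str, np.ndarray] = {}
    for f_i, fid in enumerate(expr.feature_ids):
        chrom, t = tss[fid]
        cis = np.flatnonzero((snp_map.chrom == chrom) & (np.abs(snp_map.pos - t) <= window))
        beta = np.zeros(panel.m)
        if len(cis):
            y = expr.values[:, f_i]
            if y.std() > 0:
                model = LassoCV(alphas=20, cv=3, random_state=seed, max_iter=3000, tol=1e-4)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    model.fit(Xs[:, cis], y)
                beta[cis] = model.coef_
        out[fid] = beta
    return out


def average_score_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Average expression scores across tissue replicates (snp-aligned)."""
    base = tables[0][["snp_id", "ld_score"]].copy()
    expr = np.mean([t["expr_score"].to_numpy() for t in tables], axis=0)
    base["expr_score"] = expr
    return base


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def mesc_fit(
    gwas: GWASSummary,
    scores: pd.DataFrame,
    total_h2cis: float,
    n_gwas: float | None = None,
    n_jackknife_blocks: int = 20,
) -> MediationEstimate:
    """Regress GWAS chi-square on expression and LD scores.

    ``scores`` has columns snp_id, ld_score, expr_score aligned to the GWAS
    SNPs; ``total_h2cis`` is the summed cis-genetic variance of the features
    behind the expression scores. Weighted least squares with
    heteroskedasticity weights 1/(2 * mean_j^2) from a first-pass OLS fit
    (the chi-square variance approximation), then a leave-one-block-out
    jackknife over contiguous SNP blocks for the SE of h2_med/h2 and a Wald
    test against 0.
    """
    merged = scores.merge(gwas.table[["snp_id", "z", "n"]], on="snp_id", how="inner")
    m = len(merged)
    if m < 200:
        raise ValueError(f"need >= 200 SNPs for score regression, got {m}")
    n = float(n_gwas) if n_gwas is not None else float(merged["n"].median())
    chisq = merged["z"].to_numpy() ** 2
    expr = n * merged["expr_score"].to_numpy()
    ld = n * merged["ld_score"].to_numpy()
    has_expr = np.std(expr) > 0

    def fit(idx: np.ndarray) -> tuple[float, float]:
        cols = [expr[idx], ld[idx]] if has_expr else [ld[idx]]
        X = np.column_stack([*cols, np.ones(len(idx))])
        y = chisq[idx]
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        mean = np.maximum(X @ ols, 1.0)
        coef = _wls(X, y, 1.0 / (2.0 * mean**2))
        if has_expr:
            return float(coef[0]), float(coef[1])
        return 0.0, float(coef[0])

    def components(idx: np.ndarray) -> tuple[float, float]:
        om, ga = fit(idx)
        return om * total_h2cis, ga * m  # h2_med, h2_nonmed (M = all scored SNPs)

    all_idx = np.arange(m)
    h2_med, h2_nonmed = components(all_idx)
    h2_total = h2_med + h2_nonmed
    if h2_total <= 0:
        return MediationEstimate(h2_total, h2_med, float("nan"), float("nan"), float("nan"), flagged=True)
    ratio = h2_med / h2_total
    blocks = np.array_split(all_idx, n_jackknife_blocks)
    loo = []
    for b in range(n_jackknife_blocks):
        idx = np.concatenate([blocks[i] for i in range(n_jackknife_blocks) if i != b])
        hm, hn = components(idx)
        tot = hm + hn
        loo.append(hm / tot if tot > 0 else ratio)
    loo = np.asarray(loo)
    g = len(loo)
    se = math.sqrt((g - 1) / g * float(np.sum((loo - loo.mean()) ** 2)))
    if se == 0.0:
        wald_p = 1.0 if ratio == 0.0 else 0.0
    else:
        wald_p = float(2.0 * stats.norm.sf(abs(ratio) / se))
    return MediationEstimate(h2_total, h2_med, ratio, se, wald_p)
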