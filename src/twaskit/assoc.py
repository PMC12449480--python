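"""Weighted burden tests against GWAS summary statistics, two-stage multiple
testing over genes and isoforms, permutation filtering, and the mean-chi2
effective-sample-size comparison between the isoform- and gene-level scans.

The burden statistic for a feature with cis weights w against GWAS z-scores
z with reference LD V is z_assoc = w'z / sqrt(w'Vw); under the null it is
standard normal. Isoform associations pass through two stages: ACAT
(Cauchy-combination) screening of each gene's isoform P-values with
Benjamini-Hochberg FDR across genes, then within-gene Bonferroni on the
isoforms of screened genes. A feature is transcriptome-wide significant iff
both adjusted values fall below alpha.
"""

from __future__ import annotations

import math
from itertools import permutations as iter_permutations

import numpy as np

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AssociationRecord, EffectiveSampleReport, GWASSummary, LDMatrix, SNPMap, WeightModel

__all__ = [
    "DegenerateModelError",
    "harmonize_gwas",
    "burden_test",
    "acat_combine",
    "fdr_adjust",
    "two_stage_adjust",
    "is_significant",
    "permutation_test",
    "effective_sample_increase",
]

AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class DegenerateModelError(ValueError):
    """Weight vector has (numerically) zero predicted-expression variance."""


def harmonize_gwas(gwas: GWASSummary, snp_map: SNPMap, drop_ambiguous: bool = True) -> GWASSummary:
    """Align GWAS alleles to the reference panel.

    z (and beta) are sign-flipped where the GWAS alt allele is the panel ref
    allele; SNPs with irreconcilable alleles are dropped, as are
    strand-ambiguous A/T and C/G SNPs by default.
    """
    panel = snp_map.table.set_index("snp_id")
    t = gwas.table[gwas.table["snp_id"].isin(panel.index)].copy()
    pref = panel.loc[t["snp_id"], "allele_ref"].to_numpy()
    palt = panel.loc[t["snp_id"], "allele_alt"].to_numpy()
    gref = t["allele_ref"].to_numpy()
    galt = t["allele_alt"].to_numpy()
    same = (gref == pref) & (galt == palt)
    flipped = (gref == palt) & (galt == pref)
    keep = same | flipped
    if drop_ambiguous:
        amb = np.array([(a, b) in AMBIGUOUS for a, b in zip(gref, galt)])
        keep &= ~amb
    t = t.loc[keep].copy()
    sign = np.where(flipped[keep], -1.0, 1.0)
    t["z"] = t["z"].to_numpy() * sign
    if "beta" in t.columns:
        t["beta"] = t["beta"].to_numpy() * sign
    t["allele_ref"] = pref[keep]
    t["allele_alt"] = palt[keep]
    return GWASSummary(t.reset_index(drop=True))


def _align(w: WeightModel, gwas: GWASSummary, V: LDMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    gwas_idx = {s: i for i, s in enumerate(gwas.snp_ids)}
    ld_idx = {s: i for i, s in enumerate(V.snp_ids)}
    rows = [
        (wi, gwas_idx[s], ld_idx[s])
        for s, wi in zip(w.snp_ids, w.weights)
        if s in gwas_idx and s in ld_idx and wi != 0.0
    ]
    if not rows:
        raise DegenerateModelError(f"{w.feature_id}: no overlapping weighted SNPs in GWAS/LD")
    wv = np.array([r[0] for r in rows])
    z = gwas.z[[r[1] for r in rows]]
    Vsub = V.r[np.ix_([r[2] for r in rows], [r[2] for r in rows])]
    return wv, z, Vsub


def burden_test(w: WeightModel, gwas: GWASSummary, V: LDMatrix) -> AssociationRecord:
    """Weighted burden association of one predicted feature with the GWAS trait."""
    wv, z, Vsub = _align(w, gwas, V)
    denom = float(wv @ Vsub @ wv)
    if denom <= 1e-12:
        raise DegenerateModelError(f"{w.feature_id}: w'Vw = {denom:.3g}")
    z_assoc = float(wv @ z) / math.sqrt(denom)
    p_raw = float(2.0 * stats.norm.sf(abs(z_assoc)))
    return AssociationRecord(
        feature_id=w.feature_id, level=w.level, z_assoc=z_assoc, p_raw=p_raw, gene_id=w.gene_id
    )


def acat_combine(p_values, weights=None) -> float:
    """Cauchy-combination (ACAT) of P-values; exact for a single input.

    Valid under arbitrary dependence; P-values at the 0/1 boundary are
    clamped to machine-safe values before the tangent transform.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("acat_combine requires at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    w = np.ones_like(p) if weights is None else np.asarray(list(weights), dtype=float)
    w = w / w.sum()
    t = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    return float(min(1.0, max(0.0, 0.5 - math.atan(t) / math.pi)))


def fdr_adjust(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """Benjamini-Hochberg adjustment of p_raw across features (gene-level scan)."""
    if not records:
        return records
    p = np.array([r.p_raw for r in records])
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    for r, q in zip(records, p_adj):
        r.p_fdr = float(q)
    return records


def two_stage_adjust(records: list[AssociationRecord], alpha: float = 0.05) -> list[AssociationRecord]:
    """Two-stage isoform testing: gene screen then within-gene confirmation.

    Stage 1: each gene's isoform P-values are ACAT-combined into a screening
    P, adjusted by Benjamini-Hochberg across genes (stored as p_fdr on every
    isoform of the gene). Stage 2: isoforms of stage-1-significant genes
    receive a within-gene Bonferroni P (p_fwer_within); others NaN.
    """
    if not records:
        return records
    genes: dict[str, list[AssociationRecord]] = {}
    for r in records:
        if r.gene_id is None:
            raise ValueError(f"isoform record {r.feature_id} lacks gene_id")
        genes.setdefault(r.gene_id, []).append(r)
    gene_ids = sorted(genes)
    screen = np.array([acat_combine([r.p_raw for r in genes[g]]) for g in gene_ids])
    _, screen_adj, _, _ = multipletests(screen, method="fdr_bh")
    for g, p_s, p_a in zip(gene_ids, screen, screen_adj):
        k = len(genes[g])
        stage1_pass = p_a < alpha
        for r in genes[g]:
            r.p_gene_screen = float(p_s)
            r.p_fdr = float(p_a)
            r.p_fwer_within = float(min(1.0, r.p_raw * k)) if stage1_pass else float("nan")
    return records


def is_significant(record: AssociationRecord, alpha: float = 0.05) -> bool:
    """Transcriptome-wide significance: both adjusted values below alpha.

    Gene-level records (no within-gene stage) require only p_fdr < alpha.
    """
    if not np.isfinite(record.p_fdr):
        return False
    if record.level == "gene" or not np.isfinite(record.p_fwer_within):
        ok_fwer = record.level == "gene"
        return bool(record.p_fdr < alpha and ok_fwer)
    return bool(record.p_fdr < alpha and record.p_fwer_within < alpha)


def permutation_test(
    w: WeightModel, gwas: GWASSummary, V: LDMatrix, B: int = 10_000, seed: int = 0
) -> float:
    """Permutation filter: reassign weight values to SNP positions uniformly.

    Holding z and V fixed, the weight vector's entries are permuted B times
    and the add-one estimator p = (1 + #{|z_perm| >= |z_obs|}) / (B + 1)
    returned. With fewer than 3 weighted SNPs all m! arrangements are
    enumerated exactly instead.
    """
    import warnings as _warnings

    wv, z, Vsub = _align(w, gwas, V)
    m = len(wv)
    denom = float(wv @ Vsub @ wv)
    if denom <= 1e-12:
        raise DegenerateModelError(w.feature_id)
    z_obs = abs(float(wv @ z)) / math.sqrt(denom)
    if m < 3:
        perms = np.array(list(iter_permutations(range(m))))
        W = wv[perms]
        num = np.abs(W @ z)
        den = np.sqrt(np.einsum("bi,ij,bj->b", W, Vsub, W))
        z_perm = num / den
        return float(np.mean(z_perm >= z_obs - 1e-12))
    if B < 100:
        _warnings.warn(f"permutation_test with B={B} < 100 is unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((B, m)), axis=1)
    W = wv[perms]
    num = np.abs(W @ z)
    den = np.sqrt(np.einsum("bi,ij,bj->b", W, Vsub, W))
    z_perm = num / den
    exceed = int(np.sum(z_perm >= z_obs - 1e-12))
    return float((1 + exceed) / (B + 1))


def effective_sample_increase(
    chisq_iso: np.ndarray,
    chisq_twas: np.ndarray,
    filter_mode: str = "union",
) -> EffectiveSampleReport:
    """Percent increase in effective sample size from the mean chi2 proxy.

    The burden chi2 has expectation 1 + NCP with NCP linear in GWAS sample
    size, so pct = 100 * [(mean(chi2_iso) - 1) / (mean(chi2_twas) - 1) - 1]
    estimates the relative effective-N gain. Pairs are filtered to chi2 > 1:
    'union' keeps gene pairs where either arm exceeds 1 (default); 'per_arm'
    filters each arm separately. SE by leave-one-gene-out jackknife with a
    Wald 95% CI.
    """
    a = np.asarray(chisq_iso, dtype=float)
    b = np.asarray(chisq_twas, dtype=float)
    if a.shape != b.shape:
        raise ValueError("chi2 vectors must be paired by gene")

    if filter_mode == "union":
        keep = (a > 1.0) | (b > 1.0)
        A, Bv = a[keep], b[keep]
        g = len(A)

        def estimator(mask):
            return 100.0 * ((A[mask].mean() - 1.0) / (Bv[mask].mean() - 1.0) - 1.0)

        full_mask = np.ones(g, dtype=bool)
    elif filter_mode == "per_arm":
        keep = (a > 1.0) | (b > 1.0)
        A, Bv = a[keep], b[keep]
        g = len(A)

        def estimator(mask):
            ai = A[mask & (A > 1.0)]
            bi = Bv[mask & (Bv > 1.0)]
            return 100.0 * ((ai.mean() - 1.0) / (bi.mean() - 1.0) - 1.0)

        full_mask = np.ones(g, dtype=bool)
    else:
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    if g < 2:
        raise ValueError("need at least 2 gene pairs after the chi2 > 1 filter")
    if Bv.mean() <= 1.0:
        raise ValueError("denominator mean chi2 <= 1; percent increase undefined")
    pct = estimator(full_mask)
    loo = np.empty(g)
    for i in range(g):
        mask = full_mask.copy()
        mask[i] = False
        loo[i] = estimator(mask)
    se = math.sqrt((g - 1) / g * float(np.sum((loo - loo.mean()) ** 2)))
    ci = (pct - 1.96 * se, pct + 1.96 * se)
    return EffectiveSampleReport(pct_increase=pct, se_jackknife=se, ci95=ci, n_features_used=g)
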