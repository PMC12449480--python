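"""Reusable simulation studies: calibration, recovery, and mechanism checks.

Each function runs a self-contained Monte-Carlo study through the package's
public operations and returns summary numbers. They are shared by the test
suite and the analysis drivers, so the same code path produces both.

Block LD here is the theoretical first-order structure (r_ij = rho^|i-j|
within a block, blocks independent), which is the generator's large-n limit
and keeps score regressions and z-draws exact at any SNP count.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


from .assoc import burden_test, is_significant, permutation_test, two_stage_adjust
from .finemap import compute_pips, credible_set, induced_correlation
from .mediation import compute_expression_scores, compute_ld_scores, mesc_fit
from .qtl_coloc import clpp_score, snp_causal_posterior
from .types import AssociationRecord, GWASSummary, LDMatrix, WeightModel

__all__ = [
    "ar1_ld",
    "null_z",
    "null_burden_calibration",
    "permutation_null_calibration",
    "two_stage_fdr_study",
    "credible_set_coverage",
    "mediation_study",
    "ess_doubling_study",
    "opposing_isoform_power",
    "coloc_clpp_study",
]


def ar1_ld(m: int, rho: float = 0.5, snp_prefix: str = "s") -> LDMatrix:
    """Theoretical within-block correlation: r_ij = rho^|i-j|."""
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    return LDMatrix(np.array([f"{snp_prefix}{i}" for i in range(m)]), r)


def _gwas_from_z(z: np.ndarray, snp_ids: np.ndarray, n: int) -> GWASSummary:
    se = 1.0 / math.sqrt(n)
    return GWASSummary(
        pd.DataFrame({"snp_id": snp_ids, "z": z, "beta": z * se, "se": se, "n": n})
    )


def null_z(V: LDMatrix, rng: np.random.Generator, mean: np.ndarray | None = None) -> np.ndarray:
    L = np.linalg.cholesky(V.r + 1e-10 * np.eye(V.r.shape[0]))
    z = L @ rng.standard_normal(V.r.shape[0])
    return z if mean is None else z + mean


def _random_weights(m: int, n_nonzero: int, rng: np.random.Generator) -> np.ndarray:
    w = np.zeros(m)
    idx = rng.choice(m, size=n_nonzero, replace=False)
    w[idx] = rng.standard_normal(n_nonzero)
    return w


def null_burden_calibration(
    n_features: int = 2000, m: int = 8, rho: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Burden-test P-values under the global null (z ~ MVN(0, V))."""
    rng = np.random.default_rng(seed)
    V = ar1_ld(m, rho)
    ps = np.empty(n_features)
    for i in range(n_features):
        z = null_z(V, rng)
        w = _random_weights(m, max(2, m // 2), rng)
        model = WeightModel(f"f{i}", "gene", V.snp_ids, w, 0.5, "elastic_net", 400)
        rec = burden_test(model, _gwas_from_z(z, V.snp_ids, 100_000), V)
        ps[i] = rec.p_raw
    return ps


def permutation_null_calibration(
    n_features: int = 2000, m: int = 8, B: int = 999, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """(p_perm, p_raw) pairs under an exchangeable null (z ~ MVN(0, I))."""
    rng = np.random.default_rng(seed)
    V = ar1_ld(m, 0.0)
    p_perm = np.empty(n_features)
    p_raw = np.empty(n_features)
    for i in range(n_features):
        z = rng.standard_normal(m)
        w = _random_weights(m, m, rng)
        model = WeightModel(f"f{i}", "gene", V.snp_ids, w, 0.5, "elastic_net", 400)
        gw = _gwas_from_z(z, V.snp_ids, 100_000)
        rec = burden_test(model, gw, V)
        p_raw[i] = rec.p_raw
        p_perm[i] = permutation_test(model, gw, V, B=B, seed=int(rng.integers(2**31 - 1)))
    return p_perm, p_raw


def two_stage_fdr_study(
    n_reps: int = 500, n_genes: int = 2000, iso_per_gene: int = 3, alpha: float = 0.05, seed: int = 0
) -> float:
    """Fraction of global-null replicates declaring any isoform significant."""
    rng = np.random.default_rng(seed)
    n_any = 0
    for _ in range(n_reps):
        p = rng.uniform(size=(n_genes, iso_per_gene))
        records = [
            AssociationRecord(f"g{g}.t{t}", "isoform", 0.0, p[g, t], gene_id=f"g{g}")
            for g in range(n_genes)
            for t in range(iso_per_gene)
        ]
        two_stage_adjust(records, alpha=alpha)
        if any(is_significant(r, alpha) for r in records):
            n_any += 1
    return n_any / n_reps


def credible_set_coverage(
    n_reps: int = 500,
    k: int = 6,
    m: int = 60,
    prior_variance: float = 40.0,
    level: float = 0.90,
    seed: int = 0,
) -> float:
    """Coverage of the 90% credible set in single-causal-feature replicates.

    Each replicate draws a fresh feature-correlation matrix (random sparse
    weight vectors against block LD), picks one causal feature, draws its
    z-scale effect from the fine-mapping prior, and checks whether the
    causal feature lands in the credible set.
    """
    rng = np.random.default_rng(seed)
    V = ar1_ld(m, 0.6)
    hits = 0
    for _ in range(n_reps):
        models = [
            WeightModel(f"f{a}", "isoform", V.snp_ids, _random_weights(m, 4, rng), 0.5, "elastic_net", 400)
            for a in range(k)
        ]
        omega = induced_correlation(models, V)
        kk = len(omega.feature_ids)
        causal = int(rng.integers(kk))
        lam = rng.normal(0.0, math.sqrt(prior_variance))
        mean = omega.omega[:, causal] * lam
        L = np.linalg.cholesky(omega.omega + 1e-8 * np.eye(kk))
        z = mean + L @ rng.standard_normal(kk)
        res = compute_pips(z, omega, prior_variance=prior_variance, max_causal=1)
        cs = credible_set(res, level=level)
        if omega.feature_ids[causal] in cs:
            hits += 1
    return hits / n_reps


def _block_architecture(
    m: int,
    block_size: int,
    rho: float,
    n_features: int,
    h2_cis: float,
    h2_med: float,
    h2_direct: float,
    rng: np.random.Generator,
):
    """Mediated + direct architecture over independent AR1 LD blocks.

    Returns (block LD matrices, per-block slices, joint effect vector b,
    per-feature effect dict, realized h2_med, realized h2_total).
    """
    n_blocks = m // block_size
    blocks = [ar1_ld(block_size, rho, snp_prefix=f"b{i}_") for i in range(n_blocks)]
    slices = [slice(i * block_size, (i + 1) * block_size) for i in range(n_blocks)]
    eff: dict[str, np.ndarray] = {}
    b_med = np.zeros(m)
    for f in range(n_features):
        beta = np.zeros(m)
        blk = int(rng.integers(n_blocks))
        j = slices[blk].start + int(rng.integers(block_size))
        beta[j] = math.sqrt(h2_cis) * (1 if rng.random() < 0.5 else -1)
        eff[f"feat{f}"] = beta
    var_per_feature = h2_cis  # single causal SNP, standardized scale
    alpha_sd = math.sqrt(h2_med / (n_features * var_per_feature)) if h2_med > 0 else 0.0
    for fid, beta in eff.items():
        b_med += rng.normal(0.0, alpha_sd) * beta if alpha_sd > 0 else 0.0
    d = np.zeros(m)
    if h2_direct > 0:
        d = rng.standard_normal(m)
        raw = sum(float(d[s] @ blocks[i].r @ d[s]) for i, s in enumerate(slices))
        d *= math.sqrt(h2_direct / raw)
    b = b_med + d
    h2_med_real = sum(float(b_med[s] @ blocks[i].r @ b_med[s]) for i, s in enumerate(slices))
    h2_tot_real = sum(float(b[s] @ blocks[i].r @ b[s]) for i, s in enumerate(slices))
    return blocks, slices, b, eff, h2_med_real, h2_tot_real


def mediation_study(
    ratio_target: float,
    m: int = 2000,
    block_size: int = 10,
    rho: float = 0.8,
    n_features: int = 100,
    h2_cis: float = 0.1,
    h2_trait: float = 0.3,
    n_gwas: int = 50_000,
    n_jackknife_blocks: int = 20,
    seed: int = 0,
):
    """One replicate of expression-score-regression recovery.

    Plants h2_med = ratio_target * h2_trait (the remainder direct), draws
    GWAS z-scores blockwise, builds LD and expression scores from the true
    cis effects, and fits the score regression. Returns the MediationEstimate
    plus the realized planted ratio.
    """
    rng = np.random.default_rng(seed)
    h2_med = ratio_target * h2_trait
    h2_dir = h2_trait - h2_med
    blocks, slices, b, eff, h2m, h2t = _block_architecture(
        m, block_size, rho, n_features, h2_cis, h2_med, h2_dir, rng
    )
    z = np.empty(m)
    snp_ids = []
    ld_scores = np.empty(m)
    expr_scores = np.empty(m)
    total_h2cis = 0.0
    for i, (blk, s) in enumerate(zip(blocks, slices)):
        mean = math.sqrt(n_gwas) * (blk.r @ b[s])
        z[s] = null_z(blk, rng, mean)
        snp_ids.extend(blk.snp_ids)
        ld_scores[s] = compute_ld_scores(blk)
        block_eff = {fid: beta[s] for fid, beta in eff.items() if np.any(beta[s] != 0)}
        if block_eff:
            es, h2c = compute_expression_scores(block_eff, blk)
            expr_scores[s] = es
            total_h2cis += h2c
        else:
            expr_scores[s] = 0.0
    gwas = _gwas_from_z(z, np.asarray(snp_ids), n_gwas)
    scores = pd.DataFrame({"snp_id": snp_ids, "ld_score": ld_scores, "expr_score": expr_scores})
    est = mesc_fit(gwas, scores, total_h2cis, n_jackknife_blocks=n_jackknife_blocks)
    realized = h2m / h2t if h2t > 0 else 0.0
    return est, realized


def ess_doubling_study(
    n_reps: int = 20, n_genes: int = 200, ncp_sd: float = 2.0, seed: int = 0
) -> pd.DataFrame:
    """Doubling the GWAS sample size should double mean(chi2) - 1 (+100%).

    Per gene, a latent standardized effect mu gives paired burden z-scores
    z_ref ~ N(mu, 1) and z_2x ~ N(sqrt(2) mu, 1) — the noncentrality is
    linear in N. Returns per-replicate percent-increase reports.
    """
    rng = np.random.default_rng(seed)
    rows = []
    from .assoc import effective_sample_increase

    for rep in range(n_reps):
        mu = rng.normal(0.0, ncp_sd, size=n_genes)
        z_ref = mu + rng.standard_normal(n_genes)
        z_2x = math.sqrt(2.0) * mu + rng.standard_normal(n_genes)
        rep_out = effective_sample_increase(z_2x**2, z_ref**2)
        rows.append(
            {
                "rep": rep,
                "pct": rep_out.pct_increase,
                "se": rep_out.se_jackknife,
                "lo": rep_out.ci95[0],
                "hi": rep_out.ci95[1],
                "covers_100": rep_out.ci95[0] <= 100.0 <= rep_out.ci95[1],
            }
        )
    return pd.DataFrame(rows)


def opposing_isoform_power(
    n_reps: int = 500,
    m: int = 20,
    rho: float = 0.5,
    h2_cis: float = 0.2,
    alpha_effect: float = 0.05,
    n_gwas: int = 50_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power comparison under the opposing-isoform architecture.

    Two isoforms carry equal-heritability cis effects on disjoint SNP sets;
    the trait loads on them with equal magnitude and opposite sign, so the
    gene-level genetic signal largely cancels while each isoform's does not.
    The gene-level model weights are the summed isoform effects (the
    aggregated expression's cis architecture). Isoform detection follows the
    two-stage rule; gene detection is the gene burden P < alpha.
    """
    rng = np.random.default_rng(seed)
    V = ar1_ld(m, rho)
    hits_iso = hits_gene = 0
    for i in range(n_reps):
        b1 = np.zeros(m)
        b2 = np.zeros(m)
        half = m // 2
        j1 = int(rng.integers(0, half))
        j2 = int(rng.integers(half, m))
        b1[j1] = math.sqrt(h2_cis)
        b2[j2] = math.sqrt(h2_cis)
        b_trait = alpha_effect * (b1 - b2)
        z = null_z(V, rng, math.sqrt(n_gwas) * (V.r @ b_trait))
        gw = _gwas_from_z(z, V.snp_ids, n_gwas)
        recs = []
        for t, w in enumerate((b1, b2)):
            model = WeightModel(f"iso{t}", "isoform", V.snp_ids, w, 0.5, "elastic_net", 400, gene_id="g")
            recs.append(burden_test(model, gw, V))
        two_stage_adjust(recs, alpha=alpha)
        if any(is_significant(r, alpha) for r in recs):
            hits_iso += 1
        gene_model = WeightModel("g", "gene", V.snp_ids, b1 + b2, 0.5, "elastic_net", 400)
        if burden_test(gene_model, gw, V).p_raw < alpha:
            hits_gene += 1
    return {"power_isoform": hits_iso / n_reps, "power_gene": hits_gene / n_reps, "n_reps": n_reps}


def coloc_clpp_study(
    n_reps: int = 500,
    m: int = 20,
    rho: float = 0.5,
    z_signal: float = 7.0,
    max_causal: int = 1,
    seed: int = 0,
) -> dict:
    """Median CLPP when the GWAS and QTL share vs do not share the causal SNP.

    Both scenarios use the same per-trait signal strength (matched power);
    only the identity of the causal SNP differs.
    """
    rng = np.random.default_rng(seed)
    V = ar1_ld(m, rho)
    med = {"shared": [], "distinct": []}
    for _ in range(n_reps):
        j = int(rng.integers(m))
        j2 = int(rng.integers(m))
        while j2 == j:
            j2 = int(rng.integers(m))
        for scen, jq in (("shared", j), ("distinct", j2)):
            zg = null_z(V, rng, z_signal * V.r[:, j])
            zq = null_z(V, rng, z_signal * V.r[:, jq])
            pg = snp_causal_posterior(zg, V, max_causal=max_causal)
            pq = snp_causal_posterior(zq, V, max_causal=max_causal)
            med[scen].append(clpp_score(pg, pq))
    return {
        "median_shared": float(np.median(med["shared"])),
        "median_distinct": float(np.median(med["distinct"])),
        "n_reps": n_reps,
    }
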