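"""Generator checks: genotype LD structure, variant filters, expression
architecture, and GWAS summary draws."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from twaskit import syndata
from twaskit.syndata import (
    EmptyPanelError,
    GeneConfig,
    LDProfile,
    assign_trait_effects,
    estimate_ld,
    filter_variants,
    hwe_exact_test,
    make_annotation,
    make_snp_map,
    simulate_genotypes,
    simulate_gwas_summary,
    simulate_isoform_expression,
)
from twaskit.types import GenotypePanel, SNPMap


# ---------------------------------------------------------------- genotypes
def test_dosages_are_allele_counts_with_correct_mean():
    sm = make_snp_map(10)
    panel = simulate_genotypes(200, sm, (0.5, 0.5), LDProfile(10, 0.0), seed=0)
    assert set(np.unique(panel.dosages)) <= {0.0, 1.0, 2.0}
    se = math.sqrt(2 * 0.25 / 200)
    # per-SNP bound sized for the 10-way comparison; pooled mean at 3 SE
    assert np.all(np.abs(panel.dosages.mean(axis=0) - 1.0) < 4 * se)
    assert abs(panel.dosages.mean() - 1.0) < 3 * se / math.sqrt(10)


def test_independent_snps_have_small_empirical_correlation():
    sm = make_snp_map(20)
    panel = simulate_genotypes(500, sm, (0.2, 0.5), LDProfile(20, 0.0), seed=1)
    r = np.corrcoef(panel.dosages, rowvar=False)
    off = np.abs(r[np.triu_indices_from(r, k=1)])
    assert off.mean() <= 0.1


def test_block_markov_chain_achieves_requested_adjacent_correlation():
    sm = make_snp_map(20)
    panel = simulate_genotypes(2000, sm, (0.3, 0.5), LDProfile(20, 0.9), seed=2)
    r = np.corrcoef(panel.dosages, rowvar=False)
    adjacent = np.array([r[i, i + 1] for i in range(19)])
    assert 0.8 <= adjacent.mean() <= 0.95


def test_degenerate_rho_rejected():
    with pytest.raises(ValueError):
        LDProfile(10, 1.0)


def test_ld_estimate_converges_to_block_structure_with_n():
    # at equal allele frequencies the allele-copy chain has r_ij = rho^|i-j|
    sm = make_snp_map(15)
    rho = 0.6
    theory = rho ** np.abs(np.subtract.outer(np.arange(15), np.arange(15)))
    dist = []
    for n in (200, 2000, 20000):
        panel = simulate_genotypes(n, sm, (0.5, 0.5), LDProfile(15, rho), seed=3)
        emp = np.corrcoef(panel.dosages, rowvar=False)
        dist.append(np.linalg.norm(emp - theory))
    assert dist[0] > dist[1] > dist[2]


# ------------------------------------------------------------------ filters
def _panel_from_dosages(D):
    sm = make_snp_map(D.shape[1])
    return GenotypePanel(np.asarray(D, dtype=float), sm)


def test_low_maf_snp_removed():
    rng = np.random.default_rng(0)
    common = rng.binomial(2, 0.3, size=(200, 2))
    rare = rng.binomial(2, 0.04, size=(200, 1))
    panel = _panel_from_dosages(np.column_stack([common, rare]))
    assert panel.maf[2] < 0.05
    kept, report = filter_variants(panel, maf_min=0.05, hwe_p_min=1e-5)
    assert not report.loc[2, "pass_maf"]
    assert kept.m == int(report["kept"].sum())


def test_hwe_exact_perfect_proportions_have_p_one():
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)


def test_all_heterozygote_column_fails_hwe_filter():
    rng = np.random.default_rng(1)
    D = rng.binomial(2, 0.4, size=(100, 2)).astype(float)
    D[:, 1] = 1.0  # every individual heterozygous
    panel = _panel_from_dosages(D)
    kept, report = filter_variants(panel, maf_min=0.05, hwe_p_min=1e-5)
    assert not report.loc[1, "pass_hwe"]
    assert list(kept.snp_map.snp_ids) == [panel.snp_map.snp_ids[0]]


@pytest.mark.parametrize(
    "counts", [(10, 20, 10), (30, 10, 0), (5, 25, 40), (0, 50, 0), (12, 1, 17)]
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    """Independent oracle: directly enumerate the conditional heterozygote
    distribution given allele counts and sum probabilities <= observed."""
    a, h, b = counts
    n = a + h + b
    n_rare = 2 * min(a, b) + h
    n_common = 2 * n - n_rare

    def log_weight(het):
        ra = (n_rare - het) // 2
        cb = (n_common - het) // 2
        return het * math.log(2) - gammaln(ra + 1) - gammaln(cb + 1) - gammaln(het + 1)

    hets = list(range(n_rare % 2, n_rare + 1, 2))
    w = np.array([log_weight(x) for x in hets])
    probs = np.exp(w - w.max())
    probs /= probs.sum()
    p_obs = probs[hets.index(h)]
    expected = probs[probs <= p_obs + 1e-12].sum()
    assert hwe_exact_test(a, h, b) == pytest.approx(min(1.0, expected), abs=1e-12)


def test_external_frequency_filter_and_empty_panel_error():
    rng = np.random.default_rng(2)
    panel = _panel_from_dosages(rng.binomial(2, 0.4, size=(150, 3)))
    kept, report = filter_variants(panel, external_maf=np.array([0.2, 0.005, 0.3]))
    assert list(report["pass_external_maf"]) == [True, False, True]
    with pytest.raises(EmptyPanelError):
        filter_variants(panel, external_maf=np.zeros(3))


# --------------------------------------------------------------- expression
def test_zero_heritability_expression_is_unit_variance_noise(small_panel, annotation):
    iso, gene, truth = simulate_isoform_expression(
        small_panel, annotation, GeneConfig(2, 2, h2_cis=0.0), seed=7, n_covariates=0
    )
    assert np.all(np.abs(iso.values.var(axis=0) - 1.0) < 0.1)
    assert all(np.all(b == 0) for b in truth.eqtl_effects.values())


def test_full_heritability_expression_equals_genetic_value(small_panel, annotation):
    iso, _, truth = simulate_isoform_expression(
        small_panel, annotation, GeneConfig(2, 2, h2_cis=1.0), seed=8, n_covariates=0
    )
    Xs = small_panel.standardized()
    for j, fid in enumerate(iso.feature_ids):
        np.testing.assert_allclose(iso.values[:, j], Xs @ truth.eqtl_effects[fid], atol=1e-10)


def test_realized_cis_heritability_matches_target():
    sm = make_snp_map(30)
    panel = simulate_genotypes(5000, sm, (0.1, 0.5), LDProfile(10, 0.5), seed=9)
    anno = make_annotation(1, panel.snp_map, isoforms_per_gene=1)
    iso, _, truth = simulate_isoform_expression(
        panel, anno, GeneConfig(1, 3, h2_cis=0.3), seed=10, n_covariates=0
    )
    g = panel.standardized() @ truth.eqtl_effects[iso.feature_ids[0]]
    ratio = g.var() / iso.values[:, 0].var()
    assert 0.25 <= ratio <= 0.35


def test_gene_expression_is_exact_isoform_row_sum(simulated_expression, annotation):
    iso, gene, _ = simulated_expression
    for gi, gid in enumerate(gene.feature_ids):
        tids = annotation.transcripts_of(gid)
        total = sum(iso.column(t) for t in tids)
        np.testing.assert_allclose(gene.values[:, gi], total, atol=1e-12)


def test_requesting_more_causal_snps_than_cis_snps_errors(small_panel, annotation):
    with pytest.raises(ValueError, match="causal"):
        simulate_isoform_expression(
            small_panel, annotation, GeneConfig(2, 10_000, h2_cis=0.2), seed=1
        )


def test_opposing_config_negates_second_isoform_effects(small_panel, annotation):
    iso, gene, truth = simulate_isoform_expression(
        small_panel, annotation, GeneConfig(2, 2, h2_cis=0.4, opposing=True), seed=12, n_covariates=0
    )
    gid = annotation.genes["gene_id"].iloc[0]
    t1, t2 = annotation.transcripts_of(gid)
    np.testing.assert_allclose(truth.eqtl_effects[t2], -truth.eqtl_effects[t1])


# ------------------------------------------------------------ GWAS summary
def test_null_architecture_gives_central_chisq(small_ld, small_panel, annotation):
    iso, _, truth = simulate_isoform_expression(
        small_panel, annotation, GeneConfig(2, 2, h2_cis=0.2), seed=13, n_covariates=0
    )
    truth = assign_trait_effects(truth, small_ld, {t: 0.0 for t in iso.feature_ids})
    chis = []
    for rep in range(200):
        gw = simulate_gwas_summary(small_ld, truth, 10_000, seed=rep)
        chis.append(np.mean(gw.z**2))
    n_eff = 200 * small_panel.m  # correlated within draw, independent across
    assert abs(np.mean(chis) - 1.0) < 3 * math.sqrt(2.0 / (200 * 10))


def test_single_causal_snp_mean_z_is_sqrt_n_times_effect():
    sm = make_snp_map(5)
    panel = simulate_genotypes(4000, sm, (0.5, 0.5), LDProfile(1, 0.0), seed=14)
    ld = estimate_ld(panel)
    anno = make_annotation(1, panel.snp_map, isoforms_per_gene=1)
    iso, _, truth = simulate_isoform_expression(
        panel, anno, GeneConfig(1, 1, h2_cis=0.1), seed=15, n_covariates=0
    )
    tid = iso.feature_ids[0]
    truth = assign_trait_effects(truth, ld, {tid: 1.0})
    b = truth.eqtl_effects[tid]
    j = int(np.flatnonzero(b)[0])
    n_gwas = 5000
    zs = np.array([simulate_gwas_summary(ld, truth, n_gwas, seed=100 + r).z for r in range(300)])
    expected = math.sqrt(n_gwas) * (ld.r @ b)
    se = 3.0 / math.sqrt(300)
    assert abs(zs[:, j].mean() - expected[j]) < 3 * se + 0.1 * abs(expected[j])
    off = [i for i in range(5) if abs(ld.r[i, j]) < 0.05 and i != j]
    for i in off:
        assert abs(zs[:, i].mean()) < 4 * se + 0.05


def test_analytic_and_individual_modes_agree_in_mean(small_ld, small_panel, annotation):
    iso, _, truth = simulate_isoform_expression(
        small_panel, annotation, GeneConfig(2, 2, h2_cis=0.3), seed=16, n_covariates=0
    )
    alpha = {t: 0.0 for t in iso.feature_ids}
    alpha[iso.feature_ids[0]] = 0.5
    truth = assign_trait_effects(truth, small_ld, alpha)
    n_rep, n_gwas = 300, 2000
    za = np.mean(
        [simulate_gwas_summary(small_ld, truth, n_gwas, "analytic_summary", seed=r).z for r in range(n_rep)],
        axis=0,
    )
    zi = np.mean(
        [simulate_gwas_summary(small_ld, truth, n_gwas, "individual_level", seed=r).z for r in range(n_rep)],
        axis=0,
    )
    mc_se = 1.0 / math.sqrt(n_rep)
    assert np.max(np.abs(za - zi)) < 6 * mc_se


def test_truth_mediated_heritability_matches_empirical_variance():
    sm = make_snp_map(30)
    panel = simulate_genotypes(20_000, sm, (0.2, 0.5), LDProfile(10, 0.6), seed=17)
    ld = estimate_ld(panel)
    anno = make_annotation(2, panel.snp_map, isoforms_per_gene=2)
    iso, _, truth = simulate_isoform_expression(
        panel, anno, GeneConfig(2, 2, h2_cis=0.3), seed=18, n_covariates=0
    )
    alpha = {t: 0.0 for t in iso.feature_ids}
    alpha[iso.feature_ids[0]] = 0.4
    alpha[iso.feature_ids[2]] = -0.3
    truth = assign_trait_effects(truth, ld, alpha)
    Xs = panel.standardized()
    mediated = sum(a * (Xs @ truth.eqtl_effects[t]) for t, a in alpha.items() if a != 0.0)
    # trait variance is normalized to 1 by construction
    assert abs(mediated.var() - truth.h2_med_true) < 0.03
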