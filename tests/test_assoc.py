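"""Burden test, ACAT combination, two-stage testing, permutation filter,
allele harmonization, and the effective-sample-size comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twaskit.assoc import (
    DegenerateModelError,
    acat_combine,
    burden_test,
    effective_sample_increase,
    harmonize_gwas,
    is_significant,
    permutation_test,
    two_stage_adjust,
)
from twaskit.studies import ar1_ld
from twaskit.types import AssociationRecord, GWASSummary, LDMatrix, SNPMap, WeightModel


def _gwas(z, snp_ids, n=50_000, **extra):
    se = 1.0 / math.sqrt(n)
    t = pd.DataFrame({"snp_id": snp_ids, "z": z, "beta": np.asarray(z) * se, "se": se, "n": n})
    for k, v in extra.items():
        t[k] = v
    return GWASSummary(t)


def _model(w, snp_ids, feature="f", level="gene", gene_id=None):
    return WeightModel(feature, level, np.asarray(snp_ids), np.asarray(w, float), 0.5, "elastic_net", 400, gene_id)


# --------------------------------------------------------------- burden test
def test_single_snp_indicator_weight_reduces_to_snp_z():
    V = ar1_ld(5, 0.4)
    z = np.array([1.1, -0.4, 2.7, 0.2, -1.9])
    rec = burden_test(_model([0, 0, 1, 0, 0], V.snp_ids), _gwas(z, V.snp_ids), V)
    assert rec.z_assoc == pytest.approx(2.7)
    assert rec.p_raw == pytest.approx(2 * stats.norm.sf(2.7))
    assert rec.chisq == pytest.approx(rec.z_assoc**2, abs=1e-12)


def test_equal_weights_identity_ld_closed_form():
    V = ar1_ld(2, 0.0)
    rec = burden_test(_model([1, 1], V.snp_ids), _gwas([2.0, 2.0], V.snp_ids), V)
    assert rec.z_assoc == pytest.approx(4 / math.sqrt(2))


def test_burden_invariant_to_positive_weight_rescaling():
    V = ar1_ld(8, 0.5)
    rng = np.random.default_rng(0)
    z = rng.standard_normal(8)
    w = rng.standard_normal(8)
    g = _gwas(z, V.snp_ids)
    z1 = burden_test(_model(w, V.snp_ids), g, V).z_assoc
    z2 = burden_test(_model(137.3 * w, V.snp_ids), g, V).z_assoc
    assert abs(z1 - z2) < 1e-10


def test_degenerate_weight_vector_raises():
    V = ar1_ld(3, 0.0)
    with pytest.raises(DegenerateModelError):
        burden_test(_model([0, 0, 0], V.snp_ids), _gwas([1, 1, 1], V.snp_ids), V)


def test_summary_burden_matches_individual_level_regression():
    """At large GWAS n, the summary-statistic burden z equals the z from
    regressing the phenotype on predicted expression in individual data."""
    rng = np.random.default_rng(1)
    m, n = 30, 50_000
    V = ar1_ld(m, 0.5)
    L = np.linalg.cholesky(V.r)
    X = rng.standard_normal((n, m)) @ L.T
    b = np.zeros(m)
    b[[4, 18]] = [0.02, -0.015]
    y = X @ b + rng.standard_normal(n)
    # marginal summary statistics from the same sample
    Xc = X - X.mean(0)
    yc = y - y.mean()
    r = (Xc.T @ yc) / np.sqrt((Xc**2).sum(0) * (yc**2).sum())
    gwas = _gwas(r * math.sqrt(n), V.snp_ids, n=n)
    z_sum, z_ind = [], []
    for _ in range(200):
        w = np.zeros(m)
        idx = rng.choice(m, 4, replace=False)
        w[idx] = rng.standard_normal(4)
        z_sum.append(burden_test(_model(w, V.snp_ids), gwas, V).z_assoc)
        pred = X @ w
        rr = np.corrcoef(pred, y)[0, 1]
        z_ind.append(rr * math.sqrt(n))
    assert np.corrcoef(z_sum, z_ind)[0, 1] > 0.99


def test_null_burden_p_values_are_uniform():
    from twaskit.studies import null_burden_calibration

    p = null_burden_calibration(n_features=2000, seed=21)
    assert stats.kstest(p, "uniform").pvalue > 0.01


# --------------------------------------------------------------------- ACAT
def test_acat_single_p_identity():
    assert acat_combine([0.05]) == pytest.approx(0.05, rel=1e-12)


def test_acat_identical_inputs_fixed_point():
    assert acat_combine([0.05, 0.05, 0.05]) == pytest.approx(0.05, rel=1e-10)


def test_acat_matches_cauchy_cdf_oracle():
    # independent oracle: T = mean tan((0.5-p)pi); p_combined = Cauchy sf(T)
    p = [0.01, 0.5]
    T = np.mean(np.tan((0.5 - np.array(p)) * np.pi))
    oracle = stats.cauchy.sf(T)
    got = acat_combine(p)
    assert got == pytest.approx(oracle, rel=1e-10)
    assert got == pytest.approx(0.0200, abs=5e-4)


def test_acat_input_validation():
    with pytest.raises(ValueError):
        acat_combine([])
    with pytest.raises(ValueError):
        acat_combine([0.5, 1.5])
    assert 0.0 <= acat_combine([0.0, 1.0]) <= 1.0  # boundary values clamped


# ---------------------------------------------------------------- two-stage
def _iso_records(p_by_gene):
    recs = []
    for g, ps in p_by_gene.items():
        for t, p in enumerate(ps):
            recs.append(AssociationRecord(f"{g}.t{t}", "isoform", 0.0, p, gene_id=g))
    return recs


def test_extreme_signal_survives_both_stages():
    p_by_gene = {"hit": [1e-10]}
    p_by_gene.update({f"null{i}": [float(p)] for i, p in enumerate(np.random.default_rng(2).uniform(size=999))})
    recs = two_stage_adjust(_iso_records(p_by_gene), alpha=0.05)
    hit = next(r for r in recs if r.gene_id == "hit")
    assert hit.p_fdr < 0.05 and hit.p_fwer_within < 0.05
    assert is_significant(hit)


def test_within_gene_bonferroni_on_screened_gene():
    recs = two_stage_adjust(_iso_records({"g": [1e-6, 0.9]}), alpha=0.05)
    by_id = {r.feature_id: r for r in recs}
    assert by_id["g.t0"].p_fwer_within == pytest.approx(2e-6)
    assert by_id["g.t1"].p_fwer_within == pytest.approx(1.0)


def test_unscreened_gene_gets_no_stage_two_value():
    recs = two_stage_adjust(_iso_records({"g1": [1e-9], "g2": [0.4, 0.6]}), alpha=0.05)
    g2 = [r for r in recs if r.gene_id == "g2"]
    assert all(np.isnan(r.p_fwer_within) for r in g2)
    assert not any(is_significant(r) for r in g2)


def test_two_stage_family_wise_error_under_global_null():
    from twaskit.studies import two_stage_fdr_study

    frac = two_stage_fdr_study(n_reps=200, n_genes=500, seed=23)
    assert frac <= 0.07


# -------------------------------------------------------------- permutation
def test_zero_observed_statistic_gives_p_one():
    V = ar1_ld(5, 0.0)
    z = np.zeros(5)
    p = permutation_test(_model([1, 2, 3, 0.5, -1], V.snp_ids), _gwas(z, V.snp_ids), V, B=500, seed=0)
    assert p == pytest.approx(1.0)


def test_equal_weights_are_permutation_invariant():
    V = ar1_ld(6, 0.3)
    z = np.random.default_rng(3).standard_normal(6)
    p = permutation_test(_model(np.ones(6), V.snp_ids), _gwas(z, V.snp_ids), V, B=500, seed=0)
    assert p == pytest.approx(1.0)


def test_two_snp_model_enumerates_exactly():
    V = ar1_ld(2, 0.0)
    p = permutation_test(_model([2.0, 0.5], V.snp_ids), _gwas([3.0, 0.1], V.snp_ids), V, seed=0)
    # arrangements: identity (|z| large) and swap (smaller) -> p = 1/2
    assert p == pytest.approx(0.5)


def test_permutation_p_uniform_and_concordant_with_raw_p():
    from twaskit.studies import permutation_null_calibration

    p_perm, p_raw = permutation_null_calibration(n_features=400, B=499, seed=24)
    assert stats.kstest(p_perm, "uniform").pvalue > 0.01
    rho = stats.spearmanr(p_perm[:200], p_raw[:200]).statistic
    assert rho > 0.9


# ------------------------------------------------------------- harmonization
def test_allele_flip_and_ambiguous_drop():
    sm = SNPMap(
        pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3"],
                "chrom": "1",
                "pos": [100, 200, 300],
                "allele_ref": ["A", "C", "A"],
                "allele_alt": ["G", "T", "T"],
            }
        )
    )
    gwas = _gwas(
        [2.0, -1.0, 3.0],
        ["rs1", "rs2", "rs3"],
        allele_ref=["G", "C", "A"],
        allele_alt=["A", "T", "T"],
    )
    out = harmonize_gwas(gwas, sm)
    assert list(out.snp_ids) == ["rs1", "rs2"]  # rs3 is ambiguous A/T
    assert out.z[0] == pytest.approx(-2.0)  # rs1 flipped
    assert out.z[1] == pytest.approx(-1.0)


# ---------------------------------------------------- effective sample size
def test_identical_chi2_vectors_give_zero_percent():
    rng = np.random.default_rng(4)
    chi = rng.chisquare(1, size=50) + 1.0
    rep = effective_sample_increase(chi, chi)
    assert rep.pct_increase == pytest.approx(0.0, abs=1e-10)
    assert rep.ci95[0] <= 0.0 <= rep.ci95[1]


def test_closed_form_percent_increase_of_means():
    # construct exact means 3 and 2 with all values > 1
    iso = np.array([2.0, 4.0, 3.0, 3.0])
    twas = np.array([1.5, 2.5, 2.0, 2.0])
    rep = effective_sample_increase(iso, twas)
    assert rep.pct_increase == pytest.approx(100.0)
    assert rep.ci95 == (
        pytest.approx(rep.pct_increase - 1.96 * rep.se_jackknife),
        pytest.approx(rep.pct_increase + 1.96 * rep.se_jackknife),
    )


def test_denominator_at_or_below_one_is_flagged():
    iso = np.array([2.0, 3.0])
    twas = np.array([0.9, 1.05])
    with pytest.raises(ValueError, match="undefined"):
        effective_sample_increase(iso, twas)


def test_doubled_gwas_sample_size_doubles_mean_chi2_minus_one():
    from twaskit.studies import ess_doubling_study

    df = ess_doubling_study(n_reps=20, seed=25)
    assert df["covers_100"].mean() >= 0.8
    assert 70 <= df["pct"].mean() <= 130
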