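"""Induced feature correlations, locus grouping, PIP enumeration against a
brute-force oracle, and credible-set construction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twaskit.finemap import compute_pips, credible_set, group_overlapping, induced_correlation
from twaskit.studies import ar1_ld
from twaskit.syndata import LDProfile, make_snp_map, simulate_genotypes, estimate_ld
from twaskit.types import (
    AssociationRecord,
    FeatureCorrelation,
    FineMapResult,
    TranscriptomeAnnotation,
    WeightModel,
)


def _model(w, snp_ids, fid="f"):
    return WeightModel(fid, "isoform", np.asarray(snp_ids), np.asarray(w, float), 0.5, "elastic_net", 400)


# -------------------------------------------------------- induced correlation
def test_identical_weight_vectors_fully_correlated():
    V = ar1_ld(6, 0.4)
    w = np.array([1.0, 0, 0.5, 0, 0, -0.2])
    om = induced_correlation([_model(w, V.snp_ids, "a"), _model(w, V.snp_ids, "b")], V)
    assert om.omega[0, 1] == pytest.approx(1.0)


def test_disjoint_supports_in_independent_blocks_uncorrelated():
    r = np.eye(6)
    r[:3, :3] = ar1_ld(3, 0.8).r
    r[3:, 3:] = ar1_ld(3, 0.8).r
    from twaskit.types import LDMatrix

    V = LDMatrix(np.array([f"s{i}" for i in range(6)]), r)
    wa = np.array([1.0, -0.5, 0.2, 0, 0, 0])
    wb = np.array([0, 0, 0, 0.7, 0.3, -0.1])
    om = induced_correlation([_model(wa, V.snp_ids, "a"), _model(wb, V.snp_ids, "b")], V)
    assert om.omega[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_induced_correlation_matches_empirical_predicted_expression():
    sm = make_snp_map(30)
    panel = simulate_genotypes(3000, sm, (0.2, 0.5), LDProfile(10, 0.6), seed=31)
    V = estimate_ld(panel)
    rng = np.random.default_rng(32)
    wa, wb = np.zeros(30), np.zeros(30)
    wa[rng.choice(30, 5, replace=False)] = rng.standard_normal(5)
    wb[rng.choice(30, 5, replace=False)] = rng.standard_normal(5)
    om = induced_correlation([_model(wa, V.snp_ids, "a"), _model(wb, V.snp_ids, "b")], V)
    Xs = panel.standardized()
    emp = np.corrcoef(Xs @ wa, Xs @ wb)[0, 1]
    assert om.omega[0, 1] == pytest.approx(emp, abs=0.05)


def test_degenerate_feature_excluded_with_warning():
    V = ar1_ld(4, 0.0)
    good = _model([1.0, 0, 0, 0], V.snp_ids, "ok")
    bad = _model([0, 0, 0, 0], V.snp_ids, "zero")
    with pytest.warns(UserWarning, match="degenerate"):
        om = induced_correlation([good, bad], V)
    assert om.feature_ids == ["ok"]


# ------------------------------------------------------------ locus grouping
def _anno(gene_pos):
    genes = pd.DataFrame(
        [
            {"gene_id": g, "chrom": "1", "strand": "+", "gene_start": s, "gene_end": e, "tss": s}
            for g, (s, e) in gene_pos.items()
        ]
    )
    tx = pd.DataFrame(
        [{"transcript_id": f"{g}.T1", "gene_id": g, "tss": s} for g, (s, _) in gene_pos.items()]
    )
    return TranscriptomeAnnotation(genes, tx)


def _rec(gid):
    return AssociationRecord(gid, "gene", 5.0, 1e-7, gene_id=gid)


@pytest.mark.parametrize(
    "positions,n_loci",
    [
        ({"A": (1_000_000, 1_050_000), "B": (4_050_000, 4_100_000)}, 2),  # 3 Mb apart
        ({"A": (1_000_000, 1_050_000), "B": (1_550_000, 1_600_000)}, 1),  # 0.5 Mb apart
        (
            {  # chain: A-B and B-C within window, A-C not
                "A": (1_000_000, 1_050_000),
                "B": (1_900_000, 1_950_000),
                "C": (2_800_000, 2_850_000),
            },
            1,
        ),
    ],
)
def test_single_linkage_grouping(positions, n_loci):
    loci = group_overlapping([_rec(g) for g in positions], _anno(positions), window=1_000_000)
    assert len(loci) == n_loci


# ---------------------------------------------------------------------- PIPs
def brute_force_pips(z, omega, prior_p, prior_variance, max_causal):
    """Independent oracle: full MVN likelihood over every configuration."""
    k = len(z)
    configs = []
    for size in range(max_causal + 1):
        configs.extend(itertools.combinations(range(k), size))
    log_posts = []
    null = stats.multivariate_normal.logpdf(z, np.zeros(k), omega, allow_singular=True)
    for S in configs:
        lp = len(S) * math.log(prior_p) + (k - len(S)) * math.log1p(-prior_p)
        if S:
            cols = omega[:, list(S)]
            cov = omega + prior_variance * cols @ cols.T
            lp += stats.multivariate_normal.logpdf(z, np.zeros(k), cov, allow_singular=True) - null
        log_posts.append(lp)
    post = np.exp(np.array(log_posts) - max(log_posts))
    post /= post.sum()
    pips = np.zeros(k)
    for p, S in zip(post, configs):
        for a in S:
            pips[a] += p
    return pips


def test_single_feature_huge_z_has_pip_near_one():
    om = FeatureCorrelation(["a"], np.array([[1.0]]))
    res = compute_pips(np.array([8.0]), om, prior_p=0.5)
    assert res.pip[0] > 0.99


def test_two_independent_features_signal_separates():
    om = FeatureCorrelation(["a", "b"], np.eye(2))
    res = compute_pips(np.array([6.0, 0.0]), om, max_causal=2)
    prior_p = 0.5  # default 1/k
    assert res.pip[0] > 0.95
    assert res.pip[1] < 2 * prior_p


@pytest.mark.parametrize("k,max_causal", [(4, 4), (7, 7), (10, 3)])
def test_pips_match_brute_force_enumeration(k, max_causal):
    rng = np.random.default_rng(33)
    W = rng.standard_normal((k, k))
    A = W @ W.T + 3 * np.eye(k)
    d = np.sqrt(np.diag(A))
    omega = A / np.outer(d, d)
    z = rng.standard_normal(k) * 3
    ids = [f"f{i}" for i in range(k)]
    res = compute_pips(z, FeatureCorrelation(ids, omega), prior_p=1.0 / k, prior_variance=40.0, max_causal=max_causal)
    oracle = brute_force_pips(z, omega, 1.0 / k, 40.0, max_causal)
    np.testing.assert_allclose(res.pip, oracle, atol=1e-10)


def test_pips_invariant_to_feature_ordering():
    rng = np.random.default_rng(34)
    k = 6
    base = ar1_ld(k, 0.5).r
    z = rng.standard_normal(k) * 4
    ids = [f"f{i}" for i in range(k)]
    res = compute_pips(z, FeatureCorrelation(ids, base), max_causal=2)
    perm = rng.permutation(k)
    res_p = compute_pips(
        z[perm], FeatureCorrelation([ids[i] for i in perm], base[np.ix_(perm, perm)]), max_causal=2
    )
    back = {f: p for f, p in zip(res_p.feature_ids, res_p.pip)}
    assert max(abs(back[f] - p) for f, p in zip(ids, res.pip)) < 1e-12


def test_independent_features_pip_ranking_follows_abs_z():
    z = np.array([1.0, -4.0, 2.5, 0.3])
    om = FeatureCorrelation([f"f{i}" for i in range(4)], np.eye(4))
    res = compute_pips(z, om, max_causal=1)
    assert list(np.argsort(-res.pip)) == list(np.argsort(-np.abs(z)))


def test_credible_set_grows_as_features_become_confounded():
    """With z drawn under a single causal feature, correlated features
    inherit its signal and the 90% set must spread over them."""
    rng = np.random.default_rng(36)
    k, lam = 4, 6.0
    mean_sizes = []
    for rho in (0.0, 0.7, 0.99):
        om = np.full((k, k), rho)
        np.fill_diagonal(om, 1.0)
        L = np.linalg.cholesky(om + 1e-10 * np.eye(k))
        sizes = []
        for _ in range(100):
            z = om[:, 0] * lam + L @ rng.standard_normal(k)
            res = compute_pips(z, FeatureCorrelation([f"f{i}" for i in range(k)], om), max_causal=1)
            sizes.append(len(res.credible_set))
        mean_sizes.append(np.mean(sizes))
    assert mean_sizes[0] <= mean_sizes[1] + 0.05 <= mean_sizes[2] + 0.1
    assert mean_sizes[2] > mean_sizes[0] + 1.0


# -------------------------------------------------------------- credible set
def test_credible_set_trivial_cases():
    res = FineMapResult(["a", "b", "c"], np.array([1.0, 0.0, 0.0]), [])
    assert credible_set(res) == ["a"]
    res = FineMapResult(["a", "b", "c", "d"], np.array([0.6, 0.3, 0.06, 0.04]), [])
    assert credible_set(res, level=0.9) == ["a", "b"]


def test_credible_set_ties_broken_by_feature_id():
    res = FineMapResult(["b", "a"], np.array([0.5, 0.5]), [])
    assert credible_set(res, level=0.4) == ["a"]


def test_zero_mass_returns_all_features_flagged():
    res = FineMapResult(["a", "b"], np.array([0.0, 0.0]), [])
    assert credible_set(res) == ["a", "b"]
    assert res.low_mass


def test_planted_causal_feature_coverage():
    from twaskit.studies import credible_set_coverage

    cov = credible_set_coverage(n_reps=200, seed=35)
    assert cov >= 0.88
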