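"""Covariate residualization and cross-validated cis SNP-weight models.

Two model families are trained per feature and the better cross-validated
one kept: a per-feature elastic net (mixing 0.5) and, for isoforms, a
multi-response elastic net that borrows strength across a gene's isoforms
through joint row-sparsity. cv_r2 is the squared Pearson correlation
between out-of-fold predictions and observed expression; features are
retained for association testing only when cv_r2 > 0.01 (strict).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV, MultiTaskElasticNetCV
from sklearn.model_selection import KFold

from .types import ExpressionSet, GenotypePanel, ModelDB, TranscriptomeAnnotation, WeightModel

__all__ = [
    "residualize_expression",
    "train_feature_model",
    "select_models",
    "train_models",
    "NOT_RETAINED",
]

NOT_RETAINED = -1.0  # cv_r2 sentinel for unusable features (zero-variance response)

RETENTION_THRESHOLD = 0.01


def residualize_expression(
    expr: ExpressionSet, covariates: np.ndarray | None = None
) -> ExpressionSet:
    """Least-squares residuals of expression on covariates (plus intercept).

    Rank-deficient covariate matrices have their collinear columns dropped
    with a warning. Residuals are orthogonal to the retained covariates.
    """
    C = covariates if covariates is not None else expr.covariates
    n = expr.n
    if C is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(C, dtype=float)])
    Q, R = np.linalg.qr(C, mode="reduced")
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R[0, 0]))))
    if rank < C.shape[1]:
        warnings.warn(
            f"covariate matrix rank-deficient ({rank} < {C.shape[1]}); dropping collinear columns",
            stacklevel=2,
        )
        # pivoted elimination: keep an independent column subset
        keep = []
        basis = np.zeros((n, 0))
        for j in range(C.shape[1]):
            cand = np.column_stack([basis, C[:, j]])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                keep.append(j)
                basis = cand
        C = C[:, keep]
        Q, R = np.linalg.qr(C, mode="reduced")
    resid = expr.values - Q @ (Q.T @ expr.values)
    return ExpressionSet(resid, list(expr.feature_ids), expr.level, covariates=None)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _cv_r2(y: np.ndarray, oof: np.ndarray) -> float:
    if np.std(oof) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(y, oof)[0, 1] ** 2)


def _fit_enet(X: np.ndarray, y: np.ndarray, seed: int):
    model = ElasticNetCV(
        l1_ratio=0.5, alphas=20, cv=3, random_state=seed, max_iter=3000, tol=1e-4
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _fit_multi(X: np.ndarray, Y: np.ndarray, seed: int):
    model = MultiTaskElasticNetCV(
        l1_ratio=0.5, alphas=20, cv=3, random_state=seed, max_iter=3000, tol=1e-4
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, Y)
    return model


def train_feature_model(
    X_cis: np.ndarray,
    Y: np.ndarray,
    snp_ids: np.ndarray,
    feature_ids: list[str],
    level: str,
    families: tuple[str, ...] = ("elastic_net", "multi_response"),
    k_folds: int = 10,
    seed: int = 0,
    gene_id: str | None = None,
) -> list[WeightModel]:
    """Train cis weight models for one feature or one gene's isoform set.

    Y may be a vector (one feature) or an n x k matrix (a gene's k isoforms,
    enabling the multi-response family). Out-of-fold predictions are produced
    by refitting each family inside every outer training fold, so held-out
    individuals contribute nothing to the weights that predict them. The
    best family per feature is chosen by cv_r2 (ties: fewest nonzero
    weights); final weights are refit on all individuals.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    # center globally; out-of-fold predictions exclude per-fold intercepts,
    # whose anti-correlation with held-out fold means would inflate null cv_r2
    Y = Y - Y.mean(axis=0)
    n, k = Y.shape
    if n < 2 * k_folds:
        raise ValueError(f"need n >= {2 * k_folds} individuals for {k_folds}-fold CV")
    if len(feature_ids) != k:
        raise ValueError("feature_ids length must match Y columns")
    X = _standardize(np.asarray(X_cis, dtype=float))
    m = X.shape[1]
    use_multi = "multi_response" in families and k >= 2
    use_enet = "elastic_net" in families
    if not (use_enet or use_multi):
        raise ValueError("no applicable model family")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    oof = {fam: np.zeros((n, k)) for fam in (["elastic_net"] if use_enet else []) + (["multi_response"] if use_multi else [])}
    zero_var = Y.std(axis=0) == 0
    for fold, (tr, te) in enumerate(kf.split(X)):
        fold_seed = seed + 1000 + fold
        if use_enet:
            for j in range(k):
                if zero_var[j]:
                    continue
                fit = _fit_enet(X[tr], Y[tr, j], fold_seed)
                oof["elastic_net"][te, j] = X[te] @ fit.coef_
        if use_multi and not zero_var.any():
            fit = _fit_multi(X[tr], Y[tr], fold_seed)
            oof["multi_response"][te] = X[te] @ fit.coef_.T
    # full-data refits for the stored weights
    full = {}
    if use_enet:
        full["elastic_net"] = np.column_stack(
            [
                np.zeros(m) if zero_var[j] else _fit_enet(X, Y[:, j], seed).coef_
                for j in range(k)
            ]
        )
    if use_multi and not zero_var.any():
        full["multi_response"] = _fit_multi(X, Y, seed).coef_.T
    models = []
    for j, fid in enumerate(feature_ids):
        if zero_var[j]:
            models.append(
                WeightModel(fid, level, snp_ids, np.zeros(m), NOT_RETAINED, "none", n, gene_id)
            )
            continue
        best_fam, best_r2, best_w = None, -np.inf, None
        for fam, W in full.items():
            r2 = _cv_r2(Y[:, j], oof[fam][:, j])
            nnz = int(np.sum(W[:, j] != 0))
            if r2 > best_r2 or (r2 == best_r2 and best_w is not None and nnz < int(np.sum(best_w != 0))):
                best_fam, best_r2, best_w = fam, r2, W[:, j]
        models.append(WeightModel(fid, level, snp_ids, best_w, best_r2, best_fam, n, gene_id))
    return models


def select_models(db: ModelDB, threshold: float = RETENTION_THRESHOLD) -> ModelDB:
    """Flag models retained for association testing: cv_r2 strictly > threshold."""
    for key, m in db.models.items():
        db.retained[key] = bool(m.cv_r2 > threshold)
    return db


def train_models(
    panel: GenotypePanel,
    expr_iso: ExpressionSet,
    expr_gene: ExpressionSet,
    annotation: TranscriptomeAnnotation,
    k_folds: int = 10,
    seed: int = 0,
    cis_window: int = 1_000_000,
) -> ModelDB:
    """Train gene- and isoform-level models for every annotated gene.

    The cis-SNP set for both levels is the gene body +/- cis_window. Genes
    whose window contains no SNPs are skipped. Fold assignments are derived
    deterministically from (seed, gene index) and shared between the gene
    model and its isoform models.
    """
    db = ModelDB()
    snp_map = panel.snp_map
    for gi, (_, grow) in enumerate(annotation.genes.iterrows()):
        gid = grow["gene_id"]
        mask = (
            (snp_map.chrom == grow["chrom"])
            & (snp_map.pos >= grow["gene_start"] - cis_window)
            & (snp_map.pos <= grow["gene_end"] + cis_window)
        )
        if not mask.any():
            continue
        X = panel.dosages[:, mask]
        ids = snp_map.snp_ids[mask]
        gene_seed = int(np.random.default_rng([seed, gi]).integers(0, 2**31 - 1))
        if gid in expr_gene.feature_ids:
            for m in train_feature_model(
                X, expr_gene.column(gid), ids, [gid], "gene",
                families=("elastic_net",), k_folds=k_folds, seed=gene_seed, gene_id=gid,
            ):
                db.add(m)
        tids = [t for t in annotation.transcripts_of(gid) if t in expr_iso.feature_ids]
        if tids:
            Y = np.column_stack([expr_iso.column(t) for t in tids])
            for m in train_feature_model(
                X, Y, ids, tids, "isoform", k_folds=k_folds, seed=gene_seed, gene_id=gid,
            ):
                db.add(m)
    return select_models(db)
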