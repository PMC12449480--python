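"""Spike-and-slab configuration posteriors shared by feature fine-mapping
and SNP-level colocalization.

Model: observed z-scores at a locus satisfy z ~ MVN(0, R) under the null;
a causal configuration S adds rank-|S| signal, z ~ MVN(0, R + v R[:,S] R[S,:])
with slab variance v on the z scale. Because R^{-1} R[:,S] is a selection
matrix, the matrix determinant lemma and Woodbury identity reduce each
Bayes factor to |S|-dimensional algebra:

    log BF(S) = -1/2 log|I + v R[S,S]| + 1/2 z_S' (I/v + R[S,S])^{-1} z_S

so enumeration over configurations costs O(|S|^3) each regardless of locus
size. Priors are independent Bernoulli(prior_p) per element; the null
configuration is included in the normalization.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

__all__ = ["spike_slab_posterior"]


def spike_slab_posterior(
    z: np.ndarray,
    R: np.ndarray,
    prior_p: float | None = None,
    prior_variance: float = 40.0,
    max_causal: int = 1,
    ridge: float = 1e-4,
) -> tuple[np.ndarray, list[tuple[int, ...]], np.ndarray, bool]:
    """Marginal inclusion posteriors by exhaustive enumeration.

    Returns (marginal_inclusion, configurations, configuration_posteriors,
    ridged) where ridged records whether R needed diagonal regularization
    to become positive definite.
    """
    z = np.asarray(z, dtype=float)
    m = len(z)
    R = np.array(R, dtype=float, copy=True)
    if R.shape != (m, m):
        raise ValueError("R shape must match z")
    if prior_p is None:
        prior_p = 1.0 / m
    if not 0.0 < prior_p < 1.0:
        raise ValueError("prior_p must lie in (0, 1)")
    ridged = False
    if np.linalg.eigvalsh((R + R.T) / 2.0).min() < 1e-8:
        R[np.diag_indices(m)] += ridge
        ridged = True
    v = float(prior_variance)
    configs: list[tuple[int, ...]] = []
    logpost: list[float] = []
    for size in range(0, min(max_causal, m) + 1):
        for S in combinations(range(m), size):
            s = len(S)
            log_prior = s * math.log(prior_p) + (m - s) * math.log1p(-prior_p)
            if s == 0:
                log_bf = 0.0
            else:
                idx = list(S)
                Rss = R[np.ix_(idx, idx)]
                zs = z[idx]
                sign, logdet = np.linalg.slogdet(np.eye(s) + v * Rss)
                if sign <= 0:
                    raise np.linalg.LinAlgError("non-PD configuration covariance")
                quad = float(zs @ np.linalg.solve(np.eye(s) / v + Rss, zs))
                log_bf = -0.5 * logdet + 0.5 * quad
            configs.append(S)
            logpost.append(log_prior + log_bf)
    lp = np.asarray(logpost)
    lp -= lp.max()
    post = np.exp(lp)
    post /= post.sum()
    marginal = np.zeros(m)
    for p, S in zip(post, configs):
        for a in S:
            marginal[a] += p
    return marginal, configs, post, ridged
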