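import numpy as np
import pytest

from twaskit import syndata
from twaskit.types import SNPMap


@pytest.fixture(scope="session")
def small_panel():
    """300-individual, 60-SNP block-LD panel shared across tests."""
    sm = syndata.make_snp_map(60, chrom="1", spacing=30_000)
    return syndata.simulate_genotypes(
        300, sm, (0.1, 0.5), syndata.LDProfile(block_size=10, rho=0.7), seed=11
    )


@pytest.fixture(scope="session")
def small_ld(small_panel):
    return syndata.estimate_ld(small_panel)


@pytest.fixture(scope="session")
def annotation(small_panel):
    return syndata.make_annotation(4, small_panel.snp_map, isoforms_per_gene=2)


@pytest.fixture(scope="session")
def simulated_expression(small_panel, annotation):
    cfg = syndata.GeneConfig(n_isoforms=2, n_causal=2, h2_cis=0.3, resid_cor=0.2)
    return syndata.simulate_isoform_expression(
        small_panel, annotation, cfg, seed=5, n_covariates=3, covariate_effect_sd=0.4
    )
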