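import numpy as np
import pytest

from phenogrn.model import Candidate, GeneEvidence, ModelHyperparams
from phenogrn.sampler import SamplerConfig
from phenogrn.simulate import SimulationConfig, generate_planted_network, generate_summary_evidence


@pytest.fixture
def small_cfg():
    return SimulationConfig(n_tfs=6, n_genes=20, frac_pheno_genes=0.5, n_decoys=2, seed=7)


@pytest.fixture
def small_net(small_cfg):
    return generate_planted_network(small_cfg)


@pytest.fixture
def small_evidence(small_net, small_cfg):
    return generate_summary_evidence(small_net, small_cfg)


@pytest.fixture
def quick_sampler():
    """Reduced-size sampler settings for unit tests."""
    return SamplerConfig(n_draws=400, n_tune=200, n_chains=2, seed=42, batch_size=50)


@pytest.fixture
def default_hp():
    return ModelHyperparams(alpha_prime=0.3)


def make_single(p_pheno, p_gex, p_chip, gene="g", tf="A"):
    return GeneEvidence(gene=gene, p_pheno=p_pheno,
                        candidates=(Candidate(tf=tf, p_gex=p_gex, p_chip=p_chip),))


@pytest.fixture
def make_single_evidence():
    return make_single
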