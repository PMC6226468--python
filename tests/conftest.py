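import numpy as np
import pytest

from depet.conformer_density import ensemble_to_density
from depet.fdq import fit_fdq, quench_probability_curve
from depet.synthetic_fixtures import ChainSamplerSpec, example_fdq_family, synth_conformer_cloud


@pytest.fixture(scope="session")
def fdq_family():
    """Canonical six-member alpha-alpha FDQ family (fixed parameters)."""
    return example_fdq_family()


@pytest.fixture(scope="session")
def fdq_family_ab():
    return example_fdq_family(anchor_pair="ab")


@pytest.fixture(scope="session")
def pipeline_densities():
    """Fluorophore + quencher radial densities built through the chain sampler."""
    ens_f = synth_conformer_cloud(ChainSamplerSpec(n_bonds=6, n_frames=3000, seed=11))
    ens_q = synth_conformer_cloud(
        ChainSamplerSpec(n_bonds=2, n_frames=3000, seed=12, moiety_offset=1.5)
    )
    f = ensemble_to_density(ens_f, moiety_kind="xanthene")
    q = ensemble_to_density(ens_q, moiety_kind="indole")
    return f, q


@pytest.fixture(scope="session")
def pipeline_quench_curve(pipeline_densities):
    f, q = pipeline_densities
    curve = quench_probability_curve(f, q)
    curve.fluorophore_tag = "pipeline"
    return curve


@pytest.fixture(scope="session")
def pipeline_fdq(pipeline_quench_curve):
    return fit_fdq(pipeline_quench_curve)
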