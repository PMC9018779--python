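import numpy as np
import pytest

import biopid as bp


@pytest.fixture(scope="session")
def gene_plant():
    return bp.gene_expression_plant(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def ai_spec():
    return bp.ControllerSpec("AI", mu=5.0, theta=1.0, eta=1e4, k=0.5)


@pytest.fixture(scope="session")
def ai_loop(gene_plant, ai_spec):
    return bp.compose_closed_loop(gene_plant, ai_spec)


@pytest.fixture(scope="session")
def fixture_networks(gene_plant, ai_loop):
    """A spread of networks used by serialization / nonnegativity properties."""
    nets = [gene_plant, ai_loop, bp.chain_feedback_plant(6, **bp.CHAIN6_DEFAULTS)]
    specs = [
        bp.ControllerSpec("API_CLASS1", mechanism="ADDITIVE", alpha=2.0, kappa=2.0, n=2),
        bp.ControllerSpec("API_CLASS1", mechanism="MULTIPLICATIVE", kappa=1.0, k=1.0),
        bp.ControllerSpec("API_CLASS1", mechanism="DEGRADATION", delta=2.0, kappa1=0.5),
        bp.ControllerSpec("API_CLASS2", mechanism="DEGRADATION", delta=1.0),
        bp.ControllerSpec("API_CLASS3", mechanism="MULTIPLICATIVE", kappa=2.0, n=2),
        bp.ControllerSpec("APID_ORDER2", mechanism="DEGRADATION", beta=0.4, delta=1.0),
        bp.ControllerSpec("APID_ORDER3", mechanism="DEGRADATION", delta=0.5,
                          alpha0=1.0, gamma0=1.0, delta0=0.5),
        bp.ControllerSpec("APID_ORDER4_DEG", mechanism="DEGRADATION", delta=1.0,
                          mu0=2.0, k0=0.5),
        bp.ControllerSpec("APID_ORDER4_PROD", mechanism="DEGRADATION", mu0=2.0,
                          k0=0.5, kappa0=1.0),
        bp.ControllerSpec("DIFF_OUTFLOW", mu0=4.0, k0=1.0, kappa0=1e-3),
        bp.ControllerSpec("DIFF_INFLOW", mu0=4.0, k0=1.0, kappa0=1e-3, kappa_d=2.0),
        bp.ControllerSpec("DIFF_AUTOCATALYTIC", mu0=20.0, k0=1.0, kappa0=1e-3),
    ]
    plant = bp.gene_expression_plant(1.0, 1.0, 1.0)
    nets += [bp.compose_closed_loop(plant, s) for s in specs]
    return nets
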