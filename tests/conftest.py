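import pytest

from gcgrn import default_schedules, load_parameter_version


@pytest.fixture(scope="session")
def model_I():
    return load_parameter_version("I")


@pytest.fixture(scope="session")
def model_III():
    return load_parameter_version("III")


@pytest.fixture(scope="session")
def schedules():
    return default_schedules()


@pytest.fixture(scope="session")
def no_interaction_model():
    """Three genes with every edge removed: constant switching rates."""
    from gcgrn import GENES, GeneParameters, InteractionParams, NetworkModel

    genes = tuple(
        GeneParameters(
            gene_id=g, s0=10.0, d0=0.5, s1=5.0, d1=0.25,
            kon_init=0.4, koff_init=0.6, kon_min=0.0, kon_max=2.0,
            koff_min=0.0, koff_max=2.0,
        )
        for g in GENES
    )
    inter = InteractionParams(theta={}, H={}, gamma=2.0)
    return NetworkModel(genes=genes, interactions=inter).calibrate()
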