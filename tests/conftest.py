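import pytest
from hypothesis import HealthCheck, settings

import pcetpump as pp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ubiquinone_model() -> pp.PumpModel:
    return pp.build_model(pp.load_model("complex_i_ubiquinone"))


@pytest.fixture(scope="session")
def menaquinone_model() -> pp.PumpModel:
    return pp.build_model(pp.load_model("complex_i_menaquinone"))


@pytest.fixture(scope="session")
def fes_wire() -> pp.ETChain:
    path = pp.packaged_model_path("complex_i_ubiquinone").parent / "fes_wire_complex_i.tsv"
    return pp.read_chain(path)


@pytest.fixture()
def random_pump_factory():
    def make(seed: int, **kwargs) -> pp.PumpModel:
        cfg = pp.generate_random_pump(pp.RandomPumpSpec(seed=seed, **kwargs))
        return pp.build_model(cfg)

    return make
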