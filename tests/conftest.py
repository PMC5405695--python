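import pytest
from hypothesis import HealthCheck, settings

from merochip.model import PipelineConfig
from merochip.simulate import SimulationParams, simulate_study

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study, shared across the suite."""
    return simulate_study(SimulationParams(seed=42))


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def denovo_calls(bundle):
    """De novo cascade run on every unannotated peak of every replicate."""
    from merochip.annotate import categorize_peaks
    from merochip.denovo import annotate_unknown_peaks

    unknown = [
        a.peak
        for rep in sorted(bundle.peaks)
        for a in categorize_peaks(bundle.peaks[rep], bundle.features)
        if a.category == "unannotated"
    ]
    return annotate_unknown_peaks(
        unknown, bundle.sequences, bundle.proteins, {}, PipelineConfig()
    )
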