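import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from translatome import diffexpr, simulate  # noqa: E402


@pytest.fixture(scope="session")
def default_universe():
    """Default-condition 20000-gene universe with planted truth."""
    config = simulate.SimulationConfig(seed=1)
    features, truth = simulate.simulate_gene_universe(config)
    return config, features, truth


@pytest.fixture(scope="session")
def default_experiment(default_universe):
    """Expression data simulated under the default study conditions."""
    config, features, truth = default_universe
    experiment = simulate.simulate_expression(truth, config)
    return config, features, truth, experiment


@pytest.fixture()
def tiny_matrix():
    """6-gene, 2 vs 2 expression matrix with hand-listed values (one population)."""
    values = pd.DataFrame(
        {
            "TOT_control_1": [5.0, 7.1, 9.0, 6.2, 8.8, 4.4],
            "TOT_control_2": [5.4, 7.0, 9.2, 6.0, 8.6, 4.6],
            "TOT_stress_1": [6.9, 7.3, 8.1, 6.1, 8.9, 6.5],
            "TOT_stress_2": [7.2, 7.2, 7.8, 6.3, 8.7, 6.2],
        },
        index=[f"g{i}" for i in range(1, 7)],
    )
    samples = pd.DataFrame(
        {
            "sample_id": list(values.columns),
            "condition": ["control", "control", "stress", "stress"],
            "population": ["TOT"] * 4,
            "replicate": [1, 2, 1, 2],
        }
    )
    # moderated t needs both populations present only for the one being tested;
    # duplicate the TOT samples as PB so the container validates
    pb = values.copy()
    pb.columns = [c.replace("TOT", "PB") for c in values.columns]
    samples_pb = samples.copy()
    samples_pb["sample_id"] = list(pb.columns)
    samples_pb["population"] = "PB"
    return diffexpr.ExpressionMatrix(
        values=pd.concat([values, pb], axis=1),
        samples=pd.concat([samples, samples_pb], ignore_index=True),
    )
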