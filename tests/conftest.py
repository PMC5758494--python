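import numpy as np
import pandas as pd
import pytest

from aisrisk.pipeline import PipelineConfig, covariate_tables
from aisrisk.synthetic import GeneratorConfig, generate_landscape


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A reduced landscape that keeps geostatistical tests fast."""
    return GeneratorConfig(
        n_waterbodies=250, n_parents=20, survey_count=1500, n_stations=25, seed=11
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_tables(small_landscape) -> dict[str, pd.DataFrame]:
    return covariate_tables(small_landscape)


@pytest.fixture(scope="session")
def default_pipeline_config() -> PipelineConfig:
    return PipelineConfig().with_seed(7)


def random_points(rng: np.random.Generator, n: int, span: float = 1.0) -> np.ndarray:
    return rng.uniform(0.0, span, (n, 2))
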