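import numpy as np
import pytest

from bactss.simulate import SyntheticConfig, generate_dataset, truth_scorer
from bactss.pipeline import PipelineConfig, run_analysis


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset (seed 1), shared across the suite."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_run(dataset):
    """Full analysis of the default dataset plus its recovery report."""
    result = run_analysis(
        dataset.genome, dataset.features, dataset.profiles,
        spanning_counts=dataset.spanning_counts, reads=dataset.reads,
        cis_elements=dataset.cis_elements, config=PipelineConfig(seed=1))
    report = truth_scorer(result, dataset.truth, tolerance_nt=0)
    return report, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
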