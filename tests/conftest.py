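import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mkpatterns.preprocess import preprocess_pipeline
from mkpatterns.simulate import SimulationConfig, design_sample_sheet, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# noise-free replicate columns are identical by construction; scipy warns
# about catastrophic cancellation on them, which the degenerate-row
# conventions handle deliberately
warnings.filterwarnings(
    "ignore", message="Precision loss occurred", category=RuntimeWarning
)


@pytest.fixture(scope="session")
def default_sim():
    """Default study-design simulation: 2,000 genes, 50 per group I-VI,
    300 genotype-independent responders, noise_sd_log2=0.15, 4 replicates."""
    return generate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def noise_free_sim():
    return generate_dataset(SimulationConfig(seed=7, noise_sd_log2=0.0, array_scale_sd_log2=0.0))


@pytest.fixture(scope="session")
def default_gm(default_sim):
    return preprocess_pipeline(default_sim.probe_matrix, default_sim.samples, default_sim.annotation)


@pytest.fixture(scope="session")
def noise_free_gm(noise_free_sim):
    return preprocess_pipeline(
        noise_free_sim.probe_matrix, noise_free_sim.samples, noise_free_sim.annotation
    )


@pytest.fixture()
def tiny_samples():
    """Two-replicate, single-LPS-timepoint design for hand-built matrices."""
    return design_sample_sheet(replicates=2, timepoints=(120,))


def make_gene_matrix(values: dict, samples: pd.DataFrame):
    """Build a GeneMatrix directly from {gene: {sample_id: value}}."""
    from mkpatterns.containers import GeneMatrix

    df = pd.DataFrame(values).T
    df = df[samples["sample_id"].tolist()]
    df.index.name = "gene"
    return GeneMatrix(values=df, samples=samples)
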