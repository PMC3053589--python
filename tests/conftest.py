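import numpy as np
import pandas as pd
import pytest

from exonflow.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_design,
    generate_probe_library,
    simulate_intensities,
)
from exonflow.chipdef import build_chipdef


def make_design(n_patients: int = 6, subtype_split: float = 0.5) -> pd.DataFrame:
    return generate_design(SimulationConfig(n_patients=n_patients,
                                            subtype_split=subtype_split, seed=0))


@pytest.fixture(scope="session")
def design6() -> pd.DataFrame:
    return make_design(6)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(n_genes=20, seed=7)


@pytest.fixture(scope="session")
def sim_dataset(sim_config, tmp_path_factory):
    """Complete synthetic dataset written to disk once per session."""
    from exonflow.simulate import simulate_dataset

    outdir = tmp_path_factory.mktemp("simdata")
    paths = simulate_dataset(sim_config, outdir)
    return paths


@pytest.fixture(scope="session")
def sim_parts(sim_config):
    """In-memory annotation, truth, design, probes and intensities."""
    annotation, truth = generate_annotation(sim_config)
    design = generate_design(sim_config)
    probes = generate_probe_library(annotation, sim_config, truth)
    intensities = simulate_intensities(probes, design, truth, sim_config)
    return annotation, truth, design, probes, intensities


@pytest.fixture(scope="session")
def sim_chipdef(sim_dataset):
    return build_chipdef(sim_dataset["gtf"], sim_dataset["probes"])


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
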