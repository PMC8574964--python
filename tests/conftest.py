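import numpy as np
import pandas as pd
import pytest

from netkit.simulate import (
    SampleSpec,
    SimulationConfig,
    default_cohort_design,
    generate_contaminated_cohort,
    generate_pure_profiles,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=1234)


@pytest.fixture(scope="session")
def pure_profiles(sim_config):
    """Pure per-cell-type profiles plus planted marker truth."""
    return generate_pure_profiles(sim_config)


@pytest.fixture(scope="session")
def pure_cohort(sim_config, pure_profiles):
    """Noisy but uncontaminated cohort: every sample is its pure type + noise."""
    profiles, markers = pure_profiles
    design = [
        SampleSpec(s.sample_id, s.cell_type, s.compartment, s.patient_id, {}, False)
        for s in default_cohort_design(sim_config)
    ]
    matrix, meta, _ = generate_contaminated_cohort(profiles, sim_config, design)
    return matrix, meta, markers


@pytest.fixture(scope="session")
def noisefree_cohort(pure_profiles):
    """Noise-free contaminated cohort where contaminant source types stay pure.

    TU samples carry TAM at known fractions while TAM (and every other
    type) is uncontaminated, so cohort-median contaminant profiles equal
    the pure profiles and linear unmixing is exact.
    """
    config = SimulationConfig(seed=77, noise_sigma=0.0)
    profiles, markers = pure_profiles
    design = []
    for spec in default_cohort_design(config):
        fracs = dict(spec.fracs) if spec.cell_type == "TU" else {}
        design.append(SampleSpec(spec.sample_id, spec.cell_type, spec.compartment,
                                 spec.patient_id, fracs, False))
    matrix, meta, truth = generate_contaminated_cohort(profiles, config, design)
    return matrix, meta, truth, markers, profiles


def tiny_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


def tiny_meta(rows):
    """rows: list of (sample_id, cell_type, compartment, patient, is_reference)."""
    return pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "compartment",
                       "patient_id", "is_reference"]).set_index("sample_id")
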