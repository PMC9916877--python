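import numpy as np
import pandas as pd
import pytest

from circheterosis import synthetic
from circheterosis.design import SampleDesign, default_design


@pytest.fixture(scope="session")
def noise_free_study():
    """Noise-free synthetic study: zero jitter/dropout/count noise, Poisson-free
    planted means — downstream stages must recover every planted label."""
    return synthetic.simulate_study(
        seed=11, n_circ=100, n_genes=90, jitter_sd=0.0, fn_rate=0.0,
        count_noise=0.0, dispersion=0.0,
    )


@pytest.fixture(scope="session")
def noisy_study():
    """Default-noise synthetic study at toy scale."""
    return synthetic.simulate_study(seed=7, n_circ=120, n_mirnas=20)


@pytest.fixture(scope="session")
def small_design():
    rows = []
    for gt, role in [("FP1", "FP"), ("MP1", "MP"), ("H1", "F1_high"), ("L1", "F1_low")]:
        for rep in (1, 2, 3):
            rows.append({"sample_id": f"{gt}_r{rep}", "genotype": gt, "role": role, "replicate": rep})
    samples = pd.DataFrame(rows)
    mapped = pd.Series(2e6, index=samples["sample_id"].values)
    return SampleDesign(samples, mapped)


@pytest.fixture(scope="session")
def default_design_fixture():
    return default_design(seed=0)


@pytest.fixture(scope="session")
def annotation_and_genome():
    return synthetic.generate_annotation(seed=5, n_chroms=3, n_genes=160)
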