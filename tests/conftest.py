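import numpy as np
import pandas as pd
import pytest

from teratoclass.core_io import ExpressionStudy, load_paper_fixtures
from teratoclass.synthetic_data import CompoundSpec, SimulationConfig, generate_study


@pytest.fixture(scope="session")
def bundle():
    return load_paper_fixtures()


@pytest.fixture
def tiny_study():
    """3 probe sets x 4 samples: 2 controls + 2 treated in one batch."""
    matrix = pd.DataFrame(
        {
            "c1": [5.0, 5.0, 5.0],
            "c2": [7.0, 7.0, 7.0],
            "t1": [10.0, 6.0, 6.0],
            "t2": [10.0, 6.0, 6.0],
        },
        index=["PS1_at", "PS2_at", "PS3_at"],
    )
    samples = pd.DataFrame(
        {
            "compound_id": ["CONTROL", "CONTROL", "CMP", "CMP"],
            "concentration_label": ["1x", "1x", "1x", "1x"],
            "replicate": [1, 2, 1, 2],
            "batch": [0, 0, 0, 0],
            "is_control": [True, True, False, False],
            "matched_controls": [[], [], [], []],
        },
        index=pd.Index(["c1", "c2", "t1", "t2"], name="sample_id"),
    )
    return ExpressionStudy(matrix=matrix, samples=samples)


@pytest.fixture(scope="session")
def small_synthetic():
    """One strongly deregulated teratogen + one silent non-teratogen."""
    config = SimulationConfig(
        compounds=[
            CompoundSpec("TOX", "teratogen", "20x", n_deregulated=100),
            CompoundSpec("NEG", "non_teratogen", "20x", n_deregulated=0),
        ],
        n_probe_sets=800,
        effect_size_range=(3.0, 3.0),
        noise_sd=0.1,
        batch_sd=0.5,
        n_batches=2,
        seed=7,
    )
    return generate_study(config)


def loo_config(seed=11, n_probe_sets=5000):
    """The default parameter-recovery study: 12 teratogens with planted
    deregulation in [200, 2000], 8 silent non-teratogens."""
    rng = np.random.default_rng(seed)
    scale = n_probe_sets / 5000
    lo, hi = max(int(200 * scale), 10), max(int(2000 * scale), 20)
    compounds = []
    for i in range(12):
        compounds.append(
            CompoundSpec(
                f"T{i:02d}",
                "teratogen",
                "20x",
                n_deregulated=int(rng.integers(lo, hi + 1)),
            )
        )
    for i in range(8):
        compounds.append(
            CompoundSpec(f"N{i:02d}", "non_teratogen", "20x", n_deregulated=0)
        )
    return SimulationConfig(
        compounds=compounds,
        n_probe_sets=n_probe_sets,
        noise_sd=0.25,
        batch_sd=0.5,
        n_batches=4,
        seed=seed,
    )
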