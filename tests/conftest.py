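import numpy as np
import pandas as pd
import pytest

import methsig as ms


@pytest.fixture(scope="session")
def small_params() -> ms.SimulationParams:
    """A reduced study: 4,000 probes, 120 signature CpGs, 8 cases vs 23
    controls at the default effect size and noise."""
    return ms.SimulationParams(n_probes=4000, n_signature=120, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params) -> ms.SimulatedDataset:
    return ms.generate_dataset(small_params)


@pytest.fixture(scope="session")
def small_panel(small_params) -> ms.CellTypePanel:
    return ms.generate_reference_panel(small_params)


@pytest.fixture(scope="session")
def small_run(small_dataset, small_panel) -> ms.PipelineResult:
    cfg = ms.PipelineConfig(n_boot=60, seed=11)
    return ms.run_pipeline(
        cfg, small_dataset.beta, small_dataset.manifest, small_dataset.samples,
        panel=small_panel,
    )


@pytest.fixture()
def toy_beta() -> ms.BetaMatrix:
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        rng.uniform(0.05, 0.95, (6, 4)),
        index=pd.Index([f"cg{i}" for i in range(6)], name="probe_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    return ms.BetaMatrix(df)
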