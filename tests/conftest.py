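import numpy as np
import pandas as pd
import pytest

from proteoconsensus import (
    ImputationParams,
    SimConfig,
    build_dataset_collection,
    filter_proteins,
    log2_transform,
    simulate_experiment,
)

PLANTED_OUTLIERS = {"si-NT_long_r1", "si-hVDAC1_long_r1"}


@pytest.fixture(scope="session")
def small_experiment():
    """A small mixed-species experiment with censoring and planted outliers."""
    cfg = SimConfig(
        n_human_proteins=250,
        n_mouse_proteins=40,
        seed=7,
        outlier_sample_shift=4.0,
        de_fraction=0.1,
    )
    table, annots, sheet, truth = simulate_experiment(cfg)
    return cfg, table, annots, sheet, truth


@pytest.fixture(scope="session")
def small_collection(small_experiment):
    """Dataset collection (1 + 5 imputed) for the human subset of the small experiment."""
    _, table, annots, sheet, _ = small_experiment
    logm = log2_transform(filter_proteins(table, annots, "human", 1))
    return build_dataset_collection(logm, ImputationParams(base_seed=11)), sheet


@pytest.fixture()
def toy_logmatrix():
    """4 proteins x 4 samples with two missing cells."""
    rng = np.random.default_rng(0)
    m = pd.DataFrame(
        rng.normal(25, 1, size=(4, 4)),
        index=[f"P{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(4)],
    )
    m.iloc[0, 1] = np.nan
    m.iloc[2, 3] = np.nan
    return m


def make_sheet(replicates=3):
    rows = []
    for duration in ("short", "long"):
        for treatment in ("si-NT", "si-hVDAC1"):
            for r in range(1, replicates + 1):
                rows.append({
                    "sample_id": f"{treatment}_{duration}_r{r}",
                    "treatment": treatment,
                    "duration": duration,
                    "replicate": r,
                    "included": True,
                })
    return pd.DataFrame(rows)
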