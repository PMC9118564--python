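import numpy as np
import pandas as pd
import pytest

import braintmap as bt


@pytest.fixture(scope="session")
def small_config() -> bt.SyntheticConfig:
    """A reduced cohort/transcriptome for fast end-to-end tests."""
    return bt.SyntheticConfig(
        group_sizes={"CN": 40, "EMCI": 40, "LMCI": 40, "AD": 40},
        n_rois=60,
        n_genes=300,
        n_signal_genes=5,
        signal_r_target=0.6,
        effect_sizes={"EMCI": 0.15, "LMCI": 0.25, "AD": 0.35},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return bt.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_effect_maps(small_dataset):
    pheno, imaging, _, _ = small_dataset
    return [
        bt.DiagnosisEffectModel(pheno, imaging, c).fit()
        for c in bt.build_contrasts()
    ]


@pytest.fixture()
def toy_phenotypes() -> bt.PhenotypeTable:
    return bt.PhenotypeTable(
        pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(8)],
                "diagnosis": ["CN"] * 4 + ["AD"] * 4,
                "age": [70.0, 75.0, 80.0, 72.0, 71.0, 77.0, 83.0, 74.0],
                "sex": [1, 0, 1, 0, 1, 1, 0, 0],
                "education": [16.0, 12.0, 18.0, 14.0, 20.0, 13.0, 15.0, 17.0],
            }
        )
    )


@pytest.fixture()
def hcpmmp_style_labels() -> list[str]:
    """A full 360-label two-hemisphere atlas list (180 left + 180 right)."""
    left = [f"L_A{i:03d}_ROI" for i in range(1, 181)]
    right = [f"R_A{i:03d}_ROI" for i in range(1, 181)]
    out = []
    for l, r in zip(left, right):
        out.extend([l, r])
    return out
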