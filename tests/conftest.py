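import numpy as np
import pandas as pd
import pytest

from twinewas import BetaMatrix, SimConfig, simulate_cohort


@pytest.fixture
def small_matrix():
    df = pd.DataFrame(
        [[0.1, 0.9], [0.5, 0.5]],
        index=["cgA", "cgB"],
        columns=["s1", "s2"],
    )
    return BetaMatrix(df)


@pytest.fixture
def discordant_sheet():
    """Two discordant pairs, buccal ages 10/18 plus blood 18."""
    rows = []
    for fam, exposed_twin in (("F1", "A"), ("F2", "B")):
        for twin in "AB":
            ind = f"{fam}{twin}"
            for tissue, age in (("buccal", 10), ("buccal", 18), ("blood", 18)):
                rows.append(
                    {
                        "sample_id": f"{ind}_{tissue}{age}",
                        "individual_id": ind,
                        "family_id": fam,
                        "group": 1,
                        "exposed": twin == exposed_twin,
                        "sex": "F",
                        "age": age,
                        "tissue": tissue,
                        "smoking_pack_years": 0.0,
                        "cell_epithelial": 0.8 if tissue == "buccal" else np.nan,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Small simulated cohort shared across read-only tests."""
    cfg = SimConfig(n_pairs_by_group=(8, 4, 4), n_probes=120, seed=1)
    return simulate_cohort(cfg)
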