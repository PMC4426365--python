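import numpy as np
import pandas as pd
import pytest

import subdrift as sd


@pytest.fixture(scope="session")
def schedule():
    return sd.default_nod_schedule()


@pytest.fixture(scope="session")
def drift_table(schedule):
    """One default-parameter drift realization plus its branch truth."""
    return sd.simulate_drift(schedule, sd.DriftParams(seed=42))


@pytest.fixture()
def toy_table():
    """Hand-built 3-substrain, 4-variant table.

    v1: A/A/T, v2: C/G/G, v3: T/T/T (alt in all; non-informative),
    v4: A/C/A -> pairwise SNP distances d(1,2)=d(1,3)=d(2,3)=2.
    """
    variants = pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "2"],
            "pos": [100, 200, 50, 80],
            "ref": ["A", "C", "G", "A"],
            "alt": ["T", "G", "T", "C"],
            "vclass": ["SNP"] * 4,
            "consequence": ["missense_variant", None, "intron_variant", None],
            "coding": [True, False, False, False],
        }
    )
    calls = np.array(
        [
            [False, False, True],   # A/A/T
            [False, True, True],    # C/G/G
            [True, True, True],     # T/T/T
            [False, True, False],   # A/C/A
        ]
    )
    return sd.GenotypeTable(variants, calls, ["s1", "s2", "s3"])


@pytest.fixture(scope="session")
def two_tip_schedule():
    """Two substrains separated 25 years ago: 100 generations per lineage."""
    root = sd.ScheduleNode(
        date=1989,
        children=[sd.ScheduleNode(name="A"), sd.ScheduleNode(name="B")],
    )
    return sd.SeparationSchedule(root, sampling_year=2014, generations_per_year=4)
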