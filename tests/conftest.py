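import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nucleus_df():
    """Small well-formed nucleus table covering all five genotypes."""
    rows = []
    specs = [  # (genotype intent, erbb2, cep17, mut, wt)
        ("WT", 2, 2, 0, 2), ("Amp", 8, 2, 0, 0), ("Mut", 2, 2, 1, 1),
        ("WT-Amp", 10, 2, 0, 1), ("Mut-Amp", 12, 2, 2, 0),
        ("Undetermined", 1, 1, 0, 0),
    ]
    i = 0
    for patient in ("P1", "P2"):
        for tp in ("pre", "post"):
            for img in ("img0", "img1"):
                for g, e, c, m, w in specs:
                    rows.append({
                        "patient_id": patient, "sample_id": f"{patient}-{tp}",
                        "timepoint": tp, "image_id": f"{patient}-{tp}-{img}",
                        "nucleus_id": f"n{i}", "x": float(i % 7) * 10,
                        "y": float(i % 5) * 10, "n_erbb2": e, "n_cep17": c,
                        "n_mut": m, "n_wt": w,
                    })
                    i += 1
    return pd.DataFrame(rows)


@pytest.fixture
def labeled_points(rng):
    """200 uniformly placed cells of 3 types on a 1 mm field."""
    n = 200
    return pd.DataFrame({
        "x": rng.uniform(0, 1000, n),
        "y": rng.uniform(0, 1000, n),
        "label": rng.choice(["A", "B", "C"], n),
    })
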