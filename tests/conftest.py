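import numpy as np
import pandas as pd
import pytest

import fifteend as f


@pytest.fixture(scope="session")
def norwegian():
    return f.norwegian_algorithm()


@pytest.fixture(scope="session")
def population():
    return f.norwegian_population()


@pytest.fixture(scope="session")
def joint_population():
    """Synthetic crossed population table (uniform cells) for crossed weighting."""
    rows = [
        (g, a, e, 100)
        for g in f.GENDERS
        for a in f.AGE_GROUPS
        for e in f.EDUCATION_LEVELS
    ]
    return pd.DataFrame(rows, columns=["gender", "age_group", "education", "count"])


def random_demographics(n, seed, education_subset=None):
    rng = np.random.default_rng(seed)
    edu = education_subset or f.EDUCATION_LEVELS
    return pd.DataFrame(
        {
            "respondent_id": [f"r{i:04d}" for i in range(n)],
            "gender": rng.choice(f.GENDERS, n),
            "age_group": rng.choice(f.AGE_GROUPS, n),
            "education": rng.choice(edu, n),
        }
    )


def random_truth(seed):
    """A random valid truth algorithm whose noise-free scores stay on-scale.

    Relative scores are monotone in level with level-5 scores below 1.2 and a
    pits disutility below 1.6, so at a dead location of 50 VAS units no
    generated score needs clamping.
    """
    rng = np.random.default_rng(seed)
    increments = rng.uniform(0.05, 0.28, size=(4, f.N_DIMENSIONS))
    S = np.vstack([np.zeros(f.N_DIMENSIONS), np.cumsum(increments, axis=0)])
    S = S / S[4].max() * rng.uniform(0.8, 1.2)
    S_df = pd.DataFrame(S, index=list(f.LEVELS), columns=list(f.DIMENSIONS))
    v_pits = float(rng.uniform(0.8, 1.6))
    return f.build_algorithm(S_df, v_pits)
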