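import numpy as np
import pandas as pd
import pytest

from gcoutput.config import CohortConfig, RepertoireConfig, SerologyConfig
from gcoutput.synthetic import gen_repertoire


@pytest.fixture
def small_cohort():
    return CohortConfig(subjects_per_group=2, seed=11)


@pytest.fixture
def small_repertoire(small_cohort):
    rep = RepertoireConfig(cells_per_subject=15)
    return gen_repertoire(small_cohort, rep)


@pytest.fixture
def noiseless_serology():
    return SerologyConfig(od_noise_sd=0.0, group_deficit={"anti-TNF": 40.0})


def random_junctions(rng, n, length):
    bases = np.array(list("ACGT"))
    return ["".join(rng.choice(bases, length)) for _ in range(n)]


def make_heavy_records(rng, n, n_v=2, n_j=2, lengths=(12, 15), n_founders=4):
    """Random heavy-chain records for clone-clustering tests.

    Junctions are noisy copies of a handful of founders so that pairwise
    distances straddle any clustering threshold (merges actually happen).
    """
    bases = np.array(list("ACGT"))
    founders = {length: [rng.choice(bases, length) for _ in range(n_founders)]
                for length in lengths}
    rows = []
    for i in range(n):
        length = int(rng.choice(lengths))
        junction = founders[length][int(rng.integers(n_founders))].copy()
        n_mut = int(rng.integers(0, max(2, length // 3)))
        for pos in rng.choice(length, size=n_mut, replace=False):
            junction[pos] = rng.choice(bases)
        rows.append({
            "sequence_id": f"seq-{i:03d}",
            "cell_id": f"cell-{i:03d}",
            "chain": "heavy",
            "v_call": f"IGHV{rng.integers(1, n_v + 1)}-1*01",
            "j_call": f"IGHJ{rng.integers(1, n_j + 1)}*01",
            "junction": "".join(junction),
        })
    return pd.DataFrame(rows)
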