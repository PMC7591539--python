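import numpy as np
import pandas as pd
import pytest

import stressmito as sm


@pytest.fixture(scope="session")
def cohort():
    """Default-condition cohort (11 CTR / 16 STRESS), fixed seed."""
    table, truth = sm.simulate_cohort(seed=11)
    return table, truth


@pytest.fixture(scope="session")
def scored(cohort):
    table, _ = cohort
    return sm.score_behavior(table)


@pytest.fixture(scope="session")
def small_counts(cohort, scored):
    """Modest synthetic count matrix with all three gene classes."""
    _, truth = cohort
    gt = sm.make_gene_truth(n_nuclear=300, seed=5)
    z = scored.set_index("animal_id")["integrated_z"]
    cm = sm.simulate_counts(gt, truth, seed=6, integrated_z=z)
    return cm, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def sharp_pwms():
    """Near-deterministic PWMs whose consensus scores far above background."""
    rng = np.random.default_rng(3)
    pwms = []
    for i in range(3):
        cons = rng.integers(0, 4, 8)
        mat = np.full((4, 8), 0.01)
        mat[cons, np.arange(8)] = 0.97
        pwms.append(sm.PWM(f"m{i+1}", mat))
    return pwms
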