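import numpy as np
import pandas as pd
import pytest

from rarcat import (CostMatrix, DistanceMatrix, StateSequenceSet,
                    SimulationConfig, pairwise_matrix, simulate_dataset,
                    trate_costs, transition_rates)


@pytest.fixture
def toy_seqs():
    """Three short sequences over {A, B, *} with one numeric covariate."""
    ids = ["a", "b", "c"]
    states = np.array([
        ["A", "A", "B", "B"],
        ["A", "B", "B", "B"],
        ["A", "A", "A", "*"],
    ], dtype=object)
    cov = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=pd.Index(ids, name="id"))
    return StateSequenceSet(ids=ids, states=states, alphabet=["A", "B", "*"],
                            missing_code="*", covariates=cov)


def random_seqs(rng, m, t, alphabet=("A", "B", "C"), missing="C"):
    states = rng.choice(list(alphabet), size=(m, t)).astype(object)
    ids = [f"i{k}" for k in range(m)]
    return StateSequenceSet(ids=ids, states=states, alphabet=list(alphabet),
                            missing_code=missing)


@pytest.fixture
def unit_costs():
    """Unit substitution costs, indel 1 (the Levenshtein reduction)."""
    sub = np.ones((3, 3)) - np.eye(3)
    return CostMatrix(alphabet=["A", "B", "C"], sub=2 * sub, indel=1.0, cmax=2.0)


@pytest.fixture
def separated_distance():
    """Three tight groups of 4 points each: within 0..0.2, between >= 8."""
    rng = np.random.default_rng(42)
    n = 12
    centers = np.array([0.0, 10.0, 25.0])
    pos = centers.repeat(4) + rng.uniform(-0.1, 0.1, size=n)
    d = np.abs(pos[:, None] - pos[None, :])
    return DistanceMatrix(ids=[f"p{k}" for k in range(n)], d=d)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-shaped synthetic cohort at desk scale, with its distances."""
    cfg = SimulationConfig(n=120, seed=11)
    seqs, types, mixture = simulate_dataset(cfg)
    costs = trate_costs(transition_rates(seqs), cfg.missing_code)
    dist = pairwise_matrix(seqs, costs)
    return {"config": cfg, "seqs": seqs, "types": types, "mixture": mixture,
            "costs": costs, "dist": dist}
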