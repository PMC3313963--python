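import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import epicore as ec

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def blosum62():
    return ec.load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def motif_profile():
    """A fixed three-anchor profile (dominant P9, companions P8/P4)."""
    return ec.generate_motif(anchor_strength=0.9, rng=np.random.default_rng(2024))


@pytest.fixture(scope="session")
def small_labeled_set(motif_profile):
    """40 unique motif cores vs 300 background nonamers."""
    return ec.generate_labeled_set(motif_profile, 40, 300, seed=11)


@pytest.fixture(scope="session")
def baseline_model(small_labeled_set, blosum62):
    """Untrained unit-weight model over the small labeled set's cores."""
    table = ec.loo_score_table(
        small_labeled_set.positives, small_labeled_set.negatives, blosum62
    )
    thresholds = ec.calibrate_thresholds(table)
    return ec.Model(
        cores=list(small_labeled_set.positives),
        matrix=blosum62.copy(),
        weights=ec.PositionWeights(),
        thresholds=thresholds,
    )


@pytest.fixture(scope="session")
def trained_small_model(small_labeled_set):
    cfg = ec.TrainingConfig(seed=5, patience=150, max_proposals=1500)
    return ec.train_model(
        small_labeled_set.positives, small_labeled_set.negatives, cfg
    )


def brute_force_similarity(a, b, matrix, weights=None):
    """Independent oracle: plain double loop over positions, then clamping."""
    w = [1.0] * 9 if weights is None else list(weights)
    total = sum(w[i] * matrix.score(a[i], b[i]) for i in range(9))
    return max(total, 0.0)


def brute_force_model_score(query, cores, matrix, weights=None):
    sims = [brute_force_similarity(query, c, matrix, weights) for c in cores]
    return sum(sims) / len(sims)


def random_peptides(rng, n, length=9):
    return [
        "".join(rng.choice(list(ec.AMINO_ACIDS), size=length)) for _ in range(n)
    ]
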