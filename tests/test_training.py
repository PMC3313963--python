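import numpy as np
import pytest

import epicore as ec
from epicore.training import TrainingState
from tests.conftest import brute_force_model_score, random_peptides


# ---------------------------------------------------------------------------
# the objective


def test_sn_at_fixed_sp_enumeration_example():
    table = ec.ScoreTable([11.0, 12.0], list(range(1, 11)))
    sn, t = ec.sn_at_fixed_sp(table, 0.90)
    assert t == 9.0  # exactly one negative (score 10) above the cutoff
    assert sn == 1.0


def test_sn_at_fixed_sp_separable_scores():
    table = ec.ScoreTable([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
    for sp in (0.5, 0.9, 1.0):
        sn, t = ec.sn_at_fixed_sp(table, sp)
        assert sn == 1.0 and t < 5.0


def test_sn_at_fixed_sp_all_tied_scores():
    table = ec.ScoreTable([2.0] * 5, [2.0] * 5)
    sn, t = ec.sn_at_fixed_sp(table, 0.90)
    assert t == 2.0 and sn == 0.0  # strict > leaves nothing above the tie


def test_sn_at_fixed_sp_validates_target():
    table = ec.ScoreTable([1.0], [0.0])
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            ec.sn_at_fixed_sp(table, bad)


# ---------------------------------------------------------------------------
# LOO scoring


def test_loo_table_matches_brute_force_double_loop(blosum62):
    rng = np.random.default_rng(10)
    positives = list(dict.fromkeys(random_peptides(rng, 10)))
    negatives = random_peptides(rng, 20)
    table = ec.loo_score_table(positives, negatives, blosum62)
    for i, p in enumerate(positives):
        others = positives[:i] + positives[i + 1 :]
        assert table.positive_scores[i] == brute_force_model_score(p, others, blosum62)
    for j, n in enumerate(negatives):
        assert table.negative_scores[j] == brute_force_model_score(n, positives, blosum62)


def test_two_identical_positives_score_their_self_similarity(blosum62):
    table = ec.loo_score_table(
        ["NGVLNSWTD", "ngvlnswtd"], ["ACDEFGHIK"], blosum62
    )
    # case-normalized duplicates: each LOO-scores against the other copy
    assert list(table.positive_scores) == [52.0, 52.0]


def test_loo_preconditions(blosum62):
    with pytest.raises(ValueError, match="2 positives"):
        ec.loo_score_table(["NGVLNSWTD"], ["ACDEFGHIK"], blosum62)
    with pytest.raises(ValueError, match="negative"):
        ec.loo_score_table(["NGVLNSWTD", "ACDEFGHIK"], [], blosum62)


# ---------------------------------------------------------------------------
# incremental state vs full recomputation


def _fresh_state(seed=20, n_pos=15, n_neg=40):
    rng = np.random.default_rng(seed)
    positives = list(dict.fromkeys(random_peptides(rng, n_pos)))
    negatives = list(dict.fromkeys(random_peptides(rng, n_neg)))
    return TrainingState(positives, negatives)


def _full_scores(state):
    table = ec.loo_score_table(
        state.pos_seqs, state.neg_seqs, state.matrix, state.weights
    )
    return table.positive_scores, table.negative_scores


def test_incremental_rescoring_agrees_exactly_with_full_recompute():
    state = _fresh_state()
    rng = np.random.default_rng(21)
    for _ in range(40):
        if rng.integers(2) == 0:
            proposal = state.propose_weight(int(rng.integers(9)), int(rng.choice([-1, 1])))
            if proposal is None:
                continue
        else:
            proposal = state.propose_matrix(
                int(rng.integers(20)), int(rng.integers(20)), int(rng.choice([-1, 1]))
            )
        state.accept(proposal)
    table = state.score_table()
    full_pos, full_neg = _full_scores(state)
    assert np.array_equal(table.positive_scores, full_pos)
    assert np.array_equal(table.negative_scores, full_neg)


def test_rejected_proposal_leaves_state_bit_identical():
    state = _fresh_state(seed=22)
    before = (
        state.weights.w.copy(),
        state.matrix.scores.copy(),
        state.raw_pp.copy(),
        state.raw_np.copy(),
    )
    # evaluate (and discard) a batch of proposals of both kinds
    rng = np.random.default_rng(23)
    for _ in range(10):
        state.propose_weight(int(rng.integers(9)), int(rng.choice([-1, 1])))
        state.propose_matrix(
            int(rng.integers(20)), int(rng.integers(20)), int(rng.choice([-1, 1]))
        )
    assert np.array_equal(before[0], state.weights.w)
    assert np.array_equal(before[1], state.matrix.scores)
    assert np.array_equal(before[2], state.raw_pp)
    assert np.array_equal(before[3], state.raw_np)


def test_weight_proposals_never_drive_weights_negative():
    state = _fresh_state(seed=24)
    state.weights.w[3] = 0.0
    assert state.propose_weight(3, -1) is None
    proposal = state.propose_weight(3, 1)
    assert proposal is not None


def test_matrix_proposals_stay_symmetric():
    state = _fresh_state(seed=25)
    rng = np.random.default_rng(26)
    for _ in range(25):
        p = state.propose_matrix(
            int(rng.integers(20)), int(rng.integers(20)), int(rng.choice([-1, 1]))
        )
        state.accept(p)
    assert state.matrix.is_symmetric()


# ---------------------------------------------------------------------------
# the greedy stages


def test_wt_trace_is_monotone_and_upweights_informative_anchor(motif_profile):
    data = ec.generate_labeled_set(motif_profile, 60, 400, seed=30)
    state = TrainingState(data.positives, data.negatives)
    cfg = ec.TrainingConfig(patience=120, max_proposals=1200)
    trace = ec.weight_training(state, np.random.default_rng(31), cfg)
    accepted = [r.sn for r in trace if r.accepted]
    assert accepted == sorted(accepted)
    # the dominant anchor position should not have been down-weighted
    primary = max(motif_profile.anchors)  # position 9
    assert state.weights.w[primary - 1] >= 1.0


def test_mam_trace_is_monotone_and_never_hurts_the_objective(motif_profile):
    data = ec.generate_labeled_set(motif_profile, 40, 250, seed=32)
    state = TrainingState(data.positives, data.negatives)
    sn0, _ = state.objective()
    cfg = ec.TrainingConfig(patience=100, max_proposals=800)
    trace = ec.matrix_mutation(state, np.random.default_rng(33), cfg)
    accepted = [r.sn for r in trace if r.accepted]
    assert accepted == sorted(accepted)
    sn1, _ = state.objective()
    assert sn1 >= sn0


def test_zero_budget_leaves_matrix_unchanged():
    state = _fresh_state(seed=27)
    before = state.matrix.scores.copy()
    cfg = ec.TrainingConfig(max_proposals=0)
    assert ec.matrix_mutation(state, np.random.default_rng(0), cfg) == []
    assert np.array_equal(before, state.matrix.scores)


# ---------------------------------------------------------------------------
# train_model and the Model container


def test_disabled_stages_yield_plain_baseline(small_labeled_set, blosum62):
    cfg = ec.TrainingConfig(run_wt=False, run_mam=False, seed=1)
    model = ec.train_model(
        small_labeled_set.positives, small_labeled_set.negatives, cfg
    )
    assert model.matrix == blosum62
    assert (model.weights.w == 1.0).all()
    assert set(model.thresholds) == {"high", "medium", "low"}


def test_training_is_deterministic_given_seed(small_labeled_set):
    cfg = ec.TrainingConfig(seed=7, patience=60, max_proposals=400)
    m1 = ec.train_model(small_labeled_set.positives, small_labeled_set.negatives, cfg)
    m2 = ec.train_model(small_labeled_set.positives, small_labeled_set.negatives, cfg)
    assert m1 == m2


def test_model_file_round_trip_is_lossless(trained_small_model, tmp_path):
    path = tmp_path / "model.txt"
    trained_small_model.save(path)
    assert ec.Model.load(path) == trained_small_model


def test_model_threshold_ordering_and_tier_lookup(trained_small_model):
    t = trained_small_model.thresholds
    assert t["high"] >= t["medium"] >= t["low"]
    assert trained_small_model.default_tier == "medium"
    with pytest.raises(ValueError, match="unknown tier"):
        trained_small_model.threshold_for_tier("extreme")


def test_trained_model_does_not_underperform_baseline_on_heldout(
    motif_profile, small_labeled_set, trained_small_model, baseline_model
):
    heldout = ec.generate_labeled_set(motif_profile, 40, 300, seed=77)
    from epicore.evaluation import score_labeled_set

    trained = ec.roc_and_aroc(score_labeled_set(trained_small_model, heldout)).aroc
    base = ec.roc_and_aroc(score_labeled_set(baseline_model, heldout)).aroc
    assert trained >= base - 0.02  # greedy training must not wreck generalization
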