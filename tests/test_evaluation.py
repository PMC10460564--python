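import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from smmira import AssociationMatrix, EntityIndex, NIConfig, aupr, rank_auc
from smmira.errors import ValidationError
from smmira.evaluation import (
    global_loocv,
    kfold_cv,
    local_loocv,
    make_folds,
    make_ni_scorer,
    permutation_null,
    roc_points,
    tune_hyperparameters,
)
from smmira.fixtures import FixtureSpec, generate_fixture

from _oracles import auc_pair_counting


def oracle_scorer(assoc):
    """Perfect predictor: returns the full ground-truth matrix.

    The evaluation loops pass a masked copy, so closures capture the
    unmasked truth explicitly where needed.
    """
    return assoc.A.astype(float)


def make_truth_scorer(full_assoc):
    truth = full_assoc.A.astype(float)
    return lambda masked: truth


def constant_scorer(assoc):
    return np.zeros(assoc.A.shape)


def _small_assoc(seed=0, ns=6, nm=8, p=0.25):
    rng = np.random.default_rng(seed)
    A = (rng.random((ns, nm)) < p).astype(np.int8)
    A[0, 0] = A[1, 2] = 1
    return AssociationMatrix(
        sms=EntityIndex.from_ids([f"s{i}" for i in range(ns)]),
        mirnas=EntityIndex.from_ids([f"m{j}" for j in range(nm)]),
        A=A,
    )


class TestRankAuc:
    def test_perfect_separation(self):
        assert rank_auc([0.9], [0.1, 0.2]) == 1.0

    def test_all_ties_give_half(self):
        assert rank_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_hand_counted_example(self):
        assert rank_auc([0.8, 0.4], [0.6, 0.2]) == pytest.approx(0.75)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            rank_auc([], [0.1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # discretized scores force ties into the comparison
        pos = rng.integers(0, 10, rng.integers(1, 51)) / 10
        neg = rng.integers(0, 10, rng.integers(1, 51)) / 10
        assert rank_auc(pos, neg) == pytest.approx(
            auc_pair_counting(list(pos), list(neg)), abs=1e-12
        )

    def test_matches_sklearn_on_continuous_scores(self):
        rng = np.random.default_rng(123)
        pos, neg = rng.normal(1, 1, 40), rng.normal(0, 1, 60)
        labels = np.r_[np.ones(40), np.zeros(60)]
        assert rank_auc(pos, neg) == pytest.approx(
            roc_auc_score(labels, np.r_[pos, neg]), abs=1e-12
        )


class TestRocPoints:
    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_and_trapezoid_reproduces_auc(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 8, 30) / 8
        neg = rng.integers(0, 8, 50) / 8
        pts = roc_points(pos, neg)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        fpr = np.array([p[0] for p in pts])
        tpr = np.array([p[1] for p in pts])
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert np.trapezoid(tpr, fpr) == pytest.approx(rank_auc(pos, neg), abs=1e-9)


class TestAupr:
    def test_perfect_separation(self):
        assert aupr([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_single_positive_ranked_last(self):
        n_neg = 9
        neg = list(np.linspace(0.5, 0.9, n_neg))
        assert aupr([0.1], neg) == pytest.approx(1 / (n_neg + 1))

    def test_random_scores_near_prevalence(self):
        rng = np.random.default_rng(77)
        vals = []
        for _ in range(100):
            vals.append(aupr(rng.random(10), rng.random(990)))
        assert np.mean(vals) == pytest.approx(0.01, abs=0.01)


class TestGlobalLoocv:
    def test_perfect_oracle_reaches_auc_one(self):
        assoc = _small_assoc()
        res = global_loocv(assoc, make_truth_scorer(assoc))
        assert res.auc == 1.0

    def test_constant_scores_give_half(self):
        assoc = _small_assoc()
        res = global_loocv(assoc, constant_scorer)
        assert res.auc == pytest.approx(0.5, abs=1e-12)

    def test_rank_list_covers_every_positive(self):
        assoc = _small_assoc()
        res = global_loocv(assoc, constant_scorer)
        assert len(res.per_test_ranks) == assoc.n_associations

    def test_needs_at_least_two_positives(self):
        assoc = AssociationMatrix(
            sms=EntityIndex.from_ids(["s1"]),
            mirnas=EntityIndex.from_ids(["m1", "m2"]),
            A=np.array([[1, 0]]),
        )
        with pytest.raises(ValidationError):
            global_loocv(assoc, constant_scorer)


class TestLocalLoocv:
    @pytest.mark.parametrize("axis", ["mirna_fixed", "sm_fixed"])
    def test_perfect_oracle_reaches_auc_one(self, axis):
        assoc = _small_assoc()
        res = local_loocv(assoc, make_truth_scorer(assoc), axis)
        assert res.auc == 1.0

    @pytest.mark.parametrize("axis", ["mirna_fixed", "sm_fixed"])
    def test_constant_scores_give_half(self, axis):
        assoc = _small_assoc()
        res = local_loocv(assoc, constant_scorer, axis)
        assert res.auc == pytest.approx(0.5, abs=1e-12)

    def test_pair_with_empty_candidate_set_is_skipped(self):
        # s1's row is all ones: sm-fixed candidates for (s1, *) are empty
        assoc = AssociationMatrix(
            sms=EntityIndex.from_ids(["s1", "s2"]),
            mirnas=EntityIndex.from_ids(["m1", "m2"]),
            A=np.array([[1, 1], [1, 0]]),
        )
        res = local_loocv(assoc, constant_scorer, "sm_fixed")
        tested = {(s, m) for s, m, _, _ in res.per_test_ranks}
        assert tested == {("s2", "m1")}

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValidationError):
            local_loocv(_small_assoc(), constant_scorer, "bogus")


class TestKfoldCv:
    def test_fold_sizes_for_664_positives(self):
        folds = make_folds(664, 5, np.random.default_rng(0))
        assert sorted(len(f) for f in folds) == [132, 133, 133, 133, 133]

    def test_folds_partition_the_positives(self):
        rng = np.random.default_rng(3)
        folds = make_folds(50, 7, rng)
        combined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(combined, np.arange(50))

    def test_perfect_oracle_mean_one_sd_zero(self):
        assoc = _small_assoc()
        res = kfold_cv(assoc, make_truth_scorer(assoc), k=3, repetitions=3, seed=1)
        assert res.auc == 1.0
        assert res.auc_sd == 0.0

    def test_single_repetition_deterministic(self):
        assoc = _small_assoc(seed=5)
        a = kfold_cv(assoc, constant_scorer, k=3, repetitions=1, seed=9)
        b = kfold_cv(assoc, constant_scorer, k=3, repetitions=1, seed=9)
        assert a.auc == b.auc
        assert a.per_test_ranks == b.per_test_ranks

    def test_k_exceeding_positives_rejected(self):
        assoc = _small_assoc()
        with pytest.raises(ValidationError):
            kfold_cv(assoc, constant_scorer, k=assoc.n_associations + 1)


class TestPermutationNull:
    def test_centred_on_half(self):
        mean, sd = permutation_null(60, [100] * 60, n_permutations=100, seed=0)
        assert mean == pytest.approx(0.5, abs=0.05)
        assert 0 < sd < 0.1


class TestTuneHyperparameters:
    def _fixture(self):
        spec = FixtureSpec(
            ns=12, nm=16, sim_within=0.8, sim_between=0.2,
            sim_noise_sd=0.0, within_density=0.5, seed=2,
        )
        return generate_fixture(spec)

    def test_one_element_grids_returned_unchanged(self):
        assoc, sm_sim, mi_sim, _ = self._fixture()
        su, s = tune_hyperparameters(assoc, sm_sim, mi_sim, [0.3], [40], seed=0)
        assert (su, s) == (0.3, 40)

    def test_block_gap_fixture_tie_breaks_to_smallest_dominant_value(self):
        # noiseless similarities 0.4 within / 0.02 between: every
        # threshold in (0.02, 0.4] selects exactly the co-block
        # neighbors, so all sigma_upper candidates in that band produce
        # identical rankings (higher ones only rescale by a constant);
        # the tie must resolve to the smallest candidate
        spec = FixtureSpec(
            ns=12, nm=16, sim_within=0.4, sim_between=0.02,
            sim_noise_sd=0.0, within_density=0.5, seed=2,
        )
        assoc, sm_sim, mi_sim, _ = generate_fixture(spec)
        su, _ = tune_hyperparameters(
            assoc, sm_sim, mi_sim, [0.05, 0.2, 0.4, 0.5], [8],
            inner_k=3, seed=0,
        )
        assert su == 0.05

    def test_deterministic_under_fixed_seed(self):
        assoc, sm_sim, mi_sim, _ = self._fixture()
        args = (assoc, sm_sim, mi_sim, [0.1, 0.3], [4, 8])
        a = tune_hyperparameters(*args, inner_k=3, seed=11,
                                 rbm_base_cfg=_fast_rbm())
        b = tune_hyperparameters(*args, inner_k=3, seed=11,
                                 rbm_base_cfg=_fast_rbm())
        assert a == b


def _fast_rbm():
    from smmira import RBMConfig

    return RBMConfig(hidden_units=4, epochs=10, seed=0)


class TestProtocolSimulation:
    def test_permuted_truth_scores_centre_on_half(self):
        """Shuffling the ground-truth scores destroys the signal."""
        assoc = _small_assoc(seed=8, ns=5, nm=6, p=0.3)
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(100):
            perm = rng.permutation(assoc.A.size).reshape(assoc.A.shape)
            shuffled = assoc.A.astype(float).ravel()[perm]
            aucs.append(global_loocv(assoc, lambda m, s=shuffled: s).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)
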