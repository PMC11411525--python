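import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fifi.screening import (
    BinningConfig,
    ScreeningSet,
    TanimotoKernelSVC,
    auprc,
    bin_activity,
    consensus_score,
    murcko_scaffold,
    nn_similarity,
    predict_active_probability,
    scaffold_diversity,
    sequential_screen,
    split_distinct,
    tanimoto,
    tanimoto_matrix,
    train_classifier,
)


def _bits(positions, width=32):
    v = np.zeros(width, dtype=np.uint8)
    v[list(positions)] = 1
    return v


class TestTanimoto:
    def test_identical_nonzero(self):
        v = _bits({1, 5, 9})
        assert tanimoto(v, v) == 1.0

    def test_disjoint(self):
        assert tanimoto(_bits({0, 1}), _bits({2, 3})) == 0.0

    def test_half_overlap(self):
        assert tanimoto(_bits({1, 2, 3}), _bits({2, 3, 4})) == 0.5

    def test_empty_defined_zero(self):
        assert tanimoto(_bits(set()), _bits(set())) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(_bits({1}), _bits({1}, width=16))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=4, max_size=32),
           st.lists(st.booleans(), min_size=4, max_size=32))
    def test_symmetric_and_bounded(self, a, b):
        n = min(len(a), len(b))
        va, vb = np.array(a[:n], dtype=np.uint8), np.array(b[:n], dtype=np.uint8)
        s = tanimoto(va, vb)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(vb, va)


class TestNNSimilarity:
    def test_identical_row_gives_one(self):
        train = np.vstack([_bits({1, 2}), _bits({5, 6, 7})])
        test = np.vstack([_bits({5, 6, 7})])
        best, arg = nn_similarity(test, train)
        assert best[0] == 1.0 and arg[0] == 1

    def test_single_train_row_equals_pairwise(self):
        train = np.vstack([_bits({1, 2, 3})])
        test = np.vstack([_bits({2, 3, 4}), _bits({9})])
        best, _ = nn_similarity(test, train)
        assert best[0] == tanimoto(test[0], train[0])
        assert best[1] == tanimoto(test[1], train[0])

    def test_brute_force_oracle(self, rng):
        test = rng.integers(0, 2, size=(20, 16)).astype(np.uint8)
        train = rng.integers(0, 2, size=(10, 16)).astype(np.uint8)
        best, arg = nn_similarity(test, train)
        for i in range(20):
            sims = [tanimoto(test[i], train[j]) for j in range(10)]
            assert best[i] == pytest.approx(max(sims))
            assert sims[arg[i]] == pytest.approx(max(sims))


class TestSplitDistinct:
    def _set(self, fps, ids=None):
        n = fps.shape[0]
        return ScreeningSet(
            compound_ids=ids or [f"c{i}" for i in range(n)],
            fingerprints=fps,
            labels=np.zeros(n, dtype=int),
        )

    def test_threshold_above_one_keeps_all(self):
        train = self._set(np.vstack([_bits({1, 2})]))
        test = self._set(np.vstack([_bits({1, 2}), _bits({3})]))
        test.labels = np.array([1, 0])
        kept = split_distinct(test, train, threshold=1.01)
        assert kept.n == 2

    def test_duplicate_removed(self):
        train = self._set(np.vstack([_bits({1, 2})]))
        test = self._set(np.vstack([_bits({1, 2})]))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept = split_distinct(test, train, threshold=0.2)
        assert kept.n == 0

    def test_exact_similarity_construction(self):
        # train {0..5}; tests built for Tanimoto exactly 0.1, 0.2, 0.3
        train = self._set(np.vstack([_bits({0, 1, 2, 3, 4, 5})]))
        t01 = _bits({0, 10, 11, 12, 13})           # 1 / 10
        t02 = _bits({0, 1, 10, 11, 12, 13})        # 2 / 10
        t03 = _bits({0, 1, 2, 10, 11, 12, 13})     # 3 / 10
        test = self._set(np.vstack([t01, t02, t03]), ids=["a", "b", "c"])
        best, _ = nn_similarity(test.fingerprints, train.fingerprints)
        assert np.allclose(best, [0.1, 0.2, 0.3])
        kept = split_distinct(test, train, threshold=0.2)
        assert kept.compound_ids == ["a"]  # strict <: the 0.2 row is excluded


class TestSequentialScreen:
    def test_one_percent_of_200_keeps_2(self, rng):
        sims = rng.random(200)
        docks = rng.normal(size=200)
        order = sequential_screen(sims, docks, 0.01)
        kept = order[:2]
        top2 = np.argsort(-sims, kind="stable")[:2]
        assert set(kept) == set(top2)
        assert docks[kept[0]] <= docks[kept[1]]

    def test_tie_rule_stable_input_order(self):
        sims = np.ones(10)
        docks = np.arange(10, 0, -1, dtype=float)
        order = sequential_screen(sims, docks, 0.2)
        # first 2 in input order are kept, then docking-sorted
        assert set(order[:2]) == {0, 1}
        assert docks[order[0]] <= docks[order[1]]

    def test_two_stage_brute_force_oracle(self, rng):
        sims = rng.random(50)
        docks = rng.normal(size=50)
        frac = 0.1
        order = sequential_screen(sims, docks, frac)
        k = int(np.ceil(frac * 50))
        kept = sorted(np.argsort(-sims, kind="stable")[:k], key=lambda i: docks[i])
        rest = [i for i in np.argsort(-sims, kind="stable") if i not in kept]
        assert list(order) == kept + rest

    def test_full_fraction_reduces_to_docking_rank(self, rng):
        sims = rng.random(30)
        docks = rng.normal(size=30)
        order = sequential_screen(sims, docks, 1.0)
        assert list(order) == list(np.argsort(docks, kind="stable"))

    def test_missing_docking_score_in_kept_set(self):
        sims = np.array([0.9, 0.1])
        docks = np.array([np.nan, -5.0])
        with pytest.raises(ValueError):
            sequential_screen(sims, docks, 0.5)


class TestConsensus:
    def test_identity_annihilator_arithmetic(self):
        p = np.array([0.3, 0.7])
        assert np.allclose(consensus_score(np.ones(2), p), p)
        assert np.allclose(consensus_score(np.zeros(2), p), 0.0)
        assert consensus_score(np.array([0.8]), np.array([0.5]))[0] == pytest.approx(0.4)

    def test_uniform_structure_probability_preserves_ligand_ranking(self, rng):
        p_lig = rng.random(20)
        combined = consensus_score(p_lig, np.full(20, 0.5))
        assert np.array_equal(np.argsort(-combined), np.argsort(-p_lig))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            consensus_score(np.array([1.2]), np.array([0.5]))


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_two_item_hand_value(self):
        # positive ranked second: AP = (1/2) * 1 = 0.5
        assert auprc([0, 1], [0.9, 0.1]) == 0.5

    def test_five_item_hand_value(self):
        # ranked: 1,0,1,0,0 -> AP = (1/2)(1 + 2/3) = 5/6
        labels = [1, 0, 1, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.6, 0.5]
        assert auprc(labels, scores) == pytest.approx(5 / 6)

    def test_constant_scores_equal_prevalence(self):
        labels = np.array([1] * 3 + [0] * 17)
        assert auprc(labels, np.ones(20)) == pytest.approx(3 / 20)

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        scores = rng.random(40)
        assert auprc(labels, scores) == pytest.approx(auprc(labels, 10 * scores - 3))
        assert auprc(labels, scores) == pytest.approx(auprc(labels, np.exp(scores)))

    def test_random_permutation_mean_near_prevalence(self, rng):
        labels = np.array([1] * 20 + [0] * 180)
        scores = np.arange(200, dtype=float)
        values = []
        for _ in range(300):
            values.append(auprc(labels, rng.permutation(scores)))
        mean = float(np.mean(values))
        sd = float(np.std(values))
        # random ranking concentrates near prevalence (average precision
        # carries a small positive finite-n bias, well inside the spread)
        assert abs(mean - 0.1) < 3 * sd

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auprc([1, 1], [0.5, 0.6])


class TestBinActivity:
    def test_100_distinct_values_split_28_60_12(self, rng):
        values = rng.permutation(np.linspace(1.0, 500.0, 100))
        labels = bin_activity(values)
        counts = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
        assert counts == {"active": 28, "inactive": 60, "dropped": 12}

    def test_scale_shift_rank_invariance(self, rng):
        values = rng.uniform(0.5, 100.0, size=75)
        assert np.array_equal(bin_activity(values), bin_activity(values * 7.3))

    def test_lowest_value_always_active(self, rng):
        values = rng.uniform(1.0, 50.0, size=50)
        labels = bin_activity(values)
        assert labels[np.argmin(values)] == "active"

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bin_activity(np.ones(10))

    def test_ties_share_lower_bin(self):
        values = np.concatenate([np.full(8, 1.0), np.arange(2.0, 94.0)])
        labels = bin_activity(values)
        assert set(labels[:8]) == {"active"}


class TestScaffoldDiversity:
    def test_known_frameworks(self):
        structures = {
            "a": "CCc1ccccc1",      # benzene framework
            "b": "CCCc1ccccc1",     # benzene framework (same)
            "c": "OC1CCCCC1",       # cyclohexane
            "d": "Cc1ccncc1",       # pyridine
            "e": "CCO",             # acyclic: empty framework
        }
        labels = {k: 1 for k in structures}
        assert scaffold_diversity(list(structures), structures, labels, top_k=5) == 4
        # restricting to the two benzene analogues collapses to one scaffold
        assert scaffold_diversity(["a", "b"], structures, labels, top_k=5) == 1

    def test_no_actives_in_top(self):
        structures = {"a": "CCO"}
        assert scaffold_diversity(["a"], structures, {"a": 0}, top_k=1) == 0

    def test_acyclic_counts_once(self):
        structures = {"a": "CCO", "b": "CCCC"}
        labels = {"a": 1, "b": 1}
        assert scaffold_diversity(["a", "b"], structures, labels, top_k=2) == 1

    def test_murcko_strips_side_chains(self):
        assert murcko_scaffold("CCc1ccccc1") == "c1ccccc1"


class TestTrainClassifier:
    def _separable(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 2, size=(n, 12)).astype(np.uint8)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X[:, 0] = y  # one perfectly informative bit
        return ScreeningSet([f"c{i}" for i in range(n)], X, y)

    @pytest.mark.parametrize("algo", ["logistic", "random_forest", "svm_tanimoto"])
    def test_separable_training_auprc_one(self, algo):
        s = self._separable()
        model = train_classifier(s, algo=algo, seed=0)
        p = predict_active_probability(model, s.fingerprints)
        assert auprc(s.labels, p) == pytest.approx(1.0)

    def test_seeded_determinism(self):
        s = self._separable(seed=3)
        p1 = predict_active_probability(
            train_classifier(s, "random_forest", seed=11), s.fingerprints
        )
        p2 = predict_active_probability(
            train_classifier(s, "random_forest", seed=11), s.fingerprints
        )
        assert np.array_equal(p1, p2)

    def test_tanimoto_gram_matches_pairwise(self, rng):
        X = rng.integers(0, 2, size=(5, 10)).astype(np.uint8)
        gram = tanimoto_matrix(X, X)
        for i in range(5):
            for j in range(5):
                assert gram[i, j] == pytest.approx(tanimoto(X[i], X[j]))

    def test_single_class_rejected(self):
        X = np.ones((4, 3), dtype=np.uint8)
        s = ScreeningSet(["a", "b", "c", "d"], X, np.ones(4, dtype=int))
        with pytest.raises(ValueError):
            train_classifier(s)

    def test_tanimoto_kernel_svc_fit_predict(self):
        s = self._separable(seed=5)
        model = TanimotoKernelSVC(random_state=0).fit(s.fingerprints, s.labels)
        proba = model.predict_proba(s.fingerprints)
        assert proba.shape == (s.n, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
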