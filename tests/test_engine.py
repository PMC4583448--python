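from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from selvote import (
    SVAConfig,
    SelectiveVotingClassifier,
    enumerate_pairs,
    majority_label,
    make_folds,
    proclivity,
    run_sva,
)
from selvote.base import predict, train
from selvote.ensemble import run_realization


class TestFolds:
    def test_eighty_by_ten(self):
        folds = make_folds(80, 10, np.random.default_rng(0))
        assert [len(f) for f in folds] == [10] * 8
        assert sorted(np.concatenate(folds)) == list(range(80))

    def test_remainder_fold(self):
        folds = make_folds(7, 3, np.random.default_rng(0))
        assert [len(f) for f in folds] == [3, 3, 1]

    def test_seed_determinism(self):
        a = make_folds(30, 7, np.random.default_rng(5))
        b = make_folds(30, 7, np.random.default_rng(5))
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_oversized_fold_rejected(self):
        with pytest.raises(ValueError):
            make_folds(10, 10, np.random.default_rng(0))

    @given(n=st.integers(2, 60), data=st.data())
    def test_disjoint_cover(self, n, data):
        k1 = data.draw(st.integers(1, n - 1))
        folds = make_folds(n, k1, np.random.default_rng(0))
        flat = np.concatenate(folds)
        assert sorted(flat) == list(range(n))
        assert all(len(f) == k1 for f in folds[:-1])
        assert len(folds[-1]) == (n % k1 or k1)


class TestVoteArithmetic:
    def test_pair_counts(self):
        assert len(enumerate_pairs(3)) == 3
        assert len(enumerate_pairs(4)) == 6
        assert enumerate_pairs(3) == [(0, 1), (0, 2), (1, 2)]

    @pytest.mark.parametrize("vg, vp, expected", [(2, 1, -1), (1, 2, 1), (3, 3, 0)])
    def test_majority_rule(self, vg, vp, expected):
        assert majority_label(vg, vp) == expected

    def test_negative_votes_rejected(self):
        with pytest.raises(ValueError):
            majority_label(-1, 2)

    def test_worked_split_is_exact_thirds(self):
        g, p = proclivity(np.array([[1]]), np.array([[2]]), m=3, n_realizations=1)
        assert g[0] == 1 / 3 and p[0] == 2 / 3

    def test_unanimous_gingivitis(self):
        g, p = proclivity(np.array([[3]]), np.array([[0]]), m=3, n_realizations=1)
        assert g[0] == 1.0 and p[0] == 0.0

    def test_incomplete_tally_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            proclivity(np.array([[1]]), np.array([[1]]), m=3, n_realizations=1)

    @given(st.data())
    def test_rational_normalization(self, data):
        """G + P = 1 exactly as rationals, and exactly 1.0 as floats."""
        nb = data.draw(st.integers(1, 30))
        n = data.draw(st.integers(1, 10))
        n_pairs = 6
        vg = np.array(
            [[data.draw(st.integers(0, n_pairs)) for _ in range(n)] for _ in range(nb)]
        )
        vp = n_pairs - vg
        g, p = proclivity(vg, vp, m=4, n_realizations=nb)
        total = nb * n_pairs
        for k in range(n):
            assert Fraction(int(vg[:, k].sum()), total) + Fraction(int(vp[:, k].sum()), total) == 1
            assert g[k] + p[k] == 1.0

    def test_vote_flip_monotonicity(self):
        """Turning one gingivitis vote into a periodontitis vote raises P_votes."""
        rng = np.random.default_rng(8)
        vg = rng.integers(0, 7, (10, 5))
        vp = 6 - vg
        g0, p0 = proclivity(vg, vp, m=4, n_realizations=10)
        r, k = next((r, k) for r in range(10) for k in range(5) if vg[r, k] > 0)
        vg2, vp2 = vg.copy(), vp.copy()
        vg2[r, k] -= 1
        vp2[r, k] += 1
        g1, p1 = proclivity(vg2, vp2, m=4, n_realizations=10)
        assert p1[k] > p0[k]
        assert np.array_equal(np.delete(p1, k), np.delete(p0, k))


class TestVotingLoop:
    def test_vote_conservation_every_cell(self, default_result):
        n_pairs = len(default_result.pairs)
        assert (default_result.tally_g + default_result.tally_p == n_pairs).all()
        assert (default_result.g_votes + default_result.p_votes == 1.0).all()

    def test_ensemble_sets_match_tallies(self, default_result):
        assert np.array_equal(default_result.sets_g.sum(axis=2), default_result.tally_g)
        assert np.array_equal(default_result.sets_p.sum(axis=2), default_result.tally_p)
        assert not (default_result.sets_g & default_result.sets_p).any()

    def test_separable_cohort_recovers_groups(self, separable_table):
        res = run_sva(separable_table, SVAConfig(n_realizations=20, fold_size=5, seed=0))
        assert np.array_equal(res.aggregate_labels, separable_table.labels)

    def test_seed_gives_bit_identical_results(self, default_table):
        cfg = SVAConfig(n_realizations=5, seed=11)
        a = run_sva(default_table, cfg)
        b = run_sva(default_table, cfg)
        assert np.array_equal(a.tally_g, b.tally_g)
        assert np.array_equal(a.g_votes, b.g_votes)
        assert np.array_equal(a.sets_p, b.sets_p)
        assert np.array_equal(a.per_realization_labels, b.per_realization_labels)

    def test_single_pair_reduces_to_base_classifier(self, default_table):
        """With m=2 the ensemble is one classifier: votes equal its predictions."""
        two = default_table
        from selvote.io import BiomarkerTable
        sub = BiomarkerTable(two.sample_ids, two.marker_names[:2], two.X[:2],
                             two.labels, normalized=True)
        cfg = SVAConfig(n_realizations=1, fold_size=10, classifier="lda", seed=21)
        res = run_sva(sub, cfg)
        rng = np.random.default_rng(21)
        folds = make_folds(sub.n_samples, 10, rng)
        X, y = sub.to_arrays()
        expected = np.zeros(sub.n_samples, dtype=int)
        for test_idx in folds:
            mask = np.ones(sub.n_samples, dtype=bool)
            mask[test_idx] = False
            clf = train("lda", X[mask], y[mask])
            expected[test_idx] = predict(clf, X[test_idx])
        assert np.array_equal(res.per_realization_labels[0], expected)

    def test_unnormalized_table_rejected(self):
        from selvote.simulate import CohortSpec, generate_cohort
        table, _ = generate_cohort(CohortSpec(n_gin=5, n_per=5, seed=0))
        with pytest.raises(ValueError, match="normalized"):
            run_sva(table, SVAConfig(n_realizations=1, fold_size=2))

    def test_run_realization_votes_once_per_pair(self, separable_table):
        X, y = separable_table.to_arrays()
        pairs = enumerate_pairs(separable_table.n_markers)
        folds = make_folds(len(y), 5, np.random.default_rng(0))
        vg, vp, sg, sp = run_realization(X, y, folds, pairs, SVAConfig())
        assert (vg + vp == len(pairs)).all()
        assert not (sg & sp).any()
        assert ((sg | sp).sum(axis=1) == len(pairs)).all()


class TestEstimator:
    def test_sklearn_protocol(self, separable_table):
        est = SelectiveVotingClassifier(n_realizations=3, fold_size=5, random_state=0)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        X, y = separable_table.to_arrays()
        labels = est.fit_predict(X, y)
        assert np.array_equal(labels, est.labels_)
        assert est.n_features_in_ == separable_table.n_markers
        assert (est.g_votes_ + est.p_votes_ == 1.0).all()

    def test_estimator_matches_functional_wrapper(self, separable_table):
        X, y = separable_table.to_arrays()
        est = SelectiveVotingClassifier(n_realizations=4, fold_size=5,
                                        random_state=9).fit(X, y)
        res = run_sva(separable_table,
                      SVAConfig(n_realizations=4, fold_size=5, seed=9))
        assert np.array_equal(est.tally_g_, res.tally_g)
        assert np.array_equal(est.labels_, res.aggregate_labels)
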