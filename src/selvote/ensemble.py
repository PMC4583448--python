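"""The selective-voting ensemble (SVA) loop.

Every unordered pair of markers trains its own base classifier, and each
held-out sample collects one vote per pair ("gingivitis" or "periodontitis").
The leave-k1-out partition is redrawn N_b times by freshly permuting the
sample columns; accumulated votes yield a per-sample proclivity pair
(G_votes, P_votes) ∈ [0,1]² with G_votes + P_votes = 1, and per-realization
majority labels λ*(r,k) ∈ {−1, 0, +1} (0 = tie).

The loop is exposed both as a scikit-learn style estimator
(:class:`SelectiveVotingClassifier`) and as the thin functional wrapper
:func:`run_sva` operating on a :class:`~selvote.io.BiomarkerTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_X_y

from .base import DegenerateFoldError, check_training_fold, predict, train
from .io import BiomarkerTable

logger = logging.getLogger(__name__)


@dataclass
class SVAConfig:
    """Knobs of the voting loop.

    n_realizations
        Number of independent leave-k1-out realizations N_b (study default
        1000).
    fold_size
        Held-out window size k1 (study default 10); a warning is emitted when
        k1 > n/4, since the scheme presumes the training side dominates.
    classifier
        Base-classifier kind: ``lda`` | ``qda`` | ``nb`` | ``svm``.
    seed
        Master RNG seed driving all permutations (and downstream
        tie-resolution); recorded in results for bit-reproducibility.
    """

    n_realizations: int = 1000
    fold_size: int = 10
    classifier: str = "lda"
    seed: int | None = None
    svm_c: float = 1.0
    qda_reg: float = 1e-4
    nb_var_smoothing: float = 1e-9
    max_redraws: int = 100


@dataclass
class SVAResult:
    """Everything the voting loop produces for one cohort.

    ``tally_g``/``tally_p`` are (N_b x n) integer vote counts;
    ``sets_g``/``sets_p`` are (N_b x n x n_pairs) boolean ensemble-set
    indicators over the lexicographic pair list ``pairs``.
    """

    sample_ids: list[str]
    pairs: list[tuple[int, int]]
    g_votes: np.ndarray
    p_votes: np.ndarray
    per_realization_labels: np.ndarray
    aggregate_labels: np.ndarray
    tally_g: np.ndarray
    tally_p: np.ndarray
    sets_g: np.ndarray
    sets_p: np.ndarray
    config: SVAConfig = field(repr=False, default_factory=SVAConfig)


def enumerate_pairs(m: int) -> list[tuple[int, int]]:
    """All unordered marker pairs (i, j), i < j, in lexicographic order."""
    if m < 2:
        raise ValueError("need at least two markers to form a pair")
    return list(combinations(range(m), 2))


def make_folds(n: int, k1: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random disjoint test folds covering all n samples.

    A fresh uniform permutation of the sample indices is drawn and cut into
    consecutive windows of k1 (one remainder fold of size ``n % k1`` when k1
    does not divide n).
    """
    if not 1 <= k1 < n:
        raise ValueError(f"fold size must satisfy 1 <= k1 < n, got k1={k1}, n={n}")
    perm = rng.permutation(n)
    return [perm[start:start + k1] for start in range(0, n, k1)]


def majority_label(v_g: int, v_p: int) -> int:
    """−1 if gingivitis votes lead, +1 if periodontitis votes lead, 0 on a tie."""
    if v_g < 0 or v_p < 0:
        raise ValueError("vote counts must be non-negative")
    if v_g > v_p:
        return -1
    if v_g < v_p:
        return 1
    return 0


def proclivity(
    tally_g: np.ndarray, tally_p: np.ndarray, m: int, n_realizations: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized per-sample vote fractions (G_votes, P_votes).

    Each component is one integer-sum division by N_b·m(m−1)/2; the pair sums
    to 1 exactly in rational arithmetic because every (r, k) cell contributes
    exactly m(m−1)/2 votes in total.
    """
    n_pairs = m * (m - 1) // 2
    total = n_realizations * n_pairs
    sums_g = np.asarray(tally_g).sum(axis=0)
    sums_p = np.asarray(tally_p).sum(axis=0)
    if not np.array_equal(sums_g + sums_p, np.full_like(sums_g, total)):
        raise ValueError("incomplete tally: votes do not sum to N_b * m(m-1)/2")
    return sums_g / total, sums_p / total


def run_realization(X, y, folds, pairs, cfg):
    """Vote with every pair on every fold of one realization.

    Raises DegenerateFoldError if any training complement lacks two members
    of either class (caller redraws the permutation).
    """
    n = X.shape[0]
    n_pairs = len(pairs)
    v_g = np.zeros(n, dtype=np.int64)
    v_p = np.zeros(n, dtype=np.int64)
    s_g = np.zeros((n, n_pairs), dtype=bool)
    s_p = np.zeros((n, n_pairs), dtype=bool)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        y_train = y[train_mask]
        check_training_fold(y_train)
        for p_idx, (i, j) in enumerate(pairs):
            clf = train(
                cfg.classifier,
                X[train_mask][:, (i, j)],
                y_train,
                feature_indices=(i, j),
                svm_c=cfg.svm_c,
                qda_reg=cfg.qda_reg,
                nb_var_smoothing=cfg.nb_var_smoothing,
            )
            votes = predict(clf, X[test_idx][:, (i, j)])
            gin = test_idx[votes == -1]
            per = test_idx[votes == 1]
            v_g[gin] += 1
            v_p[per] += 1
            s_g[gin, p_idx] = True
            s_p[per, p_idx] = True
    return v_g, v_p, s_g, s_p


def _run_loop(X, y, cfg: SVAConfig):
    n, m = X.shape
    pairs = enumerate_pairs(m)
    n_pairs = len(pairs)
    if cfg.fold_size > n // 4:
        logger.warning(
            "fold size k1=%d exceeds n/4 (n=%d); the leave-k1-out scheme "
            "presumes a dominant training side", cfg.fold_size, n,
        )
    rng = np.random.default_rng(cfg.seed)
    nb = cfg.n_realizations
    if nb < 1:
        raise ValueError("n_realizations must be >= 1")
    tally_g = np.zeros((nb, n), dtype=np.int64)
    tally_p = np.zeros((nb, n), dtype=np.int64)
    sets_g = np.zeros((nb, n, n_pairs), dtype=bool)
    sets_p = np.zeros((nb, n, n_pairs), dtype=bool)
    lam = np.zeros((nb, n), dtype=np.int8)
    for r in range(nb):
        for attempt in range(cfg.max_redraws + 1):
            folds = make_folds(n, cfg.fold_size, rng)
            try:
                v_g, v_p, s_g, s_p = run_realization(X, y, folds, pairs, cfg)
                break
            except DegenerateFoldError as exc:
                if attempt == cfg.max_redraws:
                    raise DegenerateFoldError(
                        f"realization {r}: {cfg.max_redraws} redraws exhausted ({exc})"
                    ) from exc
                logger.warning("realization %d: degenerate fold (%s); redrawing", r, exc)
        assert (v_g + v_p == n_pairs).all(), "vote conservation violated"
        tally_g[r], tally_p[r] = v_g, v_p
        sets_g[r], sets_p[r] = s_g, s_p
        lam[r] = np.sign(v_p - v_g)
    g_votes, p_votes = proclivity(tally_g, tally_p, m, nb)
    aggregate = np.sign(tally_p.sum(axis=0) - tally_g.sum(axis=0)).astype(int)
    return pairs, g_votes, p_votes, lam, aggregate, tally_g, tally_p, sets_g, sets_p


class SelectiveVotingClassifier(BaseEstimator):
    """Pairwise-feature voting ensemble over repeated leave-k1-out splits.

    The estimator is transductive: :meth:`fit` runs the full voting loop on
    the cohort it is given and exposes per-sample results as fitted
    attributes (like a clustering estimator's ``labels_``).

    Parameters
    ----------
    classifier : {"lda", "qda", "nb", "svm"}
        Base-classifier kind trained on every marker pair.
    n_realizations : int
        Number of independent random repartitions N_b.
    fold_size : int
        Held-out window size k1.
    random_state : int or None
        Seed for the permutation stream.

    Attributes
    ----------
    g_votes_, p_votes_ : ndarray of shape (n,)
        Proclivity toward gingivitis / periodontitis; sums to 1 per sample.
    labels_ : ndarray of shape (n,)
        Aggregate label in {−1, 0, +1}: the sign of P_votes − G_votes.
    per_realization_labels_ : ndarray of shape (N_b, n)
        Majority label per realization (0 = tie).
    tally_g_, tally_p_ : ndarray of shape (N_b, n)
        Raw integer vote counts.
    ensemble_g_, ensemble_p_ : ndarray of shape (N_b, n, n_pairs)
        Boolean ensemble-set membership over ``pairs_``.

    Examples
    --------
    >>> est = SelectiveVotingClassifier(n_realizations=50, fold_size=5,
    ...                                 random_state=0)
    >>> est.fit(X, y)                                   # doctest: +SKIP
    >>> est.g_votes_ + est.p_votes_                     # doctest: +SKIP
    array([1., 1., ...])
    """

    def __init__(
        self,
        classifier: str = "lda",
        n_realizations: int = 1000,
        fold_size: int = 10,
        random_state: int | None = None,
        svm_c: float = 1.0,
        qda_reg: float = 1e-4,
        nb_var_smoothing: float = 1e-9,
        max_redraws: int = 100,
    ):
        self.classifier = classifier
        self.n_realizations = n_realizations
        self.fold_size = fold_size
        self.random_state = random_state
        self.svm_c = svm_c
        self.qda_reg = qda_reg
        self.nb_var_smoothing = nb_var_smoothing
        self.max_redraws = max_redraws

    def _config(self) -> SVAConfig:
        return SVAConfig(
            n_realizations=self.n_realizations,
            fold_size=self.fold_size,
            classifier=self.classifier,
            seed=self.random_state,
            svm_c=self.svm_c,
            qda_reg=self.qda_reg,
            nb_var_smoothing=self.nb_var_smoothing,
            max_redraws=self.max_redraws,
        )

    def fit(self, X, y):
        """Run the voting loop on a (samples x markers) matrix and labels."""
        X, y = check_X_y(X, y)
        y = np.asarray(y, dtype=int)
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must lie in {-1, +1}")
        (self.pairs_, self.g_votes_, self.p_votes_, self.per_realization_labels_,
         self.labels_, self.tally_g_, self.tally_p_, self.ensemble_g_,
         self.ensemble_p_) = _run_loop(X, y, self._config())
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y):
        return self.fit(X, y).labels_


def run_sva(table: BiomarkerTable, cfg: SVAConfig | None = None) -> SVAResult:
    """Run the full voting loop on a normalized cohort table."""
    cfg = cfg or SVAConfig()
    if not table.normalized:
        raise ValueError("table must be log-normalized before voting (see log_normalize)")
    X, y = table.to_arrays()
    pairs, g, p, lam, agg, tg, tp, sg, sp = _run_loop(X, y, cfg)
    return SVAResult(
        sample_ids=list(table.sample_ids),
        pairs=pairs,
        g_votes=g,
        p_votes=p,
        per_realization_labels=lam,
        aggregate_labels=agg,
        tally_g=tg,
        tally_p=tp,
        sets_g=sg,
        sets_p=sp,
        config=cfg,
    )
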