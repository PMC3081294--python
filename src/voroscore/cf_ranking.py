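"""Collaborative-filtering re-ranking of docking conformations.

A roster of binary base classifiers plays the role of "users", each voting
native (+1) or non-native (−1) on every conformation ("item").  Votes are
fused three ways:

* uniform voting — rank by the number of + votes (k classifiers give k+1
  categories);
* precision-weighted voting — each vote is weighted by the classifier's
  cross-validated precision p_k; a conformation's category score is
  S⁺ − S⁻ where S⁺ (S⁻) sums the precisions of the classifiers voting
  + (−).  With k generic distinct precisions the 2^k sign patterns all map
  to distinct scores;
* CF–GA fusion — a conformation's fused value is its GA rank multiplied by
  exp(S⁻ − S⁺); conformations receiving no positive vote take a sentinel
  that sorts last.  Lower fused value = better.

Classifiers whose measured precision falls below 0.5 (worse than random)
are dropped from the roster.  A greedy RMSD pass can be applied to any
ranking to enforce structural diversity among the top solutions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .ga_scoring import RankedSet
from .pose_generation import node_rmsd

logger = logging.getLogger(__name__)

PRECISION_GATE = 0.5


@dataclass
class BaseClassifier:
    """A pluggable binary learner with a cross-validated precision."""

    name: str
    estimator: object  # sklearn-style fit/predict
    precision: float = float("nan")

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))


def default_roster(random_state: int = 0) -> list[BaseClassifier]:
    """The 12-classifier roster: logistic regression, two SVM kernels, and
    nine tree learners of graded minimum leaf size standing in for the
    C4.5/RIPPER/PART family (three variants each at min-leaf 2/5/10)."""
    scaled = lambda est: make_pipeline(StandardScaler(), est)
    roster = [
        BaseClassifier("Logistic", scaled(LogisticRegression(max_iter=2000))),
        BaseClassifier("SVM-RBF", scaled(SVC(kernel="rbf"))),
        BaseClassifier("SVM-Q2", scaled(SVC(kernel="poly", degree=2))),
    ]
    for m in (2, 5, 10):
        roster.append(BaseClassifier(
            f"TREE-M{m}",
            DecisionTreeClassifier(criterion="entropy", min_samples_leaf=m,
                                   random_state=random_state)))
        roster.append(BaseClassifier(
            f"RULE-M{m}",
            DecisionTreeClassifier(criterion="gini", max_depth=4,
                                   min_samples_leaf=m, random_state=random_state)))
        roster.append(BaseClassifier(
            f"PART-M{m}",
            DecisionTreeClassifier(criterion="entropy", max_depth=6,
                                   min_samples_leaf=m,
                                   random_state=random_state + 1)))
    return roster


def measure_precisions(
    roster: list[BaseClassifier],
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> list[BaseClassifier]:
    """Measure each classifier's precision from k-fold held-out predictions,
    then drop members below the 0.5 gate (worse than random)."""
    folds = min(folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    kept: list[BaseClassifier] = []
    for clf in roster:
        pred = cross_val_predict(clf.estimator, X, y, cv=cv)
        clf.precision = float(precision_score(y, pred, zero_division=0.0))
        if clf.precision < PRECISION_GATE:
            logger.info("discarding %s (precision %.3f < 0.5)", clf.name, clf.precision)
            continue
        kept.append(clf)
    return kept


@dataclass
class VoteRecord:
    """Per-conformation votes and precisions of the shared roster."""

    conf_id: int
    votes: np.ndarray  # (k,) entries in {+1, −1}
    precisions: np.ndarray  # (k,)

    def __post_init__(self):
        self.votes = np.asarray(self.votes, dtype=int).reshape(-1)
        self.precisions = np.asarray(self.precisions, dtype=float).reshape(-1)
        if self.votes.shape != self.precisions.shape:
            raise ValueError("votes/precisions length mismatch")
        if not np.all(np.isin(self.votes, (-1, 1))):
            raise ValueError("votes must be +1 or -1")

    @property
    def s_plus(self) -> float:
        return float(self.precisions[self.votes == 1].sum())

    @property
    def s_minus(self) -> float:
        return float(self.precisions[self.votes == -1].sum())

    @property
    def category_score(self) -> float:
        """S⁺ − S⁻ = Σ_k v_k p_k."""
        return float((self.votes * self.precisions).sum())

    @property
    def n_plus(self) -> int:
        return int((self.votes == 1).sum())


def collect_votes(
    roster: list[BaseClassifier], X_train, y_train, X_eval
) -> list[VoteRecord]:
    """Fit the roster and record its votes on an evaluation set."""
    if not roster:
        raise ValueError("empty classifier roster")
    precisions = np.array([c.precision for c in roster])
    preds = np.stack([c.fit(X_train, y_train).predict(X_eval) for c in roster])
    votes = np.where(preds == 1, 1, -1)
    return [VoteRecord(i, votes[:, i], precisions) for i in range(votes.shape[1])]


def _check_roster(votes: list[VoteRecord]) -> None:
    if not votes:
        raise ValueError("no vote records")
    k = len(votes[0].votes)
    if k == 0:
        raise ValueError("empty classifier roster")
    for v in votes:
        if len(v.votes) != k or not np.allclose(v.precisions, votes[0].precisions):
            raise ValueError("vote records do not share a classifier roster")


def _rank_desc(scores: np.ndarray, items: list) -> RankedSet:
    ranks = rankdata(-scores)
    return RankedSet(items=items, scores=scores, ranks=ranks)


def uniform_vote_rank(votes: list[VoteRecord]) -> RankedSet:
    """Rank by number of + votes (descending); ties share an average rank."""
    _check_roster(votes)
    counts = np.array([v.n_plus for v in votes], dtype=float)
    return _rank_desc(counts, [v.conf_id for v in votes])


def weighted_vote_rank(votes: list[VoteRecord]) -> RankedSet:
    """Rank by the precision-weighted category score S⁺ − S⁻ (descending)."""
    _check_roster(votes)
    p = votes[0].precisions
    if len(np.unique(p)) < len(p):
        logger.warning("non-distinct precisions: weighted categories may collide")
    scores = np.array([v.category_score for v in votes])
    return _rank_desc(scores, [v.conf_id for v in votes])


SENTINEL = np.inf  # fused value for all-negative conformations ("maximal")


def cf_ga_fuse(ga: RankedSet, votes: list[VoteRecord]) -> RankedSet:
    """Fuse GA ranks with CF votes: fused = GA_rank × exp(S⁻ − S⁺).

    Lower fused value is better.  Conformations with S⁺ = 0 (only negative
    votes) take the sentinel and occupy the last ranks in stable input
    order.
    """
    _check_roster(votes)
    ga_rank_of = dict(zip(ga.items, ga.ranks))
    fused = np.empty(len(votes))
    for i, v in enumerate(votes):
        if v.conf_id not in ga_rank_of:
            raise ValueError(f"conformation {v.conf_id} missing from GA ranking")
        if v.s_plus == 0.0:
            fused[i] = SENTINEL
        else:
            fused[i] = ga_rank_of[v.conf_id] * np.exp(v.s_minus - v.s_plus)
    finite = np.isfinite(fused)
    ranks = np.empty(len(votes))
    ranks[finite] = rankdata(fused[finite])
    n_fin = int(finite.sum())
    ranks[~finite] = n_fin + 1 + np.arange(len(votes) - n_fin)  # stable input order
    return RankedSet(items=[v.conf_id for v in votes], scores=fused, ranks=ranks)


def cf_then_ga(votes: list[VoteRecord], ga: RankedSet, T: int) -> RankedSet:
    """Keep the weighted-CF top T, order them by GA rank; the rest follow
    in CF order."""
    if T < 1:
        raise ValueError("T must be >= 1")
    cf = weighted_vote_rank(votes)
    ga_rank_of = dict(zip(ga.items, ga.ranks))
    ids = cf.items
    keep = cf.ranks <= T
    kept = sorted((i for i, k in zip(range(len(ids)), keep) if k),
                  key=lambda i: ga_rank_of[ids[i]])
    rest = sorted((i for i, k in zip(range(len(ids)), keep) if not k),
                  key=lambda i: cf.ranks[i])
    ranks = np.empty(len(ids))
    for pos, i in enumerate(kept + rest, start=1):
        ranks[i] = pos
    return RankedSet(items=ids, scores=ranks.astype(float), ranks=ranks)


def granularity(ranking: RankedSet) -> float:
    """Distinct aggregate scores divided by the number of items, in (0, 1]."""
    n = len(ranking.items)
    if n == 0:
        raise ValueError("empty ranking")
    return len(np.unique(ranking.scores)) / n


def reachable_categories(precisions: np.ndarray, weighted: bool = True) -> int:
    """Number of distinct vote categories over all 2^k sign patterns.

    Uniform voting maps k classifiers onto the k+1 possible + counts;
    precision-weighted voting maps each sign pattern to Σ v_k p_k, giving
    2^k categories whenever the precisions are subset-sum distinct.
    """
    p = np.asarray(precisions, dtype=float)
    k = len(p)
    if k == 0:
        raise ValueError("empty classifier roster")
    scores = set()
    for signs in itertools.product((1, -1), repeat=k):
        v = np.array(signs)
        scores.add(round(float(v @ p), 12) if weighted else int((v == 1).sum()))
    return len(scores)


def rmsd_diversity_filter(
    ranking: RankedSet, confs: list, min_rmsd: float = 5.0
) -> RankedSet:
    """Greedy structural-diversity pass over a ranking.

    Scanning best-first, a conformation is kept only if its ligand-node
    RMSD to every already-kept conformation exceeds ``min_rmsd`` Å;
    survivors are re-ranked 1…m.  ``confs`` is indexed by item id.
    """
    order = ranking.order()
    kept: list[int] = []
    for idx in order:
        cid = ranking.items[idx]
        if all(node_rmsd(confs[cid], confs[k]) > min_rmsd for k in kept):
            kept.append(cid)
    ranks = np.arange(1, len(kept) + 1, dtype=float)
    return RankedSet(items=kept, scores=ranks.copy(), ranks=ranks)
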