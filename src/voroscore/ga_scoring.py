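"""Evolution-strategy training of the centered linear scoring function.

The score of a conformation with attributes x is

    S(x) = Σᵢ wᵢ (xᵢ − cᵢ)          (masked attributes contribute nothing)

with weights w and centering values c optimized by a (μ+λ) evolution
strategy whose fitness is the ROC AUC of S over a labeled training fold.
Because the ES is a heuristic, training is repeated over several seeded
runs per cross-validation fold and the resulting family of functions is
combined by rank-sum aggregation: each function ranks the candidate set,
and a candidate's aggregate score is the sum of its ranks (lower = better).

An absolute-deviation variant S(x) = Σᵢ wᵢ |xᵢ − cᵢ| is available behind
``form="absolute"`` for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import GroupKFold

from .interface_features import FeatureVector, LearningSet

logger = logging.getLogger(__name__)


@dataclass
class ScoringFunction:
    """One trained instance of the centered linear score."""

    weights: np.ndarray  # (96,)
    centers: np.ndarray  # (96,)
    fold: int = 0
    run: int = 0
    form: str = "linear"  # linear | absolute
    train_auc: float = float("nan")

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1)
        if self.weights.shape != self.centers.shape:
            raise ValueError("weights/centers length mismatch")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.centers))):
            raise ValueError("non-finite scoring function")


@dataclass
class ESConfig:
    """(μ+λ) evolution-strategy settings."""

    mu: int = 10
    lam: int = 70
    max_generations: int = 500
    runs_per_fold: int = 30
    folds: int = 10
    seed: int = 0
    recombination: str = "discrete"  # discrete | intermediate
    sigma_init: float = 0.1
    stall_generations: int = 50  # stop early when best AUC stagnates
    form: str = "linear"

    def __post_init__(self):
        if self.mu < 1 or self.lam < self.mu:
            raise ValueError("need mu >= 1 and lambda >= mu")


@dataclass
class RankedSet:
    """Items with aggregate scores and final 1-based ranks (ties averaged)."""

    items: list
    scores: np.ndarray  # aggregate score per item (lower = better here)
    ranks: np.ndarray  # final ranks, average-rank ties

    def order(self) -> np.ndarray:
        """Item indices sorted best-first (stable)."""
        return np.argsort(self.ranks, kind="stable")


def score(f: ScoringFunction, x: FeatureVector) -> float:
    """Apply the scoring function; masked attributes are skipped."""
    return float(score_matrix(f, x.values[None, :], x.missing_mask[None, :])[0])


def score_matrix(f: ScoringFunction, X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Vectorized scores for an (n, 96) matrix with missing mask M."""
    dev = X - f.centers
    if f.form == "absolute":
        dev = np.abs(dev)
    terms = dev * f.weights
    terms = np.where(M, 0.0, terms)
    return terms.sum(axis=1)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve.

    Equals the probability that a random positive outscores a random
    negative, with ties counting one half; invariant under any strictly
    increasing transform of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes required")
    ranks = rankdata(scores)  # average-rank ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# (μ+λ) evolution strategy
# ---------------------------------------------------------------------------

def _es_run(
    X: np.ndarray,
    M: np.ndarray,
    y: np.ndarray,
    cfg: ESConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One ES run; returns (weights, centers, best training AUC).

    An individual is (w, c, σ) with one self-adapted step size per gene
    (d = 2·n_features genes).  Children are built by recombination of two
    uniformly drawn parents, a log-normal σ update with the standard
    learning rates τ = 1/√(2√d), τ' = 1/√(2d), then Gaussian gene
    mutation.  Survivor selection keeps the best μ of parents ∪ children,
    so the best fitness never decreases (elitism).
    """
    d = 2 * X.shape[1]
    tau = 1.0 / np.sqrt(2.0 * np.sqrt(d))
    tau_p = 1.0 / np.sqrt(2.0 * d)

    def fitness(genome: np.ndarray) -> float:
        f = ScoringFunction(genome[: d // 2], genome[d // 2 :], form=cfg.form)
        s = score_matrix(f, X, M)
        if not np.all(np.isfinite(s)):
            return -np.inf
        return roc_auc(s, y)

    genomes = rng.normal(0.0, 1.0, size=(cfg.mu, d))
    sigmas = np.full((cfg.mu, d), float(cfg.sigma_init))
    fits = np.array([fitness(g) for g in genomes])

    best = float(fits.max())
    stall = 0
    for _gen in range(cfg.max_generations):
        parents = rng.integers(0, cfg.mu, size=(cfg.lam, 2))
        if cfg.recombination == "intermediate":
            child_g = 0.5 * (genomes[parents[:, 0]] + genomes[parents[:, 1]])
            child_s = 0.5 * (sigmas[parents[:, 0]] + sigmas[parents[:, 1]])
        else:  # discrete: each gene from either parent
            pick = rng.integers(0, 2, size=(cfg.lam, d)).astype(bool)
            child_g = np.where(pick, genomes[parents[:, 0]], genomes[parents[:, 1]])
            child_s = np.where(pick, sigmas[parents[:, 0]], sigmas[parents[:, 1]])
        global_z = rng.normal(size=(cfg.lam, 1))
        child_s = child_s * np.exp(tau_p * global_z + tau * rng.normal(size=(cfg.lam, d)))
        child_g = child_g + child_s * rng.normal(size=(cfg.lam, d))
        child_f = np.array([fitness(g) for g in child_g])

        pool_g = np.vstack([genomes, child_g])
        pool_s = np.vstack([sigmas, child_s])
        pool_f = np.concatenate([fits, child_f])
        keep = np.argsort(-pool_f, kind="stable")[: cfg.mu]
        genomes, sigmas, fits = pool_g[keep], pool_s[keep], pool_f[keep]

        new_best = float(fits.max())
        if new_best > best + 1e-12:
            best, stall = new_best, 0
        else:
            stall += 1
            if stall >= cfg.stall_generations:
                break
    top = genomes[int(np.argmax(fits))]
    return top[: d // 2].copy(), top[d // 2 :].copy(), best


def train(learning_set: LearningSet, cfg: ESConfig) -> list[ScoringFunction]:
    """Cross-validated ES training: folds × runs_per_fold scoring functions.

    Folds are split at the complex level (GroupKFold on complex_id), so a
    native and its decoys always share a fold and never leak between
    training and held-out data.  Each run uses an independent seed stream
    derived from ``cfg.seed``.
    """
    X, M, y, groups = learning_set.X, learning_set.M, learning_set.y, learning_set.groups
    n_groups = len(set(groups))
    n_folds = min(cfg.folds, n_groups)
    if n_folds < 2:
        raise ValueError("need at least 2 complexes for cross-validation")
    splitter = GroupKFold(n_splits=n_folds)
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_folds * cfg.runs_per_fold)
    functions: list[ScoringFunction] = []
    for fold, (train_idx, _test_idx) in enumerate(splitter.split(X, y, groups)):
        Xt, Mt, yt = X[train_idx], M[train_idx], y[train_idx]
        if yt.min() == yt.max():
            raise ValueError(f"fold {fold} has a single class")
        for run in range(cfg.runs_per_fold):
            rng = np.random.default_rng(seeds[fold * cfg.runs_per_fold + run])
            w, c, auc = _es_run(Xt, Mt, yt, cfg, rng)
            functions.append(
                ScoringFunction(w, c, fold=fold, run=run, form=cfg.form, train_auc=auc)
            )
    return functions


def aggregate_rank(
    functions: list[ScoringFunction], confs: list[FeatureVector]
) -> RankedSet:
    """Rank-sum aggregation over a family of scoring functions.

    Each function ranks all conformations by descending score (rank 1 =
    best, ties averaged); the aggregate score is the sum of ranks over
    functions and the final rank is ascending in that sum.
    """
    if not functions:
        raise ValueError("need at least one scoring function")
    X = np.array([v.values for v in confs])
    M = np.array([v.missing_mask for v in confs])
    rank_sum = np.zeros(len(confs))
    for f in functions:
        s = score_matrix(f, X, M)
        rank_sum += rankdata(-s)
    final = rankdata(rank_sum)
    return RankedSet(items=list(range(len(confs))), scores=rank_sum, ranks=final)


def held_out_auc(
    learning_set: LearningSet, functions: list[ScoringFunction], folds: int | None = None
) -> float:
    """Mean held-out AUC of the rank-sum aggregate across folds.

    Re-derives the deterministic GroupKFold split used by :func:`train`,
    scores each test fold with the functions trained on the complementary
    data (matched by fold id), and averages the per-fold AUC of the
    negated aggregate rank.  Single-class test folds are skipped.
    """
    X, y, groups = learning_set.X, learning_set.y, learning_set.groups
    fold_ids = sorted({f.fold for f in functions})
    n_folds = folds or len(fold_ids)
    splitter = GroupKFold(n_splits=n_folds)
    aucs = []
    for fold, (_tr, test_idx) in enumerate(splitter.split(X, y, groups)):
        if y[test_idx].min() == y[test_idx].max():
            continue
        fam = [f for f in functions if f.fold == fold]
        if not fam:
            continue
        ranked = aggregate_rank(fam, [learning_set.vectors[i] for i in test_idx])
        aucs.append(roc_auc(-ranked.scores, y[test_idx]))
    if not aucs:
        raise ValueError("no scorable fold")
    return float(np.mean(aucs))
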