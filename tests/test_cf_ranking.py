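"""Vote fusion: uniform/weighted CF, CF-GA coupling, granularity, diversity."""

import numpy as np
import pytest
from scipy.stats import rankdata

from voroscore import cf_ranking as cf
from voroscore import synthetic_fixtures as sf
from voroscore.cf_ranking import VoteRecord
from voroscore.ga_scoring import RankedSet


def _records(vote_rows, precisions):
    p = np.asarray(precisions, float)
    return [VoteRecord(i, row, p) for i, row in enumerate(vote_rows)]


def test_vote_record_identities(rng):
    p = rng.uniform(0.5, 1.0, 12)
    votes = rng.choice([-1, 1], 12)
    r = VoteRecord(0, votes, p)
    assert r.s_plus + r.s_minus == pytest.approx(p.sum())
    assert r.category_score == pytest.approx(r.s_plus - r.s_minus)
    ones = VoteRecord(1, votes, np.ones(12))
    assert ones.category_score == (votes == 1).sum() - (votes == -1).sum()


def test_uniform_vote_rank_orders_by_plus_count():
    recs = _records([[1, 1, 1], [1, 1, -1], [-1, -1, -1]], [0.9, 0.8, 0.7])
    ranked = cf.uniform_vote_rank(recs)
    np.testing.assert_array_equal(ranked.ranks, [1, 2, 3])


def test_uniform_vote_category_count():
    """k classifiers admit exactly k+1 uniform categories (12 → 13)."""
    rng = np.random.default_rng(2)
    p = rng.uniform(0.5, 1.0, 12)
    assert cf.reachable_categories(p, weighted=False) == 13
    assert cf.reachable_categories(p[:3], weighted=False) == 4


def test_weighted_vote_category_count_generic():
    """12 generic distinct precisions make all 2^12 sign patterns distinct."""
    rng = np.random.default_rng(2)
    p = rng.uniform(0.5, 1.0, 12)
    assert cf.reachable_categories(p, weighted=True) == 4096


def test_weighted_vote_rank_arithmetic():
    recs = _records([[1, -1], [-1, 1]], [0.9, 0.6])
    ranked = cf.weighted_vote_rank(recs)
    np.testing.assert_allclose(ranked.scores, [0.3, -0.3])
    np.testing.assert_array_equal(ranked.ranks, [1, 2])


def test_weighted_reduces_to_uniform_with_unit_precisions(rng):
    votes = rng.choice([-1, 1], size=(30, 5))
    uni = cf.uniform_vote_rank(_records(votes, np.ones(5)))
    wei = cf.weighted_vote_rank(_records(votes, np.ones(5)))
    np.testing.assert_array_equal(uni.ranks, wei.ranks)


def test_empty_roster_rejected():
    with pytest.raises(ValueError, match="roster"):
        cf.uniform_vote_rank([VoteRecord(0, np.empty(0, int), np.empty(0))])
    with pytest.raises(ValueError, match="no vote records"):
        cf.uniform_vote_rank([])


def test_cf_ga_fuse_all_negative_sentinel():
    recs = _records([[1, 1], [-1, -1], [1, -1]], [0.8, 0.7])
    ga = RankedSet(items=[0, 1, 2], scores=np.array([1.0, 2, 3]),
                   ranks=np.array([1.0, 2, 3]))
    fused = cf.cf_ga_fuse(ga, recs)
    assert fused.scores[1] == np.inf
    assert fused.ranks[1] == 3  # sentinel sorts last
    # unanimous positive at GA rank 1: the minimum possible fused value
    assert fused.scores[0] == pytest.approx(np.exp(-1.5))
    assert fused.ranks[0] == 1


def test_cf_ga_fuse_matches_brute_force(rng):
    recs, ga, _ = sf.make_vote_fixture(sf.FixtureSpec(seed=9), n_items=20)
    fused = cf.cf_ga_fuse(ga, recs)
    ga_rank = dict(zip(ga.items, ga.ranks))
    brute = np.array([
        ga_rank[r.conf_id] * np.exp(r.s_minus - r.s_plus) if r.s_plus > 0 else np.inf
        for r in recs
    ])
    finite = np.isfinite(brute)
    np.testing.assert_allclose(fused.scores[finite], brute[finite])
    # brute-force ordering: finite ascending, sentinels after in input order
    order = list(np.argsort(brute[finite], kind="stable"))
    expect_first = [recs[i].conf_id for i in np.flatnonzero(finite)[order]]
    got = [fused.items[i] for i in fused.order()]
    assert got[: len(expect_first)] == expect_first
    assert got[len(expect_first):] == [r.conf_id for r in recs if r.s_plus == 0]


def test_cf_ga_fuse_missing_ga_entry():
    recs = _records([[1]], [0.9])
    ga = RankedSet(items=[99], scores=np.array([1.0]), ranks=np.array([1.0]))
    with pytest.raises(ValueError, match="missing from GA"):
        cf.cf_ga_fuse(ga, recs)


def test_cf_then_ga_cutoffs(rng):
    recs, ga, _ = sf.make_vote_fixture(sf.FixtureSpec(seed=10), n_items=30)
    # T >= n reduces to GA ordering
    full = cf.cf_then_ga(recs, ga, T=30)
    ga_order = [ga.items[i] for i in ga.order()]
    assert [full.items[i] for i in full.order()] == ga_order
    # T = 1: the single best CF conformation leads regardless of GA
    one = cf.cf_then_ga(recs, ga, T=1)
    best_cf = cf.weighted_vote_rank(recs)
    top_cf = best_cf.items[int(np.argmin(best_cf.ranks))]
    assert one.items[one.order()[0]] == top_cf


def test_cf_then_ga_excludes_ga_best_outside_top_t():
    # CF loves item 1, GA loves item 0; with T=1, item 0 cannot be first
    recs = _records([[-1, -1], [1, 1], [1, -1]], [0.9, 0.8])
    ga = RankedSet(items=[0, 1, 2], scores=np.arange(3.0),
                   ranks=np.array([1.0, 2, 3]))
    ranked = cf.cf_then_ga(recs, ga, T=1)
    order = [ranked.items[i] for i in ranked.order()]
    assert order[0] == 1
    assert order.index(0) > 0


@pytest.mark.parametrize(
    "scores,expected",
    [(np.arange(10.0), 1.0), (np.zeros(4), 0.25)],
)
def test_granularity_examples(scores, expected):
    ranked = RankedSet(items=list(range(len(scores))), scores=scores,
                       ranks=rankdata(scores))
    assert cf.granularity(ranked) == expected


def test_granularity_categorical():
    """13 categories spread over 260 items: granularity 0.05."""
    scores = np.repeat(np.arange(13.0), 20)
    ranked = RankedSet(items=list(range(260)), scores=scores,
                       ranks=rankdata(-scores))
    assert cf.granularity(ranked) == pytest.approx(0.05)


def test_rmsd_diversity_filter_greedy_oracle(toy, toy_decoys):
    from voroscore.pose_generation import node_rmsd

    spec, native, _ = toy
    confs = [native] + list(toy_decoys)
    # a duplicate of the best-ranked conformation must be removed
    confs.append(native)
    n = len(confs)
    ranks = np.arange(1, n + 1, dtype=float)
    ranking = RankedSet(items=list(range(n)), scores=ranks.copy(), ranks=ranks)
    filtered = cf.rmsd_diversity_filter(ranking, confs, min_rmsd=5.0)
    # greedy-scan oracle
    kept = []
    for cid in range(n):
        if all(node_rmsd(confs[cid], confs[k]) > 5.0 for k in kept):
            kept.append(cid)
    assert filtered.items == kept
    assert n - 1 not in filtered.items  # the duplicate dropped
    np.testing.assert_array_equal(filtered.ranks, np.arange(1, len(kept) + 1))


def test_rmsd_diversity_filter_identity_when_diverse(toy, toy_decoys):
    spec, native, _ = toy
    confs = list(toy_decoys)
    from voroscore.pose_generation import node_rmsd

    diverse = [c for i, c in enumerate(confs)
               if all(node_rmsd(c, confs[j]) > 5.0 for j in range(i))]
    n = len(diverse)
    ranks = np.arange(1, n + 1, dtype=float)
    ranking = RankedSet(items=list(range(n)), scores=ranks.copy(), ranks=ranks)
    filtered = cf.rmsd_diversity_filter(ranking, diverse, min_rmsd=5.0)
    assert filtered.items == list(range(n))


def test_roster_training_and_precision_gate(rng):
    """The sklearn-backed roster trains on a planted set; every measured
    precision is held-out, and sub-0.5 members are discarded."""
    ls = sf.make_planted_feature_set(sf.FixtureSpec(seed=12, effect_size=2.0,
                                                    n_natives=8))
    roster = cf.default_roster(0)
    assert len(roster) == 12
    kept = cf.measure_precisions(roster, ls.X, ls.y, folds=5, seed=0)
    assert all(c.precision >= 0.5 for c in kept)
    assert len(kept) >= 1
    votes = cf.collect_votes(kept, ls.X, ls.y, ls.X)
    assert len(votes) == len(ls)
    assert all(set(np.unique(v.votes)) <= {-1, 1} for v in votes)
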