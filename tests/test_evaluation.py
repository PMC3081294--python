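"""fnat, coarse-node RMSD measures, quality classes, metrics, reports."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from voroscore import evaluation as ev
from voroscore.ga_scoring import RankedSet
from voroscore.pose_generation import ComplexConformation


def _shift_ligand(conf, delta):
    return ComplexConformation(
        conf.receptor, conf.ligand.with_positions(conf.ligand_positions + delta))


def test_fnat_native_is_one_and_disjoint_is_zero(toy):
    _, native, _ = toy
    assert ev.fnat(native, native) == 1.0
    far = _shift_ligand(native, [300.0, 0, 0])
    assert ev.fnat(far, native) == 0.0


def test_fnat_counts_preserved_contacts(toy):
    """A pose preserving a known subset of native contacts has exactly that
    fraction; monotone under contact deletion."""
    _, native, _ = toy
    contacts = sorted(ev.native_contacts(native, cutoff=5.0))
    n = len(contacts)
    assert n > 0
    # progressively destroy contacts by moving the ligand away
    prev = 1.0
    for d in (0.0, 2.0, 4.0, 8.0, 20.0):
        f = ev.fnat(_shift_ligand(native, [d, 0, 0]), native)
        assert f <= prev + 1e-12
        prev = f


def test_fnat_undefined_without_native_contacts(toy):
    _, native, _ = toy
    separated = _shift_ligand(native, [300.0, 0, 0])
    with pytest.raises(ValueError, match="undefined fnat"):
        ev.fnat(native, separated)


def test_voronoi_contact_mode(toy):
    _, native, _ = toy
    pairs = ev.native_contacts(native, mode="voronoi")
    dist = ev.native_contacts(native, cutoff=5.0)
    assert pairs  # the docked toy complex has Voronoi cross neighbors
    assert ev.fnat(native, native, mode="voronoi") == 1.0


def test_rmsd_zero_on_identity_and_shift(toy):
    _, native, _ = toy
    i_rmsd, l_rmsd = ev.interface_and_ligand_rmsd(native, native)
    assert i_rmsd == pytest.approx(0.0, abs=1e-6)
    assert l_rmsd == pytest.approx(0.0, abs=1e-6)


def test_ligand_shift_rmsd(toy):
    """Receptor fixed, ligand moved 3 Å: L_RMSD = 3 (equal-size partners
    superpose on the receptor)."""
    spec, native, _ = toy
    shifted = _shift_ligand(native, [3.0, 0, 0])
    _, l_rmsd = ev.interface_and_ligand_rmsd(shifted, native)
    assert l_rmsd == pytest.approx(3.0, abs=1e-6)


def test_rmsd_matches_kabsch_oracle(rng, toy, toy_decoys):
    """I/L RMSD agree with an independent quaternion-free Kabsch + RMSD
    computation."""
    _, native, _ = toy
    pred = toy_decoys[0]

    def kabsch_rmsd(mobile, target):
        mc, tc = mobile.mean(0), target.mean(0)
        H = (mobile - mc).T @ (target - tc)
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1, 1, d]) @ U.T
        moved = (mobile - mc) @ R.T + tc
        return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))

    contacts = ev.native_contacts(native, 5.0)
    ri = sorted({i for i, _ in contacts})
    li = sorted({j for _, j in contacts})
    pred_iface = np.vstack([pred.receptor.positions[ri], pred.ligand_positions[li]])
    nat_iface = np.vstack([native.receptor.positions[ri], native.ligand_positions[li]])
    i_rmsd, l_rmsd = ev.interface_and_ligand_rmsd(pred, native)
    assert i_rmsd == pytest.approx(kabsch_rmsd(pred_iface, nat_iface), abs=1e-6)


@pytest.mark.parametrize(
    "fnat,i,l,expected",
    [
        (0.95, 0.5, 3.0, "High"),
        (0.05, 0.1, 0.1, "Incorrect"),
        (0.4, 3.0, 12.0, "Acceptable"),  # fails Medium RMSD, passes fallback
        (0.4, 1.5, 12.0, "Medium"),
        (0.6, 3.0, 4.0, "Medium"),  # high fnat demoted by RMSD
        (0.2, 3.5, 12.0, "Acceptable"),
        (0.2, 8.0, 20.0, "Incorrect"),
    ],
)
def test_capri_class_cascade(fnat, i, l, expected):
    assert ev.QualityLabel(fnat, i, l).capri_class == expected


def test_capri_class_falls_back_without_rmsd():
    q = ev.QualityLabel(0.35)
    assert q.capri_class == "Medium"
    assert q.rmsd_fallback


@pytest.mark.parametrize(
    "f,cls",
    [(0.5, "High"), (0.49, "Medium"), (0.3, "Medium"), (0.29, "Acceptable"),
     (0.1, "Acceptable"), (0.09, "Incorrect")],
)
def test_fnat_class_thresholds(f, cls):
    assert ev.fnat_class(f) == cls


def test_capri_never_above_fnat_tier(rng):
    """The CAPRI tier never exceeds the fnat-only tier: the contingency
    table's lower-left triangle is empty."""
    labels = [
        ev.QualityLabel(float(rng.random()), float(rng.uniform(0, 12)),
                        float(rng.uniform(0, 15)))
        for _ in range(500)
    ]
    table = ev.concordance_table(labels)
    order = list(ev.CLASSES)
    for r, fc in enumerate(order):
        for c, cc in enumerate(order):
            if c < r:  # CAPRI strictly better than fnat tier
                assert table.loc[fc, cc] == 0


def test_metrics_arithmetic():
    all_neg = ev.metrics(ev.ConfusionCounts(tp=0, fp=0, fn=10, tn=90))
    assert all_neg == {"precision": 0.0, "recall": 0.0, "accuracy": 0.9,
                       "fnr": 1.0, "tnr": 1.0}
    perfect = ev.metrics(ev.ConfusionCounts(tp=10, fp=0, fn=0, tn=90))
    assert perfect["precision"] == perfect["recall"] == perfect["accuracy"] == 1.0
    assert perfect["fnr"] == 0.0
    mixed = ev.metrics(ev.ConfusionCounts(tp=3, fp=1, fn=1, tn=95))
    assert mixed["precision"] == 0.75
    assert mixed["recall"] == 0.75
    assert mixed["accuracy"] == 0.98


def _ranking(n):
    ranks = np.arange(1, n + 1, dtype=float)
    return RankedSet(items=list(range(n)), scores=ranks.copy(), ranks=ranks)


def test_enrichment_extremes():
    n = 100
    ranking = _ranking(n)
    # all 10 acceptable poses in the top 20 ranks: top enrichment 5, bottom 0
    labels = [ev.QualityLabel(0.2 if i < 10 else 0.0) for i in range(n)]
    top, bottom = ev.enrichment(ranking, labels, tail=0.2)
    assert top == pytest.approx(5.0)
    assert bottom == 0.0
    # no acceptable pose at all: undefined
    none = [ev.QualityLabel(0.0) for _ in range(n)]
    assert ev.enrichment(ranking, none) == (None, None)


def test_enrichment_null_case(rng):
    n = 2000
    ranking = _ranking(n)
    labels = [ev.QualityLabel(0.2 if rng.random() < 0.3 else 0.0)
              for i in range(n)]
    top, bottom = ev.enrichment(ranking, labels, tail=0.2)
    assert top == pytest.approx(1.0, abs=0.15)
    assert bottom == pytest.approx(1.0, abs=0.15)


def test_top10_counts_and_report(rng):
    n = 40
    ranking = _ranking(n)
    # acceptable poses at ranks 3 and 12
    labels = [ev.QualityLabel(0.2 if i in (2, 11) else 0.0) for i in range(n)]
    best, N, R = ev.top10_counts(ranking, labels)
    assert (best, N, R) == ("Acceptable", 1, 3)
    # none in top 10: R still reports the first hit beyond 10
    labels = [ev.QualityLabel(0.2 if i == 11 else 0.0) for i in range(n)]
    best, N, R = ev.top10_counts(ranking, labels)
    assert (best, N, R) == ("Incorrect", 0, 12)
    # single acceptable at rank 1
    labels = [ev.QualityLabel(0.2 if i == 0 else 0.0) for i in range(n)]
    assert ev.top10_counts(ranking, labels) == ("Acceptable", 1, 1)


def test_report_table_recount(rng):
    n = 30
    per_target = {}
    labels_per_target = {}
    for t in range(3):
        order = rng.permutation(n)
        ranks = rankdata(order)
        per_target[f"T{t}"] = RankedSet(items=list(range(n)),
                                        scores=ranks.astype(float), ranks=ranks)
        labels_per_target[f"T{t}"] = [
            ev.QualityLabel(0.4 if rng.random() < 0.2 else 0.0) for _ in range(n)]
    df = ev.report_table({"ga": per_target}, labels_per_target)
    assert len(df) == 3
    for _, row in df.iterrows():
        ranking = per_target[row["target"]]
        labels = labels_per_target[row["target"]]
        brute_n = sum(
            1 for idx in ranking.order()[:10]
            if labels[ranking.items[idx]].fnat_class != "Incorrect")
        assert row["N"] == brute_n


def test_summarize_rank_table():
    n = [2, 9, 2, 5]
    r = [4, 1, 2, None]
    out = ev.summarize_rank_table(n, r, exclude_from_r=(2,))
    assert out["mean_R"] == pytest.approx((4 + 1) / 2)
    assert out["mean_N"] == pytest.approx(4.5)
    assert out["n_top10"] == 4


def test_concordance_summary_arithmetic():
    table = pd.DataFrame(
        [[10, 5, 5, 0], [0, 4, 4, 2], [0, 0, 3, 7], [0, 0, 0, 60]],
        index=list(ev.CLASSES), columns=list(ev.CLASSES),
    )
    out = ev.concordance_summary(table)
    assert out["high_acceptable_or_better"] == pytest.approx(100.0)
    assert out["high_medium_or_better"] == pytest.approx(75.0)
    assert out["medium_acceptable_or_better"] == pytest.approx(80.0)
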