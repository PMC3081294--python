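"""Quality assessment of ranked conformations.

Implements the two quality-class schemes used in blind docking assessment,
on the coarse one-node-per-residue model throughout (the package never
builds all-atom structures, and every report states so):

* fnat-only classes — High (fnat ≥ 0.5), Medium (0.3 ≤ fnat < 0.5),
  Acceptable (0.1 ≤ fnat < 0.3), Incorrect (fnat < 0.1);
* full CAPRI classes — the standard cascade combining fnat with interface
  RMSD (I_RMSD, after superposing the native-interface nodes) and ligand
  RMSD (L_RMSD, over the smaller partner after superposing the larger).

Also provides confusion-matrix metrics, ranked-tail enrichment, the
per-target N/R report layout, and the fnat-vs-CAPRI concordance summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .pose_generation import ComplexConformation
from .voronoi_geometry import tessellate

CLASSES = ("High", "Medium", "Acceptable", "Incorrect")
_CLASS_LEVEL = {c: i for i, c in enumerate(CLASSES)}  # 0 = best


def fnat_class(fnat_value: float) -> str:
    if fnat_value >= 0.5:
        return "High"
    if fnat_value >= 0.3:
        return "Medium"
    if fnat_value >= 0.1:
        return "Acceptable"
    return "Incorrect"


@dataclass
class QualityLabel:
    """fnat plus optional RMSD measures and the derived classes."""

    fnat: float
    i_rmsd: float | None = None
    l_rmsd: float | None = None
    rmsd_fallback: bool = False  # True when CAPRI class fell back to fnat only

    @property
    def fnat_class(self) -> str:
        return fnat_class(self.fnat)

    @property
    def capri_class(self) -> str:
        return capri_class(self)

    def at_least(self, level: str, scheme: str = "capri") -> bool:
        cls = self.capri_class if scheme == "capri" else self.fnat_class
        return _CLASS_LEVEL[cls] <= _CLASS_LEVEL[level]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def native_contacts(
    native: ComplexConformation, cutoff: float = 5.0, mode: str = "distance"
) -> set[tuple[int, int]]:
    """Cross-partner residue contacts of a conformation.

    ``mode='distance'``: node pairs within ``cutoff`` Å (default 5, the
    atom-level convention carried to the coarse model).
    ``mode='voronoi'``: pairs sharing a positive-area Voronoi facet.
    Pairs are (receptor node index, ligand node index).
    """
    rec = native.receptor.positions
    lig = native.ligand_positions
    if mode == "voronoi":
        tess = tessellate(native)
        n_rec = len(rec)
        # cross pairs are (i < j) in merged indexing: i receptor, j ligand
        return {(i, j - n_rec) for i, j in tess.cross_pairs()}
    pairs = cKDTree(rec).query_ball_tree(cKDTree(lig), r=cutoff)
    return {(i, j) for i, js in enumerate(pairs) for j in js}


def fnat(
    pred: ComplexConformation,
    native: ComplexConformation,
    contact_cutoff: float = 5.0,
    mode: str = "distance",
) -> float:
    """Fraction of the native's cross-partner contacts present in ``pred``."""
    ref = native_contacts(native, contact_cutoff, mode)
    if not ref:
        raise ValueError("undefined fnat: native has no contacts")
    obs = native_contacts(pred, contact_cutoff, mode)
    return len(ref & obs) / len(ref)


def _superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Least-squares (Kabsch) fit of ``mobile`` onto ``target``; returns
    (rotation, mobile centroid, target centroid)."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot, mc, tc


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def interface_and_ligand_rmsd(
    pred: ComplexConformation, native: ComplexConformation, contact_cutoff: float = 5.0
) -> tuple[float, float]:
    """(I_RMSD, L_RMSD) on coarse nodes.

    I_RMSD: native interface residues (both partners, from the native's
    contacts) are superposed and their RMSD measured.  L_RMSD: the larger
    partner is superposed and the RMSD taken over the smaller one.
    """
    if len(pred.receptor) != len(native.receptor) or len(pred.ligand) != len(native.ligand):
        raise ValueError("residue sets of prediction and native do not map")
    contacts = native_contacts(native, contact_cutoff)
    rec_iface = sorted({i for i, _ in contacts})
    lig_iface = sorted({j for _, j in contacts})
    nat_iface = np.vstack([native.receptor.positions[rec_iface],
                           native.ligand_positions[lig_iface]])
    prd_iface = np.vstack([pred.receptor.positions[rec_iface],
                           pred.ligand_positions[lig_iface]])
    rot, mc, tc = _superpose(prd_iface, nat_iface)
    i_rmsd = _rmsd(rot.apply(prd_iface - mc) + tc, nat_iface)

    rec_big = len(native.receptor) >= len(native.ligand)
    big_p, small_p = (
        (pred.receptor.positions, pred.ligand_positions)
        if rec_big else (pred.ligand_positions, pred.receptor.positions)
    )
    big_n, small_n = (
        (native.receptor.positions, native.ligand_positions)
        if rec_big else (native.ligand_positions, native.receptor.positions)
    )
    rot, mc, tc = _superpose(big_p, big_n)
    l_rmsd = _rmsd(rot.apply(small_p - mc) + tc, small_n)
    return i_rmsd, l_rmsd


def capri_class(q: QualityLabel) -> str:
    """Standard CAPRI quality cascade on (fnat, I_RMSD, L_RMSD).

    High: fnat ≥ 0.5 and (I ≤ 1 or L ≤ 1); Medium: fnat ≥ 0.3 and
    (I ≤ 2 or L ≤ 5), not High; Acceptable: fnat ≥ 0.1 and (I ≤ 4 or
    L ≤ 10), not better; else Incorrect.  High-fnat poses failing an RMSD
    test cascade to the tier whose RMSD caps they meet.  Missing RMSDs
    fall back to the fnat-only class with ``rmsd_fallback`` set.
    """
    if q.i_rmsd is None or q.l_rmsd is None:
        q.rmsd_fallback = True
        return q.fnat_class
    f, i, l = q.fnat, q.i_rmsd, q.l_rmsd
    if f >= 0.5 and (i <= 1.0 or l <= 1.0):
        return "High"
    if f >= 0.3 and (i <= 2.0 or l <= 5.0):
        return "Medium"
    if f >= 0.1 and (i <= 4.0 or l <= 10.0):
        return "Acceptable"
    return "Incorrect"


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """precision, recall, accuracy, FNR, TNR (zero when denominator is 0)."""
    def div(a, b):
        return a / b if b else 0.0
    return {
        "precision": div(c.tp, c.tp + c.fp),
        "recall": div(c.tp, c.tp + c.fn),
        "accuracy": div(c.tp + c.tn, c.total),
        "fnr": div(c.fn, c.fn + c.tp),
        "tnr": div(c.tn, c.tn + c.fp),
    }


def enrichment(
    ranking,
    labels: Sequence[QualityLabel],
    tail: float = 0.2,
    level: str = "Acceptable",
    scheme: str = "fnat",
) -> tuple[float | None, float | None]:
    """Enrichment of level-or-better poses in the best and worst rank tails.

    Each tail holds ⌈tail·n⌉ items; enrichment = tail proportion divided by
    the complete-set proportion.  Returns (top, bottom); ``None`` flags an
    undefined value (no level-or-better pose in the whole set).
    """
    order = ranking.order()
    good = np.array([labels[ranking.items[i]].at_least(level, scheme) for i in order])
    n = len(good)
    overall = good.mean()
    if overall == 0:
        return None, None
    k = int(np.ceil(tail * n))
    return float(good[:k].mean() / overall), float(good[-k:].mean() / overall)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def top10_counts(
    ranking, labels: Sequence[QualityLabel], level: str = "Acceptable",
    scheme: str = "fnat", top: int = 10,
) -> tuple[str, int, int | None]:
    """(best class in top ``top``, N, R) for one target and method.

    N = level-or-better solutions among the ``top`` best ranks; R = rank of
    the first level-or-better solution anywhere (None if absent).
    """
    order = ranking.order()
    classes = []
    r_first = None
    n = 0
    for pos, idx in enumerate(order, start=1):
        q = labels[ranking.items[idx]]
        cls = q.capri_class if scheme == "capri" else q.fnat_class
        if pos <= top:
            classes.append(cls)
            if _CLASS_LEVEL[cls] <= _CLASS_LEVEL[level]:
                n += 1
        if r_first is None and _CLASS_LEVEL[cls] <= _CLASS_LEVEL[level]:
            r_first = pos
    best = min(classes, key=lambda c: _CLASS_LEVEL[c]) if classes else "Incorrect"
    return best, n, r_first


def summarize_rank_table(
    n_values: Sequence[int],
    r_values: Sequence[int | None],
    exclude_from_r: Sequence[int] = (),
) -> dict[str, float | int]:
    """Summary statistics of per-target (N, R) columns.

    ``mean_R`` averages the rank of the first acceptable-or-better solution
    over targets not listed in ``exclude_from_r`` (and with a defined R);
    ``mean_N`` averages N over all targets; ``n_top10`` counts targets with
    at least one acceptable-or-better solution in the top 10 (N ≥ 1).
    """
    rs = [r for t, r in enumerate(r_values) if t not in exclude_from_r and r is not None]
    if not rs:
        raise ValueError("no target contributes a rank")
    return {
        "mean_R": float(np.mean(rs)),
        "mean_N": float(np.mean(list(n_values))),
        "n_top10": int(sum(1 for n in n_values if n >= 1)),
        "n_targets": len(n_values),
    }


def concordance_table(labels: Sequence[QualityLabel]) -> pd.DataFrame:
    """Contingency table of fnat-only class (rows) vs CAPRI class (columns)."""
    table = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for q in labels:
        table.loc[q.fnat_class, q.capri_class] += 1
    return table


def concordance_summary(table: pd.DataFrame) -> dict[str, float]:
    """Percent agreement between the fnat-only and full CAPRI schemes.

    Reports, among fnat-High conformations, the percentage that are CAPRI
    acceptable-or-better and medium-or-better, and among fnat-Medium
    conformations the percentage CAPRI acceptable-or-better.  Percentages
    are on the 0–100 scale.
    """
    high = table.loc["High"]
    med = table.loc["Medium"]
    return {
        "high_acceptable_or_better": 100.0 * (
            high[["High", "Medium", "Acceptable"]].sum() / high.sum()),
        "high_medium_or_better": 100.0 * (
            high[["High", "Medium"]].sum() / high.sum()),
        "medium_acceptable_or_better": 100.0 * (
            med[["High", "Medium", "Acceptable"]].sum() / med.sum()),
    }


def report_table(
    rankings: dict[str, object],
    labels_per_target: dict[str, Sequence[QualityLabel]],
    scheme: str = "fnat",
) -> pd.DataFrame:
    """Per-target, per-method (best, N, R) table.

    ``rankings`` maps (method name) → (target → RankedSet).  The header of
    any rendered report must state that all RMSD measures are coarse-node
    RMSDs.
    """
    rows = []
    for method, per_target in rankings.items():
        for target, ranking in per_target.items():
            best, n, r = top10_counts(ranking, labels_per_target[target], scheme=scheme)
            rows.append({"method": method, "target": target,
                         "best": best, "N": n, "R": r})
    return pd.DataFrame(rows)
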