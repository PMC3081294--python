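"""The 96-attribute Voronoi interface descriptor.

Fixed layout (missing entries are masked, value 0.0):

====== ======================================================================
c1     Voronoi interface area (Å²)
c2     number of interface residues (both partners pooled)
c3–22  fraction of interface residues of each type (alphabetical A…Y)
c23–42 mean Voronoi cell volume of interface residues of each type (Å³)
c43–63 fraction of cross pairs per category pair (21 unordered pairs)
c64–84 mean node–node distance per category pair (Å)
c85–90 fraction of interface residues per category
c91–96 mean Voronoi cell volume per category (Å³)
====== ======================================================================

Category order: hydrophobic, aromatic, small, polar, positive, negative;
pair blocks run in row-major upper-triangle order over that order (self
pairs included).  Fractions are taken over the entities present, so the
c3–c22, c43–c63 and c85–c90 blocks each sum to 1 on a non-empty interface.
Missingness (an empty defining set — e.g. no pair of some category pair at
the interface) is a mask bit, not a value; downstream scoring treats masked
terms as absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_model import AMINO_ACIDS, CATEGORIES
from .voronoi_geometry import interface_area, interface_of, tessellate

logger = logging.getLogger(__name__)

N_FEATURES = 96

#: The 21 unordered category pairs, row-major upper triangle.
CATEGORY_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (CATEGORIES[i], CATEGORIES[j])
    for i in range(len(CATEGORIES))
    for j in range(i, len(CATEGORIES))
)

FEATURE_NAMES = tuple(f"c{i}" for i in range(1, N_FEATURES + 1))


@dataclass
class FeatureVector:
    """One conformation's 96 interface attributes plus missing-value mask."""

    values: np.ndarray  # (96,)
    missing_mask: np.ndarray  # (96,) bool
    label: str = "negative"  # positive | negative
    complex_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(N_FEATURES)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool).reshape(N_FEATURES)

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())


def _pair_key(cat_a: str, cat_b: str) -> tuple[str, str]:
    ia, ib = CATEGORIES.index(cat_a), CATEGORIES.index(cat_b)
    return (CATEGORIES[min(ia, ib)], CATEGORIES[max(ia, ib)])


def featurize(conf, tess=None) -> FeatureVector:
    """Compute c1…c96 for a conformation (tessellating it if needed)."""
    if tess is None:
        tess = tessellate(conf)
    iface = interface_of(tess)
    nodes = list(conf.receptor.nodes) + list(conf.ligand.nodes)
    idx = sorted(iface.receptor_residues | iface.ligand_residues)

    values = np.zeros(N_FEATURES)
    mask = np.zeros(N_FEATURES, dtype=bool)

    values[0] = interface_area(tess)
    values[1] = len(idx)

    types = [nodes[i].residue_type for i in idx]
    cats = [nodes[i].category for i in idx]
    vols = tess.cell_volumes[idx] if idx else np.empty(0)

    # c3–c22 type fractions and c23–c42 type mean cell volumes
    for t, aa in enumerate(AMINO_ACIDS):
        members = [k for k, ty in enumerate(types) if ty == aa]
        if not idx:
            mask[2 + t] = True
        else:
            values[2 + t] = len(members) / len(idx)
        if not members:
            mask[22 + t] = True
        else:
            values[22 + t] = float(vols[members].mean())

    # cross-pair category blocks c43–c63 (fractions) and c64–c84 (distances)
    pair_groups: dict[tuple[str, str], list[float]] = {p: [] for p in CATEGORY_PAIRS}
    for i, j in iface.cross_pairs:
        key = _pair_key(nodes[i].category, nodes[j].category)
        dist = float(np.linalg.norm(tess.points[i] - tess.points[j]))
        pair_groups[key].append(dist)
    n_pairs = len(iface.cross_pairs)
    for p, pair in enumerate(CATEGORY_PAIRS):
        dists = pair_groups[pair]
        if n_pairs == 0:
            mask[42 + p] = True
        else:
            values[42 + p] = len(dists) / n_pairs
        if not dists:
            mask[63 + p] = True
        else:
            values[63 + p] = float(np.mean(dists))

    # per-category fractions c85–c90 and mean volumes c91–c96
    for c, cat in enumerate(CATEGORIES):
        members = [k for k, cc in enumerate(cats) if cc == cat]
        if not idx:
            mask[84 + c] = True
        else:
            values[84 + c] = len(members) / len(idx)
        if not members:
            mask[90 + c] = True
        else:
            values[90 + c] = float(vols[members].mean())

    return FeatureVector(values, mask)


@dataclass
class LearningSet:
    """Labeled feature vectors grouped by parent complex."""

    vectors: list[FeatureVector] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def X(self) -> np.ndarray:
        return np.array([v.values for v in self.vectors])

    @property
    def M(self) -> np.ndarray:
        """Boolean missing-mask matrix aligned with X."""
        return np.array([v.missing_mask for v in self.vectors])

    @property
    def y(self) -> np.ndarray:
        return np.array([1 if v.label == "positive" else 0 for v in self.vectors])

    @property
    def groups(self) -> np.ndarray:
        return np.array([v.complex_id for v in self.vectors])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        for i, name in enumerate(FEATURE_NAMES):
            df[f"{name}_missing"] = self.M[:, i]
        df.insert(0, "complex_id", self.groups)
        df.insert(1, "label", [v.label for v in self.vectors])
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LearningSet":
        vectors = []
        for _, row in df.iterrows():
            values = row[list(FEATURE_NAMES)].to_numpy(dtype=float)
            mask = row[[f"{n}_missing" for n in FEATURE_NAMES]].to_numpy(dtype=bool)
            vectors.append(
                FeatureVector(values, mask, label=row["label"],
                              complex_id=str(row["complex_id"]))
            )
        return cls(vectors)


def assemble_learning_set(
    natives: list[FeatureVector],
    decoys_per_native: list[list[FeatureVector]],
    missing_factor: float = 2.0,
) -> LearningSet:
    """Pool natives with their decoys, dropping data-poor decoys.

    A decoy is kept only if its missing-value count is at most
    ``missing_factor`` × the missing count of its native.  Natives are
    labeled positive, surviving decoys negative; every decoy inherits its
    native's complex_id.
    """
    if len(natives) != len(decoys_per_native):
        raise ValueError("one decoy list required per native")
    vectors: list[FeatureVector] = []
    counts = {"natives": len(natives), "decoys_in": 0, "decoys_kept": 0}
    for native, decoys in zip(natives, decoys_per_native):
        native.label = "positive"
        if not native.complex_id:
            raise ValueError("native FeatureVector needs a complex_id")
        vectors.append(native)
        threshold = missing_factor * native.n_missing
        kept = 0
        for decoy in decoys:
            counts["decoys_in"] += 1
            if decoy.n_missing > threshold:
                continue
            decoy.label = "negative"
            decoy.complex_id = native.complex_id
            vectors.append(decoy)
            kept += 1
            counts["decoys_kept"] += 1
        if decoys and kept == 0:
            logger.warning(
                "complex %s: no decoy survived the missing-value filter",
                native.complex_id,
            )
    return LearningSet(vectors, provenance=counts)
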