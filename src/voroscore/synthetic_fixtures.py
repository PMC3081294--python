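"""Deterministic synthetic fixtures: toy complexes, feature sets, votes.

Everything here is generated, seeded, and labeled synthetic: toy "proteins"
are compact residue-node clouds with realistic ~3.8 Å nearest-neighbor
spacing and valid coarse-model PDB serialization — they have no secondary
structure and do not mimic real folds.  The generators reproduce the
*shape* of a docking learning problem (one native per complex with a
planted contact zone, ~15 decoys per native ≥ 10 Å away with ≥ 400 Å²
interfaces, a 96-attribute feature matrix with planted signal and
missingness, precision-graded voters) so every pipeline stage can be
tested at desk scale without any structure download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ga_scoring import RankedSet
from .cf_ranking import VoteRecord
from .interface_features import N_FEATURES, FeatureVector, LearningSet
from .pose_generation import ComplexConformation
from .structure_model import AMINO_ACIDS, PartnerStructure, ResidueNode, category_of, load_volume_table
from scipy.stats import rankdata


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture; (spec, seed) fixes the output."""

    seed: int = 0
    residues_per_partner: int = 30
    interface_size: int = 12  # planted contact pairs
    decoys_per_native: int = 15
    n_natives: int = 10
    informative_fraction: float = 0.1
    effect_size: float = 2.0
    noise_scale: float = 1.0
    roster_size: int = 12
    precisions: np.ndarray | None = None  # drawn in (0.5, 1] when None
    contact_cutoff: float = 6.0  # Å, planted-contact definition

    def __post_init__(self):
        if min(self.residues_per_partner, self.decoys_per_native, self.n_natives,
               self.roster_size) < 1:
            raise ValueError("all fixture counts must be positive")


def _packed_cloud(n: int, rng: np.random.Generator, spacing: float = 3.8) -> np.ndarray:
    """n points packed in a ball with ≥ ``spacing`` nearest-neighbor distance."""
    radius = spacing * max(1.5, (n / 0.3) ** (1 / 3))
    for _attempt in range(8):
        points: list[np.ndarray] = []
        tries = 0
        while len(points) < n and tries < 4000 * n:
            tries += 1
            p = rng.uniform(-radius, radius, 3)
            if np.linalg.norm(p) > radius:
                continue
            if points and np.min(np.linalg.norm(np.array(points) - p, axis=1)) < spacing:
                continue
            points.append(p)
        if len(points) == n:
            return np.array(points)
        radius *= 1.2  # inflate the box and retry
    raise RuntimeError("unsatisfiable packing")


def _make_partner(
    n: int, rng: np.random.Generator, chain_id: str, label: str,
    volumes: dict[str, float],
) -> PartnerStructure:
    pos = _packed_cloud(n, rng)
    types = rng.choice(list(AMINO_ACIDS), size=n)
    nodes = [
        ResidueNode(chain_id, i + 1, t, category_of(t), pos[i], volumes[t])
        for i, t in enumerate(types)
    ]
    return PartnerStructure(label=label, nodes=nodes, source="synthetic")


def make_toy_complex(spec: FixtureSpec) -> tuple[ComplexConformation, dict]:
    """A docked native toy complex with a planted contact zone.

    The ligand cloud is slid along +x toward the receptor until at least
    ``spec.interface_size`` cross-partner node pairs fall within the
    planted contact cutoff.  Returns the native conformation plus a
    ground-truth manifest (contacts, per-partner interface residues, the
    spec used).
    """
    rng = np.random.default_rng(spec.seed)
    volumes = load_volume_table()
    receptor = _make_partner(spec.residues_per_partner, rng, "A", "receptor", volumes)
    ligand = _make_partner(spec.residues_per_partner, rng, "B", "ligand", volumes)

    rec = receptor.positions
    lig0 = ligand.positions - ligand.positions.mean(axis=0)
    rec_xmax = rec[:, 0].max()
    lig_halfwidth = -lig0[:, 0].min()

    def contacts_at(offset: float) -> set[tuple[int, int]]:
        lig = lig0 + np.array([offset, 0.0, 0.0])
        d = np.linalg.norm(rec[:, None, :] - lig[None, :, :], axis=2)
        ii, jj = np.where(d <= spec.contact_cutoff)
        return set(zip(ii.tolist(), jj.tolist()))

    offset = rec_xmax + lig_halfwidth + spec.contact_cutoff
    while len(contacts_at(offset)) < spec.interface_size and offset > 0:
        offset -= 0.25
    contacts = contacts_at(offset)
    if len(contacts) < spec.interface_size:
        raise RuntimeError("could not plant the requested contact zone")
    ligand = ligand.with_positions(lig0 + np.array([offset, 0.0, 0.0]))
    native = ComplexConformation(receptor, ligand, provenance="native",
                                 rmsd_to_native=0.0)
    manifest = {
        "spec": spec,
        "contacts": sorted(contacts),
        "receptor_interface": sorted({i for i, _ in contacts}),
        "ligand_interface": sorted({j for _, j in contacts}),
        "offset": offset,
    }
    return native, manifest


def make_decoy_ensemble(
    spec: FixtureSpec, native: ComplexConformation
) -> list[ComplexConformation]:
    """Cheap labeled decoys: the ligand re-docked at random far placements.

    Each decoy translates the ligand against the receptor from a random
    direction, then slides it inward until the Voronoi interface reaches
    ≥ 400 Å², while staying > 10 Å ligand RMSD from the native — the
    geometry the generation-and-filter pipeline produces, without paying
    for full pose enumeration.
    """
    from .voronoi_geometry import interface_area, tessellate

    rng = np.random.default_rng(spec.seed + 1)
    rec = native.receptor.positions
    lig0 = native.ligand_positions - native.ligand_positions.mean(axis=0)
    center = rec.mean(axis=0)
    rec_radius = np.linalg.norm(rec - center, axis=1).max()
    lig_radius = np.linalg.norm(lig0, axis=1).max()
    decoys = []
    while len(decoys) < spec.decoys_per_native:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        sep = rec_radius + lig_radius * 0.7
        conf = None
        while sep > 0.3 * rec_radius:  # slide inward until a real interface
            pos = lig0 + center + sep * u
            cand = ComplexConformation(
                native.receptor, native.ligand.with_positions(pos),
                provenance="decoy")
            if interface_area(tessellate(cand)) >= 400.0:
                rmsd = float(np.sqrt(np.mean(
                    np.sum((pos - native.ligand_positions) ** 2, axis=1))))
                if rmsd > 10.0:
                    cand.rmsd_to_native = rmsd
                    conf = cand
                break
            sep -= 2.0
        if conf is not None:
            decoys.append(conf)
    return decoys


def write_toy_pdb(conf: ComplexConformation, path: str | Path) -> None:
    """Serialize a toy complex as PDB: Cα plus one pseudo side-chain atom.

    The two atoms straddle the node so their mean recovers the node
    position; glycine writes its Cα only.  Output is byte-deterministic.
    """
    delta = np.array([0.5, 0.0, 0.0])
    lines = []
    serial = 1
    from .structure_model import _3LETTER, pdb_atom_line

    for partner in (conf.receptor, conf.ligand):
        positions = partner.positions
        for i, node in enumerate(partner.nodes):
            res3 = _3LETTER[node.residue_type]
            p = positions[i]
            atoms = [("CA", p)] if node.residue_type == "G" else [
                ("CA", p + delta), ("CB", p - delta)]
            for name, xyz in atoms:
                lines.append(pdb_atom_line(serial, name, res3, node.chain_id,
                                           node.residue_index, xyz))
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def make_planted_feature_set(spec: FixtureSpec) -> LearningSet:
    """A labeled 96-attribute set with planted signal and missingness.

    Positives and negatives are Gaussian in all 96 coordinates; the first
    ⌈informative_fraction·96⌉ coordinates of positives are shifted by
    ``effect_size`` standard deviations.  Complexes group one positive
    with ``decoys_per_native`` negatives.  Missingness is planted at a
    low per-native count with decoys scattered around the twice-native
    filter threshold.
    """
    if not 0 < spec.informative_fraction <= 1:
        raise ValueError("informative fraction must be in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    k = int(np.ceil(spec.informative_fraction * N_FEATURES))
    vectors: list[FeatureVector] = []
    for c in range(spec.n_natives):
        cid = f"C{c:03d}"
        native_missing = int(rng.integers(0, 3))
        for rep in range(spec.decoys_per_native + 1):
            positive = rep == 0
            x = rng.normal(0.0, spec.noise_scale, N_FEATURES)
            if positive:
                x[:k] += spec.effect_size
                n_miss = native_missing
            else:
                n_miss = int(rng.integers(0, max(1, 2 * native_missing + 2)))
            mask = np.zeros(N_FEATURES, bool)
            if n_miss:
                mask[rng.choice(N_FEATURES, size=n_miss, replace=False)] = True
            x[mask] = 0.0
            vectors.append(FeatureVector(
                x, mask, label="positive" if positive else "negative",
                complex_id=cid))
    return LearningSet(vectors, provenance={"planted_informative": k})


def make_vote_fixture(
    spec: FixtureSpec, n_items: int = 100, positive_fraction: float = 0.2,
    ga_correlation: float = 0.8,
) -> tuple[list[VoteRecord], RankedSet, np.ndarray]:
    """Simulated votes, a correlated GA ranking, and the true labels.

    Each of ``roster_size`` classifiers votes correctly on an item with
    probability equal to its nominal precision (drawn once in (0.5, 1]
    unless given).  GA scores mix the true label with Gaussian noise at
    ``ga_correlation`` weight, then become ranks.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.precisions is not None:
        p = np.asarray(spec.precisions, dtype=float)
    else:
        p = np.sort(rng.uniform(0.5, 1.0, spec.roster_size) + 1e-6)[::-1]
    labels = (rng.random(n_items) < positive_fraction).astype(int)
    correct = rng.random((len(p), n_items)) < p[:, None]
    truth = np.where(labels == 1, 1, -1)
    votes = np.where(correct, truth[None, :], -truth[None, :])
    records = [VoteRecord(i, votes[:, i], p) for i in range(n_items)]

    ga_score = ga_correlation * labels + (1 - ga_correlation) * rng.normal(size=n_items)
    ga_ranks = rankdata(-ga_score)
    ga = RankedSet(items=list(range(n_items)), scores=-ga_score, ranks=ga_ranks)
    return records, ga, labels
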