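"""Coarse-grain one-node-per-residue protein model.

Each residue is collapsed to a single node placed at the unweighted mean of
its side-chain heavy atoms plus the Cα (glycine: the Cα alone).  Residue
types are binned into six physico-chemical categories, and each node carries
the mean residue volume of its type (Pontius et al. 1996 by default; the
table ships as an editable TSV so alternative volume sets can be dropped in).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

logger = logging.getLogger(__name__)

#: The six residue categories, in the fixed order used throughout.
CATEGORIES = ("hydrophobic", "aromatic", "small", "polar", "positive", "negative")

_CATEGORY_MEMBERS = {
    "hydrophobic": "ILVM",
    "aromatic": "FYW",
    "small": "AGSTCP",
    "polar": "NQ",
    "positive": "HKR",
    "negative": "DE",
}

#: Alphabetical one-letter codes of the 20 standard amino acids.
AMINO_ACIDS = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

_CATEGORY_OF = {
    aa: cat for cat, members in _CATEGORY_MEMBERS.items() for aa in members
}

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def category_of(residue_type: str) -> str:
    """Return the physico-chemical category of a one-letter residue code.

    The six categories partition the 20 standard amino acids:
    hydrophobic (ILVM), aromatic (FYW), small (AGSTCP), polar (NQ),
    positive (HKR), negative (DE).
    """
    try:
        return _CATEGORY_OF[residue_type]
    except KeyError:
        raise ValueError(f"unknown residue {residue_type!r}") from None


def load_volume_table(path: str | Path | None = None) -> dict[str, float]:
    """Load the residue mean-volume table (Å³).

    With no argument, the packaged Pontius et al. (1996) values are used.
    A custom table must be a two-column TSV (residue, volume) covering all
    20 standard amino acids with positive volumes.
    """
    if path is None:
        src = resources.files("voroscore.data").joinpath("pontius1996_volumes.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        res, vol = line.split("\t")
        table[res] = float(vol)
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise ValueError(f"volume table incomplete, missing {sorted(missing)}")
    if any(v <= 0 for v in table.values()):
        raise ValueError("volume table contains non-positive volumes")
    return table


@dataclass(frozen=True)
class ResidueNode:
    """One coarse node: a residue reduced to a point with type metadata."""

    chain_id: str
    residue_index: int
    residue_type: str
    category: str
    position: np.ndarray  # shape (3,), Å
    mean_volume: float  # Å³

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.mean_volume <= 0:
            raise ValueError("mean_volume must be positive")
        if category_of(self.residue_type) != self.category:
            raise ValueError(
                f"{self.residue_type} is not in category {self.category}"
            )


@dataclass
class PartnerStructure:
    """An ordered set of residue nodes for one docking partner."""

    label: str  # "receptor" | "ligand"
    nodes: list[ResidueNode] = field(default_factory=list)
    source: str = "synthetic"

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of node coordinates, in node order."""
        return np.array([n.position for n in self.nodes], dtype=float)

    def with_positions(self, coords: np.ndarray, label: str | None = None) -> "PartnerStructure":
        """Copy of this partner with node coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.nodes), 3):
            raise ValueError("coordinate array shape mismatch")
        nodes = [
            ResidueNode(n.chain_id, n.residue_index, n.residue_type, n.category,
                        coords[i], n.mean_volume)
            for i, n in enumerate(self.nodes)
        ]
        return PartnerStructure(label or self.label, nodes, self.source)


def load_partner(
    pdb_path: str | Path,
    chain_selector: str,
    volumes: dict[str, float] | None = None,
    label: str = "receptor",
) -> PartnerStructure:
    """Build the coarse model of one partner from a PDB file.

    ``chain_selector`` lists the chain IDs to include (e.g. ``"A"`` or
    ``"AB"``).  Node order follows chain then residue order of the file, so
    repeated loads of the same file give identical node lists.  Waters and
    hetero groups are skipped; alternate locations resolve to the highest
    occupancy (Bio.PDB default); hydrogens are excluded.  Residues lacking a
    Cα are skipped with a warning.
    """
    if volumes is None:
        volumes = load_volume_table()
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("partner", str(pdb_path))
    model = next(structure.get_models())
    wanted = list(chain_selector)
    have = {c.id for c in model}
    for cid in wanted:
        if cid not in have:
            raise ValueError(f"chain not found: {cid!r}")
    nodes: list[ResidueNode] = []
    for cid in wanted:
        chain = model[cid]
        for residue in chain:
            hetflag, resseq, _icode = residue.id
            if hetflag != " ":
                continue  # waters and hetero groups
            resname = residue.get_resname().strip()
            one = protein_letters_3to1.get(resname)
            if one is None:
                logger.warning("skipping non-standard residue %s", resname)
                continue
            if "CA" not in residue:
                logger.warning(
                    "residue %s%s has no CA; skipped", cid, resseq
                )
                continue
            coords = [residue["CA"].get_coord()]
            for atom in residue:
                name = atom.get_id()
                if name in _BACKBONE_ATOMS or atom.element == "H":
                    continue
                coords.append(atom.get_coord())
            pos = np.mean(np.asarray(coords, dtype=float), axis=0)
            nodes.append(
                ResidueNode(cid, resseq, one, category_of(one), pos, volumes[one])
            )
    if len(nodes) < 4:
        raise ValueError("degenerate structure: fewer than 4 usable residues")
    return PartnerStructure(label=label, nodes=nodes, source=str(pdb_path))


_3LETTER = {v: k for k, v in protein_letters_3to1.items()}


def pdb_atom_line(
    serial: int, name: str, res3: str, chain: str, resseq: int,
    xyz: np.ndarray, element: str = "C",
) -> str:
    """One fixed-column ATOM record (names of ≤3 chars start at column 14)."""
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  {name:<3s} {res3:>3s} {chain:1s}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}  "
    )


def write_partner(partner: PartnerStructure, pdb_path: str | Path) -> None:
    """Serialize the coarse model as a PDB of one CA pseudo-atom per node.

    Reloading such a file reproduces the node positions exactly (each node
    has a single atom, so the side-chain mean is the atom itself).
    """
    lines = [
        pdb_atom_line(serial, "CA", _3LETTER[node.residue_type], node.chain_id,
                      node.residue_index, node.position)
        for serial, node in enumerate(partner.nodes, start=1)
    ]
    lines.append("END")
    Path(pdb_path).write_text("\n".join(lines) + "\n")
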