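"""Rigid-body candidate generation by pseudo-normal pairing.

Every surface node of each partner carries a pseudo-normal: the (negated)
sum of edge vectors to its Delaunay neighbors, flipped outward when it
points into the body, with length equal to the radius of a sphere of the
residue's mean volume.  For each (receptor vector, ligand vector) pair the
ligand is translated so the vector tips coincide, rotated so the vectors
oppose exactly, then spun about the common axis in fixed angular steps —
a conformation per step.  Decoys are the generated poses that keep a large
enough Voronoi interface while sitting far from the native pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_model import PartnerStructure
from .voronoi_geometry import interface_area, partner_delaunay_neighbors, tessellate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurfaceVector:
    """Outward pseudo-normal anchored at one residue node."""

    node_id: int
    origin: np.ndarray  # node position, Å
    direction: np.ndarray  # unit 3-vector
    length: float  # Å, radius of the mean-volume sphere

    @property
    def tip(self) -> np.ndarray:
        return self.origin + self.length * self.direction


@dataclass
class ComplexConformation:
    """Receptor (fixed frame) plus a rigidly placed ligand copy."""

    receptor: PartnerStructure
    ligand: PartnerStructure
    transform: tuple[int, int, float] | None = None  # (u id, v id, spin °)
    provenance: str = "external"  # native | decoy | external
    rmsd_to_native: float | None = None

    @property
    def ligand_positions(self) -> np.ndarray:
        return self.ligand.positions


def sphere_radius(volume: float) -> float:
    """Radius of a sphere of the given volume: (3V / 4π)^(1/3)."""
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def pseudo_normals(partner: PartnerStructure, drop_tol: float = 1e-8) -> list[SurfaceVector]:
    """One pseudo-normal per node; near-zero sums are dropped.

    The raw direction is -Σ(neighbor − node) over Delaunay neighbors, which
    points away from local neighbor mass.  Because non-convex pockets can
    still aim it inward, it is flipped when it opposes the node's radial
    direction from the partner centroid (a star-convexity heuristic).
    """
    pos = partner.positions
    neighbors = partner_delaunay_neighbors(pos)
    centroid = pos.mean(axis=0)
    vectors: list[SurfaceVector] = []
    for i, node in enumerate(partner.nodes):
        raw = -(pos[list(neighbors[i])] - pos[i]).sum(axis=0)
        norm = float(np.linalg.norm(raw))
        if norm < drop_tol:
            logger.warning("node %d: pseudo-normal cancels to zero; dropped", i)
            continue
        direction = raw / norm
        if float(direction @ (pos[i] - centroid)) < 0:
            direction = -direction
        vectors.append(
            SurfaceVector(i, pos[i], direction, sphere_radius(node.mean_volume))
        )
    return vectors


def _any_perpendicular(axis: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``axis``."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(axis @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    perp = trial - (trial @ axis) * axis
    return perp / np.linalg.norm(perp)


def _align_antiparallel(v: np.ndarray, u: np.ndarray) -> Rotation:
    """Rotation taking unit vector v to −u (minimal angle, deterministic)."""
    target = -u
    c = float(np.clip(v @ target, -1.0, 1.0))
    if c > 1 - 1e-12:
        return Rotation.identity()
    if c < -1 + 1e-12:  # v ≈ u: rotate π about any perpendicular axis
        return Rotation.from_rotvec(np.pi * _any_perpendicular(v))
    axis = np.cross(v, target)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(np.arccos(c) * axis)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """First principal axis of a point cloud, sign fixed deterministically."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # fix the sign so the axis is reproducible regardless of SVD convention
    key = axis[np.argmax(np.abs(axis))]
    return axis if key >= 0 else -axis


def place_ligand(
    ligand: PartnerStructure,
    u: SurfaceVector,
    v: SurfaceVector,
    spin_deg: float,
) -> np.ndarray:
    """Ligand node coordinates for the pose (u, v, spin).

    Steps: translate the ligand so the tips of u and v coincide; rotate it
    (about the tip) so v opposes u exactly; spin it about the u axis.  The
    spin origin is fixed by aligning the projection of the ligand's first
    principal axis onto the plane ⊥ u with a reference vector derived from
    u alone, so pose coordinates depend only on (u, v, spin).
    """
    pos = ligand.positions
    rot0 = _align_antiparallel(v.direction, u.direction)
    local = rot0.apply(pos - v.tip)  # ligand in tip frame, v opposing u
    axis = u.direction
    ref = _any_perpendicular(axis)
    pa = rot0.apply(_principal_axis(pos))
    proj = pa - (pa @ axis) * axis
    if np.linalg.norm(proj) < 1e-9:
        phase = 0.0
    else:
        proj /= np.linalg.norm(proj)
        # signed angle from ref to proj about axis
        phase = float(np.arctan2(np.cross(ref, proj) @ axis, ref @ proj))
    spin = np.deg2rad(spin_deg) - phase
    rspin = Rotation.from_rotvec(spin * axis)
    return rspin.apply(local) + u.tip


def enumerate_poses(
    receptor: PartnerStructure,
    ligand: PartnerStructure,
    step_deg: float = 5.0,
    receptor_vectors: list[SurfaceVector] | None = None,
    ligand_vectors: list[SurfaceVector] | None = None,
) -> Iterator[ComplexConformation]:
    """Stream all poses: every vector pair × every spin angle.

    Yields |U|·|V|·(360/step) conformations in a fixed deterministic order.
    """
    if 360.0 % step_deg != 0:
        raise ValueError("step_deg must divide 360")
    us = receptor_vectors if receptor_vectors is not None else pseudo_normals(receptor)
    vs = ligand_vectors if ligand_vectors is not None else pseudo_normals(ligand)
    n_spin = int(round(360.0 / step_deg))
    for u in us:
        for v in vs:
            for k in range(n_spin):
                spin = k * step_deg
                coords = place_ligand(ligand, u, v, spin)
                yield ComplexConformation(
                    receptor=receptor,
                    ligand=ligand.with_positions(coords, label="ligand"),
                    transform=(u.node_id, v.node_id, spin),
                    provenance="decoy",
                )


def node_rmsd(a: ComplexConformation, b: ComplexConformation) -> float:
    """RMSD over ligand nodes, receptors held in the common fixed frame."""
    pa = a.ligand_positions
    pb = b.ligand_positions
    if pa.shape != pb.shape:
        raise ValueError("ligand node-count mismatch")
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def _clearly_separated(pose: ComplexConformation, gap: float = 16.0) -> float:
    """Cheap screen: partners whose closest nodes are farther apart than two
    solvent-layer thicknesses cannot share an interface facet."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pose.receptor.positions).query(pose.ligand_positions, k=1)
    return float(d.min()) > gap


def build_decoy_set(
    native: ComplexConformation,
    poses: Iterable[ComplexConformation],
    min_area: float = 400.0,
    min_rmsd: float = 10.0,
    per_native: int = 15,
    seed: int = 0,
) -> list[ComplexConformation]:
    """Filter and sample decoys.

    Keeps poses with Voronoi interface area ≥ ``min_area`` Å² and ligand-node
    RMSD to the native > ``min_rmsd`` Å, then draws ``per_native`` of the
    survivors uniformly without replacement (seeded).  If fewer survive,
    all are returned with a warning.
    """
    survivors: list[ComplexConformation] = []
    for pose in poses:
        rmsd = node_rmsd(pose, native)
        if rmsd <= min_rmsd:
            continue
        if _clearly_separated(pose):
            continue  # no Voronoi interface can survive the solvent layer
        if interface_area(tessellate(pose)) < min_area:
            continue
        pose.rmsd_to_native = rmsd
        pose.provenance = "decoy"
        survivors.append(pose)
    if len(survivors) <= per_native:
        if len(survivors) < per_native:
            logger.warning(
                "only %d decoys survived the filters (wanted %d)",
                len(survivors), per_native,
            )
        return survivors
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(survivors), size=per_native, replace=False)
    return [survivors[i] for i in sorted(idx)]
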