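"""Geometric classification of docking poses.

The catalytically productive arrangement is taken to be a substrate hydroxyl
oxygen lying close to the midpoint of the coenzyme's glycosidic C-O bond (the
bond that links glucuronic acid to UDP in UDP-glucuronic acid). The default
distance cutoff is 3.8 A: a hydrogen-bond distance of 3.2 A plus a 0.6 A
docking-placement tolerance. The heavy-atom (oxygen) position is used for the
distance, so classification does not depend on whether a pose file carries
hydrogens.

A coenzyme pose is in the "correct binding mode" when it contacts a quorum of
the known UDPGA-binding residues (S38, H173, G308, L355, S375, H376, G377)
within the same cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.spatial.distance import cdist

from .errors import GeometryError
from .structures import Pose, PoseSet, ReceptorStructure

__all__ = [
    "HBOND_DISTANCE_A",
    "DOCKING_TOLERANCE_A",
    "default_orientation_cutoff",
    "BindingSiteSpec",
    "GlycosidicReference",
    "UDPGA_SITE_RESIDUES",
    "infer_connectivity",
    "neighbor_map",
    "find_hydroxyl_oxygens",
    "locate_glycosidic_midpoint",
    "min_hydroxyl_distance",
    "classify_hydroxyl_orientation",
    "count_orientations",
    "classify_udpga_binding",
]

#: Hydrogen-bond donor-acceptor distance, Angstroms.
HBOND_DISTANCE_A = 3.2
#: Empirical docking placement error, Angstroms.
DOCKING_TOLERANCE_A = 0.6


def default_orientation_cutoff() -> float:
    """Classification cutoff in Angstroms: H-bond reach plus docking error."""
    return HBOND_DISTANCE_A + DOCKING_TOLERANCE_A


#: Reported UDPGA-binding residues of UGT1A1 (author numbering).
UDPGA_SITE_RESIDUES: tuple[tuple[int, str], ...] = (
    (38, "SER"),
    (173, "HIS"),
    (308, "GLY"),
    (355, "LEU"),
    (375, "SER"),
    (376, "HIS"),
    (377, "GLY"),
)

# Single-bond covalent radii in Angstroms (Cordero et al. consensus values).
COVALENT_RADII_A: dict[str, float] = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Br": 1.20,
    "I": 1.39,
    "Se": 1.20,
}

#: Bond-detection scale applied to the sum of covalent radii.
BOND_SCALE = 1.2


@dataclass
class BindingSiteSpec:
    """Residues defining the coenzyme site and the contact rule.

    ``min_contacts`` of the listed residues must each have a heavy-atom pair
    with the ligand within ``contact_cutoff`` Angstroms for a pose to count
    as the correct binding mode.
    """

    residues: tuple[tuple[int, str], ...] = UDPGA_SITE_RESIDUES
    contact_cutoff: float = 3.8
    min_contacts: int = 5

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if not (1 <= self.min_contacts <= len(self.residues)):
            raise ValueError(
                "min_contacts must be between 1 and the number of residues"
            )


@dataclass
class GlycosidicReference:
    """The glycosidic C-O bond of the coenzyme and its midpoint (Angstroms)."""

    carbon_index: int
    oxygen_index: int
    midpoint: np.ndarray

    def __post_init__(self) -> None:
        self.midpoint = np.asarray(self.midpoint, dtype=float)
        if self.midpoint.shape != (3,) or not np.all(np.isfinite(self.midpoint)):
            raise ValueError("midpoint must be a finite 3-vector")


def infer_connectivity(
    pose: Pose, scale: float = BOND_SCALE
) -> list[tuple[int, int]]:
    """Bonds by the covalent-radius rule.

    Atoms i and j are bonded iff ``d(i, j) <= scale * (r_i + r_j)`` with
    single-bond covalent radii. Explicit bond records on the pose, when
    present, take precedence and are returned unchanged.

    Raises
    ------
    GeometryError
        If an element symbol has no tabulated covalent radius.
    """
    if pose.bonds:
        return sorted((min(i, j), max(i, j)) for i, j in pose.bonds)
    unknown = sorted({e for e in pose.elements if e not in COVALENT_RADII_A})
    if unknown:
        raise GeometryError(
            f"unknown element symbol(s) for connectivity: {', '.join(unknown)}"
        )
    radii = np.array([COVALENT_RADII_A[e] for e in pose.elements])
    coords = pose.coords
    dist = cdist(coords, coords)
    limit = scale * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero((dist <= limit) & (dist > 1e-6))
    return sorted({(min(i, j), max(i, j)) for i, j in zip(ii.tolist(), jj.tolist())})


def neighbor_map(pose: Pose, bonds: list[tuple[int, int]] | None = None) -> list[list[int]]:
    """Adjacency lists from explicit or inferred bonds."""
    if bonds is None:
        bonds = infer_connectivity(pose)
    nbrs: list[list[int]] = [[] for _ in pose.atoms]
    for i, j in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    return nbrs


def find_hydroxyl_oxygens(
    pose: Pose, bonds: list[tuple[int, int]] | None = None
) -> list[int]:
    """Indices of conjugatable hydroxyl oxygens (alcohol, phenol, enol,
    carboxylic O-H).

    A hydroxyl oxygen is bonded to exactly one carbon and no other heavy
    atom. When the molecule carries hydrogens the oxygen must additionally
    bear exactly one of them, which distinguishes an O-H from a carbonyl or
    amide oxygen; in hydrogen-free files that distinction is not available
    and any terminal one-carbon oxygen qualifies.
    """
    nbrs = neighbor_map(pose, bonds)
    elements = pose.elements
    has_hydrogens = "H" in elements
    hits: list[int] = []
    for i, elem in enumerate(elements):
        if elem != "O":
            continue
        carbon = [j for j in nbrs[i] if elements[j] == "C"]
        hydrogen = [j for j in nbrs[i] if elements[j] == "H"]
        other_heavy = [
            j for j in nbrs[i] if elements[j] not in ("C", "H")
        ]
        if len(carbon) != 1 or other_heavy or len(hydrogen) > 1:
            continue
        if has_hydrogens and len(hydrogen) != 1:
            continue
        hits.append(i)
    return hits


def locate_glycosidic_midpoint(udpga_pose: Pose) -> GlycosidicReference:
    """Locate the glycosidic C-O bond of a UDP-glucuronic acid pose.

    The bridging oxygen is bonded to both a phosphorus and a carbon, and that
    carbon (the anomeric carbon of the glucuronate ring) carries a further
    oxygen neighbor (its ring oxygen). This excludes the ribose C5'-O5'-P
    linkage, whose carbon has no second oxygen.

    Raises
    ------
    GeometryError
        If zero or more than one bridging oxygen matches (the message states
        the count).
    """
    nbrs = neighbor_map(udpga_pose)
    elements = udpga_pose.elements
    candidates: list[tuple[int, int]] = []
    for i, elem in enumerate(elements):
        if elem != "O":
            continue
        phos = [j for j in nbrs[i] if elements[j] == "P"]
        carbons = [j for j in nbrs[i] if elements[j] == "C"]
        if not phos or not carbons:
            continue
        for c in carbons:
            ring_oxygens = [
                j for j in nbrs[c] if j != i and elements[j] == "O"
            ]
            if ring_oxygens:
                candidates.append((c, i))
                break
    if len(candidates) != 1:
        raise GeometryError(
            f"expected exactly 1 glycosidic bridging oxygen, found "
            f"{len(candidates)}"
        )
    carbon, oxygen = candidates[0]
    midpoint = 0.5 * (
        udpga_pose.atoms[carbon].position + udpga_pose.atoms[oxygen].position
    )
    return GlycosidicReference(
        carbon_index=carbon, oxygen_index=oxygen, midpoint=midpoint
    )


def min_hydroxyl_distance(
    substrate_pose: Pose,
    reference: GlycosidicReference,
    bonds: list[tuple[int, int]] | None = None,
) -> float:
    """Smallest hydroxyl-oxygen-to-midpoint distance, Angstroms.

    Raises
    ------
    GeometryError
        If the substrate has no conjugatable hydroxyl.
    """
    oxygens = find_hydroxyl_oxygens(substrate_pose, bonds)
    if not oxygens:
        raise GeometryError("substrate has no conjugatable hydroxyl")
    positions = np.array([substrate_pose.atoms[i].position for i in oxygens])
    return float(np.min(np.linalg.norm(positions - reference.midpoint, axis=1)))


def classify_hydroxyl_orientation(
    substrate_pose: Pose,
    reference: GlycosidicReference,
    cutoff: float = 3.8,
    bonds: list[tuple[int, int]] | None = None,
) -> bool:
    """True iff some hydroxyl oxygen lies within ``cutoff`` (inclusive) of
    the glycosidic midpoint. Hydrogens are never the distance atom."""
    return min_hydroxyl_distance(substrate_pose, reference, bonds) <= cutoff


def count_orientations(
    pose_set: PoseSet,
    reference: GlycosidicReference,
    cutoff: float = 3.8,
) -> tuple[int, int]:
    """Count hydroxyl-oriented poses: returns ``(S_DH, S_DT)``.

    ``S_DT`` is the total pose count; ``S_DH`` the number of poses whose
    hydroxyl oxygen is within the cutoff of the reference midpoint.
    Connectivity is inferred once (pose 1) and reused, since atom ordering is
    identical across poses of a set.
    """
    bonds = infer_connectivity(pose_set.poses[0])
    s_dh = sum(
        classify_hydroxyl_orientation(pose, reference, cutoff, bonds)
        for pose in pose_set.poses
    )
    return int(s_dh), len(pose_set)


def classify_udpga_binding(
    udpga_pose: Pose,
    receptor: ReceptorStructure,
    site: BindingSiteSpec | None = None,
) -> tuple[bool, list[tuple[int, str]]]:
    """Check a coenzyme pose against the binding-site contact quorum.

    A site residue is contacted when its minimum heavy-atom distance to the
    pose's heavy atoms is within ``site.contact_cutoff``. The pose is the
    correct binding mode when at least ``site.min_contacts`` residues are
    contacted. A residue-name mismatch (e.g. a mutated site residue) warns
    but still counts by residue number; a residue number absent from the
    receptor is an error.

    Returns ``(is_correct, contacted)`` where ``contacted`` lists the
    (residue_number, residue_name) pairs found in contact.
    """
    site = site or BindingSiteSpec()
    ligand_xyz = udpga_pose.heavy_coords()
    contacted: list[tuple[int, str]] = []
    for resnum, expected_name in site.residues:
        keys = receptor.find_residue(resnum)
        if not keys:
            raise GeometryError(
                f"site residue {resnum} ({expected_name}) absent from receptor"
            )
        res_atoms = [a for k in keys for a in receptor.residue_atoms(k)]
        actual_name = res_atoms[0].residue_name
        if expected_name and actual_name != expected_name:
            warnings.warn(
                f"residue {resnum}: expected {expected_name}, found "
                f"{actual_name} (mutant site?)",
                stacklevel=2,
            )
        res_xyz = np.array([a.position for a in res_atoms if a.is_heavy])
        if res_xyz.size == 0 or ligand_xyz.size == 0:
            continue
        if float(np.min(cdist(ligand_xyz, res_xyz))) <= site.contact_cutoff:
            contacted.append((resnum, actual_name))
    return len(contacted) >= site.min_contacts, contacted
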