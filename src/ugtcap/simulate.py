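"""Synthetic pose fixtures and variant panels with known ground truth.

Docking outputs and variant capacity panels for this pipeline are not
redistributable, so every stage is exercised on generated data instead:

* :func:`generate_pose_fixture` emulates a docking campaign — a coenzyme
  pose with a known glycosidic midpoint, a small receptor stub carrying the
  seven coenzyme-site residues, and a multi-MODEL substrate pose file in
  which a controlled fraction of poses has its hydroxyl oxygen planted
  inside the orientation cutoff. The planted label table is the oracle the
  classifier must reproduce exactly.

* :func:`generate_variant_panel` draws a variant panel from the sigmoid
  capacity model itself (known sigma, gamma, mu, beta, genotypes) with
  additive Gaussian noise truncated at zero, emulating the statistical
  structure the fitting step assumes.

Substrate templates are minimal chemically plausible fragments (a phenol,
a para-diol, a propane-diol, an acetic acid), not real conformers: the
classifier needs only connectivity and a hydroxyl, and small templates keep
the fixtures readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GlycosidicReference, default_orientation_cutoff
from .model import (
    DockingSummary,
    ModelParams,
    Panel,
    VariantRecord,
    kappa,
    substrate_contribution,
)
from .structures import (
    Atom,
    Pose,
    PoseSet,
    ReceptorStructure,
    write_poses,
    write_receptor,
)

__all__ = [
    "PoseFixtureSpec",
    "PanelSpec",
    "SUBSTRATE_TEMPLATES",
    "make_udpga_pose",
    "make_receptor_stub",
    "generate_pose_fixture",
    "generate_variant_panel",
]


def _hexagon(radius: float = 1.39) -> np.ndarray:
    angles = np.arange(6) * np.pi / 3
    return np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(6)], axis=1
    )


def _phenol_template() -> tuple[list[str], np.ndarray, list[int]]:
    """Phenol ring with a para acetamide arm (acetaminophen-like)."""
    ring = _hexagon()
    coords = [*ring]
    elements = ["C"] * 6
    # phenolic oxygen on ring atom 0, pointing outward
    o_idx = len(coords)
    coords.append(ring[0] * (1 + 1.36 / 1.39))
    elements.append("O")
    coords.append(coords[o_idx] + np.array([0.0, 0.0, 0.97]))
    elements.append("H")
    # amide arm on the para carbon (ring atom 3): N-C(=O)-C
    n_pos = ring[3] * (1 + 1.40 / 1.39)
    coords.append(n_pos)
    elements.append("N")
    c_pos = n_pos + np.array([-1.35, 0.0, 0.0]) * np.sign(n_pos[0] or -1.0)
    coords.append(c_pos)
    elements.append("C")
    coords.append(c_pos + np.array([0.0, 1.23, 0.0]))
    elements.append("O")
    coords.append(c_pos + np.array([0.0, -0.75, 1.30]))
    elements.append("C")
    return elements, np.array(coords), [o_idx]


def _paradiol_template() -> tuple[list[str], np.ndarray, list[int]]:
    """Aromatic ring with hydroxyls at both para positions (estradiol-like
    in its two-hydroxyl topology)."""
    ring = _hexagon()
    coords = [*ring]
    elements = ["C"] * 6
    oxy = []
    for ring_idx in (0, 3):
        oxy.append(len(coords))
        coords.append(ring[ring_idx] * (1 + 1.36 / 1.39))
        elements.append("O")
        coords.append(coords[-1] + np.array([0.0, 0.0, 0.97]))
        elements.append("H")
    return elements, np.array(coords), oxy


def _diol_template() -> tuple[list[str], np.ndarray, list[int]]:
    """1,3-propanediol-like chain."""
    coords = [
        np.array([0.0, 0.0, 0.0]),
        np.array([1.52, 0.0, 0.0]),
        np.array([2.28, 1.32, 0.0]),
    ]
    elements = ["C", "C", "C"]
    oxy = [len(coords)]
    coords.append(coords[0] + np.array([-0.8, 1.17, 0.0]))
    elements.append("O")
    coords.append(coords[-1] + np.array([0.0, 0.0, 0.97]))
    elements.append("H")
    oxy.append(len(coords))
    coords.append(coords[2] + np.array([0.8, 1.17, 0.0]))
    elements.append("O")
    coords.append(coords[-1] + np.array([0.0, 0.0, 0.97]))
    elements.append("H")
    return elements, np.array(coords), oxy


def _carboxyl_template() -> tuple[list[str], np.ndarray, list[int]]:
    """Acetic-acid fragment; the carboxylic O-H is the conjugatable group."""
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([1.50, 0.0, 0.0])
    o_dbl = c2 + np.array([0.65, 1.04, 0.0])
    o_h = c2 + np.array([0.65, -1.15, 0.0])
    h = o_h + np.array([0.0, 0.0, 0.97])
    return (
        ["C", "C", "O", "O", "H"],
        np.array([c1, c2, o_dbl, o_h, h]),
        [3],
    )


#: template name -> (elements, coordinates, hydroxyl-oxygen indices)
SUBSTRATE_TEMPLATES = {
    "aap-like": _phenol_template,
    "e2-like": _paradiol_template,
    "diol-like": _diol_template,
    "carboxyl-like": _carboxyl_template,
}


@dataclass
class PoseFixtureSpec:
    """Controls for a synthetic docking campaign.

    ``inside_range``/``outside_range`` are the distance bands (Angstroms,
    hydroxyl oxygen to glycosidic midpoint) from which oriented and
    non-oriented poses are drawn; they must sit strictly below and above the
    cutoff so rounding to file precision cannot flip a label.
    """

    n_poses: int = 100
    frac_oriented: float = 0.3
    cutoff: float = field(default_factory=default_orientation_cutoff)
    inside_range: tuple[float, float] = (2.4, 3.6)
    outside_range: tuple[float, float] = (4.2, 9.0)
    substrate_template: str = "aap-like"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_oriented <= 1.0:
            raise ValueError("frac_oriented must lie in [0, 1]")
        if self.substrate_template not in SUBSTRATE_TEMPLATES:
            raise ValueError(
                f"unknown substrate template {self.substrate_template!r}"
            )
        if not (self.inside_range[0] < self.inside_range[1] <= self.cutoff - 0.05):
            raise ValueError("inside_range must sit below the cutoff")
        if not (self.cutoff + 0.05 <= self.outside_range[0] < self.outside_range[1]):
            raise ValueError("outside_range must sit above the cutoff")


def _atom(serial, name, element, pos, resname="LIG", resnum=1, chain="A"):
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        residue_number=resnum,
        chain=chain,
        position=np.asarray(pos, float),
    )


def make_udpga_pose() -> tuple[Pose, GlycosidicReference]:
    """A minimal UDP-glucuronate-like fragment with one glycosidic bridge.

    The anomeric carbon sits at the origin and the bridging oxygen at
    (1.4, 0, 0), so the glycosidic midpoint is exactly (0.7, 0, 0).
    """
    c1 = np.array([0.0, 0.0, 0.0])
    o_bridge = np.array([1.4, 0.0, 0.0])
    p = np.array([2.3, 1.2, 0.0])  # ~1.5 A from the bridging oxygen
    ring_o = np.array([-0.55, 1.32, 0.0])
    c5 = np.array([-1.95, 1.1, 0.0])
    c2 = np.array([-0.7, -1.25, 0.0])
    op1 = p + np.array([0.0, 1.45, 0.6])
    op2 = p + np.array([1.2, 0.8, -0.6])
    spec = [
        ("C1", "C", c1),
        ("O1", "O", o_bridge),
        ("P", "P", p),
        ("O5", "O", ring_o),
        ("C5", "C", c5),
        ("C2", "C", c2),
        ("O1P", "O", op1),
        ("O2P", "O", op2),
    ]
    atoms = [
        _atom(i + 1, name, elem, pos, resname="UDP")
        for i, (name, elem, pos) in enumerate(spec)
    ]
    pose = Pose(atoms=atoms, pose_index=1)
    reference = GlycosidicReference(
        carbon_index=0, oxygen_index=1, midpoint=0.5 * (c1 + o_bridge)
    )
    return pose, reference


_SITE = (
    (38, "SER"),
    (173, "HIS"),
    (308, "GLY"),
    (355, "LEU"),
    (375, "SER"),
    (376, "HIS"),
    (377, "GLY"),
)


def make_receptor_stub(
    around: np.ndarray | None = None, contact_distance: float = 3.0
) -> ReceptorStructure:
    """Seven coenzyme-site residues (5 atoms each) ringed around a point.

    Each residue's CA is placed ``contact_distance`` Angstroms from
    ``around`` (default: the synthetic coenzyme's glycosidic midpoint) in a
    distinct direction, so a coenzyme pose at that point contacts all seven.
    """
    if around is None:
        around = np.array([0.7, 0.0, 0.0])
    golden = np.pi * (3.0 - np.sqrt(5.0))
    atoms: list[Atom] = []
    serial = 1
    for k, (resnum, resname) in enumerate(_SITE):
        z = 1.0 - 2.0 * (k + 0.5) / len(_SITE)
        r = np.sqrt(max(0.0, 1.0 - z * z))
        theta = golden * k
        u = np.array([r * np.cos(theta), r * np.sin(theta), z])
        ca = around + contact_distance * u
        offsets = {
            "N": np.array([1.45, 0.0, 0.0]),
            "CA": np.zeros(3),
            "C": np.array([-0.9, 1.2, 0.0]),
            "O": np.array([-0.9, 2.43, 0.0]),
            "CB": np.array([0.4, -1.0, 1.1]),
        }
        for name, off in offsets.items():
            # push side-chain/backbone atoms outward so only CA faces the site
            pos = ca + off + u * np.linalg.norm(off) * 0.5
            atoms.append(
                _atom(serial, name, name[0], pos, resname=resname,
                      resnum=resnum, chain="A")
            )
            serial += 1
    return ReceptorStructure(atoms=atoms)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _place_substrate(
    elements: list[str],
    template: np.ndarray,
    oxy_indices: list[int],
    midpoint: np.ndarray,
    distance: float,
    inside: bool,
    spec: PoseFixtureSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rigidly place the template so its min hydroxyl-midpoint distance
    falls on the intended side of the cutoff, at file (3-decimal) precision."""
    lo, hi = spec.inside_range if inside else spec.outside_range
    primary = oxy_indices[0]
    for _ in range(200):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rot = _random_rotation(rng)
        coords = (template - template[primary]) @ rot.T
        coords += midpoint + distance * u
        quantized = np.round(coords, 3)
        dists = np.linalg.norm(quantized[oxy_indices] - midpoint, axis=1)
        d_min = float(np.min(dists))
        if inside and lo <= d_min <= hi:
            return quantized
        if not inside and lo <= d_min <= hi and np.all(dists >= lo):
            return quantized
    raise RuntimeError(
        "could not place substrate pose within the requested distance band"
    )


def generate_pose_fixture(
    spec: PoseFixtureSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, Path] | None, pd.DataFrame, PoseSet, GlycosidicReference]:
    """Generate a synthetic docking campaign with planted orientation labels.

    Returns the written file paths (``None`` when ``out_dir`` is not given),
    the label table (pose_index, planted_distance_A, oriented), the in-memory
    substrate :class:`PoseSet`, and the coenzyme's glycosidic reference.
    Exactly ``round(n_poses * frac_oriented)`` poses are planted inside the
    cutoff; the same seed reproduces byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    udpga_pose, reference = make_udpga_pose()
    receptor = make_receptor_stub(around=reference.midpoint)
    elements, template, oxy_indices = SUBSTRATE_TEMPLATES[
        spec.substrate_template
    ]()
    n_inside = int(round(spec.n_poses * spec.frac_oriented))
    labels = np.zeros(spec.n_poses, dtype=bool)
    labels[rng.permutation(spec.n_poses)[:n_inside]] = True
    poses: list[Pose] = []
    records = []
    for k in range(spec.n_poses):
        inside = bool(labels[k])
        lo, hi = spec.inside_range if inside else spec.outside_range
        d = float(rng.uniform(lo, hi))
        coords = _place_substrate(
            elements, template, oxy_indices, reference.midpoint, d, inside,
            spec, rng,
        )
        atoms = [
            _atom(i + 1, f"{e}{i + 1}", e, coords[i], resname="SUB")
            for i, e in enumerate(elements)
        ]
        poses.append(Pose(atoms=atoms, pose_index=k + 1))
        achieved = float(
            np.min(np.linalg.norm(coords[oxy_indices] - reference.midpoint, axis=1))
        )
        records.append(
            {
                "pose_index": k + 1,
                "planted_distance_A": round(achieved, 3),
                "oriented": int(inside),
            }
        )
    pose_set = PoseSet(ligand_id=spec.substrate_template, poses=poses)
    label_table = pd.DataFrame.from_records(records)
    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "receptor": out_dir / "receptor.pdb",
            "udpga_poses": out_dir / "udpga_poses.pdbqt",
            "substrate_poses": out_dir / "substrate_poses.pdbqt",
            "labels": out_dir / "labels.csv",
        }
        write_receptor(paths["receptor"], receptor)
        write_poses(paths["udpga_poses"], PoseSet(ligand_id="UDPGA", poses=[udpga_pose]))
        write_poses(paths["substrate_poses"], pose_set)
        label_table.to_csv(paths["labels"], index=False)
    return paths, label_table, pose_set, reference


@dataclass
class PanelSpec:
    """Controls for a synthetic variant panel drawn from the capacity model.

    Capacities are computed from the sigmoid model at each variant's realised
    oriented fraction, scaled by the genotype factor, with additive Gaussian
    noise (sd in capacity units, truncated at zero); capacities below
    ``nd_threshold`` are marked not-detected. ``noise_sd`` defaults to zero;
    panels emulating assay noise conventionally use 5% of the wild-type
    capacity.
    """

    n_variants: int = 20
    S_DT: int = 100
    true_params: ModelParams = field(
        default_factory=lambda: ModelParams(
            sigma=50.0, gamma=8.0, mu=0.4, epsilon=0.0, beta=2.5
        )
    )
    fraction_grid: tuple[float, float] = (0.05, 0.95)
    binomial_counts: bool = False
    noise_sd: float = 0.0
    nd_threshold: float = 0.0
    genotypes: dict[str, str] = field(default_factory=dict)
    ligand: str = "synthetic-substrate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.fraction_grid
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("fraction_grid must lie within [0, 1]")


def generate_variant_panel(
    spec: PanelSpec,
) -> tuple[Panel, pd.DataFrame]:
    """Draw a variant panel whose capacities follow the sigmoid model.

    The wild-type member has ``S_DH = round(S_DT / beta)`` so the generating
    ``beta`` is consistent with its definition, and its noise-free capacity
    anchors the scale. Returns the :class:`Panel` and a truth table with the
    generating fractions and noise-free capacities per variant.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.true_params
    s_dh_wild = int(round(spec.S_DT / p.beta))
    if s_dh_wild <= 0:
        raise ValueError("S_DT / beta rounds to zero oriented wild poses")
    wild_summary = DockingSummary(
        variant="wild-type",
        ligand=spec.ligand,
        S_DT=spec.S_DT,
        S_DH=s_dh_wild,
        udpga_correct_count=spec.S_DT,
    )
    # beta as realised from the integer wild counts (equals p.beta when
    # S_DT / beta is an integer)
    beta_real = spec.S_DT / s_dh_wild
    params_real = ModelParams(
        sigma=p.sigma, gamma=p.gamma, mu=p.mu, epsilon=p.epsilon, beta=beta_real
    )
    fractions = np.linspace(
        spec.fraction_grid[0], spec.fraction_grid[1], spec.n_variants
    )
    members: list[tuple[DockingSummary, VariantRecord]] = []
    rows = []

    def emit(name: str, target_fraction: float) -> None:
        if spec.binomial_counts and name != "wild-type":
            s_dh = int(rng.binomial(spec.S_DT, target_fraction))
        else:
            s_dh = int(round(target_fraction * spec.S_DT))
        summary = DockingSummary(
            variant=name,
            ligand=spec.ligand,
            S_DT=spec.S_DT,
            S_DH=s_dh,
            udpga_correct_count=spec.S_DT,
        )
        genotype = spec.genotypes.get(name, "wild/wild")
        k = kappa(genotype)
        clean = p.sigma * k * substrate_contribution(summary, params_real) + p.epsilon
        noisy = clean
        if spec.noise_sd > 0:
            noisy = max(0.0, clean + float(rng.normal(0.0, spec.noise_sd)))
        v_c: float | None = noisy
        if spec.nd_threshold > 0 and noisy < spec.nd_threshold:
            v_c = None
        members.append(
            (summary, VariantRecord(variant=name, genotype=genotype, v_c=v_c))
        )
        rows.append(
            {
                "variant": name,
                "genotype": genotype,
                "fraction": summary.fraction,
                "S_DH": s_dh,
                "clean_capacity": clean,
                "observed_capacity": noisy if v_c is not None else np.nan,
                "nd": v_c is None,
            }
        )

    emit("wild-type", s_dh_wild / spec.S_DT)
    for i, f in enumerate(fractions, start=1):
        emit(f"V{i:02d}", float(f))
    panel = Panel(ligand=spec.ligand, wild_summary=wild_summary, members=members)
    truth = pd.DataFrame.from_records(rows)
    return panel, truth
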