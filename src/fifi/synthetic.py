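"""Deterministic synthetic pockets, docked poses, and screening sets.

Everything downstream — tagging, fingerprints, screening workflows,
attribution — is exercised on complexes built here, so the generators
are first-class, tested code.  Residues are minimal (backbone N/CA/C/O
plus one or two side-chain pseudo-atoms with correct element types and
PDB atom names): enough to drive proximity tagging and interaction
typing, with no claim of physical realism.  All geometry is planted at
controlled atom–residue distances and re-verified post hoc by brute
force, and every generator is a pure function of its seed.

The screening-set generator plants a recoverable signal: active
compounds carry a carboxylate group docked within the proximity
threshold of a cationic "signal" residue (a lysine); inactive
compounds either lack the group or are posed far from that residue.
With zero noise a single FIFI-US bit — the (signal residue,
carboxylate-oxygen environment) pair — separates the classes by
construction.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .core import FifiConfig, featurize
from .screening import ScreeningSet
from .structure_io import (
    LigandPose,
    PocketRoster,
    ProteinStructure,
    define_roster,
    read_protein,
)

# Minimal residue templates: (atom name, element, local xyz).  The
# contact atom (side-chain tip, or CA for glycine) sits at the local
# origin; everything else lies at y <= -0.9 so a ligand atom placed on
# the +y side is nearest to the contact atom.
_RESIDUE_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [
        ("N", "N", (-1.2, -2.4, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.2, -0.9, 0.0)),
        ("O", "O", (1.3, -2.1, 0.0)),
    ],
    "ALA": [
        ("N", "N", (-1.2, -3.3, 0.0)),
        ("CA", "C", (0.0, -1.5, 0.0)),
        ("C", "C", (1.2, -3.3, 0.0)),
        ("O", "O", (1.3, -4.5, 0.0)),
        ("CB", "C", (0.0, 0.0, 0.0)),
    ],
    "SER": [
        ("N", "N", (-1.2, -4.2, 0.0)),
        ("CA", "C", (0.0, -2.4, 0.0)),
        ("C", "C", (1.2, -4.2, 0.0)),
        ("O", "O", (1.3, -5.4, 0.0)),
        ("CB", "C", (0.0, -1.0, 0.4)),
        ("OG", "O", (0.0, 0.0, 0.0)),
    ],
    "LYS": [
        ("N", "N", (-1.2, -5.2, 0.0)),
        ("CA", "C", (0.0, -3.4, 0.0)),
        ("C", "C", (1.2, -5.2, 0.0)),
        ("O", "O", (1.3, -6.4, 0.0)),
        ("CB", "C", (0.0, -2.0, 0.4)),
        ("NZ", "N", (0.0, 0.0, 0.0)),
    ],
    "ASP": [
        ("N", "N", (-1.2, -4.6, 0.0)),
        ("CA", "C", (0.0, -2.8, 0.0)),
        ("C", "C", (1.2, -4.6, 0.0)),
        ("O", "O", (1.3, -5.8, 0.0)),
        ("CB", "C", (0.0, -1.6, 0.4)),
        ("OD1", "O", (0.0, 0.0, 0.0)),
        ("OD2", "O", (-1.1, -0.9, 0.6)),
    ],
    "PHE": [
        ("N", "N", (-1.2, -4.2, 0.0)),
        ("CA", "C", (0.0, -2.4, 0.0)),
        ("C", "C", (1.2, -4.2, 0.0)),
        ("O", "O", (1.3, -5.4, 0.0)),
        ("CB", "C", (0.0, -1.2, 0.4)),
        ("CG", "C", (0.0, 0.0, 0.0)),
    ],
    "HIS": [
        ("N", "N", (-1.2, -4.2, 0.0)),
        ("CA", "C", (0.0, -2.4, 0.0)),
        ("C", "C", (1.2, -4.2, 0.0)),
        ("O", "O", (1.3, -5.4, 0.0)),
        ("CB", "C", (0.0, -1.2, 0.4)),
        ("NE2", "N", (0.0, 0.0, 0.0)),
    ],
}

#: atom controlling the planted distance per residue type
_CONTACT_ATOM = {
    "GLY": "CA", "ALA": "CB", "SER": "OG", "LYS": "NZ",
    "ASP": "OD1", "PHE": "CG", "HIS": "NE2",
}

# SMILES templates; actives carry a carboxylate, decoys do not.
ACTIVE_TEMPLATES = (
    "CC(=O)[O-]",
    "CCC(=O)[O-]",
    "CC(C)C(=O)[O-]",
    "OCC(=O)[O-]",
    "c1ccccc1C(=O)[O-]",
    "CCCC(=O)[O-]",
)
DECOY_TEMPLATES = (
    "CCO",
    "CCN",
    "CCOC",
    "CC(C)O",
    "c1ccccc1",
    "c1ccncc1",
    "CCS",
    "COC",
    "CC(C)C",
    "OCCO",
)


@dataclass
class PlantedContact:
    """One ligand atom placed at an exact distance from a residue."""

    compound_id: str
    smiles: str
    planted_atom: int  # heavy-atom index in the RDKit canonical order
    residue_index: int
    distance: float  # Å from the residue's contact atom


@dataclass
class FixtureSpec:
    """Recipe for a synthetic pocket plus docked poses."""

    residue_types: Sequence[str] = ("SER", "LYS", "ASP")
    spacing: float = 12.0  # Å between residue contact atoms along x
    contacts: Sequence[PlantedContact] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for rt in self.residue_types:
            if rt not in _RESIDUE_TEMPLATES:
                raise ValueError(f"no template for residue type {rt!r}")
        for c in self.contacts:
            if not 0 <= c.residue_index < len(self.residue_types):
                raise ValueError("planted contact references unknown residue")
            if c.distance <= 0:
                raise ValueError("planted distance must be positive")


def _pocket_pdb_text(residue_types: Sequence[str], spacing: float) -> str:
    """PDB text for a row of minimal residues along the x axis."""
    lines = []
    serial = 1
    for i, rt in enumerate(residue_types):
        anchor = np.array([spacing * i, 0.0, 0.0])
        for name, element, offset in _RESIDUE_TEMPLATES[rt]:
            x, y, z = anchor + np.array(offset)
            padded = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {padded:<4s} {rt:<3s} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def residue_contact_point(spec: FixtureSpec, residue_index: int) -> np.ndarray:
    """Position of a residue's contact atom in the pocket frame."""
    rt = spec.residue_types[residue_index]
    offset = dict(
        (name, np.array(xyz))
        for name, _el, xyz in _RESIDUE_TEMPLATES[rt]
    )[_CONTACT_ATOM[rt]]
    return np.array([spec.spacing * residue_index, 0.0, 0.0]) + offset


def _embed(smiles: str, seed: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable template {smiles!r}")
    molh = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(molh, randomSeed=seed) != 0:
        raise ValueError(f"embedding failed for {smiles!r}")
    return Chem.RemoveHs(molh)


def _rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _place_pose(
    mol: Chem.Mol,
    planted_atom: int,
    target: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> Chem.Mol:
    """Rigidly move a conformer so ``planted_atom`` sits exactly at
    ``target`` (optionally randomly rotated about it first)."""
    mol = Chem.Mol(mol)
    conf = mol.GetConformer(0)
    xyz = np.array(conf.GetPositions())
    if rng is not None:
        pivot = xyz[planted_atom].copy()
        xyz = (xyz - pivot) @ _rotation(rng).T + pivot
    xyz = xyz + (target - xyz[planted_atom])
    for i, row in enumerate(xyz):
        conf.SetAtomPosition(i, tuple(float(v) for v in row))
    return mol


def make_complex(spec: FixtureSpec) -> tuple[str, list[LigandPose], str]:
    """Build the pocket and the planted poses of a fixture spec.

    Returns ``(pdb_text, poses, sdf_text)``.  Each planted atom is
    placed on the +y side of its residue's contact atom, so the planted
    distance is exactly the minimal atom–residue distance for that
    atom; placements are verified to ±0.01 Å and the function raises if
    the geometry could not be realized.
    """
    pdb_text = _pocket_pdb_text(spec.residue_types, spec.spacing)
    poses: list[LigandPose] = []
    for k, contact in enumerate(spec.contacts):
        mol = _embed(contact.smiles, seed=spec.seed * 1009 + k)
        if not 0 <= contact.planted_atom < mol.GetNumAtoms():
            raise ValueError("planted atom index outside molecule")
        target = residue_contact_point(spec, contact.residue_index) + np.array(
            [0.0, contact.distance, 0.0]
        )
        placed = _place_pose(mol, contact.planted_atom, target)
        pose = LigandPose(contact.compound_id, placed)
        achieved = _min_distance_to_residue(
            pose.coords[contact.planted_atom], spec, contact.residue_index
        )
        if abs(achieved - contact.distance) > 0.01:
            raise ValueError(
                f"unrealizable geometry for {contact.compound_id}: "
                f"wanted {contact.distance:.3f} Å, got {achieved:.3f} Å"
            )
        poses.append(pose)
    return pdb_text, poses, poses_to_sdf(poses)


def _min_distance_to_residue(
    point: np.ndarray, spec: FixtureSpec, residue_index: int
) -> float:
    rt = spec.residue_types[residue_index]
    anchor = np.array([spec.spacing * residue_index, 0.0, 0.0])
    coords = np.array([anchor + np.array(xyz) for _n, _e, xyz in _RESIDUE_TEMPLATES[rt]])
    return float(np.linalg.norm(coords - point, axis=1).min())


def poses_to_sdf(poses: Sequence[LigandPose]) -> str:
    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    for pose in poses:
        mol = Chem.Mol(pose.mol)
        mol.SetProp("_Name", pose.compound_id)
        writer.write(mol)
    writer.close()
    return buf.getvalue()


def structure_from_pdb_text(pdb_text: str) -> ProteinStructure:
    """Round-trip a generated pocket through the PDB reader."""
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(pdb_text)
        path = fh.name
    return read_protein(path)


# ---------------------------------------------------------------------------
# random complexes for oracle tests


def make_random_complex(
    seed: int,
    n_residues: int = 5,
    max_ligand_atoms: int = 50,
) -> tuple[ProteinStructure, PocketRoster, LigandPose]:
    """A random pocket and one randomly placed pose, for brute-force
    distance-oracle comparisons."""
    rng = np.random.default_rng(seed)
    types = list(rng.choice(list(_RESIDUE_TEMPLATES), size=n_residues))
    spec = FixtureSpec(residue_types=types, spacing=float(rng.uniform(6.0, 10.0)), seed=seed)
    pdb_text = _pocket_pdb_text(spec.residue_types, spec.spacing)
    structure = structure_from_pdb_text(pdb_text)

    templates = ACTIVE_TEMPLATES + DECOY_TEMPLATES
    smiles = str(rng.choice(templates))
    mol = _embed(smiles, seed=seed + 7)
    while mol.GetNumAtoms() > max_ligand_atoms:  # pragma: no cover - templates are small
        smiles = str(rng.choice(templates))
        mol = _embed(smiles, seed=seed + 7)
    # drop the pose near a random residue so the roster is never empty
    near = int(rng.integers(0, n_residues))
    direction = rng.normal(size=3)
    direction[1] = abs(direction[1]) + 0.5  # bias toward the open +y side
    direction /= np.linalg.norm(direction)
    center = residue_contact_point(spec, near) + rng.uniform(3.0, 7.0) * direction
    placed = _place_pose(mol, 0, center, rng=rng)
    pose = LigandPose(f"rand_{seed}", placed)
    roster = define_roster(structure, [pose], cutoff=8.0)
    return structure, roster, pose


# ---------------------------------------------------------------------------
# twin-residue fixture: the order-sensitivity contrast


def make_twin_fixture(
    seed: int = 0, separation: float = 30.0
) -> tuple[PocketRoster, LigandPose, LigandPose]:
    """Two identical residues; the same interaction at residue 1 vs 2.

    Pose B is pose A rigidly translated by the residue separation, so
    every ligand-atom/protein-atom distance pattern is identical — only
    the residue *position* in the roster differs.  Order-aware
    fingerprints (FIFI) must change; order-blind ones (the PLEC-style
    fingerprint) must not.
    """
    spec = FixtureSpec(residue_types=("SER", "SER"), spacing=separation, seed=seed)
    mol = _embed("CCO", seed=seed + 11)
    target = residue_contact_point(spec, 0) + np.array([0.0, 3.0, 0.0])
    pose_a = LigandPose("twin_a", _place_pose(mol, 0, target))
    pose_b = pose_a.translated([separation, 0.0, 0.0])
    pose_b.compound_id = "twin_b"
    structure = structure_from_pdb_text(_pocket_pdb_text(spec.residue_types, spec.spacing))
    roster = define_roster(structure, [pose_a, pose_b], cutoff=5.5)
    if len(roster) != 2:
        raise RuntimeError("twin fixture must yield a two-residue roster")
    return roster, pose_a, pose_b


# ---------------------------------------------------------------------------
# labeled screening sets with a planted signal


@dataclass
class ScreeningBundle:
    """A generated screening study: pocket, poses, and featurized sets."""

    roster: PocketRoster
    train: ScreeningSet
    test: ScreeningSet
    train_poses: list[LigandPose]
    test_poses: list[LigandPose]
    vocab: object = None
    config: FifiConfig = field(default_factory=FifiConfig)
    signal_residue: int = 1


def _signal_atom(mol: Chem.Mol) -> int:
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "O" and atom.GetFormalCharge() == -1:
            return atom.GetIdx()
    raise ValueError("template lacks the carboxylate signal group")


def _generate_pose(
    rng: np.random.Generator,
    spec: FixtureSpec,
    compound_id: str,
    active: bool,
    signal_residue: int,
    noise: float,
    threshold: float,
) -> tuple[LigandPose, str]:
    """One labeled pose: actives dock their carboxylate oxygen within
    the threshold of the signal residue; inactives lack the group or
    sit far away."""
    if active:
        smiles = str(rng.choice(ACTIVE_TEMPLATES))
        mol = _embed(smiles, seed=int(rng.integers(1, 2**31 - 1)))
        planted = _signal_atom(mol)
        distance = float(rng.uniform(2.8, threshold - 0.6))
        target = residue_contact_point(spec, signal_residue) + np.array(
            [0.0, distance, 0.0]
        )
    else:
        far_pose = rng.random() < 0.5
        if far_pose:  # carries the group but docked away from the signal residue
            smiles = str(rng.choice(ACTIVE_TEMPLATES))
            mol = _embed(smiles, seed=int(rng.integers(1, 2**31 - 1)))
            planted = _signal_atom(mol)
        else:  # lacks the group entirely
            smiles = str(rng.choice(DECOY_TEMPLATES))
            mol = _embed(smiles, seed=int(rng.integers(1, 2**31 - 1)))
            planted = int(rng.integers(0, mol.GetNumAtoms()))
        other = [
            r for r in range(len(spec.residue_types)) if r != signal_residue
        ]
        residue = int(rng.choice(other))
        distance = float(rng.uniform(2.8, threshold - 0.6))
        target = residue_contact_point(spec, residue) + np.array([0.0, distance, 0.0])
    placed = _place_pose(mol, planted, target, rng=rng)
    pose = LigandPose(compound_id, placed)
    if not active:
        pose = _push_from_residue(pose, spec, signal_residue, threshold)
    if noise > 0:  # positional jitter that must stay inside the tag shell
        jitter = rng.normal(scale=noise, size=3)
        pose = pose.translated(jitter)
        if not active:
            pose = _push_from_residue(pose, spec, signal_residue, threshold)
    return pose, smiles


def _push_from_residue(
    pose: LigandPose, spec: FixtureSpec, residue_index: int, threshold: float
) -> LigandPose:
    """Translate a pose away (+y) until no atom is within the threshold
    of the given residue — keeps inactives out of the signal shell."""
    rt = spec.residue_types[residue_index]
    anchor = np.array([spec.spacing * residue_index, 0.0, 0.0])
    res_xyz = np.array(
        [anchor + np.array(xyz) for _n, _e, xyz in _RESIDUE_TEMPLATES[rt]]
    )
    out = pose
    for _ in range(20):
        d = np.linalg.norm(
            out.coords[:, None, :] - res_xyz[None, :, :], axis=2
        ).min()
        if d > threshold + 0.1:
            return out
        out = out.translated([0.0, 2.0, 0.0])
    raise RuntimeError("could not move pose outside the signal shell")


def make_screening_set(
    n_active: int = 50,
    n_inactive: int = 450,
    n_train_active: int = 40,
    n_train_inactive: int = 120,
    seed: int = 0,
    noise: float = 0.1,
    config: Optional[FifiConfig] = None,
) -> ScreeningBundle:
    """Generate a planted-signal screening study and featurize it with
    FIFI-US (vocabulary fitted on the training poses).

    Docking scores are drawn lower (better) for actives with heavy
    overlap, mimicking an informative but noisy scoring function.
    Deterministic per seed.
    """
    if n_active < 1 or n_inactive < 1:
        raise ValueError("need at least one active and one inactive")
    config = config or FifiConfig()
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        residue_types=("SER", "LYS", "ASP", "PHE"), spacing=14.0, seed=seed
    )
    threshold = config.proximity_threshold
    signal_residue_pos = 1  # the lysine

    def build(n_act: int, n_inact: int, tag: str) -> tuple[list[LigandPose], np.ndarray, list[str], np.ndarray]:
        poses, smiles_list = [], []
        labels = np.array([1] * n_act + [0] * n_inact)
        order = rng.permutation(len(labels))
        labels = labels[order]
        for i, lab in enumerate(labels):
            pose, smi = _generate_pose(
                rng, spec, f"{tag}_{i}", bool(lab), signal_residue_pos, noise, threshold
            )
            poses.append(pose)
            smiles_list.append(smi)
        dock = np.where(
            labels == 1,
            rng.normal(-8.0, 1.5, size=len(labels)),
            rng.normal(-5.5, 1.5, size=len(labels)),
        )
        return poses, labels, smiles_list, dock

    train_poses, train_labels, train_smiles, train_dock = build(
        n_train_active, n_train_inactive, "train"
    )
    test_poses, test_labels, test_smiles, test_dock = build(n_active, n_inactive, "test")

    structure = structure_from_pdb_text(
        _pocket_pdb_text(spec.residue_types, spec.spacing)
    )
    roster = define_roster(structure, train_poses, cutoff=threshold)
    signal_residue = roster.residues.index(("A", signal_residue_pos + 1, "", "LYS"))

    X_train, _, vocab = featurize(
        roster, train_poses, config, mode="us", fit_vocab=True
    )
    X_test, _, _ = featurize(roster, test_poses, config, mode="us", vocab=vocab)

    train = ScreeningSet(
        compound_ids=[p.compound_id for p in train_poses],
        fingerprints=X_train,
        labels=train_labels,
        docking_scores=train_dock,
        role="train",
        structures=train_smiles,
    )
    test = ScreeningSet(
        compound_ids=[p.compound_id for p in test_poses],
        fingerprints=X_test,
        labels=test_labels,
        docking_scores=test_dock,
        role="test",
        structures=test_smiles,
    )
    return ScreeningBundle(
        roster=roster,
        train=train,
        test=test,
        train_poses=train_poses,
        test_poses=test_poses,
        vocab=vocab,
        config=config,
        signal_residue=signal_residue,
    )
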