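"""Protein / ligand-pose input and binding-site roster definition.

Reads protein structures (PDB) with Biopython and docked ligand poses
(SDF) with RDKit, and derives the ordered roster of binding-site
residues that fixes the layout of every residue-blocked fingerprint.

The roster is the backbone of the whole package: fingerprint bit blocks
are laid out in roster order, so the roster must be a deterministic,
strictly ordered function of its inputs.  Residue keys sort by
(chain id, residue number, insertion code); distances use heavy atoms
only and inclusive comparison (d <= cutoff).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from rdkit import Chem
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: (chain id, residue sequence number, insertion code, 3-letter name)
ResidueKey = tuple[str, int, str, str]

DEFAULT_CUTOFF = 5.5  # Å, same threshold as interaction tagging


class EmptyStructureError(ValueError):
    """Raised when a structure file yields no usable protein atoms."""


class EmptyRosterError(ValueError):
    """Raised when no residue lies within the cutoff of any reference pose."""


@dataclass
class ProteinStructure:
    """Heavy-atom protein structure grouped by residue.

    Attributes
    ----------
    elements : list of str
        Element symbol per atom.
    coords : ndarray of shape (n_atoms, 3)
        Cartesian coordinates in Å.
    residue_keys : list of ResidueKey
        Residue key per atom (parallel to ``elements``).
    atom_names : list of str
        PDB atom names (e.g. ``CA``, ``OD1``) per atom.
    """

    elements: list[str]
    coords: np.ndarray
    residue_keys: list[ResidueKey]
    atom_names: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("protein coordinates must be finite")
        if len(self.elements) != len(self.coords) or len(self.elements) != len(
            self.residue_keys
        ):
            raise ValueError("atom arrays must be parallel")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def residues(self) -> list[ResidueKey]:
        """Unique residue keys in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for key in self.residue_keys:
            seen.setdefault(key)
        return list(seen)

    def atoms_of(self, key: ResidueKey) -> np.ndarray:
        """Indices of the atoms belonging to one residue."""
        return np.array(
            [i for i, k in enumerate(self.residue_keys) if k == key], dtype=int
        )


@dataclass
class LigandPose:
    """A docked ligand conformer: molecular graph plus 3D coordinates.

    Wraps an RDKit molecule whose conformer 0 holds the docked pose.
    Hydrogens are stripped on construction; all geometry in the package
    is heavy-atom only because docked hydrogen positions are unreliable.
    """

    compound_id: str
    mol: Chem.Mol

    def __post_init__(self) -> None:
        if self.mol.GetNumAtoms() < 1:
            raise ValueError("pose must have at least one atom")
        if self.mol.GetNumConformers() < 1:
            raise ValueError("pose must carry 3D coordinates")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("pose coordinates must be finite")

    @property
    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates, shape (n_atoms, 3), in Å."""
        conf = self.mol.GetConformer(0)
        return np.array(conf.GetPositions(), dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def translated(self, shift: Sequence[float]) -> "LigandPose":
        """Return a copy rigidly translated by ``shift`` (Å)."""
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer(0)
        s = np.asarray(shift, dtype=float)
        for i in range(mol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (p.x + s[0], p.y + s[1], p.z + s[2]))
        return LigandPose(self.compound_id, mol)

    def transformed(self, rotation: np.ndarray, translation: Sequence[float]) -> "LigandPose":
        """Return a copy under the rigid transform x -> R x + t."""
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer(0)
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new = self.coords @ R.T + t
        for i, row in enumerate(new):
            conf.SetAtomPosition(i, tuple(float(v) for v in row))
        return LigandPose(self.compound_id, mol)


@dataclass
class PocketRoster:
    """Ordered binding-site residues with their heavy-atom coordinates.

    The residue order — strictly increasing by (chain, residue number,
    insertion code) — is the contract every residue-blocked fingerprint
    layout relies on.
    """

    residues: list[ResidueKey]
    residue_coords: list[np.ndarray]
    residue_atom_names: list[list[str]] = field(default_factory=list)
    cutoff: float = DEFAULT_CUTOFF
    ordering: str = "chain-resnum-icode"

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyRosterError("roster must contain at least one residue")
        order_keys = [k[:3] for k in self.residues]
        if sorted(order_keys) != order_keys or len(set(order_keys)) != len(order_keys):
            raise ValueError("roster residues must be strictly ordered and unique")
        self.residue_coords = [np.asarray(c, dtype=float) for c in self.residue_coords]
        if not self.residue_atom_names:
            self.residue_atom_names = [
                [""] * len(c) for c in self.residue_coords
            ]

    def __len__(self) -> int:
        return len(self.residues)

    def index_of(self, key: ResidueKey) -> int:
        return self.residues.index(key)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cutoff": self.cutoff,
            "ordering": self.ordering,
            "residues": [
                {
                    "chain": k[0],
                    "resnum": k[1],
                    "icode": k[2],
                    "resname": k[3],
                    "coords": c.tolist(),
                    "atom_names": names,
                }
                for k, c, names in zip(
                    self.residues, self.residue_coords, self.residue_atom_names
                )
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PocketRoster":
        payload = json.loads(Path(path).read_text())
        residues = [
            (r["chain"], r["resnum"], r["icode"], r["resname"])
            for r in payload["residues"]
        ]
        coords = [np.array(r["coords"], dtype=float) for r in payload["residues"]]
        names = [list(r.get("atom_names", [])) for r in payload["residues"]]
        return cls(
            residues=residues,
            residue_coords=coords,
            residue_atom_names=names,
            cutoff=payload["cutoff"],
            ordering=payload.get("ordering", "chain-resnum-icode"),
        )


def read_protein(
    path: str | Path, include_hetero: bool = False
) -> ProteinStructure:
    """Read heavy atoms of amino-acid residues from a PDB file.

    Waters and hetero groups are excluded unless ``include_hetero``;
    hydrogens are always dropped.  Alternate locations resolve to the
    highest-occupancy copy (Biopython's default selection).
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("protein", str(path))
    except Exception as exc:  # pragma: no cover - parser-specific message
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc

    elements: list[str] = []
    coords: list[np.ndarray] = []
    keys: list[ResidueKey] = []
    atom_names: list[str] = []

    model = next(structure.get_models())  # first model only
    for chain in model:
        for residue in chain:
            hetflag, resnum, icode = residue.id
            if hetflag == "W":
                continue
            standard = is_aa(residue, standard=True)
            if not standard:
                if not include_hetero:
                    continue
                logger.info("including non-standard residue %s", residue.get_resname())
            if hetflag.strip() and not include_hetero and not standard:
                continue
            key: ResidueKey = (
                chain.id,
                int(resnum),
                icode.strip(),
                residue.get_resname().strip(),
            )
            for atom in residue:  # disordered atoms yield best-occupancy child
                element = (atom.element or "").strip().capitalize()
                if element in ("H", "D", ""):
                    continue
                elements.append(element)
                coords.append(np.asarray(atom.get_coord(), dtype=float))
                keys.append(key)
                atom_names.append(atom.get_name().strip())

    if not elements:
        raise EmptyStructureError(f"no amino-acid heavy atoms found in {path}")
    return ProteinStructure(
        elements=elements,
        coords=np.vstack(coords),
        residue_keys=keys,
        atom_names=atom_names,
    )


def read_poses(path: str | Path) -> list[LigandPose]:
    """Read docked ligand poses from an SDF file, input order preserved.

    Records that fail RDKit sanitization are skipped and logged with
    their zero-based record index.  Raises if no record is usable.
    Warns when a record carries no 3D information (flat all-zero z).
    """
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    except OSError as exc:
        raise ValueError(f"no valid ligand records in {path}: {exc}") from exc
    poses: list[LigandPose] = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unparsable SDF record %d in %s", idx, path)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        compound_id = name.strip() or f"mol_{idx}"
        if mol.GetNumConformers() == 0:
            logger.warning("skipping SDF record %d without coordinates", idx)
            continue
        z = np.array(mol.GetConformer(0).GetPositions())[:, 2]
        if mol.GetNumAtoms() > 1 and np.allclose(z, 0.0):
            warnings.warn(
                f"SDF record {idx} ({compound_id}) looks 2D (all-zero z)",
                stacklevel=2,
            )
        poses.append(LigandPose(compound_id, mol))
    if not poses:
        raise ValueError(f"no valid ligand records in {path}")
    return poses


def write_poses(poses: Sequence[LigandPose], path: str | Path) -> None:
    """Write poses to an SDF file (inverse of :func:`read_poses`)."""
    writer = Chem.SDWriter(str(path))
    try:
        for pose in poses:
            mol = Chem.Mol(pose.mol)
            mol.SetProp("_Name", pose.compound_id)
            writer.write(mol)
    finally:
        writer.close()


def define_roster(
    structure: ProteinStructure,
    reference_poses: Sequence[LigandPose],
    cutoff: float = DEFAULT_CUTOFF,
) -> PocketRoster:
    """Binding-site roster: residues with any heavy atom within ``cutoff``
    Å of any heavy atom of any reference pose (inclusive), ordered by
    (chain, residue number, insertion code).

    Deterministic given inputs; independent of atom-record order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not reference_poses:
        raise ValueError("at least one reference pose is required")

    ligand_coords = np.vstack([p.coords for p in reference_poses])
    tree = cKDTree(ligand_coords)
    near = tree.query_ball_point(structure.coords, r=cutoff)
    hit_keys = {
        structure.residue_keys[i] for i, hits in enumerate(near) if hits
    }
    if not hit_keys:
        raise EmptyRosterError(
            f"no residue within {cutoff} Å of any reference pose"
        )

    ordered = sorted(hit_keys, key=lambda k: (k[0], k[1], k[2]))
    coords_per_res: list[np.ndarray] = []
    names_per_res: list[list[str]] = []
    for key in ordered:
        idx = structure.atoms_of(key)
        coords_per_res.append(structure.coords[idx])
        names_per_res.append([structure.atom_names[i] for i in idx])
    return PocketRoster(
        residues=ordered,
        residue_coords=coords_per_res,
        residue_atom_names=names_per_res,
        cutoff=cutoff,
    )
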