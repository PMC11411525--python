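"""Comparison fingerprints: ECFP4, a geometric residue-typed PLIF, and
an order-blind PLEC-style pairwise fingerprint.

The PLIF here uses explicit geometric surrogate rules (hydrogen bond
2.2–4.0 Å heavy-atom distance with donor angle >= 120°; ionic <= 4.0 Å
between opposite charges; surface contact <= 4.5 Å) — a transparent,
testable stand-in for energy-based contact perception in commercial
packages.  The PLEC-style fingerprint hashes pairs of ligand/protein
atom environments for contacts <= 4.5 Å without any residue-order
information in the layout, which is precisely the property FIFI adds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import rdkit
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.spatial.distance import cdist

from .core import FingerprintVector, atom_environment_map, _environment_atoms
from .structure_io import LigandPose, PocketRoster, ResidueKey

INTERACTION_TYPES = (
    "hbond_donor",       # ligand atom donates to a protein acceptor
    "hbond_acceptor",    # ligand atom accepts from a protein donor
    "ionic_positive",    # positively charged ligand atom vs anionic residue
    "ionic_negative",    # negatively charged ligand atom vs cationic residue
    "surface_contact",   # untyped heavy-atom proximity
)

# Side-chain polar-atom roles by (residue name, atom name); backbone N/O
# handled separately.  Charged roles model physiological-pH protonation
# (LYS/ARG/HIS+ cationic, ASP/GLU anionic side chains).
_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("ASN", "ND2"),
    ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"), ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("TRP", "NE1"),
    ("CYS", "SG"),
}
_SIDECHAIN_ACCEPTORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("ASN", "OD1"),
    ("GLN", "OE1"), ("HIS", "ND1"), ("HIS", "NE2"), ("ASP", "OD1"),
    ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"), ("MET", "SD"),
}
_SIDECHAIN_POSITIVE = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("ARG", "CZ"), ("HIS", "ND1"), ("HIS", "NE2"),
}
_SIDECHAIN_NEGATIVE = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}


@dataclass(frozen=True)
class PlifConfig:
    """Geometric cutoffs for the residue-typed interaction fingerprint."""

    variant: str = "B"
    hbond_min_distance: float = 2.2
    hbond_max_distance: float = 4.0
    hbond_min_angle: float = 120.0  # degrees, at the donor heavy atom
    ionic_max_distance: float = 4.0
    surface_max_distance: float = 4.5

    def __post_init__(self) -> None:
        if self.variant not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown PLIF variant {self.variant!r}")
        for v in (
            self.hbond_max_distance,
            self.ionic_max_distance,
            self.surface_max_distance,
        ):
            if v <= 0:
                raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class PlecConfig:
    """PLEC-style fingerprint parameters (original defaults)."""

    ligand_depth: int = 2
    protein_depth: int = 4
    n_bits: int = 7653
    contact_threshold: float = 4.5


@dataclass
class InteractionContact:
    """One typed protein–ligand contact."""

    residue_key: ResidueKey
    residue_index: int
    interaction_type: str
    ligand_atoms: tuple[int, ...]
    distance: float
    angle: Optional[float] = None

    def __post_init__(self) -> None:
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction_type!r}")


def ecfp(
    pose: LigandPose | Chem.Mol, radius: int = 2, n_bits: int = 2048
) -> FingerprintVector:
    """Folded Morgan fingerprint (default ECFP4, 2048 bits) with
    bit -> atom provenance."""
    mol = pose.mol if isinstance(pose, LigandPose) else pose
    if mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    bv = gen.GetFingerprint(mol, additionalOutput=out)
    values = np.zeros(n_bits, dtype=np.uint8)
    values[list(bv.GetOnBits())] = 1
    provenance: dict[int, tuple[frozenset[int], ...]] = {}
    for bit, occurrences in out.GetBitInfoMap().items():
        sets: list[frozenset[int]] = []
        for atom, r in occurrences:
            env = _environment_atoms(mol, atom, r)
            if env not in sets:
                sets.append(env)
        provenance[int(bit)] = tuple(sets)
    layout = {
        "kind": "ecfp",
        "radius": radius,
        "n_bits": n_bits,
        "backend": f"rdkit-{rdkit.__version__}",
    }
    return FingerprintVector(values=values, layout=layout, provenance=provenance)


def _ligand_roles(mol: Chem.Mol) -> dict[int, dict[str, bool]]:
    """Donor/acceptor/charge flags per ligand heavy atom."""
    roles: dict[int, dict[str, bool]] = {}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        charge = atom.GetFormalCharge()
        polar = sym in ("N", "O")
        roles[atom.GetIdx()] = {
            "donor": polar and atom.GetTotalNumHs() > 0,
            "acceptor": (sym == "O") or (sym == "N" and charge <= 0),
            "positive": charge > 0,
            "negative": charge < 0,
        }
    return roles


def _protein_roles(resname: str, atom_name: str, element: str) -> dict[str, bool]:
    key = (resname, atom_name)
    donor = atom_name == "N" or key in _SIDECHAIN_DONORS
    acceptor = atom_name in ("O", "OXT") or key in _SIDECHAIN_ACCEPTORS
    if not (donor or acceptor) and atom_name not in ("CA", "C", "CB"):
        # fall back to element chemistry for unrecognized atom names
        donor = donor or element == "N"
        acceptor = acceptor or element == "O"
    return {
        "donor": donor,
        "acceptor": acceptor,
        "positive": key in _SIDECHAIN_POSITIVE,
        "negative": key in _SIDECHAIN_NEGATIVE,
    }


def _donor_angle(
    donor_xyz: np.ndarray,
    acceptor_xyz: np.ndarray,
    neighbor_xyz: Sequence[np.ndarray],
) -> Optional[float]:
    """Largest neighbor–donor–acceptor angle in degrees, None if no
    neighbor geometry is available."""
    best: Optional[float] = None
    for nb in neighbor_xyz:
        v1 = nb - donor_xyz
        v2 = acceptor_xyz - donor_xyz
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-9 or n2 < 1e-9:
            continue
        cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
        ang = float(np.degrees(np.arccos(cosang)))
        best = ang if best is None else max(best, ang)
    return best


def detect_contacts(
    roster: PocketRoster, pose: LigandPose, config: PlifConfig = PlifConfig()
) -> list[InteractionContact]:
    """Typed contacts between a pose and each roster residue.

    Hydrogen bonds and ionic contacts are detected per atom pair;
    surface contacts cover any remaining heavy-atom pair within the
    surface cutoff.  Donor angles use the donor's covalent heavy
    neighbors (ligand graph; <1.8 Å same-residue atoms on the protein
    side); a donor without neighbor geometry passes the angle test.
    """
    lig_xyz = pose.coords
    lig_roles = _ligand_roles(pose.mol)
    lig_neighbors: dict[int, list[np.ndarray]] = {
        a.GetIdx(): [lig_xyz[n.GetIdx()] for n in a.GetNeighbors()]
        for a in pose.mol.GetAtoms()
    }
    contacts: list[InteractionContact] = []

    for r, (key, res_xyz) in enumerate(zip(roster.residues, roster.residue_coords)):
        names = roster.residue_atom_names[r]
        resname = key[3]
        d = cdist(lig_xyz, res_xyz)
        typed_pairs: set[tuple[int, int]] = set()

        res_neighbors: list[list[np.ndarray]] = []
        intra = cdist(res_xyz, res_xyz)
        for j in range(len(res_xyz)):
            res_neighbors.append(
                [res_xyz[k] for k in range(len(res_xyz)) if k != j and intra[j, k] < 1.8]
            )

        for i in range(len(lig_xyz)):
            for j in range(len(res_xyz)):
                dist = float(d[i, j])
                if dist > config.surface_max_distance:
                    continue
                name_j = names[j] if j < len(names) else ""
                elem_j = name_j[:1] if name_j else ""
                prot = _protein_roles(resname, name_j, elem_j)
                lig = lig_roles[i]

                # hydrogen bonds (either direction), 2.2-4.0 Å
                if config.hbond_min_distance <= dist <= config.hbond_max_distance:
                    if lig["donor"] and prot["acceptor"]:
                        ang = _donor_angle(lig_xyz[i], res_xyz[j], lig_neighbors[i])
                        if ang is None or ang >= config.hbond_min_angle:
                            contacts.append(
                                InteractionContact(key, r, "hbond_donor", (i,), dist, ang)
                            )
                            typed_pairs.add((i, j))
                    if lig["acceptor"] and prot["donor"]:
                        ang = _donor_angle(res_xyz[j], lig_xyz[i], res_neighbors[j])
                        if ang is None or ang >= config.hbond_min_angle:
                            contacts.append(
                                InteractionContact(key, r, "hbond_acceptor", (i,), dist, ang)
                            )
                            typed_pairs.add((i, j))

                # ionic contacts between opposite charges, <= 4.0 Å
                if dist <= config.ionic_max_distance:
                    if lig["positive"] and prot["negative"]:
                        contacts.append(
                            InteractionContact(key, r, "ionic_positive", (i,), dist)
                        )
                        typed_pairs.add((i, j))
                    if lig["negative"] and prot["positive"]:
                        contacts.append(
                            InteractionContact(key, r, "ionic_negative", (i,), dist)
                        )
                        typed_pairs.add((i, j))

        # untyped proximity: surface patch contacts
        for i in range(len(lig_xyz)):
            for j in range(len(res_xyz)):
                dist = float(d[i, j])
                if dist <= config.surface_max_distance and (i, j) not in typed_pairs:
                    contacts.append(
                        InteractionContact(key, r, "surface_contact", (i,), dist)
                    )
    return contacts


def plif(
    contacts: Sequence[InteractionContact],
    roster: PocketRoster,
    variant: str = "B",
) -> FingerprintVector:
    """Residue-blocked interaction-type fingerprint.

    Variants: A — binary typed contacts (no surface); B — A plus a
    surface bit; C/D — count-valued analogues of A/B.  Block order
    follows the roster.
    """
    if variant not in ("A", "B", "C", "D"):
        raise ValueError(f"unknown variant {variant!r}")
    with_surface = variant in ("B", "D")
    counted = variant in ("C", "D")
    types = INTERACTION_TYPES if with_surface else INTERACTION_TYPES[:4]
    width = len(types)
    values = np.zeros(len(roster) * width, dtype=np.int64)
    provenance: dict[int, tuple[frozenset[int], ...]] = {}
    for c in contacts:
        if c.interaction_type == "surface_contact" and not with_surface:
            continue
        col = types.index(c.interaction_type)
        bit = c.residue_index * width + col
        values[bit] += 1
        sets = list(provenance.get(bit, ()))
        s = frozenset(c.ligand_atoms)
        if s not in sets:
            sets.append(s)
        provenance[bit] = tuple(sets)
    if not counted:
        values = (values > 0).astype(np.uint8)
    layout = {
        "kind": f"plif-{variant.lower()}",
        "n_residues": len(roster),
        "types": list(types),
        "counted": counted,
    }
    return FingerprintVector(values=values, layout=layout, provenance=provenance)


def _stable_hash(*parts: object, n_bits: int) -> int:
    digest = hashlib.blake2b(
        "|".join(str(p) for p in parts).encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % n_bits


def plec_like(
    roster: PocketRoster, pose: LigandPose, config: PlecConfig = PlecConfig()
) -> FingerprintVector:
    """Order-blind pairwise environment fingerprint (PLEC-style).

    For every ligand-atom/protein-atom pair within the contact
    threshold, ligand Morgan environments at depths 0..2 are paired
    with protein atom environments at depths 0..4 (depths advanced in
    lockstep, each capped at its own maximum) and folded into 7653
    bits.  Protein environments are identified by (residue name, atom
    name, depth) only — deliberately no chain or residue number, so
    identical residue types at different sequence positions are
    indistinguishable.
    """
    lig_xyz = pose.coords
    env_map = atom_environment_map(pose, config.ligand_depth)
    values = np.zeros(config.n_bits, dtype=np.uint8)
    provenance: dict[int, tuple[frozenset[int], ...]] = {}
    max_depth = max(config.ligand_depth, config.protein_depth)

    for r, (key, res_xyz) in enumerate(zip(roster.residues, roster.residue_coords)):
        names = roster.residue_atom_names[r]
        resname = key[3]
        d = cdist(lig_xyz, res_xyz)
        for i in range(len(lig_xyz)):
            for j in range(len(res_xyz)):
                if d[i, j] > config.contact_threshold:
                    continue
                name_j = names[j] if j < len(names) else ""
                for depth in range(max_depth + 1):
                    ld = min(depth, config.ligand_depth)
                    pd = min(depth, config.protein_depth)
                    if (i, ld) not in env_map:
                        continue
                    lig_hash, env_atoms = env_map[(i, ld)]
                    prot_hash = _stable_hash(resname, name_j, pd, n_bits=2**32)
                    bit = _stable_hash(lig_hash, prot_hash, depth, n_bits=config.n_bits)
                    values[bit] = 1
                    sets = list(provenance.get(bit, ()))
                    if env_atoms not in sets:
                        sets.append(env_atoms)
                    provenance[bit] = tuple(sets)
    layout = {
        "kind": "plec",
        "n_bits": config.n_bits,
        "ligand_depth": config.ligand_depth,
        "protein_depth": config.protein_depth,
        "contact_threshold": config.contact_threshold,
        "backend": f"rdkit-{rdkit.__version__}",
    }
    return FingerprintVector(values=values, layout=layout, provenance=provenance)
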