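"""Fragmented interaction fingerprints (FIFI).

A FIFI encodes, residue by residue and in residue order, which ligand
substructures sit close to each binding-site residue in a docked pose:

1. *Tagging* — every ligand heavy atom within a proximity threshold
   (default 5.5 Å) of a residue's heavy atoms is tagged for that residue.
2. *Neighbor extension* — the tagged set may be grown along ligand bonds
   by 0, 1 or 2 bonds (N0 / N1 / N2).
3. *Environment hashing* — each tagged atom contributes its circular
   Morgan environment identifiers at radii 0..R (default R = 1, i.e.
   diameter-2 "ECFP2" environments), computed on the full ligand graph.
4. *Encoding* — FIFI-BA folds each residue's hash set into a fixed
   1024-bit block (hash mod 1024) and concatenates blocks in roster
   order; FIFI-US assigns one bit per (residue, hash) pair observed in
   training, again ordered by residue, avoiding collisions entirely.

Because the blocks are laid out in residue order, two chemically
identical residues at different sequence positions produce different
bits — the property that distinguishes FIFI from order-blind pairwise
fingerprints such as PLEC.

Raw Morgan hash values are backend-dependent; layouts (block offsets,
vocabularies) are the portable contract, and persisted artifacts record
the backend version.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import rdkit
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy import sparse
from scipy.spatial.distance import cdist

from .structure_io import LigandPose, PocketRoster

__all__ = [
    "FifiConfig",
    "TaggedAtomMap",
    "ResidueEnvSets",
    "USVocabulary",
    "FingerprintVector",
    "tag_atoms",
    "extend_neighbors",
    "atom_environment_map",
    "environment_hashes",
    "residue_env_sets",
    "fifi_ba",
    "build_us_vocabulary",
    "fifi_us",
    "featurize",
]


@dataclass(frozen=True)
class FifiConfig:
    """FIFI generation parameters.

    proximity_threshold : Å within which a ligand atom is tagged for a
        residue (default 5.5 — hydrogen bonds span 2.2–4.0 Å, salt
        bridges < 4.0 Å, plus ~1 Å margin for non-optimized poses).
    neighbor_depth : bond-topological extension of the tagged set,
        one of 0, 1, 2 (N0/N1/N2).
    environment_radius : maximal Morgan radius of the hashed
        environments; 1 gives diameter-2 (ECFP2-style) substructures.
    bits_per_residue : FIFI-BA block width; must be a power of two.
    """

    proximity_threshold: float = 5.5
    neighbor_depth: int = 2
    environment_radius: int = 1
    bits_per_residue: int = 1024

    def __post_init__(self) -> None:
        if self.proximity_threshold <= 0:
            raise ValueError("proximity_threshold must be positive")
        if self.neighbor_depth not in (0, 1, 2):
            raise ValueError("neighbor_depth must be 0, 1 or 2")
        if self.environment_radius < 0:
            raise ValueError("environment_radius must be non-negative")
        b = self.bits_per_residue
        if b <= 0 or (b & (b - 1)) != 0:
            raise ValueError("bits_per_residue must be a positive power of two")

    def key(self) -> str:
        """Stable identity string used to detect config mismatches."""
        return (
            f"thr={self.proximity_threshold}|depth={self.neighbor_depth}"
            f"|radius={self.environment_radius}"
        )


@dataclass
class TaggedAtomMap:
    """Per-residue sets of tagged ligand atom indices.

    ``depth`` records the neighbor extension already applied; a map can
    only be extended once, starting from depth 0.
    """

    atoms_by_residue: dict[int, frozenset[int]]
    depth: int = 0

    def atoms(self, residue_index: int) -> frozenset[int]:
        return self.atoms_by_residue.get(residue_index, frozenset())

    def residues(self) -> list[int]:
        return sorted(self.atoms_by_residue)


#: residue index -> set of Morgan environment hash identifiers
ResidueEnvSets = dict[int, frozenset[int]]


@dataclass
class FingerprintVector:
    """A fingerprint with layout metadata and bit -> atom provenance.

    ``provenance`` maps each set bit to the tuple of atom-index sets of
    the substructure environments folded onto it (more than one set on
    a BA hash collision).
    """

    values: np.ndarray
    layout: Mapping[str, object]
    provenance: dict[int, tuple[frozenset[int], ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.values)


@dataclass
class USVocabulary:
    """Bijective map (residue index, environment hash) -> bit position.

    Built from training poses; ordered by residue index, then ascending
    hash value, so the layout is a deterministic function of the
    observed pair set.
    """

    pair_to_bit: dict[tuple[int, int], int]
    config_key: str
    n_training_poses: int
    backend: str = field(default_factory=lambda: f"rdkit-{rdkit.__version__}")

    def __len__(self) -> int:
        return len(self.pair_to_bit)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config_key": self.config_key,
            "n_training_poses": self.n_training_poses,
            "backend": self.backend,
            "pairs": [
                {"residue": r, "hash": h, "bit": b}
                for (r, h), b in sorted(self.pair_to_bit.items(), key=lambda kv: kv[1])
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "USVocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(
            pair_to_bit={
                (p["residue"], p["hash"]): p["bit"] for p in payload["pairs"]
            },
            config_key=payload["config_key"],
            n_training_poses=payload["n_training_poses"],
            backend=payload.get("backend", "unknown"),
        )


def tag_atoms(
    roster: PocketRoster, pose: LigandPose, threshold: float = 5.5
) -> TaggedAtomMap:
    """Tag ligand heavy atoms proximal to each roster residue.

    Atom ``i`` is tagged for residue ``r`` iff its minimal distance to
    any heavy atom of ``r`` is <= ``threshold`` (inclusive).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    lig = pose.coords
    mapping: dict[int, frozenset[int]] = {}
    for r, res_coords in enumerate(roster.residue_coords):
        d = cdist(lig, res_coords)
        tagged = np.flatnonzero(d.min(axis=1) <= threshold)
        if tagged.size:
            mapping[r] = frozenset(int(i) for i in tagged)
    return TaggedAtomMap(atoms_by_residue=mapping, depth=0)


def extend_neighbors(
    pose: LigandPose, tagged: TaggedAtomMap, depth: int
) -> TaggedAtomMap:
    """Grow each residue's tagged set along ligand bonds.

    The extended set for residue ``r`` contains every atom within graph
    distance <= ``depth`` bonds of any originally tagged atom.  Depth 0
    is the identity.  A map that was already extended cannot be
    extended again.
    """
    if depth not in (0, 1, 2):
        raise ValueError("depth must be 0, 1 or 2")
    if tagged.depth != 0:
        raise ValueError("map was already neighbor-extended")
    if depth == 0:
        return TaggedAtomMap(dict(tagged.atoms_by_residue), depth=0)

    adjacency: list[list[int]] = [[] for _ in range(pose.n_atoms)]
    for bond in pose.mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i].append(j)
        adjacency[j].append(i)

    extended: dict[int, frozenset[int]] = {}
    for r, seeds in tagged.atoms_by_residue.items():
        seen = set(seeds)
        frontier = deque((a, 0) for a in seeds)
        while frontier:
            atom, dist = frontier.popleft()
            if dist == depth:
                continue
            for nb in adjacency[atom]:
                if nb not in seen:
                    seen.add(nb)
                    frontier.append((nb, dist + 1))
        extended[r] = frozenset(seen)
    return TaggedAtomMap(extended, depth=depth)


def atom_environment_map(
    pose: LigandPose, radius: int
) -> dict[tuple[int, int], tuple[int, frozenset[int]]]:
    """Morgan environment identifiers per (atom, radius).

    Returns ``(atom index, radius) -> (hash id, environment atom set)``
    for every heavy atom and every radius 0..``radius``, computed over
    the full ligand graph (redundant environments included so the map
    is total).  The environment atom set is the substructure the hash
    identifies, used for bit -> atom provenance.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, includeRedundantEnvironments=True
    )
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(pose.mol, additionalOutput=out)
    mapping: dict[tuple[int, int], tuple[int, frozenset[int]]] = {}
    for hash_id, occurrences in out.GetBitInfoMap().items():
        for atom, r in occurrences:
            env_atoms = _environment_atoms(pose.mol, atom, r)
            mapping[(atom, r)] = (int(hash_id), env_atoms)
    return mapping


def _environment_atoms(mol: Chem.Mol, center: int, radius: int) -> frozenset[int]:
    if radius == 0:
        return frozenset({center})
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for bid in bond_ids:
        bond = mol.GetBondWithIdx(bid)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return frozenset(atoms)


def environment_hashes(
    pose: LigandPose, atoms: Iterable[int], radius: int
) -> frozenset[int]:
    """Union of environment hash ids of ``atoms`` at radii 0..``radius``."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    atom_set = set(atoms)
    for a in atom_set:
        if not (0 <= a < pose.n_atoms):
            raise IndexError(f"atom index {a} out of range")
    env_map = atom_environment_map(pose, radius)
    hashes = {
        env_map[(a, r)][0]
        for a in atom_set
        for r in range(radius + 1)
        if (a, r) in env_map
    }
    return frozenset(hashes)


def residue_env_sets(
    pose: LigandPose, tagged: TaggedAtomMap, radius: int
) -> tuple[ResidueEnvSets, dict[tuple[int, int], tuple[frozenset[int], ...]]]:
    """Environment hash sets per residue, plus hash provenance.

    Returns the per-residue hash sets and a map
    ``(residue index, hash) -> tuple of environment atom sets`` feeding
    fingerprint provenance.
    """
    env_map = atom_environment_map(pose, radius)
    envs: ResidueEnvSets = {}
    prov: dict[tuple[int, int], tuple[frozenset[int], ...]] = {}
    for r, atoms in tagged.atoms_by_residue.items():
        hashes: set[int] = set()
        local: dict[int, list[frozenset[int]]] = {}
        for a in atoms:
            for rad in range(radius + 1):
                if (a, rad) not in env_map:
                    continue
                h, env_atoms = env_map[(a, rad)]
                hashes.add(h)
                local.setdefault(h, [])
                if env_atoms not in local[h]:
                    local[h].append(env_atoms)
        if hashes:
            envs[r] = frozenset(hashes)
            for h, sets in local.items():
                prov[(r, h)] = tuple(sets)
    return envs, prov


def fifi_ba(
    envs: ResidueEnvSets,
    config: FifiConfig,
    roster_size: int,
    hash_provenance: Optional[Mapping[tuple[int, int], tuple[frozenset[int], ...]]] = None,
) -> FingerprintVector:
    """FIFI bit array: per-residue 1024-bit folded blocks, roster order.

    Bit ``r * bits_per_residue + (hash mod bits_per_residue)`` is set
    for every hash of residue ``r``; collisions OR-fold, and provenance
    lists the atom sets of every environment folded onto a bit.
    """
    bpr = config.bits_per_residue
    values = np.zeros(roster_size * bpr, dtype=np.uint8)
    provenance: dict[int, tuple[frozenset[int], ...]] = {}
    for r, hashes in envs.items():
        if not 0 <= r < roster_size:
            raise IndexError(f"residue index {r} outside roster of {roster_size}")
        for h in hashes:
            bit = r * bpr + (h % bpr)
            values[bit] = 1
            if hash_provenance is not None:
                sets = list(provenance.get(bit, ()))
                for s in hash_provenance.get((r, h), ()):
                    if s not in sets:
                        sets.append(s)
                provenance[bit] = tuple(sets)
    layout = {
        "kind": "fifi-ba",
        "n_residues": roster_size,
        "bits_per_residue": bpr,
        "config_key": config.key(),
        "backend": f"rdkit-{rdkit.__version__}",
    }
    return FingerprintVector(values=values, layout=layout, provenance=provenance)


def build_us_vocabulary(
    training_envs: Sequence[ResidueEnvSets], config: FifiConfig
) -> USVocabulary:
    """One bit per (residue index, hash) pair observed in training.

    Order: residue index, then ascending hash — deterministic and
    independent of training-pose order.
    """
    if not training_envs:
        raise ValueError("at least one training pose is required")
    pairs: set[tuple[int, int]] = set()
    for envs in training_envs:
        for r, hashes in envs.items():
            pairs.update((r, h) for h in hashes)
    if not pairs:
        raise ValueError("no tagged environments in any training pose")
    ordered = sorted(pairs)
    return USVocabulary(
        pair_to_bit={p: i for i, p in enumerate(ordered)},
        config_key=config.key(),
        n_training_poses=len(training_envs),
    )


def fifi_us(
    envs: ResidueEnvSets,
    vocab: USVocabulary,
    config: Optional[FifiConfig] = None,
    hash_provenance: Optional[Mapping[tuple[int, int], tuple[frozenset[int], ...]]] = None,
) -> FingerprintVector:
    """FIFI unique-substructure one-hot over a fitted vocabulary.

    Pairs absent from the vocabulary are dropped silently; the layout
    reports ``coverage`` = matched pairs / pairs present in ``envs``
    (1.0 for an empty environment set).
    """
    if config is not None and config.key() != vocab.config_key:
        raise ValueError(
            f"config mismatch: vocabulary built with {vocab.config_key!r}, "
            f"got {config.key()!r}"
        )
    values = np.zeros(len(vocab), dtype=np.uint8)
    provenance: dict[int, tuple[frozenset[int], ...]] = {}
    total = 0
    matched = 0
    for r, hashes in envs.items():
        for h in hashes:
            total += 1
            bit = vocab.pair_to_bit.get((r, h))
            if bit is None:
                continue
            matched += 1
            values[bit] = 1
            if hash_provenance is not None:
                provenance[bit] = hash_provenance.get((r, h), ())
    layout = {
        "kind": "fifi-us",
        "vocabulary_size": len(vocab),
        "config_key": vocab.config_key,
        "coverage": matched / total if total else 1.0,
        "backend": vocab.backend,
    }
    return FingerprintVector(values=values, layout=layout, provenance=provenance)


def pose_fingerprint(
    roster: PocketRoster,
    pose: LigandPose,
    config: FifiConfig,
    mode: str,
    vocab: Optional[USVocabulary] = None,
) -> FingerprintVector:
    """End-to-end FIFI for a single pose (tag, extend, hash, encode)."""
    tagged = tag_atoms(roster, pose, config.proximity_threshold)
    extended = extend_neighbors(pose, tagged, config.neighbor_depth)
    envs, prov = residue_env_sets(pose, extended, config.environment_radius)
    if mode == "ba":
        return fifi_ba(envs, config, len(roster), hash_provenance=prov)
    if mode == "us":
        if vocab is None:
            raise ValueError("mode 'us' requires a fitted vocabulary")
        return fifi_us(envs, vocab, config, hash_provenance=prov)
    raise ValueError(f"unknown mode {mode!r}")


def featurize(
    roster: PocketRoster,
    poses: Sequence[LigandPose],
    config: FifiConfig = FifiConfig(),
    mode: str = "ba",
    vocab: Optional[USVocabulary] = None,
    fit_vocab: bool = False,
) -> tuple[sparse.csr_matrix, list[FingerprintVector], Optional[USVocabulary]]:
    """Fingerprint a batch of poses into a sparse matrix, one row each.

    Returns ``(matrix, per-pose FingerprintVector list, vocabulary)``.
    For mode ``"us"`` either pass a fitted ``vocab`` or set
    ``fit_vocab=True`` to build one from these poses.
    """
    if mode not in ("ba", "us"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "us" and vocab is None:
        if not fit_vocab:
            raise ValueError("mode 'us' requires vocab or fit_vocab=True")
        training_envs = []
        for pose in poses:
            tagged = tag_atoms(roster, pose, config.proximity_threshold)
            extended = extend_neighbors(pose, tagged, config.neighbor_depth)
            envs, _ = residue_env_sets(pose, extended, config.environment_radius)
            training_envs.append(envs)
        vocab = build_us_vocabulary(training_envs, config)

    vectors = [pose_fingerprint(roster, p, config, mode, vocab) for p in poses]
    width = len(roster) * config.bits_per_residue if mode == "ba" else len(vocab)  # type: ignore[arg-type]
    matrix = sparse.csr_matrix(
        np.vstack([v.values for v in vectors]) if vectors else np.zeros((0, width)),
        dtype=np.uint8,
    )
    return matrix, vectors, vocab
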