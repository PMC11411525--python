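"""Atom-level attribution of tree-SHAP feature contributions.

A fitted tree model over an interaction fingerprint assigns a Shapley
value to every bit.  Bits carry provenance — the ligand atom sets of
the substructure environments that set them — so each bit's value can
be split equally among its contributing atoms and accumulated into a
per-atom contribution map.  Bits without provenance (absence-encoding
information, e.g. unset FIFI-US bits) go to a molecule-level remainder
term, never to atoms, so the decomposition conserves the SHAP row sum
exactly.

For residue-blocked layouts (FIFI, PLIF) the map can be restricted to
one residue's bits, and the per-residue restricted maps partition the
global map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core import USVocabulary
from .treeshap import shap_values  # re-exported model-level attribution

__all__ = [
    "AtomAttribution",
    "shap_values",
    "atom_attribution",
    "residue_feature_indices",
    "residue_filtered_attribution",
]

Provenance = Mapping[int, tuple[frozenset[int], ...]]


@dataclass
class AtomAttribution:
    """Cumulative signed contribution per ligand atom plus remainder.

    ``atom_contributions[i]`` sums the equally split SHAP shares of all
    bits whose provenance includes atom ``i``; ``remainder`` collects
    SHAP mass of bits with no atom provenance.  Conservation:
    ``atom_contributions.sum() + remainder`` equals the SHAP row sum
    over the considered features.
    """

    atom_contributions: np.ndarray
    remainder: float
    metadata: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.atom_contributions.sum() + self.remainder)


def atom_attribution(
    shap_row: np.ndarray,
    provenance: Provenance,
    n_atoms: int,
    fingerprint: Optional[np.ndarray] = None,
    feature_indices: Optional[np.ndarray] = None,
) -> AtomAttribution:
    """Split per-bit SHAP values equally among their provenance atoms.

    Parameters
    ----------
    shap_row : per-feature SHAP values for one compound.
    provenance : bit position -> atom sets of the environments behind it.
        Atoms of a bit are the union over its (possibly collided)
        environments.
    n_atoms : heavy-atom count of the compound.
    fingerprint : optional bit vector of the compound; when given, a set
        bit with nonzero SHAP but no provenance raises (provenance must
        cover every set bit), while unset bits legitimately go to the
        remainder.
    feature_indices : optional restriction to a subset of features
        (used for residue-filtered maps).
    """
    shap_row = np.asarray(shap_row, dtype=float)
    contributions = np.zeros(n_atoms)
    remainder = 0.0
    if feature_indices is None:
        features = np.flatnonzero(shap_row)
    else:
        feature_indices = np.asarray(feature_indices, dtype=int)
        features = feature_indices[shap_row[feature_indices] != 0]
    for bit in features:
        bit = int(bit)
        atom_sets = provenance.get(bit, ())
        atoms = sorted(set().union(*atom_sets)) if atom_sets else []
        if not atoms:
            if fingerprint is not None and fingerprint[bit]:
                raise ValueError(f"set bit {bit} has no atom provenance")
            remainder += shap_row[bit]
            continue
        share = shap_row[bit] / len(atoms)
        for a in atoms:
            if not 0 <= a < n_atoms:
                raise IndexError(f"provenance atom {a} outside molecule")
            contributions[a] += share
    return AtomAttribution(atom_contributions=contributions, remainder=remainder)


def residue_feature_indices(
    layout: Mapping[str, object],
    residue_index: int,
    vocab: Optional[USVocabulary] = None,
) -> np.ndarray:
    """Feature positions belonging to one residue of a residue-blocked
    layout (FIFI-BA, FIFI-US with its vocabulary, or PLIF)."""
    kind = str(layout.get("kind", ""))
    if kind == "fifi-ba":
        n_res = int(layout["n_residues"])
        bpr = int(layout["bits_per_residue"])
        if not 0 <= residue_index < n_res:
            raise KeyError(f"residue {residue_index} not in roster of {n_res}")
        return np.arange(residue_index * bpr, (residue_index + 1) * bpr)
    if kind == "fifi-us":
        if vocab is None:
            raise ValueError("fifi-us layout needs its vocabulary")
        bits = [b for (r, _h), b in vocab.pair_to_bit.items() if r == residue_index]
        max_res = max(r for (r, _h) in vocab.pair_to_bit)
        if residue_index < 0 or (not bits and residue_index > max_res):
            raise KeyError(f"residue {residue_index} not in vocabulary")
        return np.array(sorted(bits), dtype=int)
    if kind.startswith("plif"):
        n_res = int(layout["n_residues"])
        width = len(layout["types"])  # type: ignore[arg-type]
        if not 0 <= residue_index < n_res:
            raise KeyError(f"residue {residue_index} not in roster of {n_res}")
        return np.arange(residue_index * width, (residue_index + 1) * width)
    raise ValueError(f"layout kind {kind!r} is not residue-blocked")


def residue_filtered_attribution(
    shap_row: np.ndarray,
    provenance: Provenance,
    n_atoms: int,
    layout: Mapping[str, object],
    residue_index: int,
    vocab: Optional[USVocabulary] = None,
    fingerprint: Optional[np.ndarray] = None,
) -> AtomAttribution:
    """Atom attribution restricted to one residue's fingerprint block.

    Summing the filtered maps over all roster residues reproduces the
    unfiltered map exactly (the blocks partition the features).
    """
    idx = residue_feature_indices(layout, residue_index, vocab=vocab)
    attr = atom_attribution(
        shap_row, provenance, n_atoms, fingerprint=fingerprint, feature_indices=idx
    )
    attr.metadata["residue_index"] = residue_index
    return attr
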