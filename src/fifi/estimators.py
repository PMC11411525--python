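"""scikit-learn style fingerprint transformers.

Each transformer consumes a list of :class:`~fifi.structure_io.LigandPose`
objects as ``X`` and produces a sparse fingerprint matrix, so the
featurizers compose with sklearn pipelines and model selection.  The
binding-site roster is learned at ``fit`` time (from the training poses
and the protein structure) and persisted on the estimator, so training
and test fingerprints share one layout — fitted state carries the
conventional trailing underscore.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import baselines, core
from .structure_io import LigandPose, PocketRoster, ProteinStructure, define_roster


def _check_poses(X) -> list[LigandPose]:
    poses = list(X)
    if not poses:
        raise ValueError("need at least one pose")
    for p in poses:
        if not isinstance(p, LigandPose):
            raise TypeError(f"expected LigandPose, got {type(p).__name__}")
    return poses


class _RosterMixin:
    """Shared roster resolution: use a fixed roster when given, else
    derive one from the protein structure and the training poses."""

    def _resolve_roster(self, poses: Sequence[LigandPose], cutoff: float) -> PocketRoster:
        if self.roster is not None:
            return self.roster
        if self.structure is None:
            raise ValueError("provide either a roster or a protein structure")
        return define_roster(self.structure, poses, cutoff=cutoff)


class FifiFingerprinter(BaseEstimator, TransformerMixin, _RosterMixin):
    """Fragmented interaction fingerprint transformer (FIFI-BA / FIFI-US).

    Parameters
    ----------
    mode : ``"ba"`` (fixed per-residue bit blocks) or ``"us"``
        (one-hot over training (residue, substructure) pairs).
    structure, roster : binding site; pass a fitted roster to reuse a
        layout, or a structure so ``fit`` derives the roster from the
        training poses at the proximity threshold.
    proximity_threshold, neighbor_depth, environment_radius,
    bits_per_residue : see :class:`~fifi.core.FifiConfig`.

    Attributes
    ----------
    roster_ : the binding-site roster fixing the layout.
    vocab_ : the fitted unique-substructure vocabulary (mode "us").
    n_features_ : fingerprint width.
    provenance_ : per-pose bit->atom provenance of the last transform.
    coverage_ : per-pose training-vocabulary coverage of the last
        transform (mode "us").
    """

    def __init__(
        self,
        mode: str = "ba",
        structure: Optional[ProteinStructure] = None,
        roster: Optional[PocketRoster] = None,
        proximity_threshold: float = 5.5,
        neighbor_depth: int = 2,
        environment_radius: int = 1,
        bits_per_residue: int = 1024,
    ):
        self.mode = mode
        self.structure = structure
        self.roster = roster
        self.proximity_threshold = proximity_threshold
        self.neighbor_depth = neighbor_depth
        self.environment_radius = environment_radius
        self.bits_per_residue = bits_per_residue

    def _config(self) -> core.FifiConfig:
        return core.FifiConfig(
            proximity_threshold=self.proximity_threshold,
            neighbor_depth=self.neighbor_depth,
            environment_radius=self.environment_radius,
            bits_per_residue=self.bits_per_residue,
        )

    def fit(self, X, y=None):
        poses = _check_poses(X)
        if self.mode not in ("ba", "us"):
            raise ValueError(f"unknown mode {self.mode!r}")
        config = self._config()
        self.roster_ = self._resolve_roster(poses, config.proximity_threshold)
        self.vocab_ = None
        if self.mode == "us":
            _, _, self.vocab_ = core.featurize(
                self.roster_, poses, config, mode="us", fit_vocab=True
            )
            self.n_features_ = len(self.vocab_)
        else:
            self.n_features_ = len(self.roster_) * config.bits_per_residue
        return self

    def transform(self, X) -> sparse.csr_matrix:
        check_is_fitted(self, "roster_")
        poses = _check_poses(X)
        matrix, vectors, _ = core.featurize(
            self.roster_, poses, self._config(), mode=self.mode, vocab=self.vocab_
        )
        self.provenance_ = [v.provenance for v in vectors]
        if self.mode == "us":
            self.coverage_ = np.array([v.layout["coverage"] for v in vectors])
        self.layout_ = vectors[0].layout if vectors else None
        return matrix


class EcfpFingerprinter(BaseEstimator, TransformerMixin):
    """Ligand-only folded Morgan fingerprint (default ECFP4/2048)."""

    def __init__(self, radius: int = 2, n_bits: int = 2048):
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X, y=None):
        _check_poses(X)
        self.n_features_ = self.n_bits
        return self

    def transform(self, X) -> sparse.csr_matrix:
        poses = _check_poses(X)
        vectors = [baselines.ecfp(p, self.radius, self.n_bits) for p in poses]
        self.provenance_ = [v.provenance for v in vectors]
        return sparse.csr_matrix(np.vstack([v.values for v in vectors]))


class PlifFingerprinter(BaseEstimator, TransformerMixin, _RosterMixin):
    """Residue-typed geometric interaction fingerprint (variants A–D)."""

    def __init__(
        self,
        variant: str = "B",
        structure: Optional[ProteinStructure] = None,
        roster: Optional[PocketRoster] = None,
        roster_cutoff: float = 5.5,
    ):
        self.variant = variant
        self.structure = structure
        self.roster = roster
        self.roster_cutoff = roster_cutoff

    def fit(self, X, y=None):
        poses = _check_poses(X)
        config = baselines.PlifConfig(variant=self.variant)
        self.roster_ = self._resolve_roster(poses, self.roster_cutoff)
        width = 5 if self.variant in ("B", "D") else 4
        self.n_features_ = len(self.roster_) * width
        self.config_ = config
        return self

    def transform(self, X) -> sparse.csr_matrix:
        check_is_fitted(self, "roster_")
        poses = _check_poses(X)
        rows, provs = [], []
        for p in poses:
            contacts = baselines.detect_contacts(self.roster_, p, self.config_)
            fp = baselines.plif(contacts, self.roster_, self.variant)
            rows.append(fp.values)
            provs.append(fp.provenance)
        self.provenance_ = provs
        self.layout_ = baselines.plif([], self.roster_, self.variant).layout
        return sparse.csr_matrix(np.vstack(rows))


class PlecFingerprinter(BaseEstimator, TransformerMixin, _RosterMixin):
    """Order-blind pairwise environment fingerprint (PLEC-style)."""

    def __init__(
        self,
        structure: Optional[ProteinStructure] = None,
        roster: Optional[PocketRoster] = None,
        ligand_depth: int = 2,
        protein_depth: int = 4,
        n_bits: int = 7653,
        contact_threshold: float = 4.5,
        roster_cutoff: float = 5.5,
    ):
        self.structure = structure
        self.roster = roster
        self.ligand_depth = ligand_depth
        self.protein_depth = protein_depth
        self.n_bits = n_bits
        self.contact_threshold = contact_threshold
        self.roster_cutoff = roster_cutoff

    def fit(self, X, y=None):
        poses = _check_poses(X)
        self.roster_ = self._resolve_roster(poses, self.roster_cutoff)
        self.config_ = baselines.PlecConfig(
            ligand_depth=self.ligand_depth,
            protein_depth=self.protein_depth,
            n_bits=self.n_bits,
            contact_threshold=self.contact_threshold,
        )
        self.n_features_ = self.n_bits
        return self

    def transform(self, X) -> sparse.csr_matrix:
        check_is_fitted(self, "roster_")
        poses = _check_poses(X)
        rows, provs = [], []
        for p in poses:
            fp = baselines.plec_like(self.roster_, p, self.config_)
            rows.append(fp.values)
            provs.append(fp.provenance)
        self.provenance_ = provs
        return sparse.csr_matrix(np.vstack(rows))
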