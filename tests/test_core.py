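import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.distance import cdist

from fifi import synthetic
from fifi.core import (
    FifiConfig,
    TaggedAtomMap,
    build_us_vocabulary,
    environment_hashes,
    extend_neighbors,
    featurize,
    fifi_ba,
    fifi_us,
    pose_fingerprint,
    residue_env_sets,
    tag_atoms,
)
from fifi.structure_io import LigandPose


def _pose_from_smiles(smiles: str, seed: int = 1) -> LigandPose:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return LigandPose(smiles, Chem.RemoveHs(mol))


class TestTagAtoms:
    def test_threshold_straddle(self):
        spec = synthetic.FixtureSpec(
            residue_types=("SER", "LYS"),
            spacing=30.0,
            contacts=[
                synthetic.PlantedContact("near", "CO", 0, 0, 5.4),
                synthetic.PlantedContact("far", "CO", 0, 0, 5.6),
            ],
            seed=2,
        )
        _, poses, _ = synthetic.make_complex(spec)
        structure = synthetic.structure_from_pdb_text(
            synthetic._pocket_pdb_text(spec.residue_types, spec.spacing)
        )
        from fifi.structure_io import define_roster

        roster = define_roster(structure, poses, cutoff=8.0)
        near_map = tag_atoms(roster, poses[0], threshold=5.5)
        far_map = tag_atoms(roster, poses[1], threshold=5.5)
        ser_idx = roster.residues.index(("A", 1, "", "SER"))
        assert 0 in near_map.atoms(ser_idx)
        assert 0 not in far_map.atoms(ser_idx)

    def test_distant_ligand_untagged(self, twin):
        roster, pose, _ = twin
        far = pose.translated([0.0, 100.0, 0.0])
        assert tag_atoms(roster, far, 5.5).atoms_by_residue == {}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        _, roster, pose = synthetic.make_random_complex(seed)
        tagged = tag_atoms(roster, pose, 5.5)
        for r, res_coords in enumerate(roster.residue_coords):
            d = cdist(pose.coords, res_coords)
            brute = frozenset(np.flatnonzero(d.min(axis=1) <= 5.5).tolist())
            assert tagged.atoms(r) == brute

    def test_threshold_monotonicity(self):
        _, roster, pose = synthetic.make_random_complex(3)
        counts = []
        for thr in (3.0, 4.5, 5.5, 7.0):
            fp = pose_fingerprint(
                roster, pose, FifiConfig(proximity_threshold=thr), "ba"
            )
            counts.append(int(fp.values.sum()))
        assert counts == sorted(counts)


class TestExtendNeighbors:
    def test_depth_zero_is_identity(self, twin):
        roster, pose, _ = twin
        tagged = tag_atoms(roster, pose, 5.5)
        out = extend_neighbors(pose, tagged, 0)
        assert out.atoms_by_residue == tagged.atoms_by_residue

    def test_linear_chain_by_hand(self):
        # butanol chain C0-C1-C2-C3(-O4); only atom 0 tagged, depth 2
        pose = _pose_from_smiles("CCCCO")
        tagged = TaggedAtomMap({0: frozenset({0})}, depth=0)
        out = extend_neighbors(pose, tagged, 2)
        assert out.atoms(0) == frozenset({0, 1, 2})

    @pytest.mark.parametrize("depth", [1, 2])
    def test_matches_bfs_oracle(self, depth, rng):
        for smiles in ("CC(C)CO", "c1ccccc1CCN", "CC(=O)OC1CCC1"):
            pose = _pose_from_smiles(smiles)
            adj = {a.GetIdx(): [n.GetIdx() for n in a.GetNeighbors()]
                   for a in pose.mol.GetAtoms()}
            seeds = frozenset(
                int(i) for i in rng.choice(pose.n_atoms, size=2, replace=False)
            )
            tagged = TaggedAtomMap({0: seeds}, depth=0)
            out = extend_neighbors(pose, tagged, depth)
            # independent BFS
            expect = set(seeds)
            frontier = set(seeds)
            for _ in range(depth):
                frontier = {n for a in frontier for n in adj[a]} - expect
                expect |= frontier
            assert out.atoms(0) == frozenset(expect)

    def test_monotone_in_depth(self, twin):
        roster, pose, _ = twin
        tagged = tag_atoms(roster, pose, 5.5)
        n0 = extend_neighbors(pose, tagged, 0)
        n1 = extend_neighbors(pose, tagged, 1)
        n2 = extend_neighbors(pose, tagged, 2)
        for r in tagged.residues():
            assert n0.atoms(r) <= n1.atoms(r) <= n2.atoms(r)

    def test_reextension_rejected(self, twin):
        roster, pose, _ = twin
        tagged = tag_atoms(roster, pose, 5.5)
        once = extend_neighbors(pose, tagged, 1)
        with pytest.raises(ValueError, match="already"):
            extend_neighbors(pose, once, 1)


class TestEnvironmentHashes:
    def test_symmetry_equivalent_atoms_collapse(self):
        propane = _pose_from_smiles("CCC")
        # both terminal methyl carbons have identical radius-0 environments
        assert len(environment_hashes(propane, {0, 2}, radius=0)) == 1

    def test_deterministic(self):
        pose = _pose_from_smiles("CCO")
        a = environment_hashes(pose, {0, 1, 2}, radius=1)
        b = environment_hashes(pose, {0, 1, 2}, radius=1)
        assert a == b

    def test_different_centers_differ(self):
        pose = _pose_from_smiles("CCO")
        o_hashes = environment_hashes(pose, {2}, radius=1)
        c_hashes = environment_hashes(pose, {0}, radius=1)
        assert o_hashes != c_hashes

    def test_invalid_atom_index(self):
        pose = _pose_from_smiles("CCO")
        with pytest.raises(IndexError):
            environment_hashes(pose, {99}, radius=1)


class TestFifiBA:
    def test_empty_envs_all_zero(self):
        fp = fifi_ba({}, FifiConfig(), roster_size=8)
        assert len(fp) == 8 * 1024
        assert fp.values.sum() == 0

    def test_single_hash_lands_in_its_block(self):
        fp = fifi_ba({2: frozenset({12345})}, FifiConfig(), roster_size=4)
        (bit,) = fp.on_bits
        assert 2 * 1024 <= bit < 3 * 1024
        assert bit == 2 * 1024 + 12345 % 1024

    def test_collision_or_folds_with_merged_provenance(self):
        h1, h2 = 7, 7 + 1024  # equal mod 1024
        prov = {(0, h1): (frozenset({0}),), (0, h2): (frozenset({1, 2}),)}
        fp = fifi_ba({0: frozenset({h1, h2})}, FifiConfig(), 1, hash_provenance=prov)
        assert list(fp.on_bits) == [7]
        assert set(fp.provenance[7]) == {frozenset({0}), frozenset({1, 2})}


class TestUSVocabulary:
    def test_sizes_and_uniqueness(self):
        cfg = FifiConfig()
        vocab = build_us_vocabulary([{0: frozenset({5, 9})}], cfg)
        assert len(vocab) == 2
        repeated = build_us_vocabulary([{0: frozenset({5, 9})}] * 5, cfg)
        assert len(repeated) == 2

    def test_order_independent(self, small_bundle):
        cfg = small_bundle.config
        roster = small_bundle.roster
        envs = []
        for pose in small_bundle.train_poses[:6]:
            tagged = tag_atoms(roster, pose, cfg.proximity_threshold)
            ext = extend_neighbors(pose, tagged, cfg.neighbor_depth)
            e, _ = residue_env_sets(pose, ext, cfg.environment_radius)
            envs.append(e)
        v1 = build_us_vocabulary(envs, cfg)
        v2 = build_us_vocabulary(envs[::-1], cfg)
        assert v1.pair_to_bit == v2.pair_to_bit

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            build_us_vocabulary([{}], FifiConfig())

    def test_json_roundtrip(self, tmp_path):
        cfg = FifiConfig()
        vocab = build_us_vocabulary([{1: frozenset({3, 8}), 0: frozenset({4})}], cfg)
        path = tmp_path / "vocab.json"
        vocab.to_json(path)
        from fifi.core import USVocabulary

        back = USVocabulary.from_json(path)
        assert back.pair_to_bit == vocab.pair_to_bit
        assert back.config_key == vocab.config_key


class TestFifiUS:
    def test_training_pose_reproduces_one_hot(self):
        cfg = FifiConfig()
        envs = {0: frozenset({11, 22}), 1: frozenset({11})}
        vocab = build_us_vocabulary([envs], cfg)
        fp = fifi_us(envs, vocab, cfg)
        assert fp.values.sum() == 3
        assert fp.layout["coverage"] == 1.0

    def test_unseen_hashes_give_zero_with_coverage_zero(self):
        cfg = FifiConfig()
        vocab = build_us_vocabulary([{0: frozenset({11})}], cfg)
        fp = fifi_us({0: frozenset({99})}, vocab, cfg)
        assert fp.values.sum() == 0
        assert fp.layout["coverage"] == 0.0

    def test_membership_oracle(self, rng):
        cfg = FifiConfig()
        train = [{int(r): frozenset(int(h) for h in rng.integers(0, 50, size=4))
                  for r in range(3)} for _ in range(4)]
        vocab = build_us_vocabulary(train, cfg)
        query = {1: frozenset(int(h) for h in rng.integers(0, 80, size=10))}
        fp = fifi_us(query, vocab, cfg)
        for (r, h), bit in vocab.pair_to_bit.items():
            expected = r in query and h in query[r]
            assert bool(fp.values[bit]) == expected

    def test_config_mismatch_rejected(self):
        cfg = FifiConfig()
        vocab = build_us_vocabulary([{0: frozenset({1})}], cfg)
        other = FifiConfig(neighbor_depth=0)
        with pytest.raises(ValueError, match="mismatch"):
            fifi_us({0: frozenset({1})}, vocab, other)


class TestFeaturize:
    def test_ba_matrix_shape(self, twin):
        roster, pose_a, pose_b = twin
        X, vectors, _ = featurize(roster, [pose_a, pose_b, pose_a], mode="ba")
        assert X.shape == (3, 2 * 1024)
        assert len(vectors) == 3

    def test_us_fit_transform_row_sums(self, twin):
        roster, pose_a, pose_b = twin
        X, vectors, vocab = featurize(
            roster, [pose_a, pose_b], mode="us", fit_vocab=True
        )
        assert X.shape[1] == len(vocab)
        for vec in vectors:
            # one-hot per observed pair: row sum equals unique-pair count
            assert vec.values.sum() == len(vec.provenance)
            assert vec.layout["coverage"] == 1.0

    def test_depth_monotone_set_bits(self):
        _, roster, pose = synthetic.make_random_complex(5)
        bits = []
        for depth in (0, 1, 2):
            fp = pose_fingerprint(
                roster, pose, FifiConfig(neighbor_depth=depth), "ba"
            )
            bits.append(set(fp.on_bits.tolist()))
        assert bits[0] <= bits[1] <= bits[2]

    def test_all_zero_row_for_distant_pose(self, twin):
        roster, pose, _ = twin
        far = pose.translated([0.0, 200.0, 0.0])
        X, _, _ = featurize(roster, [far], mode="ba")
        assert X.sum() == 0

    def test_se3_invariance(self, rng):
        for seed in range(3):
            _, roster, pose = synthetic.make_random_complex(seed)
            R = synthetic._rotation(rng)
            t = rng.uniform(-20, 20, size=3)
            roster2 = type(roster)(
                residues=roster.residues,
                residue_coords=[c @ R.T + t for c in roster.residue_coords],
                residue_atom_names=roster.residue_atom_names,
                cutoff=roster.cutoff,
            )
            pose2 = pose.transformed(R, t)
            for mode in ("ba",):
                a = pose_fingerprint(roster, pose, FifiConfig(), mode)
                b = pose_fingerprint(roster2, pose2, FifiConfig(), mode)
                assert np.array_equal(a.values, b.values)

    def test_residue_order_sensitivity(self, twin):
        roster, pose_a, pose_b = twin
        fa = pose_fingerprint(roster, pose_a, FifiConfig(), "ba")
        fb = pose_fingerprint(roster, pose_b, FifiConfig(), "ba")
        assert not np.array_equal(fa.values, fb.values)
        # same bits, shifted by exactly one residue block
        shift = 1024
        assert set(fa.on_bits + shift) == set(fb.on_bits.tolist())
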