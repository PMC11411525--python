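# Methods

This note documents the models and procedures implemented in `fifi`, the
parameters that matter, the synthetic data the test suite runs on, and the
numerical and design choices made where more than one reasonable option
existed.

## Binding-site roster

All residue-blocked fingerprints share one layout, fixed by the *pocket
roster*: the ordered list of residues having at least one heavy atom within
a cutoff (default 5.5 Å, the same value as the tagging threshold) of at
least one heavy atom of at least one reference pose. The roster is computed
once, at fit time, from the **training** poses (union over poses), then
persisted (JSON) and reused for every subsequent pose, so training and test
fingerprints are always comparable. Ordering is strict by (chain id,
residue number, insertion code); ties are impossible because residue keys
are unique. Consequences worth knowing:

- The roster is a deterministic, SE(3)-invariant, permutation-invariant
  function of its inputs, and grows monotonically with the cutoff.
- Hydrogens never enter any distance computation: docked poses rarely have
  reliable hydrogen placement. All geometry is heavy-atom, and all distance
  comparisons are inclusive (d ≤ cutoff).
- Alternate locations resolve to the highest-occupancy copy; waters and
  hetero groups are excluded from the roster by default (a flag admits
  non-standard residues).
- Deriving the roster from a single co-crystal ligand instead of all
  training poses is supported by passing that single pose as the reference.

## FIFI generation

Parameters (defaults in parentheses):

| parameter | default | meaning |
|---|---|---|
| proximity threshold τ | 5.5 Å | ligand atom tagged for residue r when min heavy-atom distance ≤ τ. Hydrogen bonds span ≈2.2–4.0 Å, salt bridges <4.0 Å; common contact definitions use 4.5 Å, and ~1 Å margin compensates non-optimized poses. |
| neighbor depth | 2 (N₂) | tagged set grown along ligand bonds by 0/1/2 bonds before hashing. Extension enlarges the *center set*; it does not change any center's environment. |
| environment radius | 1 | maximal Morgan radius of the hashed environments (diameter 2). Identifiers at **all** radii 0..R are included, not only the maximal radius. |
| bits per residue | 1024 | FIFI-BA block width (power of two). |

Environments are computed on the **full ligand graph** with tagged atoms as
centers, which matches standard circular-fingerprint semantics; hashing
excised fragments instead would change identifiers at substructure
boundaries and is not implemented as a fidelity-bearing option. Raw Morgan
hash values are backend-dependent (RDKit version recorded in every
persisted artifact); the portable contracts are the layouts — block offsets
for BA, the explicit vocabulary for US — never the hash values themselves.

FIFI-BA folds by `hash mod 1024` inside the residue block; collisions
OR-fold and the bit's provenance keeps the atom sets of *every* folded
environment. FIFI-US builds a bijection (residue index, hash) → bit over
the pairs observed in training, ordered by residue then ascending hash, so
the vocabulary is independent of training-pose order. At inference, pairs
missing from the vocabulary are dropped silently — a fitted one-hot basis
cannot grow — and a per-pose coverage statistic (matched / observed pairs)
reports the loss. Both encodings are presence/absence bit vectors; no
count-valued variant is provided.

Invariants the test suite enforces: SE(3) invariance (bit-identical under
rigid transforms of the whole complex), N₀ ⊆ N₁ ⊆ N₂ monotonicity of tagged
sets and hence of BA set bits, monotonicity of set-bit count in τ,
determinism, and exact agreement of tagging with a brute-force O(n·m)
distance filter.

## Baseline fingerprints

**ECFP4** is RDKit's folded Morgan fingerprint (radius 2, 2048 bits) with
bit→atom provenance retained.

**PLIF** types contacts per residue with explicit geometric rules: hydrogen
bond = donor/acceptor heavy-atom pair at 2.2–4.0 Å with a donor angle
≥ 120° (largest covalent-neighbor–donor–acceptor angle; a donor without
neighbor geometry passes); ionic = opposite formal/implied charges at
≤ 4.0 Å (LYS/ARG/HIS⁺ vs ASP/GLU⁻ side chains vs ligand formal charges);
surface contact = any remaining heavy-atom pair at ≤ 4.5 Å. Variants:
A binary typed bits, B adds a surface bit, C/D the count-valued analogues.
These rules are a transparent surrogate for energy-based contact perception
in commercial packages; no bit-level fidelity to any such package is
claimed, and π-stacking, halogen bonds, cation–π and water bridges are out
of scope.

**PLEC-style**: for every ligand-atom/protein-atom pair ≤ 4.5 Å, the ligand
Morgan environment and a protein atom identifier are paired at depths
advanced in lockstep (ligand capped at 2, protein at 4) and folded into
7653 bits. Our protein structure carries no bond graph, so protein atom
environments are identified by (residue name, atom name, depth); this
deliberately excludes chain and residue number, making the fingerprint
residue-order-blind — exactly the property the twin-residue contrast test
exploits. This is a faithful-in-spirit simplification used as an
order-blind baseline, not a clone of the published implementation.

## Screening workflows

- **Similarity search**: max Tanimoto (|a∧b|/|a∨b|, 0/0 := 0) to the
  training actives.
- **Sequential hybrid**: keep ⌈f·n⌉ compounds by descending similarity
  (f = 0.01 by default; ties broken by stable input order), re-rank the
  kept set ascending by docking score (lower = better), append the rest by
  similarity. With f = 1.0 this reduces exactly to docking-rank. The choice
  to rank the filtered-out compounds at all (rather than discard them) keeps
  the output a total ranking, which AUPRC needs.
- **Consensus**: elementwise product of the ligand-model and
  structure-model probabilities; a uniform structure channel preserves the
  ligand ranking.
- **Classifiers**: logistic regression, linear/RBF SVM, SVM with a
  Tanimoto-kernel Gram matrix, random forest — all seeded, all exposing
  `predict_proba`. Default hyperparameters are fixed and sensible
  (RF: 200 trees); `tune=True` runs a small 5-fold CV grid
  (`fifi.screening.TUNING_GRIDS`) on the training set only.
- **AUPRC** is average precision (sum of precision over recall increments),
  not trapezoidal PR interpolation: it is standard, conservative, and
  well-defined under ties (tied scores enter as one group, so constant
  scores give exactly the prevalence). It is invariant under strictly
  monotone transforms of the scores. Note that the *mean* AUPRC of random
  rankings carries a small positive finite-n bias above prevalence; tests
  compare against the Monte-Carlo spread, not against prevalence alone.
- **IC50 binning**: values are ranked (ties share the lower rank, hence the
  lower bin), split into 25 equal-count bins with bin 1 = most potent;
  bins 1–7 → active, 11–25 → inactive, 8–10 dropped to remove marginal
  compounds. With 100 distinct values this yields exactly 28/60/12.
- **Scaffold diversity**: unique Bemis–Murcko frameworks among the true
  actives in the top-k (default 100) ranked compounds; all acyclic
  molecules share one empty-framework class.

## Tree SHAP and atom attribution

The attribution module ships its own **path-dependent TreeSHAP** for
sklearn decision trees and random forests: absent features descend both
children weighted by training cover, so the background distribution is the
one recorded in the tree, and local accuracy (Σφ + base = model output)
holds exactly. The implementation is verified against a brute-force
conditional-expectation Shapley enumeration on small trees and against the
model's own `predict_proba` for additivity.

Atom mapping: each bit's SHAP value is split **equally** among the atoms in
the union of its provenance environments and accumulated per atom; bits
with no atom provenance (absence-encoding information, e.g. unset FIFI-US
bits) accumulate into a molecule-level remainder, never onto atoms. Equal
splitting is the conservative choice — it assumes nothing about which atom
of a substructure carries the signal — and makes the decomposition exactly
conserving (Σ_atoms + remainder = Σ_features, tested to 1e-6). For
residue-blocked layouts the map can be restricted to one residue's block,
and the per-residue maps partition the global map exactly.

## Synthetic data: what it emulates and what it does not

The `synthetic` module generates the complete study: pockets of minimal
residues (backbone N/CA/C/O plus one or two side-chain pseudo-atoms with
correct elements and PDB atom names), poses placed so that planted
atom–residue distances hold to ±0.01 Å (verified post hoc by brute force),
and labeled screening sets in which actives dock a carboxylate oxygen
2.8–4.9 Å from a pocket lysine while inactives either lack the group or are
pushed outside the 5.5 Å shell. Docking scores are drawn from overlapping
normals (actives −8.0 ± 1.5, inactives −5.5 ± 1.5, lower = better):
informative but noisy, like a real scoring function. Default study sizes:
160 training compounds (prevalence 0.25), 500 test compounds
(prevalence 0.10), positional noise σ = 0.1 Å. Everything is a pure
function of the seed, down to byte-identical PDB/SDF text.

What passing tests show: the pipeline is wired correctly end to end — a
geometric signal planted in the poses is carried through tagging, hashing,
encoding, model fitting, and attribution without loss. What they do not
show: performance on real docking data. Real poses have conformational
noise correlated with chemistry, residues move, actives do not share one
literal anchoring group, and prevalences are far lower. The planted-signal
AUPRC of 1.0 is a *recoverability ceiling by construction*, not a
performance claim.

The label-permuted control permutes **training** labels and retrains. Its
AUPRC sits slightly above the 0.10 prevalence on average because a random
permutation still assigns the active label to ~25% truly active training
compounds, leaving residual signal; the control is therefore compared
against its own Monte-Carlo spread rather than against prevalence exactly.

## Numerical choices and degenerate inputs

- Tanimoto 0/0 := 0; AUPRC requires both classes and raises otherwise.
- `sequential_screen` raises when a kept compound lacks a docking score.
- Tagging of a pose with no atom near any residue yields an empty map and
  an all-zero fingerprint row (valid, not an error); an empty roster is an
  error.
- Re-extending an already neighbor-extended tag map is rejected, as is
  transforming with a vocabulary built under a different configuration
  (threshold/depth/radius recorded in the vocabulary key).
- Quantile binning needs at least as many values as bins (25).
- All randomness is seeded; derived seeds stay below 2³¹.

## Known limitations

- Protein-side environments in the PLEC-style fingerprint ignore protein
  connectivity (no bond graph is read from the PDB).
- PLIF donor-angle checks degrade gracefully (pass) when neighbor geometry
  is unavailable; with full structures they are always evaluated.
- mmCIF input, multi-model NMR structures beyond the first model, water- or
  cofactor-mediated contacts, and count-valued FIFI are not supported.
- The CLI exchanges matrices as Matrix Market text, which is verbose for
  very large screens; the library API returns `scipy.sparse` matrices
  directly.
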