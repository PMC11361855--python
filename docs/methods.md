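# Methods

`cycloperm` predicts the log10 membrane permeability (cm/s) of head-to-tail
cyclic peptides from structure alone.  The model combines three levels of
molecular description — atoms, residues (monomers) and the whole molecule —
in one fusion network, and expands every peptide into multiple augmented
"replicas" during training and inference.  This note records the model, the
parameter choices, the numerical decisions, and what the synthetic-data
experiments do and do not demonstrate.

## Molecule handling

A peptide enters as a SMILES string (optionally with a HELM-style monomer
sequence resolved against a monomer library CSV).  Records must parse to a
single connected molecule with at most 128 heavy atoms — the padding frame
all atom-level features share.

**Monomer division.**  Residue-level features require cutting the macrocycle
into monomers.  Only backbone amide `C(=O)–N` and ester `C(=O)–O` single
bonds that lie inside the largest SSSR ring (ring size ≥ 9) are cleaved;
bonds outside the macrocycle — including side-chain amides — are never
touched, so each monomer keeps its side chain intact.  Naively hydrolysing
the backbone would create a free amine and a carboxylic acid, i.e. new
hydrogen-bond donors/acceptors the intact peptide does not have, so cut ends
are capped: the amine nitrogen (or ester oxygen) receives a methyl group and
the acyl carbon becomes an aldehyde.  Units are ordered N→C around the ring
starting from the unit containing the atom of lowest canonical rank, which
makes the cyclic order deterministic without any database annotation.  A
record that carries an explicit monomer annotation bypasses structural
division (the synthetic generator uses this to expose ground truth).

**Conformers.**  3D features come from distance-geometry embeddings
(ETKDGv3, seeded) of the hydrogen-complete molecule, energy-minimized with
UFF (at most 200 iterations — bounded runtime on pathological macrocycles).
Embedding is retried up to 5 times with a random-coordinate fallback.
Conformer *k* of a request uses seed `base_seed + k`, so ensembles are
bit-reproducible.  Only heavy-atom coordinates are retained; all downstream
features are heavy-atom-only.

## Features

**Atom level.**  Heavy atoms are nodes with 30 features in six one-hot
blocks plus two flags: atom type (C, N, O, S, F, Cl, Br, other), heavy
degree (1–4, other), hydrogen count (0–4), formal charge (−1, 0, +1, other),
hybridization (sp, sp2, sp3/other), chirality (none, CW, CCW), in-ring,
aromatic.  Three N×N relation matrices accompany them:

- `Bond`: 0 for non-bonded pairs, otherwise aromatic 1.5, triple 3.0,
  double 2.0, conjugated single 1.4, single 1.0.  Conjugation upgrades only
  single bonds; aromatic/double/triple bonds keep their order weight — the
  weight table lists both "double" and "conjugated" categories without a
  precedence, and this resolution avoids downgrading a double bond (2.0) to
  1.4.
- `Graph`: all-pairs shortest path lengths on the bond graph.
- `Conf`: Euclidean distances (Å) from one conformer.

The two distance matrices are converted to Strength matrices by inverse-
distance attenuation: 1 on the diagonal, `1/d` off it.  3D distances can
fall below 1 Å in principle, which would give strengths above 1; they are
clipped to 1 so Strength is always a [0, 1] attention attenuator.  A zero
off-diagonal distance between distinct atoms is treated as a degenerate
geometry and raises.  Everything is padded to a fixed frame (128 by default;
dataset assembly trims the frame to the cohort's largest molecule) with a
boolean mask.

**Monomer level.**  Each monomer's capped fragment is described by the same
16 descriptors as the whole peptide (below), giving an L×16 matrix in cyclic
order, zero-padded to a maximum of 12 residues.

**Peptide level.**  16 whole-molecule descriptors plus a 2048-bit Morgan
fingerprint (1024 bits at radius 2 concatenated with 1024 bits at radius 3).

**The 16 descriptors.**  Seven topological and nine conformation-dependent
descriptors, dominated by lipophilicity, density and charged-surface terms.
Descriptors defined only in unavailable commercial software are replaced by
documented open equivalents:

| name | computed as |
|---|---|
| Vsa_EState9 | RDKit `VSA_EState9` (E-state-weighted van der Waals surface bin) |
| density | MW ÷ group-contribution van der Waals volume (Zhao-style atomic increments with bond/ring corrections) |
| MolLogP | Wildman–Crippen logP |
| fr_Al_OH | aliphatic hydroxyl count |
| logP_ow | Wildman–Crippen logP recomputed on the hydrogen-explicit graph |
| lip_violation | Lipinski rule-of-five violation count from computed MW/logP/HBD/HBA |
| h_logD | Crippen logP minus one unit per group ionizable at pH 7 (carboxylic acids, non-amide amines) — a distribution-coefficient surrogate |
| dens | MW ÷ convex-hull volume of the conformer (3D density) |
| FNSA2/FNSA4/FNSA5 | fractional charged partial negative surface areas, Stanton–Jurs style: PNSA_k ÷ total SASA with PNSA2 = (Σ SASA over q<0 atoms)·Q⁻, PNSA4 = (Σ SASA over q<0)·(Q⁻/n⁻), PNSA5 = (Σ q·SASA over q<0)/n⁻ |
| RNCS | SASA of the most negative atom × its charge fraction of Q⁻ |
| FASA_neg | SASA fraction of negatively charged atoms |
| FCASA_pos | charge-weighted SASA of positive atoms ÷ total SASA |
| FAsa_P | SASA fraction of polar (N, O, S) atoms |
| vsurf_Wp2 | polar-volume surrogate: Σ vdW sphere volumes of N/O/S atoms |

Partial charges are Gasteiger (hydrogen contributions folded into heavy
atoms); per-atom surface areas come from FreeSASA on the heavy-atom
conformer with elemental vdW radii.  These surrogates preserve each
descriptor's meaning and ordering behaviour, not the numerical values of the
original software — matching those is explicitly out of scope.

Descriptor tables are standardized by Z-score with statistics frozen on the
training rows (population standard deviation).  The strict standardizer
rejects zero-spread columns; the featurization pipeline instead maps a
cohort-constant column to exactly 0 (unit scale), since e.g. rule-of-five
violations are legitimately constant across single residues.  Monomer rows
are standardized jointly across all sequence positions with a single
standardizer — position-wise statistics would break under the rotation
augmentation.

**Descriptor selection.**  The pipeline that produced the 16-descriptor set
is implemented and testable on any tagged descriptor pool (the package ships
a ~220-descriptor RDKit pool): (1) drop constant columns, (2) for pairs with
|Pearson r| ≥ 0.9 — processed in descending |r|, ties by column order — drop
the member less correlated with the labels, (3) rank survivors by
impurity-based random-forest importance (500 trees, fixed seed), fitted
separately on the 2D and 3D blocks, and keep the top k of each.  Pearson
correlation is used throughout.

## Augmentation

Each peptide becomes R replicas (default 60) sharing its label; replica k
combines three coupled transformations:

1. **Atom order**: a seeded random atom renumbering (an enumerated SMILES
   rendering) permutes the node rows and relation matrices.
2. **Conformers**: a fresh seeded conformer of the peptide (new `Conf`
   matrix and 3D peptide descriptors) and of every monomer (new monomer
   descriptors).
3. **Sequence arrangement**: the L×16 monomer matrix is cyclically rotated
   and translated within the 12-row frame.  Arrangements are drawn uniformly
   without replacement from the L × (12 − L + 1) grid, then with replacement
   once the grid is exhausted.

Replica 0 is always the identity rendering (canonical order, first
conformer, untranslated sequence), so a 1-replica run is plain
featurization.  Per-replica seeds derive from (run seed, peptide id,
replica index) — monomer conformer seeds from (run seed, capped monomer
SMILES, replica index), which makes monomer descriptor work cacheable across
peptides sharing a residue — so featurization is reproducible independent of
dataset order.  At inference the per-replica fusion outputs of a peptide are
averaged.

Note that highly symmetric molecules (benzene being the canonical example)
can render identically under every atom renumbering; the augmentation still
permutes the underlying feature matrices deterministically.

## Model

**Atom branch** — a structure-enhanced transformer.  Inputs are embedded as
`x = (Node·W_node + Bond·W_bond) / sqrt(d_model)`: the bond matrix acts as a
relative positional encoding added to the node embedding.  Two parallel
encoder blocks share this input; one attenuates attention with the
graph-distance Strength, the other with the 3D-distance Strength.  Each
layer computes multi-head attention in which the post-softmax attention
probabilities are multiplied element-wise, per head, by the Strength matrix
(without renormalization), followed by residual + layer norm, a feed-forward
net, and a second residual + layer norm.  Padded keys receive −1e9 scores
before the softmax, and padded rows are re-zeroed after each layer.  The
element-wise reading of the strength product is the default because it
implements "attenuate attention between distant pairs" literally at the
probability level; the alternative reading — left-multiplying the block
output by Strength — is available as `strength_mode="matmul"`.  The two
block outputs are masked-mean-pooled over atoms, weighted λ_g and (1 − λ_g),
concatenated, and projected to the atom latent.  Mean pooling is used as the
readout because it is the simplest mask-safe choice.

**Monomer branch** — stacked 1D convolutions over the monomer-descriptor
sequence (kernel 3), ReLU, with either zero padding (`plain`) or circular
padding (`cyclic`, treating the sequence as a closed loop), masked global
mean pooling, and a linear head.  All conv layers share one width so their
pooled outputs can be averaged for the layer loss.  `plain` is the default
(circular padding has not proven stronger in practice); `cyclic` is exactly
rotation-invariant at full frame length.

**Peptide branch** — two MLPs, one over the standardized 16 descriptors and
one over the fingerprint, concatenated and projected to the peptide latent.

**Fusion** — the three latents are concatenated and passed through a shared
MLP to the scalar prediction.  Only the fusion output is used at inference.

**Losses.**  The training objective is

    Loss = L_fusion + γ_sub·(L_atom + L_monomer + L_peptide)
                    + γ_layer·(L_layer_a + L_layer_m + L_layer_p)

with γ_sub = 0.10 and γ_layer = 0.05.  Sub-model losses attach linear
scalar heads to each branch latent; layer losses attach linear heads to the
mean of each branch's per-layer pooled outputs.  All seven component losses
are mean squared error (the regression default).  The auxiliary heads keep
gradients flowing into every branch of the deeper network.

**Optimization.**  Adam (lr 1e-3 default, the CLI recovery runs use 3e-3),
batches of shuffled replica rows (replicas are independent training rows),
optional early stopping on validation MAE with best-weight restoration.
The networks run on a small vectorized reverse-mode automatic-
differentiation core written on numpy (float32 by default; float64
switchable), whose gradients are verified against central finite differences
in the test suite.  Default widths are deliberately desk-scale (d_model 64,
4 heads, 2 layers per block, conv channels 32/32, latent 32) and fully
configurable; the bundled experiments use smaller instances noted below.

## Dataset preparation

Labels are clipped to [−8, −4]: −8 is the common assay detection floor and
−4 the ceiling.  Clipping is idempotent.  The test set is selected by the
classic Kennard–Stone procedure on Morgan fingerprints (seed with the
maximum-distance pair, then greedily add the sample maximizing the minimum
distance to the selection) — deterministic, ties toward the lower index.
Validation folds are random, mutually disjoint, and disjoint from the test
set; the training pool for fold i is everything except the test set and
fold i.  Standardizers are fitted on training rows only; the test suite
checks that refitting with held-out rows included would change held-out
features (the leakage guard).

## Synthetic data

The generator emulates a permeability database cohort: head-to-tail
macrocycles of 5–12 residues drawn uniformly from a 26-monomer alphabet
(14 natural L-amino acids with small/medium side chains, 6 N-methylated
variants, 6 D variants), assembled by condensation and cyclization, capped
at 128 heavy atoms (oversized draws are resampled).  The ground-truth label
is

    label = clip(−6.5 + 0.8·z(logP) − 0.5·z(TPSA) − 0.4·z(HBD) + ε, −8, −4)

with ε ~ N(0, 0.3²) and z-scores over the generated cohort.  The drivers
(lipophilicity up, polar surface area and H-bond donors down) mirror the
descriptor families that dominate passive membrane permeation, which makes
the recovery experiment meaningful: a model that cannot read lipophilicity
out of the features cannot reach the noise floor.  The noise level (0.3 log
units) is on the order of the measured inter-laboratory variability of
PAMPA values for repeatedly measured peptides.

What the synthetic experiments show: that the pipeline is internally
consistent end to end — features carry the signal, the fusion model recovers
a known monotone structure–label relationship near its noise floor, and
replica augmentation improves training at small sample sizes.  What they do
not show: real assay heterogeneity, activity cliffs from single-residue
changes, conformation-dependent permeability mechanisms (the label function
is conformer-independent by construction), or transfer to measured data.

## Problem sizes and numerical choices

- Capacity check: 32 peptides, 200 epochs, train MAE < 0.1 (memorization
  sanity bound).
- Recovery: 500 peptides (noise 0.3), Kennard–Stone 10% held out, three
  training seeds on one shared featurization; the acceptance script runs a
  220-peptide single-seed variant to stay lightweight.
- Augmentation direction: 36 peptides (24 in the script), five (three)
  seeds, identical split, 1-replica vs 5-replica training, compared on
  replica-ensemble held-out MAE.
- Experiment model instance: d_model 32, 2 heads, 1 layer per block,
  conv channels 16/16, peptide hidden 32, latents 16, lr 3e-3.
- Engine float32; invariance tests that assert at 1e-6 or tighter run the
  engine in float64.
- Tie-breaks: correlation pruning processes pairs by descending |r| then
  column order; Kennard–Stone resolves ties toward the lower index; RF
  importance ties resolve by column order.

## Known limitations

- The SSSR-macrocycle division rule is an approximation for exotic linkers;
  topologies beyond head-to-tail amide/ester backbones (disulfides,
  side-chain stapling) are out of scope.
- Gasteiger/FreeSASA-based surface descriptors are rank-faithful surrogates,
  not reproductions of commercial descriptor values.
- Conformer ensembles come from distance geometry + UFF; no MD or enhanced
  sampling, so the 3D channel underrepresents the conformational ensembles
  relevant to membrane permeation.
- Training is CPU-bound numpy; the desk-scale defaults are sized for
  hundreds, not thousands, of peptides.
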