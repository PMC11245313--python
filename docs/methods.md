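# Methods

This note documents the models, the data pipeline, the synthetic
benchmark, and the numerical and design choices behind `gep`.

## Problem setting

Given the unbound structures of an antibody and an antigen, predict for
every residue of each molecule the probability that it belongs to the
binding interface of the complex: the epitope on the antigen and the
paratope on the antibody.  Interface prediction is a heavily imbalanced
binary classification problem (typically well under a quarter of
residues bind), and the geometry of the two molecules carries most of
the usable signal: binding requires complementary shapes, and the
binding region of the antibody is concentrated in the localized
complementarity-determining regions (CDRs) while the epitope can sit
anywhere on the antigen surface.

## Data representations

Both model families consume the same parsed structures, so their
outputs are directly comparable.

**Residue graph (inner structure).**  Nodes are residues, placed at the
alpha-carbon (centroid fallback when CA is absent).  Each node connects
to its at most 15 nearest neighbours within a 10 Å radius; the directed
kNN selection (ties broken by residue order) is symmetrized by adding
reverse edges, since spatial adjacency is not an inherently mutual
relation under a kNN rule.  Node features are 28-dimensional: a 21-way
one-hot over the 20 standard amino acids plus an "unclassified" slot,
followed by seven physicochemical scalars per amino-acid type (steric
parameter, polarizability, volume, hydrophobicity, isoelectric point,
helix and sheet propensity), standardized to zero mean and unit variance
over the 20 types.  Unclassified residues get zero scalars.

**Surface (outer structure).**  The built-in sampler approximates the
solvent-excluded surface: every atom sphere inflated by the 1.4 Å water
probe is covered with a near-uniform golden-spiral point set, candidates
inside any other inflated sphere are rejected (unreachable by the
probe), and survivors are pulled back to van der Waals contact along the
local normal.  van der Waals radii ship as a small JSON table.  An
externally meshed surface (OFF/PLY) can be supplied instead and takes
precedence.  Each surface point is assigned to the residue owning its
nearest atom (ties to the earlier atom in file order); that assignment
transfers residue features onto points and later averages per-point
predictions back to residues.  Residues with no surface points are
scored 0 and flagged buried — non-exposure implying non-binding — and
evaluation can exclude them.

**Labels.**  A residue is an interface residue iff any of its heavy
atoms lies within 4.5 Å of a heavy atom of the partner.  The 4.5 Å
heavy-atom cutoff is the common convention in the interface-prediction
literature; it is configurable, and enlarging it can only add positives
(monotonicity, property-tested).

## Spectral geometry

On a triangle mesh the Laplacian is the cotangent stiffness S (PSD,
zero row sums) with a barycentric lumped mass M; zero-area triangles
are dropped.  On a raw point cloud, S is a symmetric kNN graph
Laplacian with Gaussian weights exp(−d²/σᵢσⱼ) (per-point bandwidth σᵢ =
mean kNN distance) and mass σᵢ², a local-area proxy.  The generalized
eigenpairs S φ = λ M φ are computed densely below ~200 points and by
shift-invert Lanczos above, with a retry at a different shift before
failing; eigenvector signs are fixed (first nonzero entry positive) so
cached bases are bit-reproducible.  The default truncation is K = 128
eigenpairs (or P−1 if smaller); the synthetic benchmark uses K = 32 on
its ~190-point surfaces.

Geometry is rescaled to unit total surface area before the
eigendecomposition, so diffusion times are comparable across proteins
of different sizes.  The Heat Kernel Signature uses 16 log-spaced times
in [0.01, 1] on that normalized scale, each channel optionally (default
on) normalized to unit mass-weighted mean.  Heat diffusion of a signal
is Φ diag(e^(−λ tᶜ)) Φᵀ M applied per channel; at t = 0 it is the
K-band-limited projection, it conserves the mass-weighted mean exactly,
and it is a contraction in the mass norm — all property-tested.

HKS and heat diffusion depend only on intrinsic distances, hence are
invariant under rigid motions and reflections and degrade gracefully
under small perturbations; this is what makes the intrinsic-input
surface models robust to conformational change.

## Models

All trainable components run on a small in-package reverse-mode
autograd engine over numpy arrays (`gep.nn`), gradient-checked against
finite differences.  Training uses an in-package Adam.

**I-GEP.**  Two structural encoder variants: (a) `gcn_xyz` — one
symmetric-normalized graph convolution over the 28 features concatenated
with the molecule-centered, RMS-normalized 3D coordinates, followed by
batch norm, ReLU and dropout; translation-invariant by centering but
deliberately not rotation-invariant; (b) `en_invariant` — one
E(n)-invariant message-passing layer, mᵢⱼ = MLP(hᵢ ‖ hⱼ ‖ ‖xᵢ−xⱼ‖²),
hᵢ' = MLP(hᵢ ‖ Σⱼ mᵢⱼ), with coordinates never updated, so the output is
exactly E(3)-invariant per molecule.  Cross-molecule fusion is a
two-layer multi-head graph attention on the **complete bipartite graph**
between the antibody scope (the CDR mask when provided, otherwise all
antibody residues) and the whole antigen; attention normalizes over each
node's in-neighbourhood, heads are averaged, ELU follows.  Per molecule,
the structural output and both GAT layer outputs are concatenated into a
fully connected head with a sigmoid.  Defaults: hidden 32, 4 heads,
dropout 0.1, one structural layer — layer widths were an open design
choice and are configurable.

**O-GEP.**  Input features per surface point concatenate, in fixed
order, the 28 physicochemical channels, optionally the centered
RMS-normalized xyz, and optionally the HKS channels; at least one block
must be enabled.  The PointNet-style geometric module uses a learned
3×3 input transform on the xyz channels and a learned feature transform
(both initialized at the identity), a shared per-point MLP for local
features, and channel-wise max pooling for the global vector (max
pooling makes the global feature permutation- and
duplication-invariant).  The diffusion module lifts inputs with an MLP
and applies diffusion blocks — per-channel learned diffusion times
(softplus-parametrized, initialized at t = 0.1) through the spectral
operator, then a pointwise MLP with a residual connection.  The local
representation is the output of one block; the global representation
mass-weight mean-pools a linear projection after n blocks (default 4).
Spatial-gradient features are not part of the block: the diffusion +
pointwise-MLP core is sufficient here and keeps the module strictly
intrinsic.  The segmentation module — shared between the two molecules —
concatenates each point's local features with both proteins' global
vectors and applies a stack of width-1 convolutions (pointwise MLP)
ending in a sigmoid.  Geometric-module weights are shared between
antibody and antigen, so swapping the argument order exactly swaps the
outputs.

**Training.**  Class-weighted binary cross-entropy with w₊ = N₋/N₊,
computed per dataset by default ("global"); a single-class batch in
"batch" mode falls back to the global weight with a warning.  The loss
maps probabilities into [ε, 1−ε] by an affine squash rather than a hard
clamp so gradients survive saturated sigmoids.  Optimizer: Adam,
lr 5·10⁻³ for the benchmark models, no weight decay.  Optional
augmentation applies an independent Haar-uniform rotation to each
molecule per step.  One complex is one batch.  With a validation set,
the checkpoint with the best mean validation MCC is kept; otherwise the
final epoch.  Every randomness source (init, dropout, augmentation,
shuffling) derives from explicit seeds; fixed seed and data give
bit-identical runs.

**Evaluation.**  MCC at threshold 0.5 is the headline metric (no
threshold tuning), with AUC ROC and AUC PR (average-precision
summation, no interpolation) alongside; single-class label sets yield
MCC 0 with a flag and undefined AUCs.  Multi-seed results report mean
and standard deviation.  Ensembles combine aligned per-residue
predictions by elementwise mean or product.  Robustness is the 1D
Wasserstein distance between per-complex metric distributions on
original versus perturbed structures.

## Synthetic benchmark

The generator emulates desk-scale antibody–antigen complexes: each
molecule is a self-avoiding random chain (CA step 3.8 Å, persistent
direction) with N/C backbone stubs and a CB dummy per residue, 30–45
residues per molecule.  A 10-residue stretch of the antibody is grown
antiparallel to a stretch of the antigen, approaching perpendicular to
it from outside the chain's bulk, and the antibody is then translated so
the closest heavy-atom approach equals the configured contact distance
(3.5 Å by default), giving a realistic extended interface of roughly
8–10 residues per side; labels follow from the same 4.5 Å proximity rule
as real structures.  The learnable signal is compositional: interface
residues re-draw their amino acid from {TRP, PHE, MET, ILE} with
probability 0.9 — echoing the aromatic/hydrophobic enrichment of real
antibody interfaces — while the background is uniform over the 20 types.
Surfaces (256 target points), spectral bases (K = 32) and HKS are built
by the same pipeline as for real data; splits are 70/15/15 by seed.

What passing tests show — and what they do not: the benchmark verifies
that every pipeline stage is correct and that the models can recover a
planted, chemically plausible signal end to end (held-out MCC well
above the 0.3 floor, versus ≈0 for a shuffled-label control).  It does
not demonstrate performance on real antibody–antigen complexes, which
have secondary structure, rotamers, sequence statistics, and far larger
surfaces; results on the synthetic benchmark are upper-bounded by a
deliberately learnable generator, not by biology.

Benchmark problem sizes (chosen to keep a full run in minutes on one
CPU core): 60 complexes, 10 epochs, 3 seeds, ~190 surface points and
~38 residues per molecule.

## Numerical choices and degenerate inputs

* Graph construction tie-breaks by (distance, residue order); exact
  distance ties are therefore deterministic.
* Alternate-location atoms keep the highest-occupancy conformer
  (missing occupancy = 1.0); heteroatoms, waters, and all models beyond
  the first of multi-model entries are dropped.
* Isolated graph nodes are legal (message aggregation contributes
  zero); an empty antibody scope is an error.
* Degenerate (zero-area) triangles are dropped before the cotangent
  assembly; an all-degenerate mesh is an error, as is a surface
  sampling that rejects every candidate point.
* Eigen-solver non-convergence retries with a shifted operator before
  failing loudly; NaNs anywhere in a forward pass raise immediately.
* Probabilities written to disk are validated to [0, 1] and printed
  with six decimals; file round-trips are exact to 10⁻⁶.

## Known limitations

* The numpy engine is single-threaded and keeps dense per-molecule
  tensors; it is sized for hundreds of residues / a few thousand
  surface points per molecule, not for proteome-scale screening.
* The PointNet-style module's spatial transformer promotes but does not
  guarantee rigid-motion invariance; exact invariance is only available
  through intrinsic inputs (HKS without xyz) or the E(n) graph variant.
* Surface chemical features (electrostatics, hydrophobicity maps) and
  mmCIF input are out of scope; the bundle format records provenance so
  such channels could be added without changing the models.
* CDR scopes are taken from explicit residue ranges in the manifest; no
  antibody numbering scheme is imposed, and an empty specification uses
  the whole antibody.
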