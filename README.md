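# gep — geometric epitope and paratope prediction

`gep` predicts the binding residues of an antibody–antigen pair — the
**epitope** on the antigen and the **paratope** on the antibody — from the
3D structures of the two molecules, using two complementary geometric
views of each protein:

* **Inner structure (I-GEP):** a residue interaction graph (nodes =
  residues, edges = the ≤15 nearest neighbours within 10 Å) processed by
  graph neural models.  The structural encoder is either a graph
  convolution over physicochemical features plus centered 3D coordinates,
  or an *E(n)-invariant* message-passing layer that sees only
  inter-residue distances ‖xᵢ − xⱼ‖² and is therefore exactly invariant to
  rotations, translations and reflections of either molecule.  Antibody
  and antigen then exchange information through a two-layer bipartite
  graph attention (GAT) fusion, and per-residue probabilities come from a
  fully connected head over the concatenated embeddings.
* **Outer structure (O-GEP):** a sampled solvent-excluded surface (1.4 Å
  water probe) whose points inherit their residue's 28-dim
  physicochemical features.  A geometric module — PointNet-style (spatial
  transformer, shared per-point MLP, max pooling) or diffusion-based
  (learned-time spectral heat diffusion on the surface Laplacian, working
  identically on meshes and point clouds) — produces local per-point and
  global per-protein features; a shared segmentation stack of width-1
  convolutions emits per-point binding probabilities, averaged per
  residue afterwards.  The **Heat Kernel Signature**
  HKS(p, t) = Σᵢ e^(−λᵢ t) φᵢ(p)² over the Laplace–Beltrami eigenpairs
  (λᵢ, φᵢ) can be concatenated as an intrinsic, perturbation-stable
  geometric descriptor.

Training uses class-weighted binary cross-entropy (interface residues are
a small minority), Adam, optional random-rotation augmentation, and
evaluation by Matthews correlation coefficient (MCC) with AUC ROC /
AUC PR, aggregated across random seeds.  Predictions of the two families
can be ensembled by the per-residue mean or product.  A robustness
harness measures the 1D Wasserstein shift of the per-complex MCC
distribution when structures are perturbed (conformational change or
reconstruction-error proxies).

The package is aimed at structural bioinformaticians studying
antibody–antigen recognition and at method developers who want a
self-contained, dependency-light re-implementation of graph- and
surface-based binding-site prediction with a common data pipeline for
both representations.  All neural components run on a small in-package
numpy autograd engine — no GPU or deep-learning framework required.

## Worked example

Train both model families on synthetic antibody–antigen complexes (two
self-avoiding pseudo-residue chains posed at 3.5 Å contact, with a
hydrophobic-enriched interface as the learnable signal) and score
held-out epitope predictions:

```python
import numpy as np
from gep import (IGepClassifier, OGepClassifier, SynthConfig,
                 generate_dataset, evaluate)
from gep.training import ensemble_combine

manifest, samples = generate_dataset(30, SynthConfig(seed=0))
train = [samples[c] for c in manifest.split_ids("train")]
test = [samples[c] for c in manifest.split_ids("test")]

igep = IGepClassifier(variant="en_invariant", epochs=10, seed=0).fit(train)
ogep = OGepClassifier(geometric_variant="diffnet", use_hks=True,
                      epochs=10, seed=0).fit(train)

for name, clf in [("I-GEP (E(n))", igep), ("O-GEP (diffusion)", ogep)]:
    preds = clf.predict_proba(test)
    p = np.concatenate([pr["antigen"] for pr in preds])
    y = np.concatenate([s.ag_labels.per_residue for s in test])
    r = evaluate(p, y)
    print(f"{name:18s} epitope MCC {r.mcc:.3f}  AUC ROC {r.auc_roc:.3f}  "
          f"AUC PR {r.auc_pr:.3f}")

combined = [ensemble_combine(a, b, "mean")
            for a, b in zip(igep.predict_proba(test), ogep.predict_proba(test))]
p = np.concatenate([c["antigen"] for c in combined])
y = np.concatenate([s.ag_labels.per_residue for s in test])
r = evaluate(p, y)
print(f"{'ensemble (mean)':18s} epitope MCC {r.mcc:.3f}  AUC ROC {r.auc_roc:.3f}  "
      f"AUC PR {r.auc_pr:.3f}")
```

Output:

```
I-GEP (E(n))       epitope MCC 0.695  AUC ROC 0.942  AUC PR 0.889
O-GEP (diffusion)  epitope MCC 0.735  AUC ROC 0.968  AUC PR 0.923
ensemble (mean)    epitope MCC 0.749  AUC ROC 0.962  AUC PR 0.918
```

Both families recover the planted interface signal well above chance
(MCC 0 would be chance level), the surface model edges out the graph
model on the epitope, and averaging the two gives the best MCC —
the models are complementary.

The same pipeline is scriptable from the shell:

```bash
gep synth --n 30 --seed 0 --out data/           # generate bundles
gep train --bundles data --model igep --out ckpt/
gep predict --bundle data/synth0000.npz --checkpoint ckpt/igep_en_invariant_seed0.npz --out pred.tsv
gep evaluate --bundles data --checkpoint ckpt/igep_en_invariant_seed0.npz --split test
```

Real structures enter through `gep prepare`, which reads PDB files and a
JSON manifest (antibody chains, antigen chains, train/val/test split) and
writes the same bundle format, so graph and surface methods always
consume identical inputs.

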