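# bdekit

Homolytic bond dissociation enthalpies (BDEs) for organic molecules
built from C, H, O and N — enumerated from 2D structure, predicted by a
directed-edge message-passing neural network, and applied to two
weakest-bond screening problems.

## The problem

The BDE is the enthalpy change at 298 K of the gas-phase homolysis

    A–B  →  A·  +  B·         BDE = ΔH(A·) + ΔH(B·) − ΔH(A–B)

Bond strengths govern radical chemistry: the weakest C–H bond of a drug
correlates with its site of cytochrome-P450 oxidation, and the weakest
bond of a fuel molecule determines the radicals that seed soot
formation.  Quantum-chemical BDEs take hours per molecule; a trained
graph network answers in milliseconds, which makes forward screening
over thousands of candidates possible.  `bdekit` is for computational
chemists and cheminformaticians who need fast per-bond BDE estimates
with an interpretable trust signal.

## What is inside

* `bdekit.chem` — cleavage enumeration on the explicit-hydrogen graph:
  every acyclic single bond is homolyzed, fragments are canonicalized,
  symmetry-equivalent cleavages are deduplicated, and cleavages that
  would create a new stereocenter are omitted (their enthalpy is not
  single-valued in a 2D representation).
* `bdekit.featurize` — categorical atom/bond classes (element,
  chirality, aromaticity, ring-size bucket, degree, H count) and two
  directional edges per bond.
* `bdekit.model.BDEPredictor` — a scikit-learn style estimator: six
  message-passing blocks over 128-dimensional states with batch
  normalization and residual connections; a linear head on the final
  edge state added to the per-bond-class mean BDE; masked MAE loss over
  directed edges; ADAM.  Implemented directly in numpy with verified
  analytic gradients.
* `bdekit.neighbors.BondEmbeddingIndex` — PCA (128→10) over final-layer
  bond embeddings plus Euclidean nearest-neighbor search: a prediction
  whose neighbors are similar bonds with consistent BDEs can be trusted.
* `bdekit.thermo` — BDE assembly from species enthalpies, Boltzmann
  conformer averaging, covalent-radii connectivity checks, the
  composition outlier screen, and convergence-flag filtering.
* `bdekit.applications` — the weakest-bond site-of-metabolism
  classifier (tolerance-sweep ROC) and the radical-fragment sooting
  tendency (YSI) regression (weighted least squares, leave-one-out CV).
* `bdekit.synthetic` — random valence-valid molecules plus a
  deterministic graph-local BDE oracle, so the whole pipeline is
  testable without any quantum-chemistry data.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

Train on a synthetic corpus and predict the bonds of isopropanol:

```bash
bdekit synth --n-train 2000 --n-dev 250 --n-test 250 --seed 1 \
       --out bde_data.csv
bdekit train --data bde_data.csv --model-out model.bdekit \
       --epochs 85 --batch-size 64 --lr 4e-3
bdekit predict --model model.bdekit --smiles "CC(C)O"
```

The prediction output (one row per bond of the explicit-hydrogen
graph; ring and multiple bonds are excluded) is:

```
parent_smiles,bond_index,bond_type,bde_pred
CC(C)O,0,C-C,86.39
CC(C)O,1,C-C,86.39
CC(C)O,2,C-O,89.95
CC(C)O,3,C-H,99.57
CC(C)O,4,C-H,99.57
CC(C)O,5,C-H,99.57
CC(C)O,6,C-H,97.90
CC(C)O,7,C-H,99.57
CC(C)O,8,C-H,99.57
CC(C)O,9,C-H,99.57
CC(C)O,10,O-H,101.88
```

`bde_pred` is in kcal/mol.  Symmetry-equivalent bonds get identical
values (the two C–C bonds, the six methyl C–H bonds), the methine C–H
(bond 6) is distinguished from the methyls, and each prediction is the
average of the bond's two directed-edge scores.  The training command
above prints its best validation MAE (1.17 kcal/mol on this corpus);
held-out accuracy against the noiseless oracle is near 1.1 kcal/mol
(recomputed exactly by the acceptance script below).  To see which
training bonds support a prediction:

```bash
bdekit neighbors --model model.bdekit --corpus bde_data.csv \
       --smiles "CC(C)O" --bond 3 --k 10
```

```
rank,parent_smiles,bond_index,bde_kcal_mol,bond_type,distance
1,CC(N)CC(C)O,15,99.38,C-H,1.157
2,CCC(N)CC(C)O,18,99.38,C-H,1.161
3,CC(O)COC(C)(C)C,8,99.38,C-H,1.167
...
```

All ten neighbors are methyl C–H bonds adjacent to a carbinol carbon
with consistent BDEs — the prediction interpolates familiar chemistry
and can be trusted.

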