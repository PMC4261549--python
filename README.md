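# vitabind

Sequence-based prediction of protein–vitamin binding residues.

Vitamins (A, the B complex, pyridoxal-5'-phosphate, …) act as cofactors
for a large share of enzymes, and knowing *which residues* of a protein
contact the vitamin matters for annotating function and engineering
binding sites. Solved complexes are scarce, so the practical route is
prediction from sequence alone. `vitabind` implements a full pipeline
for this task:

1. **Features.** Each residue is described by a sliding window of size
   W = 17 over three tracks: the logistic-normalized PSI-BLAST PSSM
   (17 × 20 = 340 values), PSIPRED coil/helix/strand probabilities
   (17 × 3 = 51), and per-amino-acid binding propensities estimated from
   training labels (17 × 1 = 17) — a 408-D vector.
2. **Subspace selection.** Feature columns are scored by data variance,
   the Fisher score, the Laplacian score, and a joint Laplacian
   feature-weights learner whose sparsity parameter ε (default 0.5)
   sizes the selected subspace automatically.
3. **Ensemble.** One RBF C-SVM (Platt-scaled scores) is trained per
   subspace; the ensemble score is the unweighted mean of the member
   scores, and residues with score strictly above a threshold T are
   called binding.
4. **Evaluation.** Sn, Sp, Acc, MCC and AUC; T is chosen either to
   balance Sn and Sp or to maximize MCC; cross-validation runs at the
   residue level or the honest sequence level (whole sequences held
   out), with out-of-fold scores pooled before one global threshold is
   applied.

A synthetic-data module generates complete datasets (FASTA, PSSM, ss2,
labels, in the exact on-disk dialects) with plantable propensity,
profile and leakage signals, so everything here runs without downloads
or upstream tools.

## Worked example

```sh
vitabind simulate --out-dir demo --n-sequences 8 --min-length 20 \
    --max-length 30 --seed 5
vitabind train --fasta demo/sequences.fasta --pssm-dir demo/pssm \
    --ss2-dir demo/ss2 --labels demo/labels.txt --model-out demo/model.joblib \
    --selectors fisher --subspace-k 100 --fixed-c 8 --fixed-gamma 0.03125 --seed 1
vitabind predict --fasta demo/sequences.fasta --pssm-dir demo/pssm \
    --ss2-dir demo/ss2 --model demo/model.joblib --out demo/pred.tsv
head -3 demo/pred.tsv
```

```
sequence_id	position	residue	score	call
syn0000	1	W	0.023077	0
syn0000	2	D	0.023133	0
```

Each row is one residue: its 1-based position, the ensemble score in
[0, 1] (here low — the first residues of this synthetic protein are not
binding), and the binary call at the model's stored threshold. A
cross-validated evaluation of the same data:

```sh
vitabind cv --fasta demo/sequences.fasta --pssm-dir demo/pssm \
    --ss2-dir demo/ss2 --labels demo/labels.txt --out demo/cv.json \
    --cv-level sequence --folds 2 --selectors fisher \
    --fixed-c 8 --fixed-gamma 0.03125 --seed 5
```

writes Balanced and MaxMCC reports (TP/TN/FP/FN, Sn, Sp, Acc, MCC, AUC,
chosen threshold) plus a `.roc.tsv` of score/label pairs for plotting.

The same pipeline is available as a library (`vitabind.generate_dataset`,
`build_feature_matrix`, `train_ensemble`, `cross_validate`, …); see
`docs/methods.md` for the model, parameter and design details.

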