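# protdesc

Fixed-length protein descriptors and SVM sum-rule ensembles for
sequence-based protein classification.

Many protein attributes — subcellular localization, fold class,
DNA-binding, virulence — are predicted from sequence by (1) mapping each
protein to a fixed-length numeric descriptor and (2) training a
general-purpose classifier on it. No single descriptor wins everywhere,
so practical systems fuse many of them. `protdesc` is a library and CLI
for that workflow: it implements the descriptor catalogue spanning five
protein representations and combines per-descriptor support vector
machines by the weighted sum rule.

**Representations.** The amino-acid sequence `P = (p1, ..., pN)`; the
N x 20 position-specific scoring matrix (PSSM) of a PSI-BLAST profile
(`PSSM(i,j) = Σ_k w(i,k)·Y(j,k)` from a frequency-ratio matrix and a
substitution matrix; the `blastpgp -Q` text format is parsed directly);
the substitution-matrix representation (`SMR(i,j) = M(p_i, j)`); the
property response matrix (`PRM(i,j) = index(p_i,d) + index(p_j,d)`)
and the continuous Meyer-wavelet scalogram of the property-encoded
sequence, both treated as grayscale images; and the C-alpha distance
matrix `DM(i,j) = ||Coor_i − Coor_j||` from a PDB structure.

**Descriptors.** From the sequence: amino-acid composition (20),
2-grams (400), quasiresidue couple (1200), autocovariance
pseudo-composition (40), AAIndexLoc (65), global encoding (40),
physicochemical 2-grams (800), reduced-alphabet n-grams
(400/225/512/125/64), split composition (60), discrete-wavelet (52).
From any N x 20 matrix: average blocks (400), single average SA/SAN
(400), lag autocovariance (300), pseudo-PSSM (320), singular values,
2-D DCT (400), profile bigrams/trigrams (400/8000). From any
matrix-as-image: rotation-invariant LBP histogram-Fourier (176) and
blur-robust local phase quantization (512), globally or on three
subwindows (528/1536).

**Ensembles.** Each descriptor trains an RBF SVM ([0,1] normalization
and grid search on training data only; one-versus-all for multiclass);
class-posterior scores are combined as `Σ_c w_c · score_c`. The fixed
recipes

    FUS1 = 2·AAS(AC) + 2·PSSM(SAN) + 4·PSSM(PP) + PSSM(LHF_G)
           + PSSM(BGR) + PSSM(TGR) + SMR(PP) + SMR(BGR)
    FUS2 = FUS1 + 2·DM(LPQ_G)

are provided, along with 10-fold cross-validation and holdout protocols
that audit train/test isolation. See `docs/methods.md` for the full
model description and numerical choices.

## Worked example

Classify a synthetic two-class benchmark (100 proteins, disjoint
composition biases) with the hydropathy autocovariance descriptor:

```python
import numpy as np
from protdesc import (SyntheticSpec, two_class_dataset, run_protocol,
                      pooled_auc, bundled_property_table)
import protdesc.seq_descriptors as sd

spec = SyntheticSpec(n_per_class=50, seed=42)
records = two_class_dataset(spec)
labels = np.array([r.label for r in records])

prop = bundled_property_table()[0]          # Kyte-Doolittle hydropathy
table = np.vstack([np.asarray(sd.autocovariance(r, prop)) for r in records])
print(f"feature table: {table.shape[0]} proteins x {table.shape[1]} features")

res = run_protocol([table], labels, protocol="cv10", seed=42,
                   c_grid=(2.0, 32.0, 512.0),
                   gamma_grid=(2.0**-7, 0.125, 2.0))
print(f"10-fold CV accuracy: {res.accuracy:.3f}")
print(f"10-fold CV one-vs-all AUC: {res.auc:.3f}")
print(f"pooled out-of-fold AUC: {pooled_auc(res, labels):.3f}")
```

Output:

```
feature table: 100 proteins x 40 features
10-fold CV accuracy: 1.000
10-fold CV one-vs-all AUC: 1.000
pooled out-of-fold AUC: 1.000
```

The two classes draw their residues from disjoint halves of the
alphabet, so a composition-based descriptor separates them perfectly:
every fold classifies its held-out proteins correctly (accuracy 1.000)
and the ranking of the fused scores is perfect (AUC 1.000). On a
bias-free dataset the same pipeline stays at chance (AUC ≈ 0.5) — see
the test suite's end-to-end recovery checks.

From the shell, the same machinery is available as:

```sh
protdesc extract proteins.fasta -d ac --property-id KYTJ820101 -o ac.tsv
protdesc train ac.tsv --labels labels.tsv --seed 1 -o model.joblib
protdesc predict ac.tsv --model model.joblib -o scores.tsv
protdesc evaluate scores.tsv --labels labels.tsv
```

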