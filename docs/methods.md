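# Methods

`protdesc` implements a catalogue of fixed-length protein descriptors and a
weighted-sum-rule SVM ensemble for sequence-based protein classification.
This note records the model, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Representations

A protein `P = (p1, ..., pN)` over the 20 canonical amino acids (kept in
alphabetical one-letter order `A C D E ... Y`) is mapped to one of five
numeric representations:

* **PSSM** — the N x 20 position-specific scoring matrix of a PSI-BLAST
  profile search. The package parses the `blastpgp -Q` text format (the
  log-odds block by default; the percentage block is selectable) and can
  also build a PSSM from a frequency-ratio matrix `w` and a substitution
  matrix `Y` as `PSSM(i,j) = Σ_k w(i,k)·Y(j,k)`. Running PSI-BLAST itself
  is out of scope.
* **SMR** — the substitution-matrix representation: row `i` is the
  substitution-matrix row of residue `p_i`. Any 20 x 20 matrix is accepted;
  named matrices (DAYHOFF, PAM250, BLOSUM62, ...) are loaded from
  biopython.
* **PR** — the property response matrix
  `PRM(i,j) = index(p_i,d) + index(p_j,d)` for a physicochemical property
  `d`, treated as a grayscale image. Images larger than 250 per side are
  shrunk to 250 x 250 by bilinear interpolation (never upscaled).
* **WAVE** — the continuous Meyer-wavelet scalogram (scales 1..100) of the
  property-encoded sequence `PP(i) = index(p_i, d)`. `pywt.cwt` does not
  offer the Meyer family, so the transform uses the standard
  integrated-wavelet convolution algorithm on PyWavelets' discrete-Meyer
  samples: resample the antiderivative of ψ at each scale, convolve, and
  differentiate. When a scalogram feeds an image descriptor its width is
  capped at 250 columns by the same resize rule as PR.
* **DM** — the Euclidean distance matrix of the ordered C-alpha backbone
  (first model of a PDB file; highest-occupancy altloc kept).

Physicochemical properties are AAindex-style scales (20 values, one per
amino acid). Scales whose values are all 0/1 are excluded as indicator
scales. The bundled table (`data/aaindex_synthetic_subset.txt`) is a
30-entry synthetic stand-in in AAindex format — one genuine hydropathy
scale plus seeded synthetic scales — sufficient for every
property-parameterized descriptor; real analyses should point the loader
at a full AAindex file. Property selection for ensembles is a seeded
draw (`select_random_properties`); the seed is recorded in all outputs.

Non-canonical residues (B, J, O, U, X, Z) are flagged and excluded from
every counting descriptor and property lookup; the effective length `N`
counts canonical residues only. This keeps all normalizations
well-defined without inventing property values the scales do not contain.

## Descriptors

From the sequence: amino-acid composition (20), 2-grams `h(i,j)/N` (400),
quasiresidue couple for orders m = 1..3 (1200), autocovariance
pseudo-composition (20 composition values + 20 lag terms), AAIndexLoc
(20 + 20 + 25), global encoding over six physicochemical classes (40 at
the default segmentation depth), physicochemical 2-grams (800),
reduced-alphabet n-grams (400/225/512/125/64 for alphabets A1..A5), split
amino-acid composition over N-terminus / middle / C-terminus (60), and a
four-level biorthogonal discrete-wavelet descriptor (52).

From any N x 20 matrix: average blocks (400), single average with an
optional sigmoid normalization (SA/SAN, 400), column autocovariance at
lags 1..15 (300), pseudo-PSSM (320), singular values, the top-left 20 x 20
block of the orthonormal 2-D DCT (400), and profile 2-/3-grams
(BGR 400, TGR 8000).

From any matrix-as-image: LBP histogram Fourier (176 = 138 + 38 for
(P,R) = (16,2) and (8,1)) and local phase quantization (512 = 2 x 256 for
window radii 3 and 5), each globally or on three horizontal bands
(LHF_L 528, LPQ_L 1536).

Numerical choices worth stating:

* **Dispersion σ_d** of a property is the mean squared deviation of its 20
  values (no square root), matching the autocovariance normalization this
  descriptor family historically uses; `sqrt_sigma=True` selects the
  standard-deviation variant.
* **Pseudo-PSSM row standardization** divides by the root-mean-square
  deviation of the row (a z-score). A `strict_printed_formula` flag
  divides by the mean squared deviation instead, for bit-level comparison
  with implementations that inherited that form. Zero-variance rows map
  to zero rows with a warning rather than erroring, since constant rows
  occur in short profiles.
* **Average blocks** places block boundaries at `round(z·N/20)`, which
  guarantees 20 non-empty blocks for any N ≥ 20 and reduces to exact
  5%-blocks when 20 divides N.
* **DW allocation**: 52 = 4 levels x (5 DCT coefficients of the
  approximation + max/min/mean/std of approximation and of detail), with
  a `bior3.3` filter bank and symmetric padding. Requires N ≥ 16.
* **Global encoding** emits, per partition and segment, the frequencies
  of 0s and 1s and the 0→1 / 1→0 transition frequencies. The ten
  partitions pair the subset containing the first class with each
  2-combination of the remaining five classes, lexicographically. A
  `depth` parameter recomputes the measures on nested halves
  (`2^depth − 1` segments) for users who want the higher-dimensional
  variant; the default depth of 1 follows the plain description.
* **SAC** concatenates (N-terminus block, middle, C-terminus block). For
  N ≤ 40 the termini may overlap and the middle is empty; empty regions
  encode as zeros.
* **DCT "first 400 coefficients"** means the top-left 20 x 20
  low-frequency square (row-major), not zigzag order.
* **Texture preprocessing**: matrices are min-max scaled to [0, 255]
  (constant matrices map to mid-gray); LBP additionally quantizes to
  8-bit so thresholding is not driven by float noise. The LPQ filters are
  a Gaussian low-pass and a one-sided Gaussian-derivative band-pass
  defined in the frequency domain (a quadrature pair in space);
  decorrelation is disabled by default for determinism. The local
  variant splits into horizontal bands (sequence-position locality),
  remainder rows to the last band.

## Classification and fusion

Each descriptor table trains its own RBF-kernel SVM. Features are
linearly normalized to [0, 1] using the training rows only (test values
outside the training range are clipped; constant training columns map to
0 so column alignment survives). Hyperparameters come from a stratified
5-fold grid search on the training rows only — cost 2^-5..2^15 and kernel
width 2^-15..2^3 in powers of 4 by default, ties broken toward the
smallest cost then the smallest width. Multiclass is one-versus-all.

Scores are class-posterior estimates (Platt scaling) so heterogeneous
SVMs are commensurable before the weighted sum rule; raw decision values
are available via `use_probabilities=False`. When the internal sigmoid
calibration disagrees with the decision rule on the training data — a
known failure mode of the Platt fit on near-degenerate margins —
scoring falls back to a softmax of the one-versus-all decision values,
which preserves the margin ranking on the same [0, 1] scale.

The fixed fusion recipes are

    FUS1 = 2·AAS(AC) + 2·PSSM(SAN) + 4·PSSM(PP) + PSSM(LHF_G)
           + PSSM(BGR) + PSSM(TGR) + SMR(PP) + SMR(BGR)
    FUS2 = FUS1 + 2·DM(LPQ_G)

and the reduced-alphabet n-gram fusion uses weights (1, 1, 1, 0.5, 0.25)
for A1..A5. A property-parameterized component (AAS(AC)) is itself a
unit-weight ensemble over the selected properties; its component weight
is split evenly across the per-property classifiers so the nested fusion
composes with the outer sum rule.

Evaluation offers accuracy, rank-based binary AUC (ties count one half)
and one-versus-all AUC (unweighted mean of per-class one-vs-rest AUCs),
under two protocols: stratified seeded 10-fold cross-validation and a
declared holdout split. Per fold, the normalizer and the grid search are
refit on the training portion only; an audit log records the row indices
each training-side stage touched, so train/test isolation is assertable.
Besides fold-averaged metrics, the protocol result retains the pooled
out-of-fold score matrix; a single ROC over all held-out samples is the
lower-variance summary used by the synthetic benchmark.

## The synthetic benchmark

The generators produce every input the toolkit consumes: random
sequences from arbitrary 20-symbol compositions, blastpgp-style integer
profiles, ideal line/helix backbones (canonical α-helix geometry: rise
1.5 Å, radius 2.3 Å, 3.6 residues per turn), and a labelled two-class
benchmark. Its defaults are the study conditions of the recovery runs:
100 proteins per class, lengths uniform in [50, 150] (long enough for
every descriptor), and disjoint composition supports — one class draws
from the first ten amino acids, the other from the last ten. The matched
synthetic profile of a sequence is its one-hot encoding scaled to 10
plus integer noise in [−3, 3], clipped to [−10, 10]; this preserves the
sequence/matrix coherence the per-amino-acid grouping descriptors rely
on while mimicking the integer log-odds range of real profiles.

What passing shows: the full pipeline — feature extraction,
training-only normalization and tuning, fusion, cross-validation —
recovers a separable-by-construction composition signal (pooled CV AUC
≥ 0.95 for both the single AAC classifier and the FUS1-style fusion) and
stays at chance on bias-free data. Because a single 100-per-class null
dataset gives a pooled CV AUC with a standard deviation near 0.05, the
chance-level estimate averages five independent null replicates.

What passing does not show: performance on real proteins. The generator
has no evolutionary structure (no Dirichlet-mixture emission, no
homology), no length/composition confounds, and its profiles are
noise-perturbed one-hot matrices rather than alignment-derived PSSMs.
The benchmark validates the machinery, not biological signal.

Demo-scale settings: the recovery runs use a 3 x 3 hyperparameter grid
drawn from within the default ranges and a 5-property AC sub-ensemble.
These are the package's default problem sizes for the reproducible demo
protocol; analyses of real data should use the full grid and a
25-property selection.

## Known limitations

* The WAVE scalogram has ordinary convolution border effects inside the
  cone of influence of each scale; descriptors consuming it see those
  borders.
* LBP-HF rotation invariance is exact only for rotations that map the
  sampling lattice onto itself (multiples of 90°); other angles are
  approximately invariant, as for any discrete LBP.
* LPQ blur robustness is a comparative property (blurred self closer
  than an unrelated texture); it degrades on white-noise images, whose
  energy lives at frequencies blur destroys.
* The SMR ensemble layer uses one fixed substitution matrix per
  component; driving it with a set of matrices is possible by passing
  several bundles but no curated matrix collection ships with the
  package.
* FUS2 requires backbone coordinates and therefore only applies where
  structures exist.
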