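# Methods

## Property table and dinucleotide classes

The fifteen dinucleotide properties (six flexibility parameters `F-roll`,
`F-tilt`, `F-twist`, `F-slide`, `F-shift`, `F-rise`; six structural
parameters `roll`, `tilt`, `twist`, `slide`, `shift`, `rise`; three
thermodynamic parameters `energy`, `enthalpy`, `entropy`) are stored as a
15 x 10 table over the strand-symmetric dinucleotide classes
`AA/TT, AC/GT, AG/CT, AT, CA/TG, CC/GG, CG, GA/TC, GC, TA`. A dinucleotide
and its reverse complement describe the same base-pair step read from the
two strands and therefore share one value; the lookup for all sixteen
dinucleotides is generated from this identity, and a round-trip test pins
every stored number to the shipped CSV. Property indices follow table row
order (`mu = 1` is `F-roll`, `mu = 2` is `F-tilt`, ...), which is the
convention used when naming features.

Values are used as printed by default. `--standardize-properties`
(or `EncodingConfig(standardize_properties=True)`) z-scores each property
row across the ten classes (population standard deviation). The printed
rows live on very different scales — `F-tilt` spans 0.06–0.10 while `twist`
spans 31–37 — so raw covariances of different properties are not
commensurable: any statistic that aggregates or ranks across properties
(the discriminative weight vector in particular) is dominated by the
large-magnitude rows unless the rows are standardized first. The packaged
synthetic benchmark is therefore evaluated with standardized properties,
while the raw table remains the default for single-property work and for
fidelity to the printed values.

## DACC encoding

For a sequence of length `L`, position `i = 1..L-1` (1-based) of the
profile of property `mu` holds the value of the dinucleotide starting at
`i`. With profile mean `P̄_mu` taken over all `L-1` positions:

    DAC(mu, lag)       = Σ_{i=1}^{L-1-lag} (P_mu(i) - P̄_mu)(P_mu(i+lag) - P̄_mu) / (L-1-lag)
    DCC(mu1, mu2, lag) = Σ_{i=1}^{L-1-lag} (P_mu1(i) - P̄_mu1)(P_mu2(i+lag) - P̄_mu2) / (L-1-lag)

The averaging denominator is the number of summands, `L-1-lag`, the
canonical auto-cross covariance normalization. Both orderings of a DCC
pair are distinct features. The feature vector concatenates the DAC block
(property-major, lag-minor) and the DCC block (first property outer,
second property middle, lag inner): `N·LAG + N·(N-1)·LAG = N²·LAG`
features, `1350` at the defaults `N = 15`, `LAG = 6`.

Input handling: case-insensitive A/C/G/T only; `U` and IUPAC ambiguity
codes raise an error naming the 1-based position (batch encoding can skip
such records on request). The minimum length is `L >= LAG + 2` so every
lag has at least one summand. Sequences are encoded as given — no
reverse-complement canonicalization is needed because the property table
is already strand-symmetric at the dinucleotide level.

Two numerical facts worth knowing. A sequence whose steps all fall in one
class (e.g. a homopolymer) has constant profiles and encodes to the exact
zero vector. And because adjacent dinucleotides overlap by one base, the
lag-1 autocovariance has a nonzero population value even for i.i.d. random
sequences; only lags >= 2 compare disjoint dinucleotides and decay to zero
with length. Tests of the "no signal" behavior therefore use lags >= 2.

## PCA reduction

Principal components are those of the sample covariance matrix (divisor
`n-1`) of the mean-centered feature matrix; features are not rescaled
beyond the optional property standardization above. The retained dimension
is the smallest `l` with `(λ_1 + ... + λ_l) / (λ_1 + ... + λ_k) >= w`;
default `w = 0.99`. Each eigenvector's sign is fixed so its
largest-magnitude coordinate is positive, making fitted models
byte-reproducible. With fewer samples than features the fit uses the n x n
Gram matrix of centered rows (identical nonzero spectrum; components
recovered from the left singular vectors), and the total variance is taken
from the trace so the selection criterion accounts for the full spectrum.

## Classifier and discriminative weights

C-SVC with RBF kernel `exp(-gamma ||x - x'||²)`, defaults `C = 2³`,
`gamma = 2⁻³`, solver stopping tolerance fixed at `1e-4` for
reproducibility. Hotspot is `+1` everywhere; a decision value of exactly 0
predicts hotspot. Grid search maximizes mean stratified-CV accuracy over
`log2 C ∈ [-5, 15]`, `log2 gamma ∈ [-15, 3]` (step 2) with ties broken
toward the simpler model (smaller `C`, then smaller `gamma`); folds come
from a seeded shuffle so the search is repeatable.

The discriminative weight vector is `W_j = Σ_i A_i M_ij` with
`A_i = alpha_i y_i` (zero off the support set) and `M` the training
matrix. This applies a linear-kernel weight formula to an RBF model — a
pseudo-linear read-out, not the true kernel gradient — and is used for
ranking by `|W_j|`, sign retained. Weights are computed from a model
trained on the full unreduced matrix so each weight maps to a named
DAC/DCC feature.

Because the solver stops at tolerance `1e-4`, identities that compare two
separate fits (e.g. label-swap antisymmetry of decision values and of `W`)
hold to roughly that tolerance, not to machine precision; tests assert
them at `1e-3`/`1e-4`.

## Evaluation protocols

Jackknife (leave-one-out) and stratified k-fold with a seeded shuffle.
Encoding is sequence-local and computed once; everything that depends on
the training distribution — the PCA projection and the SVM — is refit on
every training split, so no held-out information enters the model that
judges it (an internal guard asserts the train/test index sets are
disjoint). `k = n` is special-cased to single-sample folds, the jackknife
limit, since stratification is undefined there.

Leave-one-out at benchmark scale is made tractable by two exact
reformulations: (a) with PCA, each fold's centered Gram matrix is an
O(n²) update of the full-data Gram matrix, and eigenvalues, training
scores and the held-out sample's scores all come from its
eigendecomposition — algebraically identical to refitting PCA in feature
space (component signs may differ, which the RBF kernel cannot see);
(b) without PCA, the RBF kernel between two rows is fold-independent, so
one kernel matrix serves every fold as submatrices. Tests assert both
paths agree with the explicit naive refit. A `fast_pca_reuse` option
(`--fast-jackknife`) instead fits PCA once on the full data — a mild
leakage deliberately provided, with a warning, to probe how much that
shortcut changes results.

Metrics: `Se = TP/(TP+FN)`, `Sp = TN/(TN+FP)`, `Acc = (TP+TN)/total`,
`Mcc = (TP·TN - FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`, with `Mcc = 0`
when any denominator factor vanishes (the formula is undefined there).
`lag_sweep` evaluates 5-fold accuracy as a function of the maximum lag,
reusing one encoding at the largest lag (a smaller maximum lag is a column
subset) and one fold seed for comparability.

Hyperparameters (`C`, `gamma`, `LAG`, `w`) are fixed before the outer
protocol; they are not re-tuned inside folds.

## Synthetic data generator

Coldspot stand-ins are i.i.d. uniform A/C/G/T. Hotspot stand-ins are
sampled by exponential tilting at the dinucleotide level: choosing the
next base `b` after current base `a` with probability
`∝ exp(eta · z_prev · v(a,b))`, where `v` is the z-scored class value of
`signal_property` for step `ab` and `z_prev` the realized value at the
dinucleotide `signal_lag` positions back. This inflates the autocovariance
of exactly the profile the encoder measures — at the planted property and
lag, plus whatever correlates with them through the property table — and
plants no motif an alignment could find, so class separation exercises the
encoder's stated mechanism and nothing else. `effect_size` scales the tilt
`eta`; at 0 the classes are exchangeable i.i.d. uniform sequences.

Defaults (the packaged study conditions): `signal_property = F-tilt`,
`signal_lag = 3`, `effect_size = 1.0`, lengths uniform in 200–500 nt —
fragment lengths in the range typical of yeast intergenic hot/cold spot
regions, and an effect calibrated (once, before the test suite was frozen)
to give strong but not saturated class separation: at these conditions the
planted `DAC(F-tilt,3)` class-mean difference is several pooled standard
errors, and benchmark-shaped jackknife accuracy is ≈ 0.99. The
`benchmark_shape` preset reproduces the 490 hotspot / 591 coldspot class
sizes of the yeast benchmark for protocol rehearsal at realistic scale.

What the generator does *not* emulate: real yeast base composition and GC
landscape, chromatin or replication-timing covariates, length/class
correlations, or any actual recombination biology. Passing tests therefore
demonstrate that the pipeline detects lag-structured property
autocovariance at realistic problem sizes with correct protocol hygiene —
not that it attains any particular accuracy on real genomes. Published
accuracies on the real yeast benchmark (≈ 82–83% jackknife accuracy, MCC
≈ 0.65, and a 173-dimension PCA at `w = 0.99`) require the original
benchmark FASTA, which is not redistributed here; users with that file can
run the identical protocol via `evaluate --pos ... --neg ...`.

## Numerical choices and degenerate inputs

- Covariance (not correlation) PCA; sample divisor `n-1`; eigenvalues
  clipped at 0; component signs fixed as above.
- The retained-dimension criterion uses the exact trace for total
  variance, so Gram-route and feature-space fits select identically.
- Zero-variance inputs: PCA refuses all-constant matrices; property
  standardization refuses a zero-variance property row.
- MCC zero-denominator convention: 0.
- Ties in `|W|` ranking keep first-seen (stable sort) order.
- Solver: libsvm via scikit-learn, tolerance `1e-4`, shrinking on,
  500 MB kernel cache; training is deterministic given fixed inputs.
- All randomness (generator, fold shuffles) flows from explicit integer
  seeds; no global RNG state is consumed.

## Problem sizes used in the shipped checks

Unit tests run on small fixtures (tens of sequences, lengths 10–500).
The end-to-end power check runs the full 490+591 benchmark-shaped set
(1081 jackknife folds with per-fold PCA+SVM refits, ~5 minutes on one
CPU) plus a 200-sequence signal-free null; the brute-force encoder
cross-check uses 100 random sequences spanning lengths 10–500.
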