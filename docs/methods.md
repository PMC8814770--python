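# Methods

## Lattice model

Icosahedral tailed-phage capsids are enumerated under the generalized
quasi-equivalence framework. For lattice steps h ≥ k ≥ 0 (chirality is not
distinguished), the classic index is T₀ = h² + hk + k²; the hexagonal
lattice has T = T₀ and 60·T₀ major capsid proteins, the trihexagonal
lattice has T = (4/3)·T₀ with an additional 60·T₀ minor proteins in
trimers. T-values are stored as exact rationals (`fractions.Fraction`) and
formatted to two decimals only at output (1.33, 5.33, 9.33, …), so
equality tests and the dual-lattice cases (T = 4 and T = 12 exist on both
lattices) are exact. Enumeration up to T = 60 by default: this covers
T = 52, the largest solved architecture, plus margin for assignment
intervals. Each (T, lattice) pair keeps one canonical representative, the
(h, k) with smallest h then k. Elongated (prolate) shells are not indexed;
"elongated" is a categorical fallback only.

## Allometric genome-to-T model

The model T = b·(G/G₀)^a with G₀ = 1 kbp is fitted by ordinary least
squares after a natural-log transform (ln T on ln G). Natural logs are used
throughout; R² is the coefficient of determination in ln–ln space. The
back-transform is direct (no smearing or small-sample correction): the
model is used as a point predictor whose error is characterized
empirically, not as an unbiased estimator of E[T|G]. The theoretical
exponent for a quasi-spherical shell with constant packaged-genome density
and constant surface per protein is 2/3 (T ∝ R², G ∝ R³); the empirical
exponent on the packaged 37-structure table is 0.713 ± 0.020 (SE), slightly
above 2/3, plausibly reflecting head-full packaging of more DNA than the
nominal genome length in part of the data.

As quality control, fixed-shape two-parameter alternatives (exponential
b·e^(aG), quadratic c₀+c₁G², reciprocal c₀+c₁/G, logarithmic c₀+c₁ln G)
are fitted alongside the power law, with R² and mean signed residual
reported on the T scale for every form; the two-parameter constraint keeps
the comparison like-for-like with the power law.

### Error model

The out-of-sample error is the mean relative error (MRE): for a random
training subset of size n, fit, predict T for the held-out records, average
|T_pred − T_emp| / T_emp. The absolute value is used — a signed mean would
cancel positive and negative residuals and understate the error. Subsets
are drawn without replacement with a caller-supplied seed; the per-n curve
uses vectorized batch OLS so 10,000 replicates per n are cheap. The curve
is summarized by MRE(n) = p·e^(−qn) + w, fitted by robust least squares
(soft-L1 loss — "robust" without a stated loss; soft-L1 is the mildest
standard choice) with non-negativity bounds, and percentile-bootstrap
confidence intervals from resampling the (n, MRE) points. On the packaged
table the curve saturates at w ≈ 0.09 from n ≈ 25, i.e. more structures
are not expected to shrink the error; ~9% is the irreducible margin of the
genome-length route.

### Architecture assignment

A genome's continuous prediction T carries the margin ΔT = T·MRE.
Candidates are the enumerated lattice values inside [T(1−MRE), T(1+MRE)];
the selected architecture minimizes |T_arch − T|, with exact ties broken
toward the hexagonal lattice (the majority among solved structures) and
then the smaller T₀. An empty candidate set yields "elongated". The
inverse map G(T) = [(T/(b(1+MRE)))^{1/a}, (T/(b(1−MRE)))^{1/a}]·G₀ is the
exact preimage of the assignment rule, so membership in the genome range
and candidacy in the assignment agree up to float boundary effects (a
property the tests exercise).

## Genome-length density

Genome-length distributions are strongly multimodal with very different
mode widths, so a single kernel bandwidth is inadequate. The sample is
partitioned into genome-length regions (defaults 17–130, 130–210, 210–270,
270–498 kbp, configurable since the partition is a judgement call); per
region, a Gaussian-KDE bandwidth is chosen by 5-fold cross-validated
held-out log-likelihood over 30 log-spaced candidates in [0.1, 30] kbp
(finer than the narrowest plausible mode, wider than the jumbo-region
spread). Region densities are combined weighted by their sample fraction —
the combination rule is otherwise underdetermined, and sample-fraction
weighting is the choice that makes the mixture a proper density of the
pooled sample — then renormalized to unit trapezoid mass on a 2,048-point
grid extended 3 bandwidths past the data. Peaks are strict local maxima
with prominence above 1% of the maximum density, suppressing float-noise
maxima.

## MCP/T library

Candidate MCPs are CDS features whose `/product` contains "major capsid"
(case-insensitive substring; `/note` is not searched), with genome length
taken as record length / 1000 (topology ignored). External
structural-function confidence scores gate entries at score ≥ 2
(boundary inclusive); entries without scores are excluded with a warning.
Dereplication keeps the first representative of each exact amino-acid
sequence. Labels: phages matching the high-resolution table by name get
the structural T (precedence over the model); all others get the
genome-to-T assignment, with alternative candidate Ts recorded. HK97-fold
validation against structure databases requires external services and
visual inspection and is represented only by an externally supplied
`hk97_validated` flag (default true).

## Similarity (proximity-matrix) classifier

Pairwise similarity is blastp percent identity: thresholds are quoted in
percent, which fixes the interpretation. External all-vs-all blastp
tabular files are read directly (12-column outfmt 6; rows with e-value
> 0.001 dropped; multiple scores per pair symmetrized by maximum). The
self-contained alternative is a Smith–Waterman aligner (BLOSUM62, affine
gaps 11/1, identity over alignment length) with a Karlin–Altschul e-value
filter (λ = 0.267, K = 0.041, the published BLOSUM62-11/1 constants,
threshold 0.001 to match the tabular rule). The e-value filter matters:
without it, short perfect-identity local islands between unrelated
sequences enter the matrix as spurious ~100%-identity pairs, which real
blastp discards.

Prediction is nearest-neighbour: the label of the most similar training
entry at or above the minimum-similarity threshold, no call otherwise.
Ties break toward the smaller T then the lexicographically smaller id, so
evaluation is order-invariant. Evaluation repeats uniform (unstratified)
80/20 splits; coverage is calls/test-size and accuracy is correct/calls,
reported as undefined (NaN) — never zero — when no calls were made.
Relative T difference between paired MCPs uses the smaller T as
denominator (|Tᵢ−Tⱼ|/min(Tᵢ,Tⱼ)), making the statistic unbounded above and
asymmetric, which is the reading that admits very large percentage
differences between distant pairs; the denominator is configurable in
principle but fixed here for determinism.

## Random-forest classifier

Features (22): canonical-residue count, isoelectric point, and the 20
canonical amino-acid frequencies. Ambiguity codes are excluded from both
numerator and denominator (logged). The isoelectric point is computed by
bisection on pH ∈ [0, 14] to |charge| < 1e-4 with the Bjellqvist pKa set,
shipped as an editable data file: positive groups (N-terminus 7.50,
K 10.00, R 12.00, H 5.98) contribute 1/(1+10^(pH−pKa)), negative groups
(C-terminus 3.55, D 4.05, E 4.45, C 9.00, Y 10.00) subtract
1/(1+10^(pKa−pH)). The charge is monotone in pH, so bisection is exact to
tolerance; a brute-force grid scan is the test oracle.

Classes: T-values whose genome ranges (at the reference MRE) overlap
transitively are merged — the genome-length route cannot separate them, so
their label distinction in the library is not trustworthy; all T ≥ 25
collapse into a single jumbo class (too few large genomes); elongated is
its own class. Library labels rounded to two decimals (9.33) match scheme
members (28/3) through a 0.5% relative tolerance.

Forest settings: 250 trees, 4 features per split, depth ≤ 20, minimum leaf
1, minimum split 46, bootstrap, balanced class weights, seeded. A
prediction is correct when the predicted class contains a member T within
the error margin (default 9%) of the entry's library T — measured against
the library T, the most permissive reading — and elongated predictions
must match exactly. Splits whose training part misses a class are
resampled (logged, capped). Accuracy versus training size n (defaults
n_lib·i/20, i = 1..19) is summarized by ACC(n) = g·log₁₀n + h (robust
least squares, bootstrap CIs), inverted as n(A) = 10^((A−h)/g) to project
the library size needed for a target accuracy.

Diagnostics: per-feature permutation (shuffle one test column) and dropout
(retrain without the feature) accuracy deltas; clade profiling flags
features whose clade mean departs from the library mean by more than one
library standard deviation. Clade membership comes from an external
phylogenetic analysis and is consumed as an id list.

## Synthetic data

Generators are pure functions of their seed.

- **Capsid records**: G log-uniform on [15, 500] kbp (the span of solved
  structures); T = b·G^a·e^ε, ε ~ N(0, σ²). Defaults a = 2/3, b = 0.5,
  σ = 0.1 — the theoretical exponent, and roughly the empirical prefactor
  and ln-space scatter of the solved-structure table.
- **Genome mixtures**: Gaussian mixtures truncated to positive values by
  resampling; defaults 40 and 160 kbp, the two densest regions of real
  phage isolate collections.
- **MCP classes** (composition generator): i.i.d. residues from per-class
  composition simplices, lengths Normal (clipped ≥ 30 aa), genome lengths
  back-computed from the class T through the inverse allometric map with
  ±2% multiplicative jitter so that library building round-trips the
  labels. Default profiles: T = 4 / 7 / 19 classes at 330 / 400 / 500 aa
  with A / G / F enrichment — mimicking the observation that length and a
  few residue frequencies carry most of the class signal.
- **MCP families** (ancestry generator): one random ancestor per class,
  members by per-residue substitution at a given rate. Composition classes
  are what the forest exploits but their pairwise alignment identities are
  label-uninformative; families are what the similarity route exploits.
  Real MCP libraries have both structures at once — plus phylogenetic
  autocorrelation, indels, and convergent architectures in unrelated
  clades, none of which are emulated. Passing tests on these generators
  demonstrate that each route recovers the signal it is designed for, not
  that real-library accuracies are reproduced.

## Problem sizes and numerical choices

The error-curve analyses use 10,000 replicates per training size
(batch-OLS vectorization makes these cheap); the test suite trims the
26-point decay curve to 2,000 replicates per n, where the decay-fit R² is
already stable to two figures. Classifier evaluations in the tests use a few random
splits on libraries of ~180 entries, which is sufficient for the
separable/null contrasts being asserted. Degenerate inputs are rejected
loudly: fewer than 3 records or non-positive values for the fit, singular
designs in the alternative-model comparison, empty KDE regions, values
outside all regions, single-class training sets, non-convergent robust
fits (reported with the optimizer's diagnostics).

## Known limitations

- The genome-length route is blind to packaging strategy; its ~9% error
  floor will not improve with more structures.
- Composition features ignore residue order and structure; the forest
  cannot extrapolate to T-numbers absent from its training classes.
- The internal aligner approximates blastp percent identity; scores differ
  in detail (no compositional adjustment, single best local alignment).
- Real-library headline accuracies depend on a curated external MCP
  library and are therefore validated here only through the synthetic
  constructions described above.
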