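# Methods

This note records the modeling choices behind `wdsvr`: the kernels and their
exact conventions, the regression and importance machinery, the synthetic
data generator and what it does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Model

The regression target is the measured affinity itself — K_d in nM for
dissociation-constant data (low K_d = strong binding) or a dimensionless
relative affinity. All sequences in a dataset share one length L; the
kernels are undefined across lengths and the data layer enforces this.

### Weighted-degree kernels

The plain WD kernel of degree d sums position-aligned exact k-mer matches,
k = 1..d, weighted by β_k = 2(d−k+1)/(d(d+1)) (the canonical WD weighting;
Σβ_k = 1, longer k-mers weighted less because they are implied by their
prefixes). A `uniform` scheme (β_k = 1) exists for unit tests.

The shift/mismatch extension sums, for each k, exact-mismatch count
m′ = 0..m, start position i, and displacement s′ = 0..s:

    β_{k,m′} · γ_i · ω_{s′} · ( I[a_k(i+s′) =_{m′} b_k(i)] + I[a_k(i) =_{m′} b_k(i+s′)] )

Conventions fixed here, chosen so the extension degenerates cleanly:

- **Both displacement directions are counted even at s′ = 0**, where the two
  indicators coincide; with ω_s = 1/(2(s+1)) this makes the s = 0, m = 0
  case equal the plain WD kernel *exactly* (enforced by test), which in turn
  makes the reduction chain plain-WD ⊂ shift/mismatch ⊂ restricted coherent.
- **=_{m′} means Hamming distance exactly m′**; the sum over m′ ≤ m supplies
  at-most-m behavior. Mismatch weights decay as β_{k,m′} = β_k λ^{m′} with
  λ = 0.5 by default (configurable in (0, 1]) so exact matches dominate.
- **Window clipping**: both compared windows must lie inside [1, L];
  displaced windows that would overrun are skipped. This is the only reading
  of the shift bound that never indexes past the sequence end.
- **Position weights γ_i default to 1** (no experiment here assigns
  non-uniform positional weight; the hook exists in `KernelConfig`).

The restricted (Round-2) kernel is the same bookkeeping with m = 0, except a
term at (k, i, s′) counts only if the matched string is one of the selected
anchors (k-mer, position i). Equivalently it is an inner product over the
selected anchor-indicator features plus their shift cross-terms; an empty
selection gives the zero kernel.

Every kernel has a literal-enumeration oracle (`naive_*`) in the same
module; the optimized implementations (cumulative-sum window counting over
all pairs at once, per-anchor rank-one accumulation for the restricted case)
are held equal to the oracles to 1e−10 in the suite. Complexity per pair is
O(dLs(m+1)); a full matrix is O(n² dLs(m+1)) and takes well under a second
at n = 400, L = 12, d = 7, s = 1, m = 1.

### Normalization

Cosine (unit-diagonal) normalization K′ = K/√(K_aa K_bb) is available on
every kernel matrix. The pipeline default is:

- **Round 1: normalized.** The dense kernel's scale grows with d; the unit
  diagonal makes C = 1 a reasonable default across the whole grid.
- **Round 2: raw.** The restricted kernel lives on a sparse ~140-feature
  space. Normalizing it is degenerate for sequences carrying no anchor
  (zero self-similarity — a hard error) and distorting for sequences
  carrying few: one incidental anchor would be inflated to unit norm.
  Keeping it raw avoids both; its values are O(1) anyway since Σβ_k = 1.

Both paths remain selectable (`normalize`, `normalize_round2`).

### ε-SVR

The dual problem on the precomputed kernel is solved by scikit-learn's
libsvm backend (tolerance 1e−6, no iteration cap); this package owns the
contract around it: matrix validation, full-length dual-coefficient
bookkeeping, prediction from cross-kernel blocks, and JSON serialization
(coefficients + intercept + kernel config + training sequences, so a saved
model reloads to bit-identical predictions).

C and ε are not meaningfully knowable a priori, so the defaults are
scale-free: C = 1 on normalized kernels and ε = 0.1·std(y). Both are
exposed in `PipelineConfig` and can be added as grid axes.

### Exact linear-weight expansion and importance

For every kernel here, f(x) = Σ_j c_j K(x_j, x) + b is *exactly* linear in
the positional k-mer indicators of x: each kernel term against a fixed
support vector is a finite sum of indicators on x (a mismatch term is the
sum over the exact-Hamming-ball of the support vector's window; a shift term
is an indicator at the displaced position). `linear_weights` materializes
w(k, σ, i) by enumerating those indicators — exact at any (s, m) for raw
kernels, verified to 1e−10 against kernel-space prediction. The only
approximation in the package is for cosine-normalized models, where the
test-side normalizer 1/√K(x,x) varies with x and is replaced by its
training-set mean (refused unless an explicit `approximate` flag is set;
the pipeline sets it for Round-1 importance and logs the substitution).

Positional importance under a uniform i.i.d. background over {A,C,G,T}^L
follows in closed form: a feature (k′, τ, j) overlapping the conditioned
window (k, σ, i) on ov positions contributes
w·(I[τ agrees with σ on the overlap]·4^{−(k′−ov)} − 4^{−k′}), and
non-overlapping features cancel. Q therefore recenters to zero per position
by the law of total expectation (asserted at 1e−9), and the whole matrix
matches brute-force enumeration of all 4^L sequences at small L to 1e−8.
The background is uniform i.i.d. because the flow-cell sequences the data
model emulates are unbiased random DNA; an empirical background would
conflate sequence composition with effect size.

Selection operates on position-anchored pairs (σ, i), not bare strings:
per k, the `n_per_side` (default 10) most Q-negative anchors (expected K_d
drop = affinity gain) are taken first, then the most Q-positive among the
remainder — the two lists cannot collide even under massive ties, and ties
break lexicographically by (k-mer, position), making selection deterministic
and iteration-order-free. At d = 7, L = 12 this yields 140 anchors versus
the 21,844 k-mer species of the full kernel.

## Pipeline protocol

Grid search maximizes mean CV Pearson on the *training* data with one seeded
fold partition shared across grid points (paired comparisons; ties go to the
smaller (d, s, m)). Round-2 search recomputes the Round-1 fit and selection
once per fold and reuses them across the (d, s) grid. In the final CV report
both rounds are refit per fold and all four metrics recorded, together with
SHA-256 fingerprints of each fold's train/test sequence sets and of the
exact set the selection saw — so leakage-freedom is checkable after the
fact, not just asserted. The full pipeline is deterministic given (dataset,
config, seed); there is no other randomness source.

The shipped defaults mirror the published protocol (grid d ∈ [2,9],
s ∈ [0,7], m ∈ [0, min(d,3)], 10-fold CV); that full grid is a
cluster-scale computation, so the `preset_gcn4_hitsflip` configuration pins
the settings reported best for dissociation-constant 12-mer data — Round 1
(d=7, s=1, m=1), Round 2 (d=7, s=0) — and the test suite and acceptance
script run either the preset or small explicit grids. Problem sizes there
(n = 400 landscapes, 10 seeds, 5-fold splits) were chosen as the package's
own desk-scale defaults; they complete in seconds to a couple of minutes.

## PWM baseline

The additive model fits ln K_d (proportional to binding free energy, which
the additivity assumption concerns) by least squares on the n × 4L one-hot
design. The blocks are rank-deficient (each position's four columns sum to
the constant vector), so individual weights are identifiable only up to
per-position offsets; the minimum-norm pseudo-inverse solution fixes the
gauge and the fitted *values* are unique (asserted by gauge-shift test). No
intercept column is added — the blocks already span constants. Predictions
are exponentiated back to the affinity scale before metrics, so comparisons
with the kernel methods are like-for-like.

## Synthetic landscapes

`generate_landscape` draws uniform random DNA and builds
ln K_d = baseline + mono effects + planted k-mer effects + N(0, noise_sd),
then exponentiates and clips to the configured range (clipping is counted
and logged; the presets keep it under 5%). Effects act on the ln scale,
consistent with free-energy additivity — so a landscape built from
mononucleotide effects alone is *exactly* a PWM landscape, giving a sharp
differential test (PWM exact there, beaten when a ≥2-mer interaction is
planted).

Each planted anchor has an `implant_frac`: that fraction of sequences gets
the k-mer written in at the anchor's position (or a random valid position
for anywhere-anchors) before affinities are computed. Pure uniform sampling
would leave a positioned 7-mer with 4^{−7} occupancy — no carriers at
realistic n — whereas real high-affinity datasets are strongly
motif-enriched (a filtered optimal-site set carries its consensus in the
majority of sequences); the implant step reproduces that enrichment.
Whether an anchor *fires* is always decided from final sequence content, so
chance occurrences count.

Presets: `hitsflip_like` (n = 400 12-mers, K_d clipped to [8, 1000] nM
around a 150 nM baseline, noise sd 0.25 on ln K_d, consensus 7-mer TGACTCA
at position 3 with effect −1.0 = 4× the noise sd and implant 0.55, plus the
10-mer TATGACTCAT anywhere at −0.5, implant 0.10) and `mitomi_like`
(n = 300 52-mers, relative scale clipped to (0, 1], an E-box-like CACGTG
anywhere). The generator also returns each sequence's noiseless ln-affinity,
from which the attainable correlation ceiling
√(Var(signal)/(Var(signal)+σ²)) is computed; the pipeline is held to within
0.1 of it in a fixed-seed regression test.

What the generator does **not** emulate: measurement-intensity noise models,
sequence-composition bias, duplicate reads, multiple competing motifs of
graded strength, or flanking-context effects. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
structure under realistic enrichment and noise — not performance on any
particular real assay.

## Numerical and degenerate-input choices

- Kernel matrices are explicitly symmetrized ((K+Kᵀ)/2) before use; PSD is
  checked in tests (smallest eigenvalue ≥ −1e−8 after symmetrization).
- Duplicate sequences are merged on cleaning (mean affinity,
  first-occurrence order); cleaning is idempotent and total.
- "nan"/unparsable affinity tokens load as missing and are dropped by
  cleaning rather than failing the load.
- Affinity filtering is strictly-less-than, matching the "K_d below
  threshold" definition of optimal sites.
- Spearman uses average ranks for ties; correlations of constant vectors
  raise rather than return NaN. RMSRE is returned as a fraction and printed
  as a percentage in reports.
- k-mer statistics count each sequence once regardless of occurrence
  multiplicity; sd is the sample (n−1) standard deviation; a k-mer absent
  from every sequence reports NaN statistics, never zeros.
- All user-facing coordinates are 1-based; 0-based indexing never leaves the
  implementation.

## Known limitations

- Exact importance requires the raw-kernel weight expansion; for normalized
  Round-1 models the training-mean normalizer approximation is used (ranking
  quality is what matters for selection, and the exhaustive-enumeration test
  covers the raw path).
- The restricted kernel anchors k-mers to absolute positions; affinity
  signal occurring at unselected registers of an anywhere-motif is invisible
  to Round 2 except through shift terms.
- Landscapes whose truth takes a few discrete levels cap Spearman well below
  1 for *any* predictor (ties in truth against continuous predictions);
  rank-based evaluation on such landscapes reflects tie structure as much as
  model quality.
- No variable-length support, no FASTQ/SAM input, no suffix-tree kernel
  acceleration (the direct O(dLs) pair contract is fast enough at the
  intended scales), and no reimplementation of external comparison methods —
  externally produced predictions can be scored via the comparison harness.
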