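# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations behind crefkit.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Promoter scanning and the CREF matrix

**Window.**  The proximal regulatory window is the 1501-bp interval from
1000 bp upstream to 500 bp downstream of the TSS in transcription
orientation, including the TSS base itself (1000 + 1 + 500).  For a gene
with several transcripts the TSS is the start of the 5'-most transcript;
transcript ties are broken by lexicographic transcript id.  Internally all
coordinates are 0-based half-open; GFF3 is converted from 1-based inclusive
on read.  Windows clipped at contig edges are kept and flagged.

**Scores.**  Scanning uses the MATCH-style information-weighted similarity:
per-position weight `I(i) = Σ_b f(i,b) ln(4 f(i,b))`, raw score
`Σ_i I(i) f(i, b_i)`, rescaled between the per-position least- and
most-probable bases so the matrix similarity score (MSS) lies in [0, 1] and
the consensus scores exactly 1.  The core similarity score (CSS) restricts
the same quantity to the five consecutive positions of highest information
content.  A pseudocount of 0.01 is added to the base probabilities before
computing `I(i)` so zero-frequency bases never produce `ln 0`.  A window is
a hit when MSS and CSS both clear the active profile's thresholds.

**Thresholds.**  The canonical per-motif MATCH profiles are proprietary, so
profiles are user-suppliable per motif (TSV); the shipped uniform defaults
are `minFN = (MSS 0.70, CSS 0.75)` and `minFP = (MSS 0.90, CSS 0.95)`,
preserving the intended sensitivity ordering (every minFP hit is a minFN
hit).  Numerical results at a given threshold therefore characterise this
implementation, not any external scanner.

**Conventions.**  Both strands are scanned at every position; overlapping
occurrences each count, and a palindromic site counts once per strand.
Windows containing ambiguous bases (N) are skipped, not scored.  A fully
uninformative (uniform) PWM is degenerate: its rescaling range is zero, its
scores are defined as 0, and it can never produce hits.  Genes whose TSS
cannot be resolved (mixed strands/contigs, missing contig) are dropped and
logged; an annotation with no resolvable gene is a fatal error.  The CREI
(incidence) variant binarises counts at > 0.

**Multiplicity quantiles** use the type-1 (inverted-CDF) empirical quantile
rounded half-up, so count summaries stay integers.

## Robust decomposition and eigen-modules

The split `C̃ = C + S` minimises `‖C‖* + λ‖S‖₁` subject to exact equality,
solved by inexact augmented Lagrange multipliers: alternating singular-value
thresholding on `C` and entrywise soft thresholding on `S`, with multiplier
update `Y ← Y + μ(C̃ − C − S)`.  Defaults follow the published IALM
practice and are exposed as knobs: `λ = 1/√max(g, m)`,
`Y₀ = C̃ / max(‖C̃‖₂, ‖C̃‖∞/λ)`, `μ₀ = 1.25/‖C̃‖₂`, growth factor 1.5
(capped at 10⁷·μ₀), convergence when `‖C̃ − C − S‖_F/‖C̃‖_F ≤ 10⁻⁷`,
at most 1000 iterations (non-convergence returns the best iterate with a
flag).  With λ fixed the solution is scale-equivariant:
`rpca(αC̃) = (αC, αS)`.

The SVD of `C` is truncated to the requested depth.  Level 0 — the leading
triplet — is the dense baseline (promoter windows share a large common
motif load) and is excluded from gaps, comparisons and enrichment by
default.  **Polarization** resolves the SVD sign ambiguity: the sign making
the motif-eigenvector's loadings positively skewed (`Σ v³ > 0`) is applied
to the motif vector and propagated to the gene vector so `ρₖ ≥ 0`; an
exactly zero skew falls back to the sign of the largest-magnitude loading,
with label-order tie-breaks; loadings are then sorted descending, ties
again by label.  Polarizing twice equals polarizing once.  Serialized
loadings use `%.17g` and are re-read at round-trip precision so
polarization orders that hinge on near-ties survive a write/read cycle.

## Stability, perturbation theory, and cross-species comparison

The relative distance `d_k = (ρₖ − ρₖ₊₁)/ρₖ` is the normalized gap between
adjacent modules.  For a symmetric perturbation `E` of the motif Gram
matrix `CᵀC`, the first-order expansion of the k-th eigenvector uses
eigenvalue denominators `λₖ − λⱼ` with `λ = ρ²`.  (The corresponding
expansion is sometimes written with singular-value differences
`ρₖ − ρₖ₊₁`; since the expanded vectors are eigenvectors of `CᵀC`, whose
eigenvalues are the squared singular values, the `ρ²` form is the
mathematically standard one and is what this package implements.  The two
differ only by the local scale factor `ρₖ + ρₖ₊₁`, so the inverse-gap law
below is unaffected.)  After normalizing by the local scale, sensitivity
∝ 1/d_k: `sensitivity_curve` verifies this empirically by sweeping a
constructed gap and measuring the mean rotation of the k-th eigenvector
under random symmetric perturbations of fixed spectral norm.  The law
describes intra-pair mixing, so the construction keeps all other levels
well separated and rejects gaps that are not the smallest spectral scale;
within that regime the log–log slope of deviation vs. gap is ≈ −1 and
first-order predictions converge quadratically to an exact eigensolver's
results as ‖E‖ → 0.

Cross-species comparison uses motif-eigenvectors only (species share the
motif universe; gene spaces differ and are never compared directly).  Per
level: Pearson correlation after sign alignment (the second species'
vector is flipped when that makes r positive, and the flip is recorded);
Deming regression with error-variance ratio δ = 1, both axes being loadings
of the same kind; and the rotation angle of species B's level-k vector
within species A's (k, k+1) plane, `atan2(|⟨v, vₖ₊₁⟩|, |⟨v, vₖ⟩|)`, using
absolute inner products (sign-free, hence in [0°, 90°]) with the
out-of-plane fraction `1 − ‖projection‖²` reported separately rather than
folded into the angle.  Classification per level: *conserved* when
r ≥ 0.95; otherwise *saltation* when the focal species' gap d < 0.05 (the
near-degeneracy that licenses a qualitative rotation), else *divergent*.
Both thresholds are configurable.

## Enrichment

Enrichment of a gene set toward a pole of a gene-eigenvector is the
one-sided Wilcoxon/Mann–Whitney rank-sum test of member vs. non-member
loadings.  Ranks are computed on the raw sign-fixed loadings with midranks
for ties (count data make ties likely); the pole selects the alternative
direction, avoiding any double sign handling.  For ≤ 10 members in a
universe of ≤ 30 the null is enumerated exactly by dynamic programming over
doubled midranks (ties handled exactly); larger problems use the normal
approximation with tie and continuity corrections.  A set covering the
whole universe is degenerate with p = 1.  Raw p-values are reported;
Benjamini–Hochberg adjustment is available behind a flag and off by
default.  Unresolvable set members are dropped and counted.

## Repeat-motif (MPA) analysis

An MPA is a motif with at least one hit (either strand) on any repeat
consensus sequence at the active profile.  Pole counts intersect the MPA
set with the top-N motifs of the polarized order; N defaults to 100 and the
positive pole is the default (a both-poles mode is available — which pole
convention best matches any particular published figure is not decidable
from pole counts alone).  Relative change from a reference species is
`100·(focal − reference)/reference`, defined only for positive reference
counts.  Jaccard similarity of two motif sets is `|A∩B|/|A∪B|`, with two
empty sets defined as 1 and flagged.  Repeat intervals are accepted as BED
(0-based half-open) or RepeatMasker `.out` (1-based inclusive, normalized
on read); promoter-overlap flagging requires ≥ 1 bp overlap under half-open
semantics, so adjacent intervals do not overlap.  Cross-species
presence/absence of an insertion is an input annotation, not computed.

## Synthetic data: what it emulates, and what it does not

**Count matrices.**  The planted signal is
`L = Σₖ ρₖ uₖ vₖᵀ ≥ 0` with a dense constant baseline column (level 0) and,
per level, a zero-sum two-pole factor on its own disjoint coordinate block:
a sparse strong positive pole (block/3 entries at +2a) and a spread weaker
negative pole (2·block/3 entries at −a).  This gives exactly orthonormal
factors, positive skew (so polarization recovers the planted orientation),
and entrywise non-negativity whenever pole strengths stay below the
baseline.  Default strengths decrease linearly from 0.45 to 0.20 of the
largest value compatible with non-negativity; the cap at < 0.5 keeps the
signal non-negative even when a species pair rotates a strong pole onto a
negative one at up to 90°.  Observed counts are
`round(max(0, base + S))` where `base` is Poisson with mean `L` (the
natural observation model for occurrence counts; `none` and
rounded-Gaussian are alternatives) and `S` plants exactly
`⌈corruption_fraction·g·m⌉` large positive outliers at seeded positions.
The pre-rounding matrix is returned alongside for exactness checks.

**Species pairs.**  Species B shares A's motif factors except at one
adjacent pair, rotated in-plane by a prescribed angle; the shared spectrum
is adjusted so the pair's relative distance equals the prescribed gap
(applied to both species — the saltation diagnosis reads the gap off the
focal species); B's gene factors are freshly drawn on a permuted block
assignment, since species do not share gene spaces.

**Scenario scale.**  The default scenario (2000 genes × 400 motifs, 6
levels, 40° at pair (4, 5), gap 2%) uses a baseline depth of 51200 counts
per cell.  Depth is an explicit signal-to-noise knob: a 2% gap is by design
maximally perturbation-sensitive, so Poisson sampling noise rotates the
pair by an angle ∝ 1/(d·ρₖ) ∝ 1/√depth, and the default keeps that an
order of magnitude below the planted rotation (the robust L1 fit also
interacts with heteroscedastic count noise at a near-degenerate pair,
shrinking toward smaller recovered angles by an amount with the same
scaling).  Real promoter motif counts are far smaller — order 0–30 — so
passing recovery tests at this depth demonstrates correctness of the
estimator chain, not that a 2% gap is resolvable at biological counting
noise; at realistic depth such a pair is genuinely unidentifiable, which is
the scientific point of the sensitivity law.

**Sequence fixtures.**  Promoter fixtures plant motif consensus sequences
at non-overlapping seeded positions (either strand) in a 1501-bp i.i.d.
background of configurable GC content, and re-draw the background until a
scan of the assembled sequence returns exactly the planted counts for every
library motif — the fixture is sound by construction, and an independent
brute-force scanner in the test suite confirms it.  Repeat-consensus
fixtures follow the same scheme at the set level (planted motifs present,
all others absent).  The random PWM generator draws sharp motifs (dominant
base probability 0.94, length 15) and redraws candidates whose consensus,
at any shifted overlap, would reach the scan threshold under an
expected-background completion — such near-repeats would stall the
rejection loop.  The generator emulates none of the realities of genome
evolution: no indels or substitutions, no transposition mechanism, no
dinucleotide structure, no TSS shifts; passing fixtures show scanner and
bookkeeping exactness, not robustness to genomic complexity.

**Gene sets.**  Enriched sets draw members without replacement with
probability ∝ `((g − r + 1)/g)^(strength·g/100)` for descending rank r:
uniform at strength 0, concentrated in roughly the top 100 ranks at
strength 1.  Null sets draw uniformly.

## Determinism

Every generator takes one explicit seed and touches no global state; the
pipeline writes a manifest with a SHA-256 checksum per output, and reruns
with the same config and inputs are byte-identical.  Derived seeds stay
below 2³¹.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic data
at desk scale: 300 × 120 rank-6 matrices for recovery, 50 promoter fixtures
for scanner exactness, the 2000 × 400 two-species scenario, 200 Monte-Carlo
replicates per gap for the sensitivity law, and 2000 null sets for
enrichment calibration.  These sizes were chosen as the smallest at which
each property is measured comfortably above its sampling noise.

## Known limitations

- TRANSFAC per-motif thresholds being proprietary, only uniform default
  profiles ship; species-level numeric results from the literature that
  depend on those thresholds (and on full genomes) are out of reach and not
  claimed.
- Whether overlapping occurrences of a motif should count separately is a
  convention; they do here.
- The RPCA model treats noise as sparse outliers; under dense
  heteroscedastic count noise the L1 fit slightly biases near-degenerate
  eigenvector pairs (see Scenario scale above).
- Multi-species simultaneous alignment of modules and confidence intervals
  for correlations/angles are not implemented.
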