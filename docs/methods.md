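# Methods

## Model and procedure

The pipeline treats a tumour's substitution catalog as a draw from a mixture
of mutational signatures. A signature is a probability distribution over the
96 strand-normalized trinucleotide substitution classes (the mutated base is
always reported as a pyrimidine; purine references are reverse-complemented
together with their flanks, which makes classification an involution under
strand flips — a property the tests assert). Given a fixed catalog
**M** (96 × S) and a sample's class-count vector **s**, exposures are refit
by non-negative least squares on the raw counts,

    w* = argmin_{w ≥ 0} || s − M w ||²,

and reported both as fitted counts and normalized proportions. NNLS refitting
against a fixed catalog is the standard substitute when the original
de novo factorization (NMF) is not being re-run; de novo extraction is out of
scope here. Each mutation of class *c* in sample *j* is then attributed to
the signature maximizing the posterior p(σ) ∝ w_j(σ)·M(c,σ). Hard argmax
assignment is used because downstream analyses count whole substitutions per
signature; the posterior and runner-up margin are stored so a user can check
sensitivity to soft assignment. Exact ties go to the lowest catalog column
index and are flagged; a class with zero mass under every exposed signature
is attributed uniformly over the exposed signatures and flagged unresolved.

Protein consequences use the standard genetic code only. Classification:
identical translation → silent; mutant stop → nonsense; wild-type stop →
stop-loss; codon 1 Met lost → start-loss; everything else missense. Only
missense ("non-silent, non-terminating") substitutions enter the property
and neo-epitope analyses. Charge is assigned Asp = Glu = −1,
Lys = Arg = His = +1, all other residues 0 (His is treated as fully
positive, ignoring pKa nuance). The hydropathy difference is
KD(wild-type) − KD(mutant) with a positive difference labelled "increase";
this direction is kept literally even though the label is arguably inverted
(the mutant is then *less* hydrophobic) — `label_convention="mut_minus_wt"`
swaps it. The charge delta is mutant − wild-type, in [−2, 2]; a ±2 change
(e.g. Glu→Lys) is classed the same as ±1, with the magnitude retained.

For candidate neo-epitopes a window of up to 17 residues centred on the
mutant position is cut from the mutant protein, clamped at the protein ends
and kept whenever at least 9 residues remain (proteins shorter than 9
residues are rejected with a reason code). All contiguous 9-mers containing
the mutant residue are enumerated — exactly 9 for a full centred 17-mer, at
most m − 8 for a boundary window of length m. The binding model itself is
deliberately external: any object mapping (peptide, allele) → EC50 in nM
plugs in. Bundled are a constant stub, a TSV-backed table predictor, and a
deterministic hash-based pseudo-predictor for tests (log-uniform EC50s,
~1% strong-binder mass per prediction, independent of any biology by
construction — which is exactly what the signature-independence null test
needs). A substitution is a candidate neo-epitope when any peptide × allele
prediction is *strictly* below the 50 nM threshold; the default allele panel
is the ten HLA-A2 alleles 01, 02, 03, 06, 11, 12, 16, 17, 19, 50.

Expression preprocessing: transcripts with more than 20% missing values are
dropped, the remaining transcripts are ranked by variance (missing values
ignored) and the top 5,000 kept, rows are median-centred, samples are
Pearson-correlated pairwise-complete, and the correlation matrix is
hierarchically clustered using uncentred-correlation distance
1 − Σxᵢyᵢ/(√Σxᵢ²·√Σyᵢ²) — the classic Cluster 3.0 metric. The linkage
method is not dictated by that tool choice; average linkage is used here.
Gene-set scores (TIL, MCC) are per-sample means over the set members present
in the matrix, with per-sample missing entries excluded. The "top quartile"
is rank-based — the ⌈n/4⌉ highest-scoring cases, ties broken by stable
sample order with a warning — because the stratification counts cases, not
interpolated percentiles. The 3-group stratification is TIL-top-only /
everyone-else / MCC-top-only; samples in both or neither top quartile fall
in the middle group, a set-logic consequence of the definition.

## Statistics

Cuzick's test for trend across G ordered groups is implemented from its
rank-sum formulation: with pooled mid-ranks over N observations, group
scores lᵢ and rank-sums Rᵢ,

    T = Σ lᵢ Rᵢ,  E(T) = (N+1)/2 Σ nᵢlᵢ,
    Var(T) = (N+1)/12 (N Σ nᵢlᵢ² − (Σ nᵢlᵢ)²) · (1 − Σ(t³−t)/(N³−N)),

z = (T − E)/√Var referred to the standard normal, two-sided by default (a
one-sided alternative is a flag). Group scores default to consecutive
integers; the z is invariant to affine rescaling of the scores, which the
tests assert. Zero variance (all values tied) degenerates to z = 0, p = 1.
The implementation is validated against a hand-computed fixture
(T = 50, E = 42, Var = 14, z = 8/√14 ≈ 2.138), against 10,000-permutation
nulls on random small datasets, and against its type-I error over 2,000
null simulations.

Contingency tables use Pearson's χ²; for 2×2 tables with any expected cell
below 5, Fisher's exact p is promoted to primary and the rule is recorded.
The per-signature association tables report raw p-values deliberately — the
multiple-testing correction in the source design applies to a pathway
screen that is out of scope here — along with per-group mean counts and the
number of carriers; a configurable exclusion list (defaulting to the
historically low-carrier signatures 6, 17, 20, 26, 30, applied only when
present) yields "N.D." rows. "Proportional" mode divides each sample's
counts by its total, which makes results invariant to per-sample load (also
asserted); samples with zero totals are a hard error there.

The logrank machinery accumulates, at each event time, the per-group
observed and expected events and the full hypergeometric covariance of
O − E. The same accumulation yields the standard (G−1)-df χ² test and the
1-df trend test z = c'(O−E)/√(c'Vc) with ordered integer scores c. The
plain logrank is cross-checked against lifelines' `logrank_test` in the
suite; Kaplan–Meier curves and Cox proportional hazards (Efron tie
handling, Wald CIs) are delegated to lifelines, with constant covariates
rejected by name before fitting.

## Synthetic cohorts: what they emulate, and what they do not

The generator's defaults emulate the scale of the motivating cohort: 266
samples, Poisson(100) coding substitutions per sample, symmetric
Dirichlet(1) exposure mixtures (the source data give no distributional
detail for exposures; these are design choices, not data facts) over four
toy signatures — an age-like C>T@NCG profile, APOBEC-like C>T@TCN and
C>G@TCN profiles (≥90% of mass on their motif classes; 95% in the bundled
profiles), and a flat profile — plus an optional broadly-patterned
`brca_like` profile. Mutations are placed only on the coding strand of
synthetic CDS (start codon, no internal stops, GC within ±0.05 of target by
rejection), so consequence annotation is always defined; the analyses only
use coding, non-silent substitutions, so nothing is lost by omitting
introns and intergenic sequence. Planted effects: the MCC module mean
follows total mutational burden (effect 0.8 per SD), the TIL module follows
APOBEC-C>G counts (0.8), the ordinal infiltrate follows a latent Gaussian
with mean 1.0 × standardized APOBEC-C>G charge-increasing count cut at its
empirical tertiles (balanced, deterministic groups), and the hazard is
exponential ∝ exp(0.7·z(MCC) − 0.7·z(TIL)). Censoring is independent
uniform on (0, τ), with τ solved by bisection so the expected censored
fraction equals the configured rate (default 0.3). Missing expression
values are "NA" in TSV, default rate 0. A single integer seed drives all
stages through fixed named sub-streams; identical configs give
byte-identical outputs.

What the synthetic cohorts do *not* emulate: transcription-strand bias,
clustered mutations (kataegis), indels/rearrangements/copy number, realistic
codon usage or gene length distributions, linkage between expression modules
beyond the planted covariates, batch effects, or informative censoring.
Passing tests therefore demonstrate that the machinery recovers planted
structure under its own model assumptions — not that the biological
associations hold in any real cohort.

## Problem sizes and numerical choices

The heavier checks run at fixed, stated sizes: exposure recovery at 50
samples × 2,000 mutations (observed MAE ≈ 0.01 against a 0.05 bound);
attribution accuracy at 30 samples × 1,000 mutations of a well-separated
3-signature catalog (≈ 0.94 against a 0.90 bound); planted-effect power and
null calibration at 100 seeds each of 150-sample cohorts with ~40 mutations
per sample; Cuzick calibration at 2,000 null datasets and 20 permutation
comparisons of 10,000 permutations; the survival layer at 200 replicates of
n = 500 (Cox) and 100 seeds of 3 × 100 (logrank trend). Unit-level
simulation examples use 20–30 seeds. The NNLS grid-search oracle runs on
catalogs restricted to ≤3 signatures and 6 classes with a 10⁻³ simplex
step and closed-form optimal scaling per direction.

Tie-breaks are stable-input-order throughout (burden extremes, quartile
boundaries, variance ranking); catalog columns must sum to 1 within 10⁻⁹;
exposure rows within 10⁻⁸; attribution ties are detected at a 10⁻¹² margin.
An empty mutation table yields an all-zero spectrum with a warning, but an
all-zero spectrum is a hard error for refitting ("no mutations to fit"), as
is a charge-increase trend in which every count is zero after exclusions.

## Known limitations

- Hard-argmax attribution understates uncertainty for samples whose
  exposures overlap on shared classes; the stored posteriors allow
  re-analysis but no soft-count tables are produced.
- The hash pseudo-predictor is a null model, not a binding model; real
  EC50s must come from an external predictor via the table interface.
- The per-substitution deduplication key for neo-epitope analyses is
  (gene, protein position, wild-type, mutant); genomic-position-level
  duplicates collapse only if they agree on that key.
- Whether "increase in hydrophobicity" should mean wt − mut > 0 is
  genuinely ambiguous in the convention adopted; the literal reading is the
  default and the flag documents the alternative.
- `sample_correlation_cluster` computes an O(n²) pairwise-complete distance
  in Python loops; it is intended for cohort-scale (hundreds of samples),
  not single-cell-scale, inputs.
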