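# Methods

This note documents the models implemented in `crisprselect`, the
defaults that matter, what the synthetic data do and do not emulate,
and the numerical choices made where the design was open.

## 1. Amplicon model

An amplicon design is a reference sequence (uppercase ACGT), an ordered
exon/intron tiling in 0-based half-open coordinates, a cut site (a
position *between* bases), and two substitution sets: the mutation of
interest (Mut) and the synonymous internal control (WT*). Protein
positions elsewhere in the package are 1-based, following community
convention. Validation enforces: gap- and overlap-free region tiling,
ref-base agreement for every substitution, cut site inside the
amplicon, and all substitutions within 60 bp of the cut site (the reach
of a single-stranded donor's homology arms). Canonical splice sites are
modeled as the two intronic bases flanking each exon–intron junction
(donor GT / acceptor AG positions in real genes); the package flags
InDels overlapping these dinucleotides but does not claim to quantify
splicing efficiency — that would require transcript-level data.

The built-in `example_design()` gives each template **two** base
changes (the edit plus a PAM/seed-blocking change), as knock-in donors
have in practice. This matters quantitatively: with a single-base
template, a sequencing error at that one position converts an unedited
read into a false knock-in call at rate `error_rate/3`, which biases the
Mut:WT* ratio upward precisely when the Mut arm is depleted (at a
planted per-day fitness of 0.6 and 0.5% error the bias reaches tens of
percent). With two positions, a false call requires two coincident
specific errors (~3 × 10⁻⁶ per read) and the bias is negligible.

## 2. Selection-experiment simulator

Cells are a mixture of diploid genotypes; each genotype has two allele
outcomes (Mut knock-in, WT* knock-in, unedited, or an InDel with a
position and nonzero net length) and per-day growth multipliers
`base_fitness` and `cisplatin_fitness`. Growth is a discrete daily
multiplicative update; the treated condition applies the drug
multiplier on days `(start, end]` of the treatment window (default
days 2–12, so ten drug days separate baseline from endpoint and
`E[R(D12)] = w^10` for a Mut-only deficit `w`). A continuous-time
equivalent is `ln w` per day.

Reads sample *alleles* independently from the pooled genotype mass
(amplicon PCR cannot phase the two alleles of a cell) — multinomially
at the requested depth, or exactly proportional (largest-remainder
rounding) in deterministic mode. Sequencing noise is uniform per-base
substitution only; InDel errors are off. Output is plain 4-line FASTQ
at constant Q37 with the ground truth (genotype trajectories, allele
fractions, closed-form expected R) serialized to JSON. Identical
arguments and seed give byte-identical FASTQ.

The default genotype mixture (`standard_select_mix`) reflects the
editing-outcome structure of the assay: knock-in on one allele paired
with a cut-site InDel on the other (18% Mut, 18% WT*), InDel/InDel
(38%), unedited/InDel (16%), unedited/unedited (10%) — 82% of alleles
modified, consistent with the >80% editing efficiency such experiments
achieve. The per-genotype proportions are parameters, not claims; the
intron-guide variant places the second-allele InDel in the intron
(single-allele editing), leaving one coding-intact allele.

What the simulator does **not** emulate: PCR duplicates and chimeric
templates, quality-score variation, paired-end structure, InDel
sequencing errors, cell-level growth stochasticity (growth is
deterministic given fitness; only read sampling is random). Passing
tests therefore demonstrate correctness of the quantification machinery
under a clean error model, not robustness to every sequencing artifact.

## 3. Read classification

Each read is called by global affine-gap alignment to the reference
(match +2, mismatch −2, gap open −6, gap extend −1; Gotoh algorithm via
Biopython) with InDel events left-normalized to their leftmost
equivalent position. Decision order: **DISCARDED** (aligned-column
identity < 0.8, or truncation over a template position), **INDEL** (any
event within ±20 bp of the cut site — InDels elsewhere are treated as
background and do not veto template calls), **MUT_KI** / **WTSTAR_KI**
(full substitution set present, other set absent), **AMBIGUOUS**
(partial or mixed template sets, including template recombination),
else **UNEDITED**. Frameshift status is the exonic net length change
mod 3; each InDel carries a region label (splice-site dinucleotides
take precedence over exon/intron) from the event nearest the cut site.

For throughput, two closed-form fast paths bypass the dynamic program
while producing identical calls (property-tested): equal-length reads
explained by substitutions alone are compared per position, and reads
whose length differs by Δ are tested against every placement of a
single contiguous InDel of net length Δ using prefix/suffix mismatch
cumulative sums (O(L)); the leftmost minimal-mismatch placement
reproduces the aligner's left-aligned gap convention. Multi-InDel or
heavily damaged reads fall back to the aligner. At 0.5% per-base error
the per-read category accuracy is ≈99.7%, and the residual
misclassification (a template-position error demotes a knock-in read to
AMBIGUOUS) is symmetric between Mut and WT*, so the ratio is unbiased
to well under 1%.

## 4. Selection statistics

Raw ratio `r = MUT_KI / WTSTAR_KI` uses classified knock-in counts
only; AMBIGUOUS and DISCARDED reads never enter (the rest of the
denominator cancels in the ratio). Each replicate is normalized to its
own baseline within each condition; replicates are never pooled before
testing. Zero WT* raises an explicit undefined-ratio error; zero Mut
with nonzero WT* returns R = 0 with a warning (observable extinction).
No continuity correction is applied. The default significance contrast
mirrors the experimental design: treated vs untreated normalized R at
the endpoint, paired across replicates (two-sided t on differences);
Welch's unpaired t is available for cross-cell-line comparisons. A
constant nonzero difference (zero variance) is a degenerate-data error,
not a p-value.

## 5. Statistical primitives

Implemented from their defining formulas and validated against
enumeration oracles: Fisher's exact test (two-sided by the
probability-mass rule with a 10⁻⁷ relative guard against floating-point
ties), chi-square goodness of fit, Wilcoxon rank-sum (exact
enumeration of the rank-sum distribution up to combined n = 20 without
ties, otherwise normal approximation with tie and continuity
corrections; the exact/approximate switch is an enumeration-cost
choice), Benjamini–Hochberg and Holm adjustments (monotonicity
enforced, capped at 1, order-preserving), and the Poisson-binomial CDF
by exact dynamic-programming convolution (both tails consistent to
10⁻¹²). Only special functions (log-gamma, regularized incomplete
gamma, normal and t CDFs) come from `scipy.special`.

## 6. Cohort genomics

* **Helicase-domain status**: a sample is MUT iff it carries a missense
  or truncating (stopgain/frameshift/nonstop) variant at a protein
  position inside a helicase-domain interval; variants outside the
  intervals, other classes, or missing protein positions (warned,
  skipped) leave it WT. The intervals are configuration, not code —
  the default `((6, 260), (440, 730))` spans the two conserved
  ATPase/helicase lobes of an XPD-family helicase.
* **TP53 status**: pathogenic/likely-pathogenic label or deep deletion;
  variants of uncertain significance stay WT.
* **LOH**: any overlapping allele-specific copy-number segment with
  minor copy number 0; NA when no segment overlaps.
* **TMB**: nonsynonymous count divided by the registered covered
  megabases per platform (WES 38; Oncopanel v1/v2/v3
  0.753334/0.826167/1.315078; 341/410/468/505-gene panels
  0.896665/1.016478/1.139322/1.25964; Caris 1.4). Harmonization
  standardizes `log10(TMB + 1)` within each platform stratum (sample
  SD); the log transform tempers the right skew of mutation burden.
  Strata of size 1 or zero spread yield z = NA with a warning.
* **Spectrum**: 96 channels in COSMIC order (substitution type major,
  trinucleotide alphabetical minor); purine-reference sites are
  collapsed by reverse complement; indels/MNVs excluded and counted;
  ref-mismatching variants skipped with a warning.
* **Signature refitting**: nonnegative least squares (Lawson–Hanson
  active set) of a provided signature matrix whose columns are
  nonnegative and sum to 1. The package ships a *synthetic* signature
  generator (sparse Dirichlet profiles) for testing; published COSMIC
  profiles are an input the user supplies, not data redistributed here.
* **Domain enrichment**: chi-square of observed [in-domain, outside]
  counts against the domain's length fraction of the protein.

## 7. Mutual exclusivity / cooccurrence

The alteration matrix binarizes nonbenign variants of passing classes
(missense, stopgain, frameshift, nonstop, splice) per gene × sample,
keeping sequencing-technology strata as separate matrices. The
background model is the maximum-entropy/logistic form
`p_ij = σ(μ_i + ν_j)` with expected row and column sums constrained to
the observed margins — the canonical parameterization satisfying
"tumor-specific alteration rates are preserved". Fitting is alternating
safeguarded Newton sweeps from zero initialization (deterministic);
convergence requires both margin residual max-norms below 10⁻⁸
(achieved ~10⁻⁹ in practice). All-zero/all-one rows or columns have no
finite parameter; they are fixed at their observed value and reported.

Pair tests refer the observed overlap `k` to the Poisson-binomial null
with `q_j = p_Aj p_Bj`: exclusivity `p = P(X ≤ k)`, cooccurrence
`p = P(X ≥ k)`; stratified analyses test within stratum and concatenate
nothing across strata. BH adjustment is applied within each
direction × stratum family with the conventional 0.01 threshold.

**Calibration domain and a known limitation.** The null treats the
fitted `p_ij` as known. When the background is estimated from a large
gene matrix whose per-gene rates are mostly low (the way the method is
used in practice), null exclusivity p-values are near-uniform — the
package's calibration study uses 100 genes at rates 0.03–0.15, 600
samples, per-sample rate dispersion 0.4, 500 random pairs. When the
matrix contains only a handful of genes mutated at 10–50%, conditioning
on the fitted margins shrinks the overlap variance below the
Poisson-binomial variance and the test becomes conservative (null
z-scores with SD ≈ 0.8 at 40 genes); results in that regime are valid
but lose power. Fisher's exact test on the same pairs is reported for
comparison and is directionally more conservative still for
exclusivity.

## 8. Survival analysis

Kaplan–Meier product-limit estimation with Greenwood variance; the
log-rank test over pooled event times with multivariate hypergeometric
variance (χ² with groups − 1 df); Cox proportional hazards by
Newton–Raphson on the partial likelihood, Efron tie handling by default
(Breslow available), convergence at max |Δβ| < 10⁻⁹ or 25 iterations,
covariates centered for numerical stability. Wald tests are reported;
the global score statistic at β = 0 is exposed and, for a single binary
covariate without ties, reproduces the log-rank χ² to 10⁻¹⁴ (a known
identity, verified numerically). A coefficient passing |β| > 15 during
iteration is treated as monotone likelihood (complete separation) and
raises an error naming the covariate. Binary covariates are coded 0/1
with wild type as reference; the interaction model uses two main
effects and their product. Time units are caller-defined.

One stated invariant was corrected during implementation: adding a
subject censored *after* the last event does change the product-limit
curve at earlier times (the subject enlarges every earlier risk set);
the properties actually guaranteed — and tested — are that a subject
censored before the first event leaves the curve unchanged and that
late censoring adds no event times.

## 9. Cohort simulator

Per-sample alteration propensities are logit-normal offsets (SD =
`sample_rate_dispersion`) around per-gene marginal rates (defaults
shaped like a muscle-invasive bladder cancer driver panel: TP53 50%,
ERCC2 10%, ...). Planted pairs post-process the matrix: exclusive pairs
resolve overlaps with the given strength (strength 1 ⇒ zero overlap);
cooccurring pairs copy alterations. The locus gene's variants receive
genomic positions drawn from a trinucleotide-channel mixture over a
provided signature matrix, placed on a simulated locus reference so the
spectrum round-trips exactly; 93% are missense and 87% fall in the
helicase-domain intervals by default, with a 6% LOH fraction among
mutant samples — matching the mutational landscape such cohorts
report. Survival is exponential per locus-gene status (defaults 0.035
vs 0.06 events/month) with exponential censoring; platform-specific
mutation-burden scales (panels enriched ~1.4–1.6×) exercise the
harmonization. Benign/synonymous decoy rows test the class filter.

## 10. Validation-study sizes

The studies in `crisprselect.studies` (asserted in
`tests/test_acceptance.py`, reported by `scripts/acceptance.py`) use:
classifier fidelity at depth 5,000 and 0.5% error (6 replicates, 30k
labeled reads); selection recovery at depth 10,000, 3 replicates, w ∈
{1.0, 0.9, 0.8, 0.6}, with the delta-method standard error of mean R
(the empirical SD over 3 replicates has only 2 df and makes a
"3 SE" bound a coin flip); 1,000 neutral count-level simulations for
the t-test's type-I error; enumeration oracles at n ≤ 12; the
calibration conditions of §7; 100 Poisson-resampled spectra of 500
mutations for signature recovery; 1,000 log-rank null simulations at
n = 200 and 50 Cox fits at n = 2,000 with ~20% censoring for a planted
log-HR of 0.7. The full battery runs in about half a minute on one CPU.
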