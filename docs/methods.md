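# Methods

This note documents the models behind each stage, the defaults that
matter, the numerical choices, and the limits of what the synthetic
generators can show.

## Electropherogram quantification

A trace is a fragment-size grid (bp) with signal density in pg/µL per bp.
All quantities are trapezoidal integrals; window edges falling between
grid points are linearly interpolated, and the open-ended >5000 bp window
integrates to the last grid point (10,380 bp, the upper-marker position —
marker peaks are assumed removed upstream by the instrument software).
Window boundaries are inclusive-low/exclusive-high; because the integrand
is continuous this only matters for bookkeeping, not mass.

cfDNA concentration sums the 50–550 bp mass (mono- through tri-nucleosome
fragments) over the four column eluates, each weighted by its elution
volume (defaults 85/40/20/20 µL), divided by plasma volume (default
3.6 mL): ng cfDNA per mL plasma. Elution-recovery fractions divide each
eluate's 50–550 bp mass by the total; a zero total raises rather than
returning NaNs.

Purity: a sample is called gDNA-contaminated when the pooled >5000 bp
signal exceeds 50 pg/µL, strictly. The threshold is applied to the whole
sample, not per eluate — masses are pooled across eluates and expressed as
a per-µL equivalent of eluate 1, which reduces to the plain bin amount for
a single-eluate sample. The plasma gDNA estimate is max(0, Qubit −
Bioanalyzer) in ng/mL: Qubit reads total dsDNA while the trace sum counts
only 50–550 bp fragments, so the difference approximates high-molecular-
weight contamination; negative differences are unphysical and clamp to 0.

The mean mono-nucleosome fragment size is the density-weighted mean over
[50, 250) bp and is undefined (an error) when that window is empty.

## Cohort statistics

The rank-sum test is implemented directly. For pooled n ≤ 12 the null
distribution of W (sum of the first sample's midranks) is enumerated over
all C(n, n_x) group assignments — a valid permutation test with ties —
and the two-sided p is min(1, 2·min-tail). Larger samples use the normal
approximation with the tie-corrected variance and a 0.5 continuity
correction. The two paths agree to ~0.01 for typical 6+6 data; the exact
worst case of the continuity-corrected approximation over the whole 6+6
support is 0.0155 (enumerable), which is the bound the tests assert.

Pearson r uses the product-moment formula with p from
t = r√((n−2)/(1−r²)); Kaplan–Meier curves and the log-rank test are
delegated to lifelines. Median splits assign the sample at the median to
the low arm. Outlier removal is never silent: `drop_outliers_3iqr` returns
a keep-mask for points within 3×IQR of the quartiles and must be invoked
explicitly.

## Consensus variant filter

Variant keys are normalized by trimming the shared allele suffix, then the
shared prefix (advancing the position), keeping at least one base per
allele. Candidates merge across callers on the normalized key; consensus
depth and alt count come from the deepest supporting caller (ties broken
by caller name), and VAF is recomputed as alt/depth rather than trusting
caller-reported VAFs, which follow caller-specific definitions.

The verdict is a pure conjunction: callers ≥ 2, depth ≥ 10, VAF ≥ 0.05,
alt reads ≥ 8 with germline alt reads = 0, population allele frequency
< 1e-4 (strict, the fraction form of "below 0.01%"), and significance not
benign/likely benign (case-insensitive, underscores equal spaces). Failure
reasons list every violated criterion (germline support is reported under
criterion IV together with the read-support floor). A site with no
population-frequency annotation fails criterion V — conservative, since
the frequency is unknown. A site missing from the germline-counts table
counts as 0 germline alt reads: absence of evidence of germline support,
as opposed to absence of the annotation needed for criterion V. Upstream
caller FILTER columns are ignored; the five criteria are the gate, and the
audit table (every candidate, per-criterion booleans) stands in for manual
review.

## Depth titration

The downsampling schedule compounds first and floors once:
depths[k] = ⌊start·(1−r)^k⌋. Per-step flooring would give 117/93/74/59
from 147× at r = 0.2; compounding gives 117/94/75/60. Count thinning keeps
each read independently with probability target/current: the retained
total is Binomial(total, ratio) and the retained alt reads are
hypergeometric given the retained total — statistically identical to
read-level BAM subsampling, without alignments in scope. Detection
probability is the exact binomial tail P[X ≥ min_reads],
X ~ Binomial(depth, VAF); the minimum depth for a target probability is
found by linear scan, valid because the tail is nondecreasing in depth.

## Tumor fraction and clonality

A copy-number event with tumor copy number c and cellular prevalence φ in
a sample of tumor fraction TF shifts the expected tumor/normal log2 ratio
to log2((TF·φ·c + TF·(1−φ)·2 + (1−TF)·2)/2): three cell populations —
tumor with the event, tumor without, normal — mix linearly in coverage.
Limits: TF→0 gives 0 for any c; TF→1, φ=1 gives log2(c/2).

Bins are normalized as log2 of total-count-normalized tumor/normal ratios
and median-centered (the median bin is assumed copy-neutral); bins with a
zero count on either side are dropped. Segmentation is recursive binary
splitting on mean shift: a split is accepted when the SSE reduction
exceeds `penalty` (default 12) times a robust per-bin noise variance
(MAD of within-chromosome successive differences, scaled by 1/√2), with a
minimum segment length of 10 bins. The greedy pass is followed by a
bottom-up merge at the same threshold (greedy boundaries sometimes survive
with no real step behind them) and a coordinate-descent polish that
re-places each internal boundary optimally given its neighbors — on
150-bin three-piece instances this lands within 5% of the exhaustive
two-changepoint optimum.

The fit searches TF over 0.01–0.60 (step 0.01), c over 0–8, and φ over
{0.25, 0.5, 0.75, 1}, minimizing length-weighted squared error of segment
means against the model. Three choices here were forced by identifiability
and are worth spelling out:

1. **Only clear events inform TF.** Segments with |log2R| < 0.05 are
   excluded from the TF objective (but still classified afterwards). A
   small-TF solution has a finer state lattice and can always fit
   near-zero noise segments better; letting them vote drags TF toward the
   noise floor.
2. **Complexity charges.** Within a segment, each state's squared error is
   charged +2·Var(mean) for being non-neutral and +5·Var(mean) for being
   subclonal, where Var(mean) is the segment-mean sampling variance
   (per-bin noise variance over n_bins), capped at (0.02 log2R)².
   Uncharged, the dense subclonal lattice absorbs any noisy mean exactly
   and the fit drifts to wrong TFs. The cap emulates the fixed state
   priors of production HMM callers: priors do not grow when data get
   noisier, which is precisely why low-coverage profiles inflate false
   subclonal calls while clean deep profiles do not — the behavior the
   cross-depth comparison measures. On noise-free data the charges vanish
   and a subclonal state is preferred only when it beats the best clonal
   state by more than δ = 10% relative error.
3. **Parsimony tie-breaks.** The model is exactly degenerate under
   (TF, c) ↔ (TF/2, 2(c−2)+2) and clonal-at-TF ↔ subclonal-at-TF/φ. Ties
   in fit error are broken by the smallest length-weighted
   Σ(|c−2| + 4(1−φ)), then by the larger TF.

TF = 0 is returned when no segment reaches the 0.05 event floor, or when
the all-neutral fit of the event segments is within ε = 1e-4 per unit
length of the best alternative. `frac_genome_subclonal` is the fraction of
segmented genome length in subclonal states.

Concordance between two call sets matches non-neutral events by reciprocal
overlap ≥ 50%: clonal concordance is the fraction of the reference's
clonal events matched by a clonal event of the same direction; subclonal
events unique to the test set are false subclonal; subclonal events of the
reference missing from the test set are missed; matched pairs with
different clonality labels are swaps.

This module is deliberately a simplified stand-in for HMM-based CNV
callers: no GC or mappability correction, no transition priors, no
sex-chromosome ploidy handling. The clonality/TF mixture algebra is the
testable core.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given (spec, seed); seeds spawn via
`numpy.random.SeedSequence`.

**Traces.** Components (mono/di/tri-nucleosome, gDNA) are truncated
normals renormalized on the grid so each integrates exactly to its
specified amount — mass conservation is testable. Defaults: means
167/340/510/8000 bp, SDs 20/30/14/400 bp (instrument-realistic widths;
the tri peak must not leak past the 550 bp quantification edge), grid
35–10,380 bp at 1 bp. Noise is additive zero-mean Gaussian clipped at 0
(baselines are nonnegative); clipping biases integrals upward by
~0.4·σ per zero-signal bp, which is why quantification is tested to 1%
noise-free but 10% at noise of 5% of peak height. Elution series
distribute a total cfDNA mass over four eluates by specified fractions;
recovery analysis inverts this to within integration error.

**Cohort.** Per group, concentration is log-normal (σ_log = 0.55) and
fragment size normal, coupled by a Gaussian copula so the rank correlation
tracks the specified correlation. Calibration anchors are the published
group medians — Bioanalyzer concentrations 7.6 (healthy), 5.8 (RP), 8.3
(disease-free), 22.2 ng/mL (mCRPC, outlier-free) — size medians
158/160/154/150 bp with SDs backed out of the reported min–max ranges via
the expected-range factor d₂(n) at the reported group sizes (14/17/10/19),
and the mCRPC size–concentration correlation −0.56. mCRPC survival is
exponential with a 30-month median and 30% uniform censoring. These are
distributional calibrations: passing tests show the generator reproduces
the anchors at large n, not that the pipeline reproduces the clinical
cohort, whose samples are unavailable.

**Callsets.** True somatic variants (defaults: the four consensus loci of
the worked clinical case, with invented VAFs of 6–10% so depth titration
is informative) appear in each caller independently with per-caller
sensitivities (0.95/0.90/0.85/0.90) and a shared Binomial(depth, VAF) alt
count at constant site depth (147×). False positives are unique to one
caller, so they deterministically fail the two-caller rule and give a
brute-force-checkable truth partition; germline contaminants are seen by
all callers with ~50% VAF, nonzero germline support at 40×, a 1%
population frequency, and benign/likely-benign labels. No sequencing-error
model, no trinucleotide context, no caller-specific VAF biases.

**Bin profiles.** The synthetic genome is 20 chromosomes × 150 Mb at 1 Mb
bins (bin width and layout are configurable; nothing downstream assumes
this layout). Counts are negative binomial with variance µ + µ²/r,
r = 500 — a ~4.5% CV floor representing residual systematic noise
(GC/mappability) on top of Poisson sampling — and µ = 10 counts per
fold-coverage per bin, an *effective* information count (raw read counts
per 1 Mb bin are far larger but highly correlated; the effective scale was
chosen once so that 10× profiles retain clonal events while losing
subclonal ones, matching the qualitative low-pass behavior the pipeline is
meant to expose). The default truth is mCRPC-like: clonal loss (chr8),
clonal gains (chr10, chr12), a c=6 amplification (chr13), and two
subclonal events — chr16 c=3 φ=0.5 and chr4 c=1 φ=0.5, both chosen off
the clonal lattice (TF·φ·(c−2) not a multiple of TF) so that subclonality
is identifiable from the log2 ratio at all; an on-lattice subclonal event
is mathematically indistinguishable from a clonal one and is always
labelled clonal by parsimony.

## Problem sizes and determinism

Test and acceptance workloads are sized for a single CPU: enumeration
oracles at pooled n ≤ 12, Monte-Carlo checks at 10⁴–10⁵ draws, the
cross-depth CNV comparison at 20 seeds × 3000-bin genomes per depth, and
the full demo pipeline in a few seconds. Every random stage takes an
explicit seed; identical (spec, seed) gives byte-identical outputs,
including written TSV/JSON/VCF artifacts, and the pipeline report records
a SHA-256 hash of the canonical config.

## Known limitations

- Quantification assumes marker peaks are pre-removed and does not
  deconvolve overlapping peaks; heavy baseline noise biases integrals
  upward (clipping).
- The purity threshold's per-eluate vs pooled application is a modeling
  choice (pooled); both are defensible readings of the lab rule.
- The consensus filter starts from caller VCFs; it does not re-call or
  re-align, and ensemble behavior of the real callers (shared error modes,
  correlated false positives) is not modeled.
- The CNV module's absolute TF accuracy on noisy data is limited by
  segmentation quality (~±0.03 noise-free, wider under noise); it is not a
  replacement for a production caller on real data.
- Survival simulation uses independent uniform censoring, not the
  administrative censoring of a real study.
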