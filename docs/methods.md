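# Methods

This note records the statistical models, the defaults and why they are
set where they are, the numerical edge cases, and what the synthetic
benchmarks do and do not demonstrate.

## Coordinates and data model

All intervals are 0-based half-open internally; GFF3 (1-based inclusive)
is converted only at the file boundary, BED is passed through. A gene is
a 5′UTR / CDS / 3′UTR triple on one strand with the UTRs required to
abut the CDS; CDS lengths must be multiples of 3. Operons are ordered
gene lists (a gene belongs to at most one); TSS, intrinsic terminators
and ncRNAs are independent feature sets. Strain labels are generic
(`WT` / `mutant`) so the pipeline is not tied to one regulator.

## Spike-in normalization and half-life estimation

After transcription arrest the absolute mRNA pool shrinks, while a
sequencing library always sums to its depth; spike-ins of constant
abundance anchor the absolute scale. For spike *i* in timepoint library
*T_n* vs its time-zero library *T_0*,
`k_i = (ERCC_n,i/ERCC_0,i)/(Total_n/Total_0)`, and the library factor
*k* is the geometric mean of `k_i` over the `spike_top_k = 25` most
abundant spikes (ranked in *T_0*); spikes with zero *T_n* counts are
dropped with a warning and fewer than `spike_min_usable = 10` survivors
is an error. Note that *k* as printed is invariant to uniform
library-depth scaling — dividing by *k* does not correct depth — so the
pipeline optionally rescales libraries to equal totals first
(`decay_equal_depth`, default on). With equal depths, dividing raw
counts by *k* makes gene counts proportional to true molecule numbers,
which is what makes half-life recovery well-posed; this is verified on
compositional simulations.

Half-lives: OLS of ln(count) on time (defaults 0, 2.5, 5, 10, 15 min),
*t*½ = −ln2/slope for negative slopes, +∞ otherwise; *R*² is the OLS
coefficient of determination. Zeros at later timepoints are dropped
rather than pseudocounted (a `decay_pseudocount` of +0.5 is available);
fewer than 3 positive points marks the fit failed rather than raising.
Filters: retain iff t₀ count ≥ `decay_min_t0 = 50` (raw counts, at the
earliest timepoint) AND *R*² ≥ `decay_min_r2 = 0.7`, boundaries
inclusive. The published wording ("counts <50 and R² <0.7 were
excluded") reads literally as exclude-only-if-both-fail; that would
retain noisy low-count fits, so the default is exclusion on either
failure (`decay_filter_mode: or`), with the literal `and` selectable.

Differential stability: two-sided two-sample *t* (pooled variance;
Welch by `decay_ttest: welch`) on replicate half-lives per gene, BH
across genes, significant iff q < 0.05 and |log₂(mut/WT)| > 0.5. The
printed gate "fold changes > log₂(0.5)" is self-contradictory
(log₂(0.5) = −1); |log₂FC| > 0.5 is used, as in the TE model.
Degenerate replicates: zero variance in both groups with equal means
gives p = 1; zero variance with unequal means gives the smallest
representable p with a warning (this arises only on noiseless input).
The number of decay replicates is not hard-coded; the generator
defaults to 3.

## The TE linear model

Counts are log₂-CPM transformed with a 0.5 pseudocount
(`log2((c+0.5)/(total+1)·1e6)`); observation-level (voom-style)
weighting is deliberately not implemented. The gene-wise model is the
cell-means parameterization of the 2 assays × 2 strains design; the
three contrasts are ΔRPF, ΔRNA, and TE = ΔRPF − ΔRNA, so
`log2fc_te = log2fc_rpf − log2fc_rna` holds to machine precision by
construction and the contrast set has rank 2 — the joint *F* uses 2
numerator degrees of freedom, not 3.

Variance moderation is the standard empirical-Bayes shrinkage: posterior
s² = (d₀s₀² + d·s²)/(d₀ + d), with the prior degrees of freedom d₀ and
prior variance s₀² solved by method of moments from the mean and
variance of the gene-wise s² (an under-dispersed ensemble gives d₀ = ∞,
i.e. complete shrinkage). Moderated *t* and *F* use d₀ + d denominator
df. Null calibration of the moderated *F* was checked by simulation
(1,000 null genes, NB dispersion 0.05, 5 replicates per cell): the raw
p < 0.05 fraction stays within three Monte-Carlo standard errors of
0.05 across seeds. Moderation can be disabled, in which case the
statistics reduce exactly to classical OLS *t*/*F* (tested against
`scipy.stats.ttest_ind`).

Gene-level selection: BH on the joint-F p-values at `te_fdr = 0.05`;
within passing genes, contrasts enter the selected set in decreasing |t|
order for as long as the *F* recomputed over the not-yet-selected
contrasts (rank-aware, via the pseudo-inverse of their covariance)
remains above the critical *F* at the nominal level. The within-gene
cutoff is nominal rather than the genome-wide BH threshold: tying it to
the smallest raw p among passing genes would make one ultra-significant
gene veto contrast selection everywhere else. Selected contrasts must
also pass |log₂FC| > `te_lfc = 0.5`.

Expression filter: a gene is removed when its mean count per sample is
below `te_min_mean = 15` in *both* the RPF and RNA matrices (the
literal reading; `either` selectable). The RNA-only model (all gene
biotypes, mean ≥ 15 in RNA samples) is the same machinery restricted to
one two-group contrast.

## Pause detection

Reads are assigned to CDS positions (assignment rule recorded in the
manifest; the generator emits offsets directly). Per replicate, a pause
is a position with occupancy > `pause_fold = 10` times the mean of the
trimmed CDS (first/last `pause_trim = 30` nt excluded; the mean includes
zero positions, and an all-zero trimmed profile yields no pauses rather
than NaN folds). CDSs shorter than 2·trim + 1 are skipped with a reason.
Pauses are called per replicate and then intersected: a site must recur
at identical (gene, position) — optional ±w nt tolerance — in
`pause_min_reps = 4` replicates. Consensus at min_reps = 1 is the union
and at n the intersection (tested).

Co-localization: the universe is every trimmed-CDS nucleotide of the
analyzed genes in genome coordinates; peaks are extended ±`pause_flank =
30` nt and merged; the 2×2 table (pause/non-pause × inside/outside) is
tested with Pearson χ² without continuity correction (`chi2_correction`
toggles Yates). Pause-strength comparison between strains is a
two-sample *t* on fold occupancies, over all pauses or only those near
peaks.

## CLIP peaks

The caller is a transparent threshold/merge scan on merged tagged
coverage: maximal runs ≥ `peak_min_cov = 10`, gaps < `peak_merge_gap =
10` merged, runs < `peak_min_len = 20` dropped. It is deterministic,
idempotent, and invariant to coverage rescaling that preserves threshold
crossings; peak boundaries are therefore emergent, not tuned to match
any particular external caller.

Enrichment: per-peak counts (a read counts in every containing peak;
caller output is disjoint) are tested tagged vs untagged with an NB GLM
(log link, Wald test on the condition coefficient), per-peak dispersions
estimated by method of moments within conditions and shrunk halfway
toward a fitted a₀ + a₁/μ trend; dispersion → 0 reduces to Poisson and
the p-values were anchored against an exact conditional binomial ratio
test (within 2×) on toy counts. Size factors default to median-of-ratios
over the peak counts; when the candidate set is dominated by genuinely
bound regions that estimator absorbs the enrichment itself, so the
pipeline passes whole-library read totals instead. Significance requires
q < `clip_fdr = 0.05` *and* positive log₂FC (enrichment only).

Annotation attaches every applicable label per peak — UTR5, UTR3,
ncRNA, terminator by overlap; TSS by containment; CDS_first60 /
CDS_last60_near_stop / CDS_deep measured from the start/stop codon in
the gene's orientation with a `window_cds = 60` nt window; intergenic
only when nothing else applies — plus a flag for near-stop peaks that
also overlap the next gene of the same operon.

Motif scanning compiles IUPAC strings (default core `AUGGAUG`; extended
consensus `RUACARGGAUGU` available) to overlapping-match regexes with
T/U equivalence; no reverse-complement scanning by default since peaks
are strand-resolved transcripts. Enrichment versus background sequences
is a χ² on match-start frequencies.

## Integration

Peak-to-gene assignment counts a peak anywhere on the transcript
(5′UTR–3′UTR) by default; a stricter 5′UTR + first-60-nt mode exists
(`peak_association: utr5_first60`). Classification is a pure function of
the per-layer significance calls and the peak assignment: direct /
indirect / binding_only / none as defined in the README; "significant
increase in the mutant ⇒ the regulator represses" is stated in the
output header. Venn cells across the three expression methods partition
the genes significant in ≥ 1 method; localization fractions are over
label instances (multi-labelled peaks contribute several).

## Synthetic data: what it emulates, and what it does not

Decay is sampled compositionally — a multinomial over genes plus
constant spikes at fixed depth — precisely the fractions-not-molecules
regime the spike normalization inverts; optional gamma noise (variance
`noise`, mean 1) adds extra-Poisson biological variability. Gene-level
ribo/RNA counts are negative binomial with variance μ + φμ²; the default
dispersion φ = 0.05 is a typical biological-replicate value for
bacterial RNA-seq. RPF reads are placed uniformly along the CDS except
planted pause positions (fold × the local rate). CLIP reads fall
uniformly over transcribed nucleotides, with planted peaks multiplying
the tagged rate by their enrichment factor and the motif written into
the genome at peak centers. A `noiseless=True` mode replaces sampling
with rounded expectations for exact end-to-end checks.

Not emulated: alignment artifacts, rRNA contamination, positional
coverage bias, UV-crosslinking biochemistry, read-length effects,
operon-level count correlation, or biphasic decay. Passing benchmarks
therefore demonstrates correctness of the statistical machinery under
its stated assumptions, not robustness to real-data artifacts.

## Benchmark sizes and measured behavior

The validation experiments (`regulonmap.validation`, driven by the test
suite and `scripts/acceptance.py`) use 1,000 genes for the decay, TE
and stability calibrations, 50 planted pauses, 50 peaks / 500 pauses
for co-localization (200 null repeats), ~150 genes for CLIP detection
and 60 genes for the noiseless end-to-end run — sizes chosen so each
experiment completes in seconds while leaving Monte-Carlo standard
errors small relative to the bounds checked.

Known limitation, measured and documented rather than hidden: with 5+5
replicates at φ = 0.05 a single log₂ contrast has sampling s.d. ≈ 0.21
(≈ 0.29 for TE), so only ~57% of planted 1-log₂ effects land within
±0.2 of truth even though ~97% are detected as significant with the
correct sign; point-estimate accuracy at that tolerance would require
φ ≤ ~0.015 or ~4× the replicates. Half-lives much shorter than the
first sampling interval (≲ 1 min) and biphasic decay are outside the
estimator's reliable range.
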