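# regulonmap

Integrated transcriptomic mapping of a bacterial post-transcriptional
regulator's regulon — the kind of question asked about CsrA-family
RNA-binding proteins, which bind GGA motifs in mRNAs and alter
translation, RNA stability, or transcription elongation. The package
combines four analysis layers, each testable end-to-end on synthetic
data, and classifies genes as directly or indirectly regulated by
joining expression changes with in-vivo binding evidence.

## What it computes

**RNA stability** (rifampicin time courses with ERCC-style spike-ins).
Raw counts of each timepoint library *T<sub>n</sub>* are normalized
against its time-zero library with per-spike factors

```
k_i = (ERCC_n,i / ERCC_0,i) / (Total_n / Total_0)
```

taking the geometric mean of the 25 most abundant spikes. Half-lives
come from ordinary least squares on a semi-log plot, *t*<sub>1/2</sub> =
−ln 2 / slope, with fits filtered on starting counts (≥ 50) and *R*²
(≥ 0.7). Strain differences are tested per gene with Student's *t* on
replicate half-lives, Benjamini–Hochberg FDR 5%, and a |log₂ ratio| >
0.5 gate.

**Translation / RNA / TE** (paired ribosome profiling + RNA-seq, two
strains, five replicates). A gene-wise linear model on log-CPM tests
three contrasts: translation (RPF<sub>mut</sub> − RPF<sub>WT</sub>), RNA
abundance (RNA<sub>mut</sub> − RNA<sub>WT</sub>), and their interaction,
translational efficiency TE = ΔRPF − ΔRNA. Residual variances are
moderated by empirical-Bayes shrinkage; gene-level significance uses a
joint *F* (rank 2) with BH correction, followed by a nested-F descent
that picks the driving contrasts, gated at |log₂FC| > 0.5.

**Ribosome pausing.** Positions with > 10-fold occupancy over the mean
of the CDS (first/last 30 nt trimmed) are pause sites; only pauses
shared by ≥ 4 of 5 replicates count. Pause co-localization with binding
peaks (± 30 nt) is tested with a two-sided Pearson χ².

**CLIP peaks.** A threshold/merge caller on merged tagged coverage
yields candidate peaks; tagged-vs-untagged enrichment is tested per peak
with a negative-binomial Wald test (median-of-ratios or library-total
size factors, trended method-of-moments dispersions), BH at 5%. Peaks
are annotated against 5′UTR / CDS (first 60 nt, deep, last 60 nt near
the stop codon) / 3′UTR / ncRNA / TSS / terminator features, with
operon-aware downstream-gene flags, and scanned for the AUGGAUG
consensus (χ² enrichment versus the genome).

**Integration.** A gene with ≥ 1 significant layer *and* a peak on its
transcript is `direct`; a significant gene without a peak is `indirect`;
a peak without expression change is `binding_only`. Sign convention: a
significant increase in the mutant means the regulator represses.

## Worked example

```
regulonmap simulate --seed 1 --out run/ --n-genes 40
regulonmap decay --out run/
regulonmap te --out run/
regulonmap clip --out run/
regulonmap pauses --out run/
regulonmap integrate --out run/
```

which logs, for this seed:

```
INFO regulonmap: simulated 40 genes into run/
INFO regulonmap: 40 genes tested, 4 significant
INFO regulonmap: TE model on 40 genes
INFO regulonmap: 43 candidate peaks, 12 significant
INFO regulonmap: consensus pauses: WT=7 mutant=7
INFO regulonmap: classified 40 genes
```

Here 12 of 43 candidate peaks pass the tagged-vs-untagged test (the 12
planted binding sites), 4 genes change RNA stability between strains,
and 7 pause sites survive the 4-of-5 replicate consensus in each strain.
`run/summary.json` then reports the classification tallies — for this
run `{'binding_only': 7, 'direct': 5, 'indirect': 6, 'none': 22}` — the
Venn overlap of the three expression methods, and peak-localization
fractions. The motif report for the same run shows the planted AUGGAUG
motif at ~18-fold enrichment in peaks over the genome (χ² p ≈ 4e-23).
Every stage writes plain TSV plus a `manifest_<stage>.json` recording
parameters, seed and version; outputs are byte-identical across runs
with the same seed.

All thresholds above are config keys (flat `key: value` YAML, see
`regulonmap.config.DEFAULTS`) and can be overridden with `--config`.

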