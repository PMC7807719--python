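# Methods

`isoswitch` analyses strand-specific, single-nucleotide counts of mRNA 5′
ends (TSS-seq-like) and 3′ ends (TES-seq-like) across a time course of
cell-state transitions, and asks how usage shifts between a gene's *main*
transcript start/end site and its *alternative* sites — in particular the
switching events in which an upstream alternative TSS overtakes, and often
represses, the canonical promoter. This note documents the model behind
each stage, the parameters that matter, the synthetic data the package is
validated on, and the numerical choices made where the design was open.

## Cluster calling

Raw end counts are normalized per sample to tags per million (TPM), where
the library size is the total number of counted ends on both strands of
that sample (for 3′-end libraries, counted *after* internal-priming
filtering, so artifact reads do not dilute the scale).

Single-nucleotide positions are grouped by simple distance clustering: two
nonzero positions join a cluster when every gap between consecutive
nonzero positions between them is at most `max_dist` (default 5 nt). A
cluster consisting of a single position is kept only when its TPM is at
least `singleton_floor_tpm` (default 3 TPM; the threshold is inclusive —
the floor is a normalized-signal threshold, and inclusivity is our
documented convention).

Per-sample tag clusters are aggregated into consensus clusters: clusters
below 1 TPM in their own sample are dropped; surviving spans on the same
contig and strand merge transitively when the gap between spans is at most
20 nt (span distance, not midpoint distance — the simplest rule consistent
with a distance parameter). Consensus boundaries are then trimmed to the
central mass of the pooled (all-samples) signal between the cumulative
quantiles `q_low = 0.05` and `q_up = 0.95`: walking positions 5′→3′, the
kept interval runs from the first position whose cumulative fraction
strictly exceeds `q_low` to the last position whose cumulative fraction is
at most `q_up`, extended outward if rounding would leave less than
`q_up − q_low` of the mass. The apex is the position of maximal pooled
signal inside the trimmed interval, with ties broken to the 5′-most base
on the cluster's strand. Per-sample TPMs are re-summed over the trimmed
interval. Trimming never widens a cluster, always contains the apex, and
aggregated clusters of one kind/strand never overlap (all
property-tested against brute-force oracles).

A consequence of the 20-nt aggregation distance worth knowing: two genuine
promoters closer than roughly `20 + cluster width` merge into a single
consensus cluster and can no longer be analysed as a tandem pair. The
synthetic generator therefore draws tandem spacings from 40 nt upward.

## Artifact filters

**Internal priming (3′ ends).** Oligo-dT priming on genomic A-rich tracts
creates false 3′-end signal just upstream of the tract. Degenerate
poly(A) tracts are all 20-mer windows with at most 8 mismatches to the
homopolymer read on the transcript strand (A-runs for + transcripts,
T-runs in the reference for − transcripts), merged into maximal tracts. A
3′-end site is removed, *before* TES cluster calling, when a same-strand
tract overlaps it or begins within 5 nt downstream of it (downstream in
the direction of transcription).

**Spurious 5′ ends.** A library prepared without the decapping step
reports ends that were ligatable without a cap, i.e. not genuine TSSs.
For each TSS consensus cluster, base-wise *raw* counts over the cluster
± 5 bp are Spearman-correlated between the reference-timepoint sample and
the non-decapping control; the cluster is excluded when r > 0.5 with
p < 0.05 (large-sample t approximation, average ranks for ties). A
spurious call requires positive evidence: when either window is constant
(typically an all-zero control) the correlation is undefined and the
cluster is kept. The reference sample defaults to the first replicate of
the first timepoint and is configurable.

## Gene assignment

Each cluster is assigned to at most one gene — the closest gene in the
same orientation, measured apex to ORF start (TSS) or apex to ORF end
(TES); clusters inside an annotated ORF are `internal` to the containing
gene; clusters whose apex falls inside an opposite-strand ORF are treated
as antisense and left unassigned. External rules:

* within 100 bp of the ORF boundary: assigned unconditionally;
* 100–1000 bp away: a 30-bp window slides base-by-base (step 1 nt, the
  strictest reading; configurable) across the gap, and every window must
  have median mRNA coverage > 0. For TES clusters each window must
  additionally have median ≥ 5% of the gene-body median and max ≤ 5× the
  gene-body max — evidence the gap is continuously transcribed as part of
  the same mRNA rather than a neighbouring unit. The 5%/5× criteria are
  applied to TES assignment only, matching their origin in 3′-end
  processing rules;
* beyond 1000 bp: unassigned.

The mRNA coverage used for the window rules is the coverage at the
timepoint of the cluster's maximal expression. 5′ UTR length is the
distance from the TSS apex to the first base of the start codon; 3′ UTR
length the distance from the ORF 3′ boundary to the TES apex; internal
clusters have none.

## Main/alternative classification and usage

Roles are defined *within* each transition: the main cluster is the one
with the highest TPM at the transition's reference timepoint, provided it
reaches 1 TPM there (ties break to the 5′-most apex); every other
assigned cluster reaching 1 TPM at any timepoint of the transition is an
alternative. Genes without a definable main are excluded from usage
statistics for that transition rather than imputed. A cluster may be main
in one transition and alternative in another; roles are per transition.

Alternative usage at a timepoint is `alt / (alt + main)` on the TPM
scale, with `alt` the sum over the gene's alternatives (pairwise,
per-cluster analyses use each alternative separately); usage change is
the difference between a transition timepoint and the reference, in
[−1, 1]. The ratio is invariant under any common rescaling of a gene's
clusters, so proportional co-induction of both promoters produces zero
usage change by construction.

## Differential expression

Per-cluster raw counts (summed over the consensus interval) are
normalized by median-of-ratios size factors. The fold change is
`log2((mean_T + 0.5) / (mean_ref + 0.5))` on normalized means.

For the per-cluster test we document a deliberate design choice. A
per-cluster Welch t on log2(normalized + 0.5) with three replicates has
2–4 degrees of freedom; its p-values cannot fall far enough for genuinely
induced clusters to survive multiplicity adjustment (a true 4-fold
induction at NB dispersion 0.05 typically reaches only p ≈ 0.003–0.03,
and detection after BH stalls near 40%). The matrix-level driver
therefore applies classical empirical-Bayes variance moderation: pooled
per-cluster variances are shrunk toward a count-level-aware prior
(var ≈ a + b/mean, the Gamma–Poisson relation for log counts, fitted
across clusters) with prior degrees of freedom estimated by matching the
moments of log variance ratios against the scaled-inverse-chi-square
model. The moderated t gains the prior's degrees of freedom; detection of
4-fold inductions rises above 95% while the null type-I error stays
within [0.02, 0.08] at α = 0.05 (both simulation-tested). The
un-moderated Welch test remains available (`moderate=False`, or
`test_cluster` directly), and an externally computed DE table
(cluster_id, log2fc, padj — e.g. from DESeq2) can be substituted
anywhere these results are consumed.

Significance thresholds downstream are always log2fc ≥ 1 (or ≤ −1) with
BH-adjusted p < 0.05. Comparisons are each transition timepoint against
the transition's reference.

## Switching and response calls

For each gene with a main TSS, every strictly upstream, ORF-external
alternative forms a pair with the main. At a timepoint where the
alternative is significantly ≥ 2-fold up, the main response is `down`
(significantly ≤ −2-fold), `up`, or `unchanged`. A *switching event*
additionally requires the alternative's TPM to reach the main's TPM at
that same timepoint; co-downregulation requires both pair members
significantly down. Gene- and transition-level calls aggregate as "any
pair, any timepoint fired". Raising the dominance threshold can only
shrink the switch set, and every switch is also an
alternative-upregulation event (both invariants tested).

The same two conditions applied between an ORF-internal cluster and a
promoter cluster of the same gene call internal↔promoter switches, with
the direction (which role was dominant before, which rose) recorded.

## Internal TSSs and truncated ORFs

A TSS cluster is internal when its apex lies in `[orf_start, orf_end)` on
the gene strand. Internal clusters significantly ≥ 2-fold up at ≥ 1
transition timepoint pass the *relaxed* cutoff. The *stringent* cutoff
additionally requires (i) internal TPM ≥ one third of the gene's main
promoter cluster at the same timepoint — computed on TSS-cluster TPM, the
internally consistent choice between the two possible readings (TSS-seq
vs mRNA-seq quantities), and (ii) a predicted downstream ORF of ≥ 300 nt.
ORF prediction scans the transcript-sense sequence from the internal apex
to the annotated stop in all three frames (sense strand only, standard
code) and reports the longest AUG…stop candidate entirely inside the
window; candidates may be out of frame with the annotation. The internal
transcript's leader length is the distance from the apex to the first
AUG in frame with the annotated ORF. Candidate protein sequences can be
exported for external domain scanning; no HMM engine is included.

## Determinants of main-TSS repression

For genes whose upstream alternative is significantly ≥ 2-fold up in one
aggregated comparison (default: last transition timepoint vs reference;
configurable), one record per gene collects: apex-to-apex pair distance
(entering the regression as log2 nt), the alternative's post-transition
level (log2(TPM + 0.5); the pseudo-count is ours and documented), the
main's pre-transition TPM, the main's log2 fold change (the response),
and a per-gene nucleosome occupancy-change covariate supplied externally
(its computation from chromatin data is out of scope; the synthetic
generator plants it with a negative effect). When a gene has several
qualifying alternatives one is chosen at random under a fixed seed, so
the table is reproducible.

Records split at 80 bp pair distance (proximal < 80 ≤ distal); groups are
compared by two-sample Kolmogorov–Smirnov (asymptotic p) and Pearson
correlation. Level subsets keep records with alternative level at or
above its 50th percentile and prior main level at or below its 50th
percentile — nearest-rank percentiles, boundaries inclusive.

The three-predictor fit is ordinary least squares with intercept. Each
predictor's effect size is its semi-partial correlation: the correlation
between the response and the residual of that predictor regressed on the
others. sr² equals the R² drop when the predictor is removed from the
full model (asserted to 1e-8–1e-10), and the reported p-values are the
OLS coefficient t tests, which test exactly these unique effects.
Collinear designs (condition number above 1e8) are rejected with the
variable names.

## Mutant de-repression

Mutant TSS clusters map to control clusters by ≥ 1 bp same-strand
overlap (maximal overlap wins; ties to the 5′-most control start);
mutant-only clusters are assigned to genes de novo. Per gene and per
replicate (replicates pair across genotypes by index), raw read counts of
the main TSS versus the summed alternatives form a 2×2 table with
genotype columns. The replicate-stratified stack is tested with the
Cochran–Mantel–Haenszel statistic

    ((|Σ_k (a_k − E_k)| − ½·continuity)²) / Σ_k V_k ,

with a_k the main/control cell and E_k, V_k the conditional
hypergeometric mean and variance given the stratum margins; p from
chi-square with 1 df. The continuity correction is on by default and the
corrected remainder is squared even when |Σ(a−E)| < ½, matching the
canonical R implementation bit-for-bit (verified against an independent
reference implementation to 1e-6 over 10,000 random stacks). Strata with
a zero margin carry no information and are dropped. BH adjustment runs
across genes ("adjusted p" without a named method in the field's usage;
BH chosen for consistency with the DE module).

A gene shows *increased relative expression* when the CMH adjusted
p < 0.05 and the pooled main-read proportion is larger in the mutant;
it is *de-repressed* when additionally its control time course showed the
repression signature (an upstream alternative significantly up with the
main significantly down). De-repressed genes are a subset of the
increased-relative-expression genes by construction, asserted on every
run. Relative main usage for reporting is main TPM over the summed TPM of
the gene's clusters (library-scale invariant); the test itself uses raw
counts.

## Synthetic data

The generator plants a genome (non-overlapping single-ORF genes on both
strands, ORF lengths multiples of 3 with proper start/stop codons,
intergenic spacing > 1.2 kb so assignment windows are unambiguous) and a
cluster architecture per gene, then draws replicate tracks.

Study conditions (the defaults): 100 repressed + 100 co-activated + 100
neutral event genes, 300 stable background genes, 30 internal-switch and
30 internal-induced genes, 20 spurious promoters, 50 internal-priming
artifacts; 4 timepoints (reference + 3), 3 replicates, 2×10⁶ counted ends
per library, NB dispersion 0.05. Main TSSs sit ~N(75, 15) nt upstream of
the AUG (so the measured median main 5′ UTR is ~75 nt); tandem spacings
mix a proximal (40–79 nt) and a distal (90–300 nt) regime; terminators
sit ~100 nt past the stop. Main levels are drawn 25–80 TPM and
alternative baselines 2–6 TPM — the weakly-expressed-promoter scale
(< 10 TPM); baselines much below ~2 TPM correspond to 2–6 reads at this
depth, where no three-replicate test retains power, so they are not a
useful validation regime. Induced alternatives rise 8–20×; repressed
mains fall 3–8× (deeper for distal pairs, the planted distance effect);
co-activated mains rise 3–6×; neutral alternatives are capped at 40% of
the main so planted classes stay crisp. Repressed genes draw occupancy
change ~N(0.8, 0.4) versus N(0, 0.4) otherwise — the planted negative
occupancy effect on the main's response.

Counts: each cluster spreads its expectation over ~8 nt with a geometric
profile (p = 0.5) decaying into the gene; replicate noise is
Gamma–Poisson with the gamma factor shared by all clusters of one gene in
one sample, so every position is marginally negative binomial
(variance m + 0.05 m²) while a gene's promoters fluctuate together — as
biological replicates do, and as the CMH test's null requires (drawing
the factors independently per cluster makes within-gene proportions
jitter and visibly inflates CMH type-I error). Dispersion 0 reduces to
Poisson. Spurious clusters are mirrored into a non-decapping control
track; priming artifacts place 3′ ends 1–5 nt upstream of planted A₂₀
tracts mid-ORF; chance A/T-rich windows near genuine terminators are
scrubbed from the random background so filter specificity can be scored
exactly. Background "housekeeping" loci on a separate contig absorb the
remainder of each library, keeping planted TPMs on their nominal scale
and stabilizing size factors. An mRNA-like coverage track consistent with
each isoform's span, and the per-gene occupancy covariate, are emitted
alongside.

What the generator does *not* emulate: promoter sequence content (no
TATA boxes or motifs), transcription-directional biases in cluster shape,
overlapping or intron-containing genes, tandem genes closer than the
assignment window, read-level errors and mappability, and
count correlation structure beyond the single gene-level factor. Passing
tests therefore demonstrate that the statistical logic of every stage is
correct and well calibrated under a realistic noise model — not that the
pipeline is robust to annotation errors or alignment artifacts in real
libraries.

Problem sizes used by the test suite and the acceptance script (a ~660
gene cohort, 500-case oracle sweeps, 10⁴ random CMH stacks, 100
regression seeds) were chosen so each validation estimate has small
sampling error while the whole suite completes in about a minute.

## Reproducibility

All randomness flows from explicit integer seeds; reruns with the same
seed and configuration produce byte-identical result tables (hashes are
asserted in the test suite, and the CLI writes a `hashes.json` per run).
The CLI stage subcommands recompute the pipeline from the dataset
manifest and write the requested stage's tables, guaranteeing
staged-versus-full equivalence by construction.

## Known limitations

* The DE engine is a moderated t on log counts, not an NB GLM; very low
  counts (< ~5 reads) remain hard calls, and externally computed DE
  tables are the recommended route when an NB engine's output exists.
* The spurious-TSS filter needs a non-decapping control; without one, no
  clusters are removed.
* Antisense and bidirectional-promoter signal is excluded, not modelled.
* UTR lengths assume single-ORF gene models; introns in UTRs are not
  represented.
* The CMH test conditions on margins; strong per-replicate composition
  shifts between genotypes (e.g. library-scale artifacts) are not
  distinguishable from usage shifts.
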