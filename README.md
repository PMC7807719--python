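# isoswitch

Genome-wide analysis of transcript-start and transcript-end heterogeneity
across cell-fate transitions, from strand-specific single-nucleotide
5′-end (TSS-seq-like) and 3′-end (TES-seq-like) count tracks.

During developmental transitions many genes express *alternative*
transcription start sites (TSSs) and polyadenylation sites alongside their
canonical *main* site, and in a recurrent regulatory motif an upstream
alternative TSS is induced, overtakes the main TSS, and represses it
(the LUTI-type switch). `isoswitch` implements the full analysis chain
needed to measure this from end-sequencing data:

1. **cluster calling** — distance clustering of single-nucleotide end
   positions (`maxDist = 5`, singletons kept above 3 TPM) and cross-sample
   consensus aggregation (≥ 1 TPM, merge within 20 nt, boundaries trimmed
   to the 0.05–0.95 cumulative-signal quantiles);
2. **artifact filtering** — internal-priming 3′ ends near degenerate
   (A)₂₀ tracts (≤ 8 mismatches, ≤ 5 nt downstream) removed before TES
   clustering; spurious TSS clusters flagged by Spearman correlation
   (r > 0.5, p < 0.05, cluster ± 5 bp) with a non-decapping control;
3. **gene assignment** — closest same-orientation gene within 100 bp, or
   100–1000 bp with 30-bp sliding-window mRNA-coverage support (plus
   5 %-of-gene-median and 5×-gene-max window criteria for 3′ ends);
   5′/3′ UTR lengths from the cluster apex;
4. **main/alternative classification** per transition and the alternative
   usage ratio `alt / (alt + main)`;
5. **differential expression** per cluster (median-of-ratios
   normalization, moderated t on log2 counts, BH adjustment; an external
   DESeq2-style table can be plugged in instead);
6. **switching analysis** — a switching event requires the upstream
   alternative ≥ 2-fold up (FDR < 0.05) *and* at least the main TSS's
   TPM at the same timepoint; main-TSS responses classified down / up /
   unchanged; internal↔promoter switches with direction;
7. **internal TSSs** — relaxed (2-fold induced) and stringent (≥ ⅓ of the
   main level, predicted ORF ≥ 300 nt) cutoffs, truncated-ORF prediction
   and in-frame leader lengths;
8. **determinant regression** — main-TSS fold change (Y, log2) explained
   by alternative level, log2 pair distance (80 bp proximal/distal
   split), and nucleosome occupancy change, with per-variable
   semi-partial correlations (sr);
9. **mutant de-repression** — replicate-stratified Cochran–Mantel–Haenszel
   tests of main-vs-alternative read proportions between mutant and
   control cells.

A synthetic-data generator (`isoswitch.synthetic`) plants genomes,
architectures, artifacts and negative-binomial replicate noise with full
ground truth, so every stage is validated end to end without any external
download.

## Worked example

```python
from isoswitch.synthetic import CohortParams, build_cohort_spec, simulate_tracks
from isoswitch.pipeline import run_cohort_analysis

params = CohortParams(n_repressed=20, n_coactivated=20, n_neutral=20,
                      n_stable=60, n_internal_switch=5, n_internal_induced=5)
spec = build_cohort_spec(params, seed=42)
dataset = simulate_tracks(spec, seed=43)
result = run_cohort_analysis(dataset)

events = result["tables"]["events"]
print(f"TSS clusters called: {len(result['tables']['tss_clusters'])}")
print(f"spurious clusters removed: {int(result['tables']['spurious_calls'].spurious.sum())}")
print(f"genes with a switching event: {events.loc[events.is_switch, 'gene_id'].nunique()}")
fit = result["regression"]
print(f"determinant regression: n={fit.n}, adjusted R2={fit.adjusted_r2:.2f}")
for name, sr in fit.semi_partial.items():
    print(f"  sr({name}) = {sr:+.2f}  (p = {fit.p_values[name]:.2g})")
```

prints

```
TSS clusters called: 380
spurious clusters removed: 20
genes with a switching event: 25
determinant regression: n=65, adjusted R2=0.29
  sr(alt_level) = +0.26  (p = 0.019)
  sr(log2_distance) = -0.27  (p = 0.012)
  sr(occupancy_change) = -0.55  (p = 1.9e-06)
```

The 25 switching genes are exactly the 20 planted repressed genes plus the
5 internal-to-promoter switch genes; all 20 planted spurious promoters are
caught by the non-decapping filter. In the regression, larger tandem
distances and occupancy gains between the paired TSSs associate with
deeper repression of the main TSS (negative sr), the effects planted by
the generator.

The same analysis runs from files through the CLI:

```bash
isoswitch simulate --out ds --seed 5              # FASTA/GFF3/bedGraph + manifest
isoswitch run --manifest ds/manifest.yaml --out results --seed 7
isoswitch switch --manifest ds/manifest.yaml --out results --seed 7   # one stage
```

Every stage writes plain TSV; `run` also writes `hashes.json`, and
identical seeds reproduce identical bytes.

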