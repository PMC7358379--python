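# plexquant

Pooled-reference TMT proteomics analysis: cross-plex relative
quantification, power-gated differential expression, and pathway
dysregulation statistics — with a ground-truthed synthetic-data generator
so every stage is testable without any external download.

## The problem

Isobaric labelling (TMT 11-plex) quantifies up to 11 samples in one
LC-MS/MS run, but a six-group × three-replicate toxicology study has 18
samples and must be split across two plexes. Comparing across plexes
requires a *bridge*: a pooled-reference channel, made by mixing all study
samples equally, included (here twice) in every plex. `plexquant`
implements the analysis such a design needs:

1. **Relative quantification.** Per protein, each sample's summed
   reporter-ion intensity is divided by the plex's pooled-reference
   abundance (arithmetic mean of its pooled channels):
   `r_is = I_is / mean(I_i,ref)`. Because the reference is the same
   mixture in every plex, any plex-level batch factor cancels — the merged
   matrix is invariant to rescaling a whole plex.
2. **Merging and QC.** Plexes merge on the proteins quantified in every
   sample of every plex (the "commonly detected" set). Reproducibility is
   reported as the coefficient of variation of the pooled-channel ratios
   per protein (sd/mean, in %).
3. **Differential expression.** Per protein and treatment:
   ratio = mean(treatment)/mean(control), a two-sided pooled-variance
   Student t-test, and post-hoc power of that test at the observed Cohen's
   d via the noncentral t distribution
   (δ = d·√(n₁n₂/(n₁+n₂)), power = P(|T| > t_crit)). Two gates are
   exposed: *p-gate* (p < 0.05, crossed with a fold-change bound,
   ratio > 1.15 or < 0.85) for protein counts, and *power-gate*
   (power > 0.8, i.e. β < 0.2) for pathway statistics.
4. **Pathway dysregulation.** For each pathway,
   *percent coverage* = 100·(detected members)/(annotated members) and,
   per treatment, *percent change* = 100·(changed members)/(detected
   members). A pathway is flagged *treatment-specific* when percent change
   ≥ percent coverage. Right-tailed Fisher (hypergeometric) enrichment is
   computed against either the full annotation universe or the detected
   proteins ("user dataset") as background.
5. **Reporting.** Mitochondrial/non-mitochondrial splits, treatment
   correlation matrices, row-max-scaled heat-map data, volcano tables, a
   functional-class breakdown, and a machine-readable summary that is
   re-derivable from the stage TSVs.

The synthetic-data generator (`plexquant.simulate`) emulates the two-plex
design — log-normal channel noise, per-plex dropout, batch scale factors,
modest planted effect ratios (1.15–2) on 10% of proteins per treatment,
and one planted pathway per treatment — and records the complete ground
truth for recovery scoring.

## Worked example

```bash
plexquant simulate --preset paper --seed 1 --out fixture/
plexquant run --config config.yaml     # config points at fixture/, control: DMSO
```

which prints

```
wrote 7 files to fixture/ (seed 1)
done: 4505 overlapping proteins, summary in results/summary.json
```

and the summary contains (abridged):

```
n_total_detected: 4987   n_overlap: 4505
median pooled CV %: 1.35   frac<5%: 1.0
FCCP:          changed=440 (9.8%), power-gate=799, flagged pathways=['PW001']
dinoterb:      changed=437 (9.7%), power-gate=778, flagged pathways=['PW002']
picoxystrobin: changed=432 (9.6%), power-gate=775, flagged pathways=['PW003']
pinacyanol:    changed=436 (9.7%), power-gate=516, flagged pathways=['PW004']
triclocarban:  changed=439 (9.7%), power-gate=523, flagged pathways=['PW005']
top FCCP enrichment: PW001, p = 5.3e-12 (k = 24)
```

Reading this: of 4,987 proteins detected in at least one plex, 4,505 are
quantified in all 22 channels and form the analysis set. Pooled-channel
CVs (median 1.35%, all below 5%) confirm the two plexes were bridged
reproducibly. Each treatment changes ≈10% of proteins under the
p + fold-change gate — matching the generator's planted 10% — and each
treatment's planted pathway (`PW001`–`PW005`) is both flagged by the
coverage-vs-change statistic and its top Fisher-enrichment hit.

The same stages are available as library functions
(`relative_abundance`, `merge_common`, `pooled_cv`, `differential_table`,
`pathway_dysregulation`, `fisher_enrichment`, …) and as the subcommands
`validate`, `simulate`, `quantify`, `diffexp`, `pathways`, `run`,
`summarize`.

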