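# Methods

## Study design and quantification model

The pipeline targets multi-plex isobaric (TMT) experiments bridged by a
pooled internal reference: each plex carries, besides treatment/control
replicates, one or more channels of an equal mixture of *all* study
samples. For protein *i* in sample *s* of plex *b*, the measured summed
reporter intensity is modelled as

    I_ibs = a_i · e_ig(s) · c_b · ε,   ε ~ logNormal(0, σ²)

with `a_i` the baseline abundance, `e_ig` the treatment effect ratio
(1 for the control), `c_b` a plex-level batch factor, and multiplicative
channel noise. The pooled channel carries the mean of all sample signals
in place of `a_i·e_ig`. The relative abundance

    r_ibs = I_ibs / mean_over_ref_channels(I_ib,ref)

cancels `c_b` exactly, which is what makes concatenating plexes valid.
The per-plex reference abundance is the **arithmetic mean** of the pooled
channels; with a single pooled channel this degenerates to plain division
with no rescaling, which is why the mean was chosen over the sum.
Proteins with missing or zero reference are dropped (and counted), never
imputed. No further normalization (median centering, total-intensity
scaling) is applied by default because the ratio-to-reference step is the
model; the merge keeps the complete cases — proteins quantified in every
sample of every plex.

## Pooled-channel CV

Reproducibility is summarized by the per-protein CV (sample sd with n−1
denominator over mean, in %) of the pooled-channel *ratios*, combined
across plexes and per plex. Note a subtlety: ratios are self-normalized
by their own per-plex reference mean, so with two pooled channels the
log-ratio noise is (ε₁−ε₂)/2 with sd σ/√2 — at σ = 0.02 the median CV is
≈1.4%, not the raw-channel √(e^{σ²}−1) ≈ 2%. The 5% threshold used for
the "fraction reproducible" summary refers to the ratio CV.

## Differential statistics

Tests run on natural-scale ratios (the fold-change conventions 1.15/0.85
are natural-scale; a log2 option exists). Per protein and treatment:

* **ratio** — mean of treatment replicate ratios over mean of control
  replicate ratios;
* **p-value** — two-sided *pooled-variance* Student t-test
  (df = n₁+n₂−2). Student rather than Welch because the design has equal,
  tiny group sizes and spreadsheet-style pooled t is the convention this
  pipeline mirrors. Zero pooled variance yields p = 1 (equal means) or
  p = 0 (unequal, logged);
* **post-hoc power** — power of that test at the *observed* Cohen's
  d = |x̄−ȳ|/s_pooled, via the noncentral t distribution with
  noncentrality δ = d·√(n₁n₂/(n₁+n₂)): power = P(T > t_crit) +
  P(T < −t_crit). At d = 0 this equals α exactly. The opposite-sign tail
  from scipy can return NaN at large δ; it is vanishingly small there and
  is zeroed, with the result clipped to [0, 1]. Zero pooled sd gives
  power 1 (means differ) or α (equal). Post-hoc power is the only
  coherent reading of a per-protein power gate when no a-priori effect
  size exists; it is a monotone transform of |t|, so the power-gate is
  effectively a second, more stringent |t| threshold.

Two gates are exposed and deliberately kept apart:

* the **p-gate** (p < 0.05) crossed with a fold-change bound is used for
  headline changed-protein counts;
* the **power-gate** (power > 0.8, β < 0.2) feeds the pathway statistics.

Fold-change modes: `symmetric015` (ratio > 1.15 or < 0.85 — a symmetric
reading of "0.15-fold change") and `ipa` (> 1.15 or < 0.8, the asymmetric
variant used by enrichment-upload conventions). Both are implemented
because the two conventions genuinely coexist; neither is asserted as
uniquely correct, and the run log always records which was used.
Zero-variance (degenerate) proteins keep their edge-case p/power values
but are excluded from every gate rather than crashing or being flagged.
No multiple-testing correction is applied by default (raw p-values are
the convention being mirrored); Benjamini–Hochberg would be a
straightforward extension and is intentionally not silently enabled.

## Pathway statistics

For pathway P with `n_annotated` members in the annotation universe,
`n_detected` of them in the commonly-detected set and, per treatment,
`n_changed` of the detected members passing the power-gate:

    percent_coverage = 100 · n_detected / n_annotated
    percent_change_t = 100 · n_changed_t / n_detected

P is flagged **treatment-specific** for t when
`percent_change_t ≥ percent_coverage`. Ties flag true by default (`ge`);
a strict `gt` rule is selectable. Coverage is a property of the dataset
(detection depth), so the flag asks whether a treatment perturbed at
least as large a share of the visible pathway as the instrument could see
of the pathway at all. Pathways with no detected member report coverage 0
with undefined percent change and no flags.

Enrichment is the right-tailed hypergeometric (Fisher exact) p-value
P(X ≥ k) with k = |changed ∩ pathway ∩ background|, drawn n = |changed|
from N = |background| containing K pathway members. Two backgrounds are
supported: the full annotation universe (`global_annotation`) and the
detected proteins (`user_dataset`); the latter removes detection bias and
is generally more conservative when pathways concentrate among detectable
proteins. This open, comparable statistic replaces proprietary
pathway-scoring engines; its p-values are not expected to match theirs
numerically.

The functional-class breakdown assigns each (mitochondrial) protein to
exactly one of twelve classes (OXPHOS, TCA cycle, lipid metabolism,
redox, transport, cell death/defense, signaling, protease, protein
targeting, RNA/DNA/protein synthesis, nucleotide metabolism, carbohydrate
metabolism); unmapped proteins are counted as `unassigned` with a logged
count.

## Synthetic-data generator

The generator's defaults are the study conditions the analysis assumes:
two 11-channel plexes, five treatments + DMSO control in triplicate
(set 1: FCCP/dinoterb/picoxystrobin; set 2: pinacyanol/triclocarban/DMSO),
two pooled-reference channels per plex; 5,000 proteins with baselines
log-uniform over 10⁵–10⁷; 10% of proteins perturbed per treatment with
ratios uniform in [1.15, 2] (reciprocal with probability ½ for a
down-regulated mix); channel noise σ = 0.02 (pooled-ratio CVs < 5%,
matching the reproducibility regime the analysis expects); per-plex
whole-protein dropout 5% (a protein undetected in one MS run is absent
from that plex's export); plex batch factors (1.0, 1.25); 12% of proteins
tagged mitochondrial with uniformly assigned functional classes; 186
pathways of 25–80 members, 35% of each pathway's members drawn from an
annotated-but-undetectable pool (so percent coverage sits near 60%
rather than 100%), and one *planted* pathway per treatment with 70% of
its measurable members drawn from that treatment's true effect set.

Intensities are rounded to integers, like the count-like summed reporter
intensities of vendor protein-level exports. A deliberate numerical
consequence: multiplying a plex's integer intensities by 10 is exact in
float64, the two-channel reference mean scales exactly, and IEEE division
is correctly rounded — so the plex-rescaling invariance of the merged
matrix holds *bit for bit*, and the test suite asserts it at that
strength. With fractional intensities the invariance would hold only to
1 ulp.

Everything is drawn from `numpy.random.default_rng` streams derived from
a single seed; identical parameters and seed reproduce every output file
byte for byte.

What the generator does **not** emulate: peptide-level aggregation and
shared peptides, reporter-ion isotope interference and ratio compression,
intensity-dependent noise and missingness (dropout is abundance-blind),
correlated effects across treatments, and annotation errors. Passing
tests therefore demonstrate the pipeline's arithmetic, gating and
recovery behaviour under the stated noise model — not robustness to those
real-data pathologies.

## Calibration behaviour and a known limitation

On independent groups the pooled t-test is exactly calibrated (a
Monte-Carlo test verifies a 5% rejection rate at α = 0.05). The pipeline
as a whole, however, tests *ratios that share a per-plex pooled-reference
denominator*. Within one plex the shared reference cancels from the
t statistic (it is scale-invariant), but when treatment and control sit
in different plexes each group carries its own reference noise, which
shifts the two group means jointly without inflating the within-group
variance the test estimates. With two pooled channels per plex the
between-group variance gains σ² on top of the 2σ²/3 the test accounts
for, inflating the null rejection rate from 5% to ≈15% for cross-plex
comparisons (≈11% pooled over this design, where three of five
treatments sit opposite the control). This is a property of
pooled-reference bridging itself, not of the implementation; any analysis
of such a design that treats per-plex ratios as independent observations
inherits it. Consequences and mitigations:

* the p+fold-change gate is barely affected (the reference noise is far
  smaller than the 0.15 fold-change floor), which is one more reason the
  headline protein counts use it;
* the power-gate and p-gate null rates on cross-plex comparisons are
  conservative-breaking (too permissive); pathway statistics are driven
  by planted-signal contrast large enough to dominate this leak;
* placing the control in the same plex as the treatments of interest, or
  adding replicate-level blocking, removes the effect; both are design
  choices upstream of this package.

## Numerical and degenerate-input choices

* Missing cells: empty string or `NA` on input; NaN internally; merged
  matrices contain none by construction.
* Reference mean uses `skipna`: a protein quantifiable through one of two
  pooled channels is kept; only all-missing/zero references drop it.
* Correlations: Pearson on ratio vectors; fewer than 3 proteins is an
  error, zero variance reports NaN rather than failing.
* Heat-map scaling divides by row maxima, which are strictly positive by
  the matrix invariant.
* Volcano tables keep p < 0.05 and |ratio−1| ≥ floor (0.15 default,
  0.5 for the top non-mitochondrial view); the conventional significance
  line is −log10 p = 1.3.
* Enrichment uses `hypergeom.sf(k−1, N, K, n)`; the suite proves equality
  with exact integer enumeration for every configuration with N ≤ 25.
* Ordering is deterministic everywhere (first-plex protein order, design
  channel order, sorted JSON keys), so reruns are byte-identical.

## Problem sizes

The shipped default scales — 5,000 proteins for the study-shaped fixture,
1,000 for the null fixture, 100,000 draws per point for the Monte-Carlo
power oracle, exhaustive Fisher enumeration to N = 25 — were chosen so
the statistical assertions have comfortable margins (binomial standard
errors well inside the asserted tolerances) while a full test-suite run
stays in the tens of seconds.
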