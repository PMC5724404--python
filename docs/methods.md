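# Methods

## Model and assumptions

The package treats the fluorescence of a non-expressed probe on an
RMA-normalized array as draws from a unimodal background distribution that
is approximately Gaussian on the log2 scale, shared across probes within one
experiment but specific to each experiment (scanner, labeling and
hybridization conditions shift it). Because female genomes lack a Y
chromosome, Y-chromosome probes in female samples sample exactly this
background: any signal they show is cross-hybridization, not transcript.

The threshold is the one-sided upper confidence limit of that background:

    T = mean(F) + z(c) * sd(F)

where `F` is the pooled female fluorescence of the selected Y probes, `c`
is the confidence level (default 0.95, giving z = 1.6449), and sd uses the
n−1 denominator appropriate to small-sample upper-limit estimation. A probe
with fluorescence at or above `T` in a sample is called expressed there.
By construction about `1 − c` of true background values exceed `T`, so a
~5% false-positive call rate among silent probes is inherent to the design,
not a defect; the pipeline's warning when a female sample shows Y-specific
fluorescence above `T` is therefore only raised per sample, and a single
flagged sample on a 95% limit is expected noise while several flagged
probes in the same sample suggest aneuploidy or a sex-label error.

Key assumptions, and what violates them:

- **Mixed-sex cohort.** At least two samples per sex; an all-male or
  all-female study cannot derive a threshold (use
  `run_external_threshold` with a threshold obtained elsewhere).
- **Probe-level sex specificity.** Only Y probes whose male/female ranges
  are disjoint with males high qualify; Y genes with X homologues or in the
  pseudoautosomal region fail this and are correctly discarded.
- **One threshold for all probes.** The probe effect is *not* modeled per
  probe; calls near `T` (roughly `T` ± 1 log2 unit) are the least reliable,
  and genes with low fluorescence just above `T` may still be silent.
- **No sex-chromosome aneuploidy.** Excluding such subjects is the
  caller's responsibility.

## Procedure and numerical choices

1. **Sex test.** Two-sided Mann–Whitney U per Y probe (sidedness is a
   deliberate default: the selection step should also flag the anomalous
   female-high case rather than silently one-siding it away). For tie-free
   inputs with pooled n ≤ 12 the exact permutation null is used so small-n
   p-values are reproducible to machine precision; otherwise the normal
   approximation with tie correction. Two identical constant groups give
   p = 1 (no separation), not an error.
2. **Overlap filter.** Non-overlap means `min(male) > max(female)`
   (male-high orientation); a sign-agnostic disjointness mode exists by
   flag for exploratory use. Testing and filtering operate at probe level —
   a gene may contribute several probes — and genes are reported as the
   distinct symbols of selected probes. The significance-stage gene count
   aggregates by "any significant probe" by default ("all probes" by flag).
3. **Pooling.** Female values of all selected probes form one vector; a
   per-probe-threshold-then-max variant was rejected because the method's
   point is a single experiment-wide threshold. The one-sided quantile is
   the recorded default (the threshold is an *upper limit* of background);
   a two-sided 1.96 mode is selectable.
4. **Level bins.** below = [−∞, T), low = [T, 6), medium = [6, 10],
   high = (10, ∞). The interval edges 6 and 10 are conventional landmarks
   on the log2 scale; the half-open-below convention makes the bins a clean
   partition (6 → medium, 10 → medium, a value exactly at T → low) and is
   stated in every output header. Bins require T ≤ 6.
5. **Top-fraction profiling.** Per sample, the top ⌈fraction · P⌉ probes by
   fluorescence (ties broken by probe id for cross-platform determinism);
   per-sample sets are intersected across all samples, then mapped to
   distinct gene symbols. Intersecting per-array lists, rather than ranking
   a pooled average, is deliberate: a gene must be top-ranked in *every*
   sample to enter the signature.
6. **Over-representation.** Hypergeometric upper tail P(X ≥ k) computed as
   a log-space sum of pmf terms (gammaln + logsumexp) so tails of order
   1e-60 keep relative accuracy; Benjamini–Hochberg across sets; default
   background is all genes in the annotation (user-overridable); sets with
   fewer than 2 background members are skipped as degenerate; default
   enriched cutoff is adjusted p ≤ 1e-9 (a deliberately stringent value
   suited to the very dense signals of top-expression signatures).
   Enriched-set counts and p-values depend on the gene-set release and
   background in use and are not comparable across databases.
7. **qPCR validation.** Spearman rank correlation (average ranks on ties)
   between probe fluorescence and Ct, paired per probe per sample
   (`collapse="mean"` averages a gene's probes first). Both the signed rho
   and |rho| are reported: Ct is inversely related to abundance, so
   agreement is a *negative* rho, but magnitude is what is usually quoted.
8. **External threshold.** For matrices without sex structure a
   user-supplied threshold is applied; a probe is non-expressed when below
   threshold in every sample. No attempt is made to derive a threshold
   without female samples.

Degenerate inputs: empty groups, constant vectors in correlation, missing
sex labels, non-finite values and inconsistent count parameters raise
errors naming the offending item; they are never silently imputed.

## Synthetic data

`SimulationConfig`/`generate` emulate the statistical structure the method
relies on: background probes ~ Normal(bg_mean, bg_sd) in every sample,
Y-specific probes with `male_effect` added in males only, and planted
expressed probes at low/medium/high level means. Defaults describe a
16-sample mixed-sex cohort — 9 males, 7 females, 124 Y probes of which 4
male-specific, background mean 2.8 / sd 0.5 log2 units (a typical RMA
floor), male effect 6 log2 units (Y-specific transcripts are far above
background in males), level means 5 / 8 / 12 at noise sd 0.3. Seeds are
required arguments; identical seeds give byte-identical output.

Not emulated: per-probe affinity offsets (the probe effect), correlation
between probes, batch structure, and heavy-tailed noise. Passing tests on
this generator therefore demonstrates correctness of the *procedure* under
its own model — exact recovery of planted male-specific probes, threshold
convergence to mean + 1.6449·sd of background — not robustness to real
arrays' probe-level heterogeneity, which a single global threshold by
design does not capture.

`make_paper_fixture` is a fully synthetic, deterministic worked-example
dataset whose *constructed* truth mirrors the qualitative findings expected
of a leukocyte cohort: 124 Y probes; exactly 4 probes (3 genes: DDX3Y,
EIF1AY, TXLNG2P) significant and non-overlapping; 23 Y genes sex-significant
in total (the other 20 significant but range-overlapping by construction);
sex-neutral probes built by dealing sorted draws alternately to the sexes so
their U statistic sits at its null mean; the pooled female fluorescence of
the 4 selected probes affinely rescaled to mean 2.85 and sd 0.699 so the
one-sided 95% limit is exactly 4.0; an SRY-like probe capped below
threshold everywhere; 11 housekeeping genes floored above it; and a
13-gene qPCR panel with Ct = 34 − 1.5·Fi + Normal(0, 2) — a slope and
dispersion chosen as a typical array-vs-qPCR concordance regime, which
yields |rho| ≈ 0.88. These values are construction targets of the fixture,
not measurements of any real cohort.

## Problem sizes

The test suite and acceptance script run on desk-scale data chosen to make
every check exact or statistically well-powered while remaining quick: the
500-probe × 16-sample fixture; exhaustive enumeration oracles at pooled
n ≤ 10 (Mann–Whitney) and N ≤ 12 (hypergeometric); 100 seeded replicates of
130-probe recovery runs (400 planted probes, 12,600 neutral ones — binomial
slack on the false-positive rate is ±0.6%); a 10,000-probe background matrix
for external-threshold classification; and a 1,600-value pooled female
vector for the convergence check (Monte-Carlo tolerance ±0.06).

## Known limitations

- The threshold is experiment-specific and cannot be transferred between
  datasets; each study needs its own female samples.
- A single global threshold ignores probe-specific background; calls close
  to `T` should be treated as tentative (per-probe methods are
  complementary here, and the package only *counts concordance* with their
  call sets rather than reimplementing them).
- Normalization is upstream: the package validates that inputs are finite
  and rectangular but cannot detect an un-normalized or linear-scale
  matrix beyond the explicit `--log2` flag.
- Gene-level summaries use "any expressed probe" by default, which is
  permissive for genes with many probes.
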