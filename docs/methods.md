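# Methods

## Problem and model

`tmtquant` analyses multiplexed isobaric (TMT six-plex) reporter-ion
quantification experiments in which five samples — an unexposed
*Bacillus pumilus* SAFR-032 ground control and four space-surviving
strains (UV-Space, UV-Mars, Dark-Space, Dark-Mars) — are labeled on
channels 126–130 and a pooled reference (equal-mass mix of all five
samples) occupies channel 131.  Each plex is one biological replicate,
measured in technical triplicate; two plexes are combined into a single
quantitative comparison.

The observation model behind both the simulator and the normalization
stack is multiplicative:

    x[p, c, j, r] = b[p] · f[p, c] · L[c, j] · B[j] · ε

where `b[p]` is the protein baseline, `f[p, c]` the true fold change of
condition c relative to the control (`f = 1` for unchanged proteins),
`L[c, j]` a per-channel loading/labeling factor in plex j, `B[j]` a
per-plex batch factor, and `ε` unit-mean log-normal noise.  The pooled
reference channel's true signal is the arithmetic mean of the five
samples' `b·f`, and it carries its own loading factor and noise draw:
it is a measured channel, not an oracle.

## Ingest

PSM records are filtered on co-isolation interference (kept when
≤ 75 %, inclusive) and mean reporter signal-to-noise (kept when
strictly > 10); the asymmetric boundary semantics mirror how the two
thresholds are conventionally phrased ("threshold was 75 %" vs "greater
than 10").  Protein abundance per channel is the *sum* of its surviving
PSM intensities.  A protein counts as quantified in a technical
replicate only if its row exists with all six channels finite and
strictly positive — a zero is treated as not quantified, which keeps
the later log2/ratio arithmetic total.  Proteins must be quantified in
every technical replicate of a plex (complete-case filter); technical
triplicates are then averaged as raw intensities, before any
normalization, and the protein set is intersected across plexes.
Averaging intensities rather than ratios is a deliberate choice: it
keeps the additive rollup and the normalization factors commutative,
and the alternative is a one-line change at the call site.

Protein inference/grouping is out of scope: `protein_id` is taken
verbatim from the input table.

## Normalization

Three stages, applied to the intersection of the plexes' protein sets,
default order SL → TMM → IRS (an ordered-subset `stages` option allows
the variant that defers TMM until after batch correction):

1. **Sample loading (SL).**  Each channel is multiplied by
   (grand mean of channel totals)/(channel total).  Idempotent;
   factors are recorded.
2. **TMM.**  For channel k against a reference channel r (chosen as the
   channel whose library-size-scaled 75th percentile is closest to the
   mean of all channels' — the standard convention), per-protein
   M = log2((x_pk/N_k)/(x_pr/N_r)) and A = ½·log2(x_pk·x_pr/(N_k·N_r)).
   The central 40 % of M (trim 0.30 per tail) and 90 % of A (trim 0.05)
   are kept (rank-based, intersection) and the factor is 2^(weighted
   mean of surviving M) with inverse asymptotic-variance weights,
   treating intensities as if counts; an unweighted switch exists
   because reporter intensities are not true counts.  Factors are
   rescaled to geometric mean 1.  The *applied* per-channel divisor is
   the effective size N_k·f_k (again geometric mean 1): a channel that
   is a pure s-fold copy of the reference has factor 1 but effective
   scaling s, so pure scale shifts are removed while compositional
   trims behave like the canonical estimator.  After SL the totals are
   equal and the distinction vanishes.  If fewer than 10 proteins
   survive trimming the untrimmed mean is used with a warning.
   The implementation reproduces edgeR's `calcNormFactors(method="TMM")`
   to ~1e-12 relative on integer matrices (frozen cross-check in the
   test suite) and an independent brute-force evaluation of the formula
   to 1e-10 on random matrices.
3. **IRS.**  Per protein, the anchor is the geometric mean of the
   reference-channel intensities across plexes (geometric, because the
   factors are multiplicative); every channel of plex j is multiplied
   by anchor/reference_j.  Afterwards each protein's reference value is
   identical across plexes to floating tolerance.  Proteins with a
   nonpositive reference intensity are dropped with a logged reason.

The `NormalizationReport` records every multiplier actually applied and
can replay them against the raw input to reproduce the output
bit-for-bit.  The final table is log2-transformed, one column per
(condition, plex).

The published description of TMM ("aligning the median of the
distribution") loosely paraphrases the method; the canonical trimmed
weighted mean is implemented and the discrepancy documented here rather
than resolved.

## Differential abundance

Per strain, the control-relative log2 ratio is the across-plex mean of
(strain − control) within-plex differences.  A classical one-way
fixed-effects ANOVA across the five strains uses the two plexes as
replicates (technical replicates were already averaged): 4 between- and
5 within-group degrees of freedom.  This is statistically weak but
faithful to the study design being emulated; degenerate rows are
flagged (all-identical → p = 1 by convention; zero residual variance
with unequal means → p = 0).  No multiple-testing correction is applied
to the calls — significance is raw P ≤ 0.05 — but a Benjamini–Hochberg
q-value column is emitted alongside for transparency.

Up/down calls use |log2 ratio| ≥ log2(1.5) (inclusive), independent of
significance; counting reports per-strain totals, per-strain uniques
(differential in exactly one strain), the ≥1-strain union and its
ANOVA-significant subset, with the identity
union = Σ uniques + multi-strain checked on every run.  Reported fold
changes are 2^|log2| rounded half-up to one decimal.  Strain profiles
are clustered agglomeratively (Euclidean distance, average linkage —
the source names neither; scipy's deterministic tie-breaking) and
exported as a quoted-label newick string.

## COG summaries

Annotations come from a user-supplied delimited mapping; a bundled code
table expands both the table-style abbreviations (CTM, EPC, …) and the
standard single-letter COG codes.  Unannotated proteins are "function
unknown".  A protein with k categories contributes one count to each
(standard bar-chart convention), and unchanged calls contribute
nothing; the conservation identity (total counts = Σ per-protein
|categories| × |differential strains|) is asserted in tests.  The
summary counts the fold-change set, not the significant subset,
matching the figure convention it emulates.

## Survival and assay statistics

Surviving fraction is CFU(d)/N0 with N0 the dose-0 count; log reduction
is log10(N0/CFU).  Zero-colony plates are censored at the detection
limit (default 10 CFU/ml) and reported as bounds, never as infinite
reductions.  Replicate dilution series are averaged as back-calculated
CFU/ml before fractions are taken.  Enzyme-activity/ATP endpoint
comparisons use one-way ANOVA plus Tukey's HSD on the pooled
within-group variance (scipy's studentized-range implementation;
Tukey–Kramer under unequal n) with star tiers ≤0.05 / ≤0.005 / ≤0.0001.

## Synthetic data: what it does and does not emulate

The generator reproduces the study design (2 plexes × 3 technical
replicates × 6 channels, pooled reference on 131) and its nuisance
structure: log-uniform per-channel loading factors, per-plex batch
factors, compositional bias (a configurable minority of truly changed
proteins), unit-mean log-normal noise parameterized by CV
(σ² = ln(1+CV²)), and whole-row dropout per technical replicate —
matching the complete-case filter's semantics.  PSM-level export splits
protein rows by Dirichlet(5) weights and attaches co-isolation and S/N
covariates from user-supplied distributions, emitting records on both
sides of both filters.  Survival counts are Poisson draws around
N0·10^(−slope·dose); when dose 0 is simulated the curve's N0 is the
observed dose-0 draw so the curve's invariants hold.

Defaults are the study conditions where stated (2 plexes, 3 technical
replicates, batch factor 2×, loading up to 1.5×, 1000 proteins with 100
differential between 1.5× and 4×) plus two free choices: noise CV 0.1
(a typical technical-replicate CV for reporter-ion data; the source
reports none) and dropout 0.05.  Each differential protein changes in
one randomly chosen strain by default (`differential_conditions="all"`
spreads it), with random direction (`fold_change_sign` restricts it).
All randomness flows from one seed through `numpy.random.SeedSequence`
with fixed spawn keys (0 → truth, (1, crc32(plex_id)) → that plex), so
stages are independently reproducible.

Not emulated: chromatography, isotopic impurity leakage between
channels, spectrum-level interference (co-isolation is a scalar
covariate only), peptide-to-protein inference ambiguity, and
intensity-dependent missingness.  Passing recovery tests therefore
demonstrates that the pipeline inverts the modeled nuisances — loading,
batch, composition, noise, dropout — not that it corrects ratio
compression or impurity effects in real reporter-ion data.

## Numerical choices and problem sizes

Tolerances: IRS postcondition and replay checks assert at ~1e-10
relative or exact bit equality; TMM oracle equivalence at 1e-10;
boundary comparisons (±1.5-fold, co-isolation ≤75, S/N >10) are exact.
Calibration experiments use 5000 proteins (ANOVA type-I error) and 5000
Monte-Carlo runs (Tukey family-wise error, evaluated through the
equivalent max-studentized-range decision rule, spot-checked against
the pairwise procedure); recovery experiments use 1000 proteins with
100 spiked at 2-fold.  These sizes give Monte-Carlo standard errors
well inside the asserted bands while keeping the whole suite fast.

## Known limitations

- With 2 biological replicates the per-protein ANOVA is underpowered
  and its p-values should be read as descriptive flags, as in the
  emulated analysis; no moderated-variance model is provided.
- IRS factors are per-protein; proteins absent from a plex's reference
  channel cannot be rescued.
- The prose fold statements for the MarR regulators (~1.5-fold
  Dark-Space, ~1.6-fold UV-Space) do not match either MarR table row
  under 2^|x|; they are excluded from the worked example rather than
  reconciled.
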