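# Methods

## Scope and data model

The package implements the count-level analysis of an nCounter miRNA
expression experiment.  Its unit of input is the RCC lane file: sectioned
text with a `Code_Summary` table of `CodeClass,Name,Accession,Count` rows.
The supported code classes are Endogenous, Positive, Negative, Ligation and
Housekeeping; `Reference` and `SpikeIn` are accepted as panel-version
synonyms, and probes with unrecognised classes are kept but excluded from
all control computations (with a warning) rather than dropped.  Counts are
non-negative integers; all downstream matrices are pandas DataFrames
indexed by probe name with one column per lane.

## Normalization

Both normalization stages use the same construction: a lane's factor is the
cohort's arithmetic mean of per-lane geometric means of a control probe set,
divided by that lane's own geometric mean.  This is the vendor-style factor
definition; it makes identical lanes come out at exactly 1, is invariant to
globally rescaling all counts, and equalizes the control geometric means
across lanes after application.  Zero counts entering a geometric mean are
replaced by 1 — the smallest observable digital signal — with a warning.

The two stages are sequential: positive factors are estimated from the raw
spike-in counts, content factors from the *positive-normalized* reference
gene counts.  Estimating both from raw counts would correct the technical
lane scale twice (each factor alone is an estimate of its reciprocal), a
failure mode that the synthetic recovery tests exposed directly.  Flag
ranges are closed intervals — [0.3, 3.0] for the positive stage,
[0.1, 10.0] for the content stage; a factor exactly at a boundary passes.
Flagged lanes are retained and recorded, never silently excluded; exclusion
is left to the caller.

## Background and detection

The limit of detection is computed per lane from that lane's own eight
negative controls as mean + k·SD with k = 2 by default and the n−1 (sample)
SD — lanes differ in ambient background, so no pooling.  Detection is a
strict comparison: a probe is detected when its normalized count exceeds
the lane LOD (a count exactly at the LOD is not detected).  The prevalence
filter retains endogenous miRNAs detected in strictly more than a fraction
(default 0.5) of the lanes under consideration.  Two denominator
conventions exist for that rule — the contrast's tumor-plus-control union,
and the case group alone; the union is the default and both are selectable
(`prevalence_mode`).  Detection normally runs on normalized counts against
the raw-negative LOD; a raw-count detection mode is available
(`detection_source: raw`).

## Differential expression

Group means are arithmetic means of normalized counts (the printed group
averages of the motivating study reproduce their printed fold changes under
plain division, which fixes this estimator).  The signed fold change is the
case/control ratio when ≥ 1 and the negative reciprocal otherwise, so the
output never lies strictly between −1 and 1 and −2 means halved.
Significance is the fold-change magnitude criterion alone, strict:
|FC| > 2.  A two-sided Welch t-test on log2(count+1), BH-adjusted across
the retained probes, is reported for context; it is not part of the call
because the upstream instrument software's p-value algorithm is unspecified
and not reproducible.  Group means of zero are floored at 1.0 (the same
smallest-signal convention as the geometric-mean guard) so the ratio is
defined for probes retained by a union-denominator filter that are silent
in one group.  Ordered output ties are broken by probe name for
determinism.

## Target annotation

All miRNA–target lookups are offline against a TSV with a closed evidence
vocabulary (`validated` / `predicted`).  The packaged default table curates
the melanoma-relevant interactions of miR-146a-5p (TRAF6, IRAK1, SMAD4,
WASF2) and miR-4286 (TGFB1, TGFBR2, RUNX3, HDAC3, WASF2; PTEN and MAP3K1
as predictions); it is a small curated snapshot, not a database export, and
any table with the same columns can be substituted.  Matching strips the
`hsa-` species prefix and is case-insensitive.  The inverse-expression
filtering that a paired mRNA dataset would allow is represented only by the
evidence filter hook — no mRNA data, no guessed procedure.

## The synthetic cohort generator

The generator emulates the study conditions: 6 control / 8 BRAF wild-type /
7 BRAF-mutant lanes, 827 endogenous miRNAs, and the full control
architecture (six positives at 128/32/8/2/0.5/0.125 fM, eight negatives,
six ligation controls, five reference genes).  Default parameters, chosen
once as representative of FFPE miRNA panels:

| parameter | default | meaning |
|---|---|---|
| `baseline_log_mean`, `baseline_log_sd` | 3.0, 1.6 | lognormal abundance of unplanted miRNAs (median ≈ 20 counts; a wide spread so a realistic fraction of the panel sits below the LOD) |
| `effect_map` | 6 up / 52 down | planted signed folds at the reported magnitudes: the named up-regulated miRNAs at their printed folds (6.33, 4.19, 3.61, …), named down-regulated ones at −17.3/−11.6/−10.5, plus 49 synthetic-named down probes spaced over the 4–20× band |
| `effect_baseline` | 100 | control-side mean of planted probes (down-planted probes sit at baseline×\|fold\| in controls), keeping planted effects detectable on both sides |
| `lane_scale_sigma` | 0.4 | lognormal σ of the per-lane technical scale the normalization must remove |
| `nb_dispersion` | 0.1 | negative-binomial dispersion (var = μ + 0.1 μ²) of endogenous and reference counts — FFPE-like overdispersion |
| `background_lambda` | 12 | Poisson mean of negative controls |
| `ligation_neg_mean` | 5 | Poisson mean of ligation negatives, below ambient background: with equal means the below-LOD rule would fail by construction, whereas real unligated constructs clear it with a margin |
| `pos_scale` | 250 counts/fM | positive titration gain (POS_A ≈ 32 000, POS_E ≈ 125 counts) |

Each probe family draws from its own seeded random stream, so changing one
family's parameters (e.g. doubling `pos_scale`) leaves all other counts
bit-identical.  A `zero_noise` mode replaces every draw by its rounded mean
with identity lane scales, giving exact planted-fold recovery for identity
tests.  The ground-truth ledger records lane scales, planted folds, true
group means, and the detectable set — probes whose true means exceed the
expected LOD (λ + 2√λ under Poisson background; exactly rint(λ) in
zero-noise mode) in every group.

What the generator does *not* emulate: cartridge/batch covariates,
ligation-efficiency bias tied to RNA fragmentation, probe-specific affinity
differences, or correlated miRNA programs.  Passing recovery tests
therefore demonstrate that the pipeline's arithmetic and filtering recover
known signals under realistic count noise — not that the biological
conclusions of any particular tissue study are reproduced, which would
require the unreleased raw data.

## Numerical choices and problem sizes

Factor idempotence and spike-in geomean equalization hold to 1e−9 relative;
the noise-free lane-scale recovery property to 1e−6.  Statistical checks
run at the study's own scale: the recovery suite uses the default
6/8/7 × 827 cohort at a fixed seed (median relative fold-change error
< 0.25, significant-set Jaccard ≥ 0.9), and the type-I calibration uses
1 000 null NB probes at n = 8 vs 6 — normalized with identity factors, since
no lane effects are planted there and factor-estimation noise is shared
within a lane and would correlate the probes' tests.  Degenerate t-test
cells (zero variance in both groups) report p = 1.  All tests and drivers
complete in seconds on one CPU.

## Known limitations

- The exact ratio estimator behind one published table cell (a 4.19 fold
  change whose printed group means divide to 4.43) is ambiguous; the
  pipeline's estimator is plain division of arithmetic group means, and no
  attempt is made to reverse-engineer that cell.
- The published detection-summary integers and full DE lists depend on
  unreleased raw data and are out of reproduction scope; the logic that
  produces their *shape* is what is tested.
- No batch correction across cartridges and no alternative normalizations
  (quantile, total-count) — deliberately out of scope.
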