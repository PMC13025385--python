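# nanomir

A tested, reusable implementation of a NanoString nCounter miRNA expression
analysis for FFPE tumor profiling: RCC lane-file parsing, control-probe
quality control, dual-stage geometric-mean normalization, limit-of-detection
background filtering, detection-prevalence filtering, signed fold-change
differential expression with cross-group intersection, and annotation of
hits against a curated table of validated miRNA–target interactions.  A
synthetic cohort generator with a ground-truth ledger makes every stage
exercisable and testable without instrument data.

It is written for bioinformaticians analyzing nCounter miRNA panels
(melanoma vs healthy skin in the motivating design: 6 control, 8 BRAF
wild-type, 7 BRAF-mutant lanes over an 827-miRNA panel) and for anyone who
wants the nSolver-style normalization arithmetic as an inspectable library.

## The method

Each lane ℓ contributes raw digital counts per probe. The pipeline applies:

1. **Positive-control normalization.** With g_ℓ the geometric mean of the
   six spike-ins (POS_A..POS_F, 128→0.125 fM) in lane ℓ, the factor is
   `P_ℓ = mean_ℓ'(g_ℓ') / g_ℓ`, flagged outside [0.3, 3.0].
2. **Content normalization.** The same construction over the five mRNA
   reference genes (ACTB, B2M, GAPDH, RPL19, RPLP0), estimated on the
   positive-normalized counts, flagged outside [0.1, 10.0]. Normalized
   counts are `x̃ = x · P_ℓ · C_ℓ`.
3. **Limit of detection.** Per lane, `LOD_ℓ = mean(neg) + 2·SD(neg)` over
   the eight negative controls (sample SD). A probe is detected when its
   normalized count strictly exceeds `LOD_ℓ`.
4. **Prevalence filter.** A miRNA enters differential analysis only if
   detected in strictly more than 50 % of the contrast's lanes (tumor and
   control together by default).
5. **Signed fold change.** With arithmetic group means m̄_case, m̄_ctrl,
   `FC = m̄_case/m̄_ctrl` if ≥ 1, else `−m̄_ctrl/m̄_case`; a miRNA is called
   significant when `|FC| > 2` (strict). A Welch t-test on log2(count+1)
   with Benjamini–Hochberg adjustment is reported alongside but never
   drives the call.
6. **Intersection and targets.** miRNAs overexpressed in every contrast are
   intersected and annotated with validated target genes from a packaged
   interaction table.

Lane QC additionally checks that the 0.5 fM POS_E spike-in exceeds every
negative control, that the ligation positives clear the LOD in increasing
order LIG_POS_C < LIG_POS_B < LIG_POS_A while the ligation negatives stay
below it, and that the positive titration is log-log linear (R² ≥ 0.95).

## Worked example

```bash
nanomir simulate --out cohort --seed 1
nanomir run-all --input-dir cohort --design cohort/design.tsv \
    --contrast BRAFwt:control --contrast BRAFmut:control --out run
```

or, step by step, the numbered drivers under `analysis/`. On the default
synthetic cohort (seed 1) they print:

```
21 lanes; LOD range 15.1-24.7 counts
positive factors 0.725-1.692 (0 flagged outside 0.3-3.0)
content factors 0.802-1.259 (0 flagged outside 0.1-10.0)
POS_E above background in all lanes: True; ligation controls pass in all lanes: True

BRAFwt + controls (14 lanes): 606 miRNAs in >=1 lane, 470 in >50%, 330 in all
BRAFwt vs control: 470 miRNAs tested, 59 significant at |FC|>2 (7 up, 52 down)
  recovery: median rel FC error 0.132, sensitivity 1.00, Jaccard 0.983
BRAFmut vs control: 492 miRNAs tested, 60 significant at |FC|>2 (8 up, 52 down)
  recovery: median rel FC error 0.174, sensitivity 1.00, Jaccard 0.967
overexpressed in both tumor groups: ['miR-1268a', 'miR-146a-5p', 'miR-19b-3p',
                                     'miR-21-5p', 'miR-4286', 'miR-4488']
shared by both: WASF2
```

The generator plants 6 up- and 52 down-regulated miRNAs at known folds; the
recovery lines compare what the pipeline found against that ledger — the
fold changes come back with ~13–17 % median error at these sample sizes,
every planted effect is recalled, and the few extra calls are
near-threshold noise probes.  The intersection recovers exactly the planted
shared up-regulated set, and the target stage reports the validated targets
of the two headline miRNAs (TRAF6, IRAK1, SMAD4, WASF2 for miR-146a-5p;
TGFB1, TGFBR2, RUNX3, HDAC3, WASF2 for miR-4286) with WASF2 as their
shared target.

## Layout

- `src/nanomir/` — the library: `rcc` (file I/O, count matrices), `qc`
  (LOD, factors, lane rules), `detection`, `de`, `targets`, `simulate`
  (synthetic cohorts + ledger), `pipeline` + `cli` (orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — modeling assumptions, parameter choices, limitations.
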