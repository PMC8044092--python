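# Methods

## The estimation problem

Plasma cell-free DNA (cfDNA) is mostly nucleosome-protected DNA released by
dying blood cells; in cancer patients a fraction of it (circulating tumor
DNA, ctDNA) derives from tumor cells. At nucleosome-depleted regions (NDRs)
— open chromatin at active promoters and, distinctively, at first
exon–intron junctions — cfDNA is preferentially degraded *in the tissue
where the gene is transcribed*. The local relative coverage of an NDR in a
plasma sample is therefore a linear read-out of that sample's tissue
mixture: for a tumor-specific gene it moves from ~1 (healthy plasma) toward
the tumor's dip level as the ctDNA fraction grows, and for a blood-specific
gene it moves the opposite way. The package estimates the ctDNA fraction of
a plasma sample from the relative coverage of a small set of such NDRs.

## Pipeline

1. **Windows** (`regions`). Per transcript, a promoter NDR window (−150 to
   +50 bp around the TSS) and a first exon–intron junction NDR window (−300
   to −100 bp relative to the first exon end), both in transcript
   orientation, each normalized against the −2000..−1000 and +1000..+2000 bp
   flanks around its anchor. Coordinates are 0-based half-open internally;
   on the minus strand an offset interval [s, e) maps to genomic
   [anchor−e, anchor−s). A scan variant emits k-th exon–intron /
   intron–exon junction and gene-end windows with the same geometry; these
   serve only the expression–coverage correlation analysis.
2. **Relative coverage** (`coverage`). Records are trimmed to their central
   61 bp (sharpening the nucleosome footprint), per-position depth is
   counted, divided by the mean depth over the two 1 kb flanks, truncated at
   2.0 per position, and averaged over the NDR window. A zero flank mean
   yields a missing value, never 0 or ∞; a missing value among a model's
   selected features is a prediction error, not an imputation.
3. **Scores** (`scoring`). The degradation score of an NDR is
   `(mean(cancer) − mean(healthy)) / sd(cancer)` with the sample standard
   deviation (n−1) over cancer samples; the healthy side may be a single
   merged-pool value when individual healthy samples are shallow, and a
   bootstrap over merged 10-sample subsets supplies a healthy-side sd.
   Tumor-degraded NDRs score negative, blood-specific NDRs positive.
4. **Shortlisting** (`features`). Tumor candidates: fpkm_tumor > 10,
   fpkm_blood < 1 and score < −0.2 at both NDRs; blood candidates the
   mirror image; pan-cancer blood-only candidates: fpkm_blood > 5 and
   fpkm < 1 in every tumor type, expression criteria only. Identical or
   overlapping windows collapse to the most extremely scored
   representative (ties: smallest transcript id).
5. **Dilution** (`dilution`). A mixture at expected fraction f from a
   source of purity π draws round(N·f/π) of the source's N records without
   replacement and tops up to N from the concatenated healthy pool, so
   depth matches the undiluted sample. Grids run 0.005..0.05 in 0.0025
   steps, then 0.05-steps up to and including π.
6. **Model** (`model`). Stability selection: repeatedly (default 1000×,
   200× in the desk-scale studies) draw half the samples, standardize
   within the draw, fit an L1 path with strength chosen by 10-fold CV
   (minimum mean CV error), and record nonzero features; features with
   selection frequency ≥ 0.99 form the model, refit on the full training
   set. Predictions are clamped to [0, 1].

## Numerical choices

* **Lasso path floor.** The path's smallest strength is 0.01 of the largest
  when a fit has fewer samples than features and 1e−3 otherwise, following
  glmnet's `lambda.min.ratio` convention. This matters: the dilution-grid
  design makes many candidate NDRs informative and mutually correlated, so
  the CV error curve is nearly flat and an unbounded path drifts into dense
  fits in which correlated features substitute freely and no feature is
  selected stably. The floored path yields sparse-enough fits with a sharp
  selection-frequency cliff (a handful of features at ≥ 0.99).
* **CV rule** is minimum mean CV error, not 1-SE (recorded in model
  metadata). Response transforms (log, logit) exist behind a flag and are
  off by default.
* **Score denominator** is the sample sd (n−1) of the cancer values; a zero
  sd leaves the score undefined rather than infinite.
* **Truncation order**: the per-position cap (2.0) applies before averaging
  over the window.
* **Ties and degeneracies**: frequency ranking breaks ties by descending
  mean |coefficient| then feature id; a constant response yields an
  intercept-only model; constant-response subsample draws are skipped
  (> 5 % skipped is an error).

## The synthetic generator

The generator plants everything the method assumes and nothing more.

* **Genome/annotation**: ~150 non-overlapping multi-exon transcripts (2–4
  exons, first exon 600–1400 bp) on one chromosome with ≥ 4.5 kb intergenic
  gaps so scan windows of neighboring genes never touch.
* **Expression**: tissue-specific genes draw fpkm log-uniformly in
  [20, 200] in their tissue and uniformly in [0, 0.45] elsewhere — a ≥ 2×
  margin on the shortlisting thresholds; shared genes are expressed in all
  tissues, unexpressed genes nowhere.
* **Dip model**: the target relative coverage of an expressed gene's NDR is
  max(0.3, 1 − a·log10(fpkm+1)) with a set so fpkm = 30 maps to ≈ 0.5,
  times a per-gene lognormal accessibility jitter (sd 0.25) and a smaller
  per-NDR component (sd 0.12). The two components are sized so the
  promoter-vs-junction correlation of dip depth is ≈ 0.8, matching the
  strong but imperfect coupling seen in real cfDNA, and so dip strength
  spans the wide range real expressed genes show. Dip footprints carry
  250 bp raised-cosine shoulders beyond the scored window — real NDR
  footprints are smooth, not rectangular — and phased-nucleosome
  oscillation (amplitude 0.15 × dip depth, period 190 bp) decorates the
  flanks outside the footprint.
* **Fragments**: midpoints are sampled from the per-tissue intensity
  (degradation = thinning; length and position independent), lengths from a
  mono/di-nucleosomal mixture: a Laplace-peaked mono component (mode
  166 bp, sd 10 — real cfDNA histograms drop off sharply around the
  protection mode, and a rounded Gaussian of this width would leave the
  integer mode ambiguous) plus 10 % di-nucleosomal Gaussian at 332 bp
  (sd 25). Each fragment carries its tissue of origin as a provenance
  label.
* **Biological variability**: tumor patients carry a global multiplier on
  dip depth (sd 0.1, shared by a patient's samples); blood dip depth varies
  per donor *and per NDR* (sd 0.05). The per-NDR granularity is deliberate:
  a single global donor multiplier would shift a whole cohort's blood NDRs
  coherently, which is biologically implausible and makes healthy-vs-healthy
  score exceedances co-occur across genes.

What the generator does *not* emulate: GC/mappability bias, sequencing
error, duplicates, read pairs, or real genome sequence. Passing tests
therefore demonstrate the statistical machinery — window arithmetic,
normalization, calibration of the dilution design, selection and
regression — under the paper's depth and design conditions, not robustness
to platform artifacts.

## Study conditions (desk scale)

The reference experiments mirror the published design at matched depths:
29 healthy donors at ~5× (merged ~145× pool), high-burden sources at ~90×,
detection negatives as 40 ~80× pool resamples. Source purities are
[0.35, 0.40, 0.44, 0.47, 0.52, 0.58, 0.60, 0.86] (8 samples / 5 patients)
for training and [0.38, 0.45, 0.55, 0.62] (4 samples / 2 unseen patients)
for testing, chosen inside the published 35–86 % range so the default
grids contain exactly 231 training and 113 test samples; the second tumor
type uses 7 training sources (215 samples) and 3 held-out sources (93).
Stability selection uses 200 repeats in these studies (scaled from 1000;
the frequency threshold is unchanged).

## Known limitations

* **Detection at the 2 % threshold.** Positives include grid samples whose
  expected fraction equals the threshold exactly; with fragment-sampling
  noise at ~90× the low-fraction prediction sd is ~0.013 with ~6 features,
  so such samples are detected only about half the time under any unbiased
  estimator. The measured sensitivity/specificity at 2 % is therefore in
  the high 80s / mid 90s rather than 100 %, and this is a property of the
  design, not of the implementation.
* **Healthy-null scoring.** Scoring a healthy cohort against a *separately
  sequenced* healthy pool is dominated by the pool's own per-feature
  sampling noise (~0.06 relative-coverage units at merged ~145×), which the
  score's cancer-side sd does not normalize away; the null false-positive
  check therefore scores pool resamples against their own pool, the same
  construction used for the detection negatives.
* The in-silico mixtures resample alignment intervals; they do not
  re-simulate library preparation, and all diluted samples of one source
  share that source's realized coverage quirks, exactly as in-silico
  dilution of real BAMs does.
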