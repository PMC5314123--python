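# Methods

## Generative model of a synthetic study

Each dataset (cohort) is a two-group, two-channel tiling-array experiment.
The generator works on the log2(bound/input) scale, the scale on which the
downstream statistics operate:

* every probe *p* has a baseline log-ratio `b_p ~ N(0, 1)` drawn once per
  dataset and shared by both groups (it cancels in group differences and is
  largely removed by per-array median centering);
* sample *s* of probe *p* observes
  `L_ps = b_p + Δ_p·1[s in stress] + ε_ps`, with `ε_ps ~ N(0, σ)` i.i.d.;
* `Δ_p` is the planted mean shift: `+e` for every probe of a gene planted
  *hyper*, `−e` for *hypo*, and for a *mixed* gene the first ⌈k/2⌉ of its
  k probes get `+e` and the rest `−e` (an odd probe count favours hyper);
  `e = effect_logratio × effect_multiplier`, 0 for unplanted genes;
* channel intensities are reconstructed as `input = 2^U`, `U ~ Uniform(6, 12)`
  and `bound = input · 2^L`, so both channels are strictly positive and the
  log-ratio of the pair is exactly `L`.

Defaults: σ = 0.5, e = 1.0, 3 probes of 60 bp per gene. Gene regions are
non-overlapping, probes equally spaced within them, coordinates 0-based
half-open. Determinism: the study seed is split into one child stream per
dataset (`numpy.random.SeedSequence.spawn`), so identical configurations are
byte-identical and adding a cohort does not perturb the others.

What this emulates — group mean shifts against probe-level array noise at
the real cohorts' sample sizes (rat PFC 4v4, human CD34+ 8v10, monkey PFC
4v4, pooled monkey CD3+ 3v3 ×2, whole blood 5v5, buccal 3v3; the pooled
CD3+ cohorts are simulated as one replicate per pool). What it deliberately
does not model: dye bias, spatial artifacts, GC/sequence-dependent
immunoprecipitation efficiency, copy-number confounds, inter-probe
correlation within a fragment, and platform-specific noise magnitudes (no
public estimate exists for the original arrays, so σ is a free parameter).
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under its own assumptions, not performance on real
arrays.

## Probe-level testing

Per-probe differential methylation uses a two-sided Welch *t* test on
median-centered log-ratios, stress minus control, with positive effects
labelled *hyper*. Welch was chosen over the pooled-variance *t* because
group variances cannot be assumed equal at n = 3–10; a Wilcoxon rank-sum
alternative is exposed (`test="wilcoxon"`) for heavy-tailed data. Degenerate
probes (zero variance in both groups) take `p = 1` when the means agree and
`p = 0` otherwise; a probe with effect exactly 0 is never given a direction.
FDR control is Benjamini–Hochberg step-up applied per dataset across all of
its probes, threshold q < 0.2 everywhere (configurable). Normalization is
per-array median centering only; intensity-dependent (loess) correction
would need probe sequence/GC covariates the synthetic arrays do not have.

At q < 0.2 with three probes per gene and a "≥ 1 significant probe" gene
rule, single-cohort gene lists intentionally contain an appreciable
false-positive fraction; the design relies on the cross-cohort intersection,
not the single-cohort call, as the discovery filter (see the benchmark notes
below).

## Gene classification and intersection funnel

A probe contributes to every gene region it overlaps by ≥ 1 bp (promoter
regions can abut; a probe on the boundary counts for both genes). Gene
classes: *hyper* iff ≥ 1 hyper probe and no hypo probe; *hypo* symmetric;
*mixed* iff both; *none* otherwise — so {hyper, hypo, mixed} is exactly
"differentially methylated" (DM).

The funnel has three stages, each a subset of the previous:

1. **core overlap** — DM (any direction, mixed included) in *every* core
   dataset;
2. **direction consistent** — the same non-mixed class in every core dataset
   (a single mixed call disqualifies);
3. **extension consistent** — that same class in every extension dataset;
   genes absent from an extension call table are dropped and logged.

Ortholog harmonization precedes the funnel: with a mapping table each
(dataset, local gene) resolves to exactly one ortholog group (ambiguity is
an error, unmapped genes are dropped and counted); without one, symbols are
matched case-insensitively. When several local genes of one dataset fall in
one group, their classes merge by direction union (hyper + hypo ⇒ mixed;
any DM beats none).

## Validation statistics

* **2^−ΔΔCt**: ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt subtracts
  the calibrator-group mean ΔCt (the control group, stratified by age when
  an age column is supplied); fold = 2^−ΔΔCt, also reported as
  percent-of-calibrator. MeDIP enrichment is the same arithmetic with the
  input fraction as reference channel, reported with group means ± s.e.m.
* **t tests** are two-tailed at α = 0.05, Welch by default with a
  pooled-variance switch (`equal_var=True`).
* **Two-way ANOVA** (group × age, interaction included) uses Type II sums of
  squares by default — with the unbalanced cell counts typical of animal
  cohorts, Type II main effects are not contaminated by the interaction —
  and sequential Type I on request; on balanced designs both equal the
  classical closed forms. A design with an empty cell is an error naming the
  cell; a zero-total-variance dataset reports SS = 0, F = 0, p = 1; a
  residual SS below 1e−12 of total is treated as an exact perfect fit.
* **Fisher's LSD** compares group levels within each age with
  t = Δmean / √(MSE·(1/n₁+1/n₂)) on the ANOVA residual df, two-sided, no
  multiplicity adjustment (the classical protected-LSD convention); it
  refuses to run on zero MSE.

## Benchmark designs and their calibration

The benchmark module fixes four seeded designs (replicate *i* of base seed
*s* uses seed `s·1000 + i`, keeping seed blocks disjoint):

* **Recovery benchmark** — one 4v4 cohort, 200 genes of which 20 planted DM
  (8 hyper, 8 hypo, 4 mixed), effect 1.0, σ = 0.5. At these conditions the
  BH(0.2) step-up over 600 probes with 10% non-null settles near p ≈ 0.006,
  where the Welch test (noncentrality ≈ 2.83 at ~6 df) has per-probe power
  of only ≈ 0.1 — so measured gene-level sensitivity is ≈ 0.2 with
  empirical FDR ≈ 0.1–0.17 and direction accuracy ≈ 0.86. The benchmark
  reports what the method actually achieves there; it is a calibration
  statement about FDR-controlled discovery at small n, not a failure of the
  implementation (raw p < 0.05 power per probe is ≈ 0.6 at the same
  conditions).
* **Funnel demo** — the seven-cohort design, effect 1.5, σ = 0.3, 100
  genes: 8 shared DM genes (2 all-hyper, 6 mixed), 4 partial multi-cohort
  genes, and a tissue-specific background DM set (15% of the universe) in
  every peripheral cohort. The background sets keep each cohort's DM
  fraction near the ~20% seen in real studies of this kind, which both
  powers the BH step-up in the small pooled cohorts and keeps per-cohort
  false-gene rates low enough (≈ 4–10%) that the five-way overlap is driven
  by the shared genes. Measured: stage counts 8 → 2 → 1 with ANK3 as the
  surviving candidate in ≥ 95% of seeds (200/200 at seeds 0–199).
* **Trajectory design** — 2 groups × 3 ages (PND7/21/62), n = 7 control /
  9 stress per cell, σ = 0.3, control means (1.0, 1.1, 2.0) and a −1.0
  deficit planted in the stress group at the last age only: stable
  expression before weaning, adult rise, stress effect emerging at
  adulthood. Fisher's LSD flags exactly the planted age in ≈ 90% of
  replicates (the expected rate is 0.95² ≈ 0.90: two null ages tested at
  α = 0.05 each, with power ≈ 1 at the planted age).
* **Null calibrations** — 1000 null probes (4v4, σ = 0.5) for type-I error
  of the probe test; 10,000 random p-vectors of length ≤ 8 (a quarter
  rounded to create ties) against a literal O(m²) BH step-up reference;
  1000 random balanced two-factor designs for SS conservation.

Problem sizes (probes, genes, replicate counts) were chosen so the whole
suite and the acceptance script each run in well under a minute of compute
per benchmark while keeping Monte-Carlo error far from the decision
boundaries.

## Known limitations

* No moderated (empirical-Bayes) variance estimation and no merging of
  adjacent probes into regions; at n ≤ 4 per group the per-probe Welch test
  is honest but weak, as the recovery benchmark quantifies.
* Gene assignment uses the provided regions as-is; there is no
  nearest-gene fallback and no transcript-isoform resolution.
* The intersection carries no statistical significance of the overlap size
  itself (no permutation null), matching the descriptive use of such Venn
  funnels.
* qPCR quantification assumes perfect amplification efficiency (no Pfaffl
  correction) and the trajectory model is a fixed-effects ANOVA, not a
  mixed/longitudinal model.
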