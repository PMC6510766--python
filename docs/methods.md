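# Methods

This package implements peak-set analytics for tracking chromatin
reorganisation across treatment timepoints, starting from called
ChIP-seq peaks (BED-world intervals). Everything upstream — library
preparation, alignment, peak calling, signal tracks — is out of scope;
everything downstream of a peak call is implemented and tested here.

## Interval model and overlap semantics

Coordinates are 0-based half-open (BED). Touching intervals do not
overlap; the overlap criterion for every "peak contains a site / is
positive for a mark" question is ≥ 1 bp by default and configurable
where it matters (`intersect(min_overlap_bp=...)`). Strand is ignored
(histone-mark peaks are unstranded), and chromosome names are exact
strings — no silent `chr` normalisation.

The engine keeps per-chromosome start-sorted arrays with a running
maximum of interval ends, so overlap-existence queries are two binary
searches; correctness with nested intervals follows because any
overlapping target contributes its end to the prefix maximum.
`merge_union` additionally fuses book-ended intervals when building a
consensus universe: the universe is about contiguous covered territory,
not strict overlap. Both operations are validated against brute-force
all-pairs and coverage-array oracles in the test suite.

The consensus universe is this package's explicit stand-in for an
unstated step: comparing peak populations across samples and timepoints
requires a common element set, and we take the merged union of the
contributing peak sets, with each merged element recording its source
peaks.

## Seven-way mark-combination classification

Elements positive for at least one of EZH2, H3K4me3, H3K27me3 fall into
the seven non-empty mark combinations. Codes 3 (EZH2+H3K4me3), 4
(EZH2-only) and 7 (H3K4me3-only), and the assignment of the two
EZH2+H3K27me3 combinations to codes {1, 2}, follow the published
numbering; the remaining codes were open and are pinned as
1 = triple-positive, 2 = EZH2+H3K27me3, 5 = H3K4me3+H3K27me3 (bivalent
without EZH2), 6 = H3K27me3-only. The mapping is a module constant and
overridable per call. "Positive for" is binary peak overlap against
each mark's own calls — no signal cutoff over the union universe, since
the source procedure is presence/absence combinatorics.

Promoter annotation uses a ±2,000 bp window around the TSS (a common
H3K4me3-promoter convention; the choice is a parameter). With
`window_bp=0` only elements covering the TSS base qualify. Nearest-gene
assignment minimises the bp distance to a TSS (0 when the TSS is inside
the element) with lexicographic tie-breaking for determinism.

## REMI scoring

A population's *signature* is, per catalogue factor, the number of
elements containing ≥ 1 validated site of that factor (an element with
several sites of one factor counts once), plus the derived fraction.
The catalogue emulates a merged ReMap-style export: BED4 with the
factor name in the name column.

The score comparing a test population to a reference composition is

    score[f] = log2( (f_test[f] + p) / (f_ref[f] + p) ),
    p = pseudocount / max(n_test, n_ref),   pseudocount = 0.5 by default

This is a **reconstruction**: the original supplementary equations were
not available, so a single log-ratio form with a size-scaled
pseudocount serves all three published contexts, which differ only in
the reference — (1) the unweighted average of several samples'
signatures, (2) the all-peaks signature of the parent population,
(3) the same all-peaks reference applied per rank bin. The form was
chosen for its invariants: exactly 0 when compositions agree (including
a factor absent from both sides, which sees equal pseudocounts),
antisymmetric under swapping test and reference, monotone in the test
fraction, and convergent to the pure log2 ratio as populations grow
(the pseudocount scales as 1/n). Output headers carry a note naming the
form. Averaged reference signatures store fractional counts so the mean
fraction is represented exactly.

No significance is attached to scores — the procedure reports scores,
not p-values. `binomial_score_se` supplies the delta-method standard
error `sqrt(f(1-f)/n) / (f ln 2)` (divided by `sqrt(k)` for a k-factor
group mean) used by the synthetic-recovery and null-flatness checks
only.

## Fold-change dynamics

Per-element fold change between two timepoints is computed on the
consensus universe; elements missing either timepoint or with
non-positive baseline are excluded and reported. Cross-timepoint
normalisation defaults to total-signal scaling (the later timepoint is
rescaled to the earlier one's total over shared elements), because
global H3K4me3 levels are treated as stable and only relative
redistribution is of interest; `normalize=None` disables it.

The ranking is total (ties broken by element id), largest to smallest.
The three-way split at FC = 1.5 uses closed boundaries — FC = 1.5 is
"increased", FC = 1/1.5 is "decreased" — a deterministic choice where
the source is silent. Binning cuts the ranked order into consecutive
1000-peak subsets; the final partial bin is retained and flagged rather
than dropped. Each bin is scored against the all-binned-peaks
composition and aggregated over the named factor groups
A = {EZH2, SUZ12, CtBP2}, B = {BCL11A, IKZF1, BATF, SMAD1},
C = {KDM5A, IRF3, GATAD1, SNAPC1}, D = {SMAD2, SMAD3, SMAD4} by
unweighted mean.

## Presence/absence selection

"Found in sample S" is ≥ 1 bp overlap of a universe element with S's
own peak calls, evaluated on the merged universe of all query samples.
The selection keeps elements overlapping ≥ 1 peak in every required
sample and 0 peaks in every forbidden one. Because pure
presence/absence can understate differences (a mark may be low but not
absent), an optional intensity floor reclassifies weak peaks as absent.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume,
starting at the peak-call level:

* **Elements.** Non-overlapping consensus elements placed per
  chromosome with a ≥ 300 bp gap; widths log-normal (σ = 0.35, median
  1 kb for promoter elements, 600 bp for non-promoter, clipped to
  250–4000 bp) — typical H3K4me3 geometry; the values are configuration,
  not claims.
* **Marks.** Each element draws a subgroup from the seven-way mixture;
  the marks of that combination realise peaks over the element with
  ±40 bp boundary jitter (strictly less than half the minimum gap, so
  elements never fuse and classification can recover the planted
  subgroup exactly).
* **TF sites.** Per factor, a Bernoulli draw per element with rate =
  background × the multipliers of every stratum the element belongs to
  (subgroup, bivalency, promoter status, FC class, RR-specific status,
  CpG status), optionally × `fc_gradient^u` where u is the element's
  descending planted-FC percentile. Successful draws place one short
  site inside the element.
* **Intensities.** log2 intensity = per-element baseline
  (N(6, 1)) + planted log2 FC × (t / t_max) + N(0, 0.1) noise per
  sample × timepoint. Planted effects are ±1 log2 unit for the
  increased/decreased classes (15% each in the standard scenario),
  0 for stable.
* **Cohort.** Five samples (3 TN, 2 RR) × timepoints {0, 1 or 7, 56}
  days; a configurable fraction of elements (4% in the standard
  scenario) is RR-specific — present, in all marks and timepoints, only
  in RR samples.
* **Genes/CpG.** Each promoter element carries one TSS at its midpoint
  (so planted promoter status is exact); CpG islands are sub-intervals
  planted preferentially in bivalent elements (70% vs 10%).

The standard scenario fixes 2 × 50 Mb chromosomes, 20,000 elements,
1,000 genes, a 50-factor catalogue containing groups A–D, and the
planted enrichments the analyses look for (group A in the decreased
class and bivalent elements, B in the increased class, C at promoters,
D flat, EZH2/SUZ12 at 4× in RR-specific elements). Determinism is
byte-level: one seed, one byte stream.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: peak-call noise (false/missed calls, so
per-sample peak sets are identical up to the planted RR-specific
differences; treatment-naive samples are replicas of each other),
presence/absence changes over time (temporal signal lives entirely in
the intensity table), correlated factor co-occurrence beyond shared
strata, copy-number or mappability artefacts, and any genome sequence
content (CpG islands are labels, not sequence). With 1,000 genes
against 20,000 elements only ~5% of elements are promoters, so
promoter-stratified analyses on the standard scenario operate on small
strata.

## Numerical and degenerate-input choices

* Empty populations have no signature (error), rather than NaN
  fractions.
* Percent change from a zero baseline is reported as undefined
  (`None`), not an exception or infinity.
* FC is undefined where the baseline intensity is ≤ 0 or either
  timepoint is missing; such elements are excluded and listed.
* Score ranking ties break by factor name; FC ranking ties by element
  id; nearest-gene ties by gene id — all orderings are total and
  deterministic.
* Mixture/proportion validation uses exact sums with a 1e-9 tolerance;
  site rates are clipped to [0, 1] after multipliers.

## Problem sizes used by the checks

The verification suite runs the interval oracles on 200 random
instances (n, m ≤ 500), subgroup recovery on 50 seeds of the 20,000-
element standard scenario, enrichment recovery at multipliers
{1.41, 2, 3} over 50 seeds of ~10,000-peak populations, bin-series null
flatness over 50 seeds of 20 × 1000-peak bins, and the RR-specific
end-to-end selection at 10,000 elements. `scripts/acceptance.py`
recomputes the same quantities at 10 seeds per stochastic check.

## Known limitations

* The score form is a reconstruction (see above); alternative forms
  (e.g. difference of fractions) can be swapped in via the signature
  API but are not implemented as built-ins.
* `intersect` pair enumeration is worst-case quadratic; it is linear-ish
  on real peak data and exact, but not built for dense all-vs-all site
  catalogues (signature construction uses the existence fast path
  instead).
* The CLI covers the pipeline's file-level entry points; multi-sample
  orchestration (cohort loops, reference bookkeeping) is left to the
  analysis scripts, which is where it is exercised.
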