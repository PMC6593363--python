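# Methods

This note documents the models, rules and numerical choices behind
`cnvrpipe`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates and genotype encoding

All intervals are 1-based inclusive (`length = end − start + 1`);
converters to 0-based half-open BED live only at I/O boundaries. The
genome is tiled into fixed windows of `window_length` bp (default
1,000); a trailing partial window is kept in the layout but masked from
calling, so partial-window artefacts can never produce calls of
non-multiple length. Genotypes are integers 0–8 with 2 the diploid
reference; the undetermined state CN_ is encoded as −1 in memory and
`"CN_"` on disk.

## Read-depth caller

The caller is intentionally simple: its job is to honour the external
contract of window-based multi-sample read-depth callers (integer
genotypes on a window grid, minimum event span of three windows) so
that the downstream CNVR machinery — the part this package exists for —
can be exercised end to end. It is not a reimplementation of a mixture
model caller and should not be benchmarked as one.

1. **Normalisation.** Each sample's counts are scaled so its total
   equals the cohort mean total. Zero-total samples are excluded with a
   warning.
2. **Per-window CN estimate.** The window reference depth λ_w is the
   across-sample **median** of normalised counts, robust to a minority
   of carriers. The estimate is `round(2x/λ_w)` clipped to [0, 8],
   with exact halves resolved **toward 2** (a half-way signal should
   not create a stronger variant claim than the data support).
3. **Significance.** A window is flagged when the estimate differs
   from 2 and the observed count is in either exact Poisson tail at
   level α (default 10⁻³): `min(P(X ≤ ⌊x⌋), P(X ≥ ⌈x⌉)) < α` under
   λ_w. Each side is tested at α rather than doubling the smaller
   tail; with the default α this is what keeps heterozygous
   duplications (expected depth 1.5 λ) detectable per window at
   λ = 100 (threshold x ≥ 133, per-window sensitivity ≈ 0.93, versus
   x ≥ 135 and ≈ 0.90 with doubled tails — a difference that compounds
   over the run-length requirement below). Windows with λ_w = 0 are
   masked.
4. **Segmentation.** Per sample and chromosome, maximal runs of
   ≥ `min_adjacent_windows` (default 3) consecutive flagged windows of
   consistent direction (all estimates < 2, or all > 2) become one
   call; a flagged gain window terminates a loss run and vice versa,
   so adjacent opposite events yield two abutting calls. The call
   genotype is the median of the window estimates in the run, halves
   again toward 2. Boundaries snap to window boundaries, so every call
   has length ≥ 3 windows and a multiple of the window length.

**Limitations.** The median reference mis-references windows where more
than half the cohort carries a variant (common CNVs will be missed or
mis-genotyped). Heterozygous duplications are the least detectable
class: at λ = 100 the per-window flag probability is ≈ 0.93, and
because an unflagged interior window splits a run, recovery of long
CN3 events decays geometrically with span — a structural property of
per-window testing with a contiguity requirement, not a bug. Sex
chromosomes get autosome semantics.

## Sample QC

QC is strictly per dataset; the pipeline refuses to pool samples of
different datasets into one calling/QC group unless explicitly
overridden, because read-depth comparison across library preparations
and platforms confounds genotype distributions.

* **PCA rule.** Principal components of the normalised count matrix
  (samples as observations, windows centred). A sample is flagged when
  its Euclidean distance d from the coordinate-wise median in
  (PC1, PC2) exceeds `median(d) + k_mad · 1.4826 · MAD(d)` (default
  k_mad = 6; 1.4826 makes the MAD a consistent normal-scale estimate,
  so k_mad reads as "robust standard deviations"). A small noise floor
  (10⁻⁹ of the PC scale) prevents float jitter from flagging clones of
  identical profiles. This replaces by-eye outlier reading with a
  deterministic rule.
* **IQR rule.** A sample is flagged when its deletion proportion
  (fraction of its calls with CN < 2 — call counts, not bases) or its
  total call count falls more than 1.5 IQRs outside [Q1, Q3] of its
  dataset, quartiles by linear interpolation (type 7). An analogous
  upper-side rule on the metadata coverage field exists but is off by
  default.

All calls from failing samples are removed; removal is idempotent.

## CNVR construction

Reciprocal overlap of two same-chromosome intervals is the intersection
length as a fraction of each; a pair qualifies at threshold 0.5 when
both fractions reach it. CNVRs are the **connected components**
(single-linkage closure) of the qualifying-pair graph. Single linkage
is deliberate: clique-style semantics would make CNVR membership
dependent on presentation order, while components are order-free; the
threshold is configurable. The implementation is a start-sorted sweep
with union–find and is required (and tested) to agree with a
brute-force all-pairs oracle.

Clustering is genotype-agnostic, so a CNVR's members may mix losses and
gains: the category is DEL if all member CNs are in {0, 1}, AMP if all
are ≥ 3, MIX otherwise. CNVRs observed in fewer than two distinct
samples are dropped before genotyping.

**Genotype assignment.** Per sample, member CNVs are grouped by CN
class and class widths summed; the class with the largest aggregate
width wins. Ties go to the class closest to CN2 (the weaker variant
claim); a residual tie (CN1 vs CN3, equidistant from 2) goes to the
lower CN — deletions have the cleaner depth signature, so they are the
safer residual choice. A deterministic residual rule is mandatory
either way. Samples without a member CNV get a provisional CN2.

**CN2 correction.** Because a 50 % threshold permits overlapping
CNVRs, a sample can be diploid-by-default at one CNVR while carrying a
CNV in another CNVR overlapping it. For each test CNVR, provisional
CN2 genotypes are demoted to CN_ when the sample has a member CNV in a
different CNVR sharing ≥ 1 bp with the test CNVR. The correction runs
over the post-singleton-filter CNVR set (the retained regions are the
analysis universe) and is idempotent. CN_ samples are excluded from
HWE/parity denominators and treated as missing in clustering.

Cross-dataset combination happens only at the merge step: `union` mode
coalesces overlapping or bookended (end + 1 = start) regions into a
non-redundant set with total bp and percent-of-genome; `unique_coords`
mode counts regions with identical coordinates across datasets once.

## Population-genetic tests

* **HWE.** Only diallelic autosomal spectra are testable — within
  {CN0, CN1, CN2} (deletion side) or {CN2, CN3, CN4} (duplication
  side) with ≥ 2 classes present; a spectrum mixing sides (e.g. CN0
  with CN3) has no unambiguous allele decomposition and is reported as
  non-qualifying rather than tested. The allele frequency is estimated
  from the counts; the Pearson χ² statistic (1 df, no continuity
  correction by default; a Yates-style option exists) is referred to
  the χ² distribution. Requiring ≥ 2 classes rather than all 3 keeps
  rare-allele CNVRs (no minor homozygote observed) testable; the class
  spectrum is reported alongside.
* **Parity.** Pass when even-genotype individuals (CN0, CN2, CN4, CN6,
  CN8) are at least as many as odd (CN1, CN3, CN5, CN7); ties pass.
  CN6 is even arithmetic, so it counts with the homozygote-like
  classes. Note that under Hardy–Weinberg sampling this test is only
  guaranteed in expectation: at allele frequency q the heterozygote
  share 2pq approaches 1/2 as q → 1/2, and with n = 100 the binomial
  fluctuation makes failures non-negligible for q ≳ 0.3 even at exact
  HWE — the test is a red flag, not a filter.
* **Clustering.** Sample distance is 1 − Spearman ρ over CNVRs
  genotyped in both samples (average ranks; genotypes are small
  integers, so ties are pervasive and the convention matters). Pairs
  with < 2 shared genotyped CNVRs or a zero-variance vector get the
  maximum distance 2 with a warning. Agglomeration is Ward on the
  dissimilarities (the ward.D2 convention; verified against an
  independently hand-worked 4-point example). Samples are ordered by
  id first so results do not depend on input order.

## Annotation

A CNVR is associated with a gene when it overlaps the gene span
extended by `gene_flank` on both sides (default 5 Mb, deliberately
exposed in the configuration — it is unusually large, and analyses that
want conventional promoter-scale flanks should set it accordingly).
Body hits are classified per sub-feature — CDS, UTR, exon, and introns
derived as gaps between consecutive exons of each transcript rather
than trusted from the annotation — and flank-only hits are labelled
upstream/downstream by strand (left/right with a warning for strandless
genes). Labels combine component and CNVR category ("cds del") so the
database search can retrieve, say, coding-sequence deletions. BED-like
tracks (QTL/gap/repeat/segdup) are annotated by ≥ 1 bp overlap; a gap
containing a CNVR boundary is flagged, since depth anomalies at
assembly gaps can masquerade as breakpoints.

## Report database

The database is fully static: plain HTML plus vanilla JavaScript,
rendered with stdlib string templating, no network access needed.
Filter defaults (length 1 kb – 3 Mb, detected in ≥ 2 samples) are both
rendered and embedded as machine-readable JSON so integrity tests can
compare the displayed statistics against direct recomputation. Read
alignment screenshots are replaced by per-window depth plots from the
count matrix — the input this pipeline actually has — serving the same
purpose of visual genotype verification; up to 3 samples per observed
genotype are chosen by seeded sampling without replacement, with the
per-CNVR stream derived from (seed, crc32(cnvr_id)) so one CNVR's
plots are stable regardless of how many others are rendered.

## Synthetic cohorts

The generator emulates exactly the signal structure the pipeline
consumes:

* **Allele frequencies** per breed; where not given explicitly they
  are drawn from a rare-skewed density ∝ 1/q truncated to
  [0.01, 0.4] — the neutral site-frequency-spectrum shape, matching
  the strongly rare-shifted spectra of real CNV cohorts.
* **Genotypes** by Hardy–Weinberg sampling (allele dosage
  Binomial(2, q)) within breed; deletion alleles subtract one copy
  each, duplication alleles add `gain` copies (default 1; a gain-3
  allele models high-amplification loci with homozygote CN8).
* **Counts** Poisson with expectation λ · CN/2 per window (λ default
  100 reads/window), linear interpolation for partially covered
  windows, optional per-dataset batch scaling, optional negative
  binomial overdispersion, and an exact noise-free mode
  (counts = expectations) for analytic caller tests.
* **Problem samples**: low coverage as binomial thinning (default
  multiplier 0.3, i.e. a sample sequenced at ~30 % of cohort depth);
  batch outliers as a systematic 1.5× bias on a random 20 % of
  windows.

Not emulated: GC and mappability bias, segmental-duplication depth
artefacts, read-level errors, and linkage between loci. Tests passing
on these cohorts demonstrate that the rules behave as specified under
the assumed noise model; they do not certify caller calibration on
real alignments.

## Experiment sizes

The experiment suite uses problem sizes chosen to make the statistical
assertions stable while keeping the suite quick to run: recovery under
Poisson noise uses 10 replicates of 20 samples × 5 Mb with planted 5–6
kb events (short events dominate real CNV length spectra and are the
hardest case for boundary accuracy); QC recall/specificity uses 100
cohorts of 20 samples × 5,000 windows; HWE calibration uses 2,000
regions × 500 samples; parity uses 10,000 Hardy–Weinberg cohorts;
breed-cluster recovery uses 50 replicates of two 10-sample breeds with
15 disjoint breed-specific loci each; database integrity uses 200
regions.
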