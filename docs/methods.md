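# Methods

## Scope and model

`aupdscan` implements the analysis chain used to characterise chromosome-arm
acquired uniparental disomy (aUPD) in myeloid neoplasms and in clonal
haemopoiesis screens: detection of terminal copy-neutral loss of
heterozygosity from SNP-array B-allele frequency (BAF) and log R ratio (LRR)
profiles, quantification of parental methylation imbalance at an imprinted
locus (*MEG3*/*DLK1* at 14q32) from methylation-specific PCR (MS-PCR) peak
heights, decomposition of JAK2 V617F allele burdens into homozygous and
heterozygous cell compartments, ordering of aUPD14q versus JAK2 V617F
acquisition, and the minimal affected region (MAR) across cases.

The central mixture model: in a sample where a fraction *f* of cells carries
a copy-neutral aUPD event, heterozygous SNPs have BAF displaced from 0.5 to
0.5 ± *f*/2 while total intensity is unchanged (LRR ≈ 0). After folding BAF
about 0.5 (mirrored BAF, mBAF = 0.5 + |BAF − 0.5|), the segment-level signal
is mBAF = *f*·1 + (1 − *f*)·0.5, inverted as *f* = 2·(mBAF − 0.5). The same
identity applied to chromosome 9p BAF gives the JAK2-homozygous cell
fraction, and allele counting gives the conservation identity
*v* = *f*_hom + *f*_het/2 for the V617F burden *v*.

At the imprinted locus, the methylated (paternal) allele dose in a sample
with paternal aUPD at fraction *f* is 1 + *f* and the unmethylated
(maternal) dose is 1 − *f*; the raw MS-PCR ratio M/(M+U) is therefore
(1 + *f*)/2, and after normalising control samples to zero the methylation
value equals *f*/2, ranging from −0.5 (complete maternal gain) to +0.5
(complete paternal gain). A trisomic extra paternal copy instead gives raw
ratio (1 + *f*)/(2 + *f*), and trisomy with random parental origin shows no
group-level bias.

## Detection pipeline

1. **QC filter.** SNPs with BAF > 0.9 or < 0.1 (homozygous range) are
   removed, as are interior SNPs whose flanking neighbours' BAFs differ by
   more than 0.6. Both rules are evaluated on the original position-sorted
   series: the neighbour rule sees hom-range SNPs even though they are
   themselves removed, matching the written order of the source protocol;
   the first and last SNP are exempt from the neighbour rule.
2. **Mirroring.** mBAF = 0.5 + |BAF − 0.5|; this makes the per-SNP
   duplicated-haplotype sign irrelevant.
3. **Circular binary segmentation (CBS).** For a series of *n* mirrored
   values, every contiguous block (*i*, *j*) with block and complement both
   at least `cbs_min_width` = 5 points is scored with the two-sample
   statistic T = (mean_arc − mean_complement)/(s·√(1/m + 1/(n−m))), where
   *s* is the whole-series standard deviation (constant under permutation,
   so it does not affect the permutation test). Linear blocks enumerate all
   circular two-way partitions because a wrapping arc is the complement of
   a linear one and |T| is symmetric. The max-|T| split is accepted when a
   permutation test (1000 shuffles, α = 0.01, seeded generator, early
   stopping once significance is impossible) rejects homogeneity, and the
   procedure recurses on the sub-series. Ties in the max search break to
   the smallest (*i*, then *j*). No post-hoc merge/undo pass is applied to
   the segmentation itself.
4. **Classification.** A segment is aUPD when mean mBAF > 0.56 (strict), its
   mean LRR lies within ±0.15 of zero (half the single-copy LRR shift at
   typical array noise), and it is telomeric. At the noiseless mixture level
   the 0.56 threshold corresponds to a minimum detectable clone fraction of
   0.12.
5. **Call merging.** The published definition is "a region of allelic
   imbalance with neutral copy number extending to the telomere". When CBS
   subdivides such a region, the final call is the union of the terminal
   qualifying segment and adjacent proximal segments that also exceed the
   imbalance threshold at neutral copy number (`merge_terminal_call`). This
   operates on calls, not on the segmentation, which is reported unchanged.

### Telomere gate

"Extends to the telomere" is operationalised as: the segment contains the
last retained SNP and its end lies within `telomere_tol_bp` (default 1 Mb)
of the last pre-QC probe on the chromosome — arrays have no probes in
telomeric repeats, so probe-terminal is the practical definition. The
effective tolerance is `max(telomere_tol_bp, 10 × the segment's own
retained-probe spacing)`: inside a high-fraction aUPD region the QC filter
legitimately removes most probes (heterozygous SNPs are pushed into the
homozygous exclusion range), so the last retained probe can sit several
median spacings from the chromosome end without any evidence against
telomeric extension. At realistic array densities (probe spacing ≲ 3 kb)
the absolute 1 Mb term dominates and the gate is unchanged.

### Clone-fraction estimation near the exclusion bound

The estimator *f* = 2·(mBAF − 0.5) is exact for an uncensored band, and it
is what `estimate_clone_fraction` and `Segment.clone_fraction` compute. For
large clones, however, the band 0.5 + *f*/2 approaches the mirrored ceiling
imposed by the homozygous-SNP exclusion (0.9 at default bounds): retained
values are then draws from a normal truncated above, and the plain mean
understates the band by up to ≈ 0.025 in mBAF (≈ 0.05 in *f*) at *f* = 0.8
with BAF noise sd 0.03. Merged calls therefore estimate the band centre by
truncated-normal maximum likelihood (Nelder–Mead on location and log-scale)
whenever the sample mean is within 3 sample-sd of the ceiling; otherwise the
plain mean is used. The correction is continuous in effect, deterministic,
and inactive for small and moderate clones.

## Statistics

`stats_core` implements the two rank statistics in full rather than
delegating, so small-sample behaviour and tie handling are explicit:

- **Spearman's rho**: Pearson correlation of tie-averaged rank vectors;
  two-sided p from the t approximation t = ρ·√((n−2)/(1−ρ²)) on n−2 df,
  with optional exact permutation enumeration for n ≤ 10. The t
  approximation is standard at the n = 19 pair count used here.
- **Mann–Whitney U**: rank-sum U with average-rank ties; exact two-sided p
  by enumeration of all C(n, n_a) rank assignments when the pooled sample
  has ≤ 12 tie-free observations, else the normal approximation with
  tie-corrected variance and continuity correction.

Both are cross-checked in the test suite against SciPy and against
independent enumeration/d²-formula oracles. All tests are two-sided.

## Synthetic data

The generator (`synthetic_cohort`) draws germline genotypes per SNP
(heterozygous with probability 0.3, otherwise AA/BB equiprobably), places
positions uniformly on the chromosome, and applies the mixture displacements
described above inside event intervals. Defaults: BAF noise sd 0.03
(typical het-cluster spread on modern arrays), LRR noise sd 0.15,
homozygous-cluster half-normal sd 0.01, MS-PCR peak coefficient of variation
0.05. A single integer seed drives all streams; cohorts derive per-case
sub-seeds from a splittable seed sequence and are byte-reproducible.

What the generator does *not* emulate: probe-level GC or intensity bias,
genotyping error, runs of germline homozygosity, interstitial events,
segmental duplications, or exome capture bias (exome VAF series are
simulated separately with binomial read sampling). Passing recovery tests
therefore demonstrate correctness of the inference chain under its own
model assumptions, not robustness to array artefacts.

Default problem sizes in tests and examples — 2000 probes per simulated
chromosome, 100 null chromosomes for specificity, 1000 Monte-Carlo
replicates for order-call robustness — were chosen as the smallest sizes at
which the mixture signal, the permutation test and the recovery tolerances
are comfortably resolved.

## Clonal ordering

`decompose_jak2` inverts the conservation identity: *f*_hom = 2·(BAF9 − 0.5),
*f*_het = 2·(*v* − *f*_hom). Negative *f*_het or totals above 1 within a
tolerance (default 0.05) are clamped as measurement noise; larger violations
raise an explicit model-inconsistency error rather than being silently
clamped. Note the ~4.5× error amplification from (*v*, BAF9) into *f*_het:
analyses of noisy measurements should widen the tolerance accordingly. The
order rule is symmetric twofold dominance: aUPD14q-first if
*f*14 ≥ 2·(*f*_hom + *f*_het), JAK2-first under the mirrored condition,
uncertain between. aUPD9p is assumed to duplicate the mutant allele, and
clonal nesting is not resolved — only marginal cell fractions are reported.

## Region arithmetic

Coordinates are 1-based inclusive throughout; BED export converts to 0-based
half-open. Interval length is end − start + 1; megabase sizes and prevalence
percentages are rounded half-up to one decimal, the convention that
reproduces the packaged case table's printed size column. The MAR is
[max(starts), min(ends)] over contributing intervals on one chromosome;
intervals resolved only to the nearest megabase are excluded by default
(conservative MAR) but counted, and an empty intersection is reported
explicitly rather than raised. The packaged table contains one printed size
cell (case E09895) that is internally inconsistent with its own coordinates
by exactly 0.1 Mb under every convention that fits the other 25 precise
cells; the table transcribes the printed value and the test suite pins the
discrepancy.

## Variant QC

All sequencing QC thresholds are inclusive lower bounds (depth ≥ 4,
alternate depth ≥ 2, quality ≥ 20, base-call quality ≥ 10, strand /
base-quality / tail bias and HWE p ≥ their floors); a record must satisfy
every rule, and rejections are attributed to the first violated rule in that
fixed order, so rejection counts plus passes conserve the input count. The
rare-variant filter keeps in-region variants that are novel (no database
frequency) or whose folded minor allele frequency min(af, 1 − af) is ≤ 1%.
VAF-based aUPD confirmation feeds alt/total read fractions through the array
pipeline unchanged, except that the copy-neutrality gate is skipped: exome
VAF carries no usable dosage signal. The INFO keys carrying the bias/HWE
p-values and the population frequency are configuration (defaults `SBP`,
`BQBP`, `TBP`, `HWEP`, `POP_AF`, `BQ`), since no single caller convention
is universal.

## Known limitations

- Interstitial (non-telomeric) copy-neutral LOH is out of scope by design.
- The truncation-corrected band estimator assumes a single dominant clone;
  polyclonal mixtures yield an effective average fraction.
- Batch-wise methylation normalisation is supported (one control set per
  bisulphite batch) but the default is a global control offset.
- The exact Mann–Whitney path is limited to 12 tie-free observations;
  beyond that the tie-corrected normal approximation is used, which is
  accurate at the group sizes involved here but approximate for tiny
  heavily-tied samples.
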