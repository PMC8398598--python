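# Methods

This note records the models, parameters and design decisions behind
`nbpanel`, and what the synthetic-data validation does and does not show.

## Panel model

A panel is a merged, sorted set of target regions in three classes: gene
targets, chromosomal-region tiles (1p36/11q/17q), and copy-number
reference probes.  Coordinates are 0-based half-open internally (BED
convention); 1-based coordinates appear only at SAM/VCF boundaries.
Overlapping or bookended records of the same class are merged on load;
the merge is idempotent and permutation-invariant, and `total_target_bp`
is the sum of merged-region lengths.  Analysis bins (default 100 bp,
configurable, minimum 10) tile each region exactly; only the last bin of
a region may be short.

## Synthetic data generator

The generator emits *pre-aligned* reads — positions and CIGARs are
computed directly — because the pipeline under test begins after
alignment; no aligner is involved, and alignment artifacts (mismapping,
multi-mapping) are out of scope.

* **Fragments**: lengths are Normal(mean 250 bp, SD 50 bp), clipped below
  at 2x read length (read length 100 bp).  The lower truncation means
  mates never overlap, so allele draws at a site are independent across
  the reads that cover it — this is what makes the per-site alt count
  exactly Binomial and lets detection-power checks use a closed form.
  These sizes are fixture choices typical of sonicated capture libraries,
  not measurements of any particular assay.
* **Enrichment**: on-target fragments are placed uniformly among
  placements overlapping a target; the off-target fragment count is
  calibrated against the realized on-target *read* count so that the
  uniquely-aligned on-target read fraction converges to the configured
  value (default 0.45).  Off-target fragments land uniformly outside
  target +/- 500 bp.
* **Copy number**: the sampling rate over a CNV segment scales by
  `(purity * CN + (1 - purity) * 2) / 2`; segment boundaries inside a
  target region split the region's rate function, so intragenic partial
  deletions have sharp (fragment-smeared) edges.
* **SNVs**: each *fragment* overlapping a configured site carries the
  alternate allele with probability
  `purity * vaf * CN / (purity * CN + (1 - purity) * 2)`, where `vaf` is
  the allele fraction within tumor cells; `expected_vaf` exposes this
  generative probability for parameter-recovery tests.  A configuration
  whose alt equals the reference base is rejected as invisible.  A
  separate `reference_seed` lets replicate runs share one genome.
* **Rearrangements**: `del` and `translocation` junctions join the
  sequence left of breakpoint A to the sequence starting at breakpoint B.
  Each junction emits chimeric fragments at the rate expected for one
  derived allele out of two; reads straddling the junction get terminal
  soft clips exactly at the junction coordinate, reads fully on one side
  become discordant mates.  Other junction orientations (duplication-,
  inversion-type) are not simulated; the caller's orientation taxonomy is
  exercised with handcrafted alignments instead.
* **Noise**: base-call errors are off by default; an optional uniform
  substitution rate (0.001 in the specificity tests) stress-tests SNV
  thresholds.  MAPQ is 60, with an optional fraction of MAPQ-0 reads to
  exercise the unique-alignment filter.  Duplicates, FFPE deamination and
  sequencer error profiles are not modeled.

Fixed seeds give byte-identical FASTA/SAM/JSON; all randomness flows from
`numpy.random.default_rng([seed, stream])`.

What passing tests show, and what they do not: the callers recover the
generator's truth under idealized mapping and noise.  Real libraries add
GC bias, mappability artifacts, duplicate structure and FFPE damage; the
control-model dispersion would be wider and breakpoint refinement noisier
than in these conditions.

## Coverage QC

"Uniquely aligned" is operationalized as MAPQ >= 20 (configurable);
secondary, supplementary, unmapped and duplicate-flagged reads are always
excluded.  A read is on-target if it overlaps any target by >= 1 bp; the
denominator counts reads, not pairs.  Depth counts only M/=/X-aligned
bases, so soft clips never contribute.  `coverage_at_fraction(q)` returns
the largest depth v with at least a fraction q of target *bases* at depth
>= v; a per-region variant (quantile over region mean depths) is available
behind a flag, the base-level metric being the stricter, standard choice.

## Copy-number calling

* **Control model**: each diploid control is library-size normalized to
  the pooled median; expected depth is the per-bin across-control median;
  dispersion is `max(1.4826 * MAD, sqrt(expected))`.  The Poisson floor
  prevents zero dispersion when controls are few or identical.  Bins with
  expected depth below 10 are masked.  Median/MAD were chosen over
  mean/SD for robustness to a contaminated control; with the floor active
  at panel depths the two aggregations are nearly indistinguishable.
* **Ratios**: the sample is scaled onto the control model by the median
  of expected/observed over the reference-probe bins (all unmasked bins
  when the panel has none), then `r = d_obs / d_exp` and
  `z = (d_obs - d_exp) / dispersion` per unmasked bin.  Ratios are
  invariant to any common rescaling of sample and controls.
* **Region calls**: a region needs >= 3 unmasked bins; a call requires a
  strict majority (> 50%) of bins with `|z| > 3` *all in one direction* —
  any significant bin of the opposite sign yields a `mixed_direction`
  no-call.  This is deliberately conservative: a focal event inside a
  larger region should surface as a partial deletion, not flip a
  region-level call.
* **Absolute copy number**: `CN = (2 r - 2 (1 - p)) / p` from the mean
  ratio over significant bins, clipped at zero.  Purity is user-supplied
  (default 1.0); the package does not infer it.  Categories:
  amplification CN >= 8 (diagnostic convention for high-level *MYCN*
  amplification, >= 4-fold over diploid), gain CN >= 2.5, loss CN <= 1.5,
  deep loss CN <= 0.5, else neutral.

Measured on the bundled study conditions (12-region panel, 65 reference
probes, five 1000x controls): recovery of CN {1, 3, 4, 8, 40} at purity
{0.5, 1.0} within 20%, and no calls on diploid-vs-diploid comparisons.

## Structural-variant calling

* **Fragment model**: median and MAD-scaled SD of outer distances of
  proper inward pairs (>= 100 required); discordance cutoff
  `mean + 3 SD`.  The multiplier is a design choice; three robust SDs
  keeps ~99.9% of proper pairs concordant.
* **Orientation taxonomy**: different contigs -> translocation; same
  contig inward-but-distant -> deletion-like; outward -> duplication-like;
  same strand -> inversion-like.  Separating classes prevents merging
  opposite-type events during clustering.
* **Clustering**: single linkage within a class; a pair joins a cluster
  if both anchor positions are within 500 bp of some member;
  >= 3 supporting pairs required (panel depths give hundreds of pairs per
  real event, so this threshold is about noise, not sensitivity).
* **Deletion-tail guard**: at 1000x the right tail of the fragment-length
  distribution alone produces clusters of "discordant" inward pairs just
  past the cutoff (~0.1% of pairs, tens per kilobase of target).  In
  end-to-end calling, deletion-like clusters must therefore show a median
  mapping distance above `cutoff + 3 fragment-SD`.  True deletions of a
  few hundred bases and up pass easily; fragment-tail clusters do not.
  This guard applies only to the deletion-like class.
* **Refinement**: terminal soft-clip coordinates (>= 5 clipped bases) are
  collected near each cluster side; the modal clip position gives
  base-pair resolution, otherwise the cluster-extent midpoint is reported
  at interval resolution.  Ties break toward the most frequent, then
  smallest, position.
* **TERT classification**: a junction end inside the gene body is
  intragenic; within 25 kb 5' of the TSS (strand-aware) is upstream.  The
  window is configurable; the two classes are reported distinctly because
  only the upstream regulatory class has an established link to
  telomerase overexpression, while intragenic junctions (as in the
  *ALK*:*TERT* fusion configuration) are of unclear significance.
* **Partial deletions**: within a gene of >= 6 bins, an internal run of
  >= 3 loss-significant bins flanked by neutral bins is a partial
  deletion; a whole-gene run is left to the region-level CNV call.  A
  breakpoint within 500 bp of a run edge upgrades confidence to
  `breakpoint_supported`; a breakpoint in the gene without the depth
  signature is reported as `breakpoint_only` rather than suppressed,
  since low tumor content can erase the depth signal while the junction
  remains visible.
* **Consensus merging**: calls from different callers collapse under
  single linkage when both breakpoints lie within 500 bp and types match
  exactly; the consensus takes the per-breakpoint median position and the
  union of caller names; calls with fewer than 2 distinct callers are
  discarded.  With window 0 only coincident calls merge; with
  min-callers 1 nothing is discarded.  Output and result are invariant to
  callset and call order.

## SNV calling

Pileup counts M/=/X-aligned bases with base quality >= 13 and MAPQ >= 20.
Calling thresholds (depth >= 100, alt reads >= 10, VAF >= 0.05) are set
so that a 10.5% subclone is comfortably callable at panel depth while the
same variant at exome-like 45x fails the support requirement most of the
time; all are configurable, and the minimum reportable VAF is a
deliberate choice rather than an assay property.  Indels are out of
scope; low-quality bases are counted per site as excluded events.

Tumor-only mode is primary: without a matched normal, allele fractions in
[0.40, 0.60] or >= 0.90 set a `possible_germline` *flag* (optionally
forced by a user-supplied population-variant list).  Flagged calls are
excluded from pathway-hit counting by default but never dropped from
output — rigorous hard filtering risks discarding rare but relevant
somatic variants, and the flag keeps the decision reviewable.

Hotspot annotation is a static lookup keyed by (gene, protein change),
bundled for recurrent *ALK* and *TP53* hotspots and user-extendable; the
package does not predict protein consequences.

`detection_probability(f, c, k)` is the exact binomial tail
`P(X >= k), X ~ Binomial(c, f)` — monotone increasing in `f` and `c`,
decreasing in `k`.  The generator's non-overlapping mates make this exact
for simulated data; real overlapping mate pairs would correlate counts
slightly.

## Risk engine

Telomere maintenance (TMM) markers: *MYCN* amplification, *TERT*
rearrangement (either breakpoint class, reported distinctly), *ATRX*
alteration (SNV, partial deletion, or region-level loss).  One positive
marker gives its status, two or more give `multiple`, none gives `none`.
Risk classification is a pure truth table: TMM-positive with >= 1
RAS/MAPK or p53/MDM2 pathway hit (SNV or amplification in the gene sets)
is ultra-high-risk; TMM-positive without a hit is high-risk; TMM-negative
is reported as `tmm_negative` with an explicit caveat rather than
"low-risk", because ALT without *ATRX* alteration and telomerase
overexpression without a detected rearrangement both evade a DNA panel.

The default pathway gene sets (RAS/MAPK: ALK, NRAS, KRAS, HRAS, BRAF,
RAF1, NF1, PTPN11, FGFR1; p53/MDM2: TP53, MDM2, PPM1D, CDKN2A) are a
documented stand-in for a site-specific curation and are user-overridable.

FISH comparison sums per-ratio-class cell fractions into an aberrant-cell
percentage; cohort concordance produces per-marker 2x2 counts whose sum
always equals the cohort size, with discordant samples listed.  The
oncoplot matrix orders fixed marker rows before per-gene SNV rows and
sorts columns by risk class, then alteration burden, then sample id —
making it invariant to input order.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use compact study conditions
chosen so each check has clear statistics: copy-number work uses a
12-region + 65-probe panel at 1000x with five controls; SV recovery uses
a three-gene panel at 500x with a translocation and a 1.5 kb intragenic
deletion; SNV power uses a 400 bp region at 1000x and 500 replicates at
45x; QC calibration uses a 25 kb mixed panel at 150x and enrichment 0.45.

## Known limitations

No purity inference, no allele-specific copy number or copy-neutral LOH
(a SNP-backbone design would be required), no indel calling, no
assembly-based breakpoint reconstruction, no duplicate-read or FFPE
artifact simulation, and no claim about ALT or telomerase expression
status.  Region-level CNV calls on low-purity samples degrade first for
single-copy losses, mirroring the behavior of depth-ratio methods
generally.
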