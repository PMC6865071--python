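# Methods

This note documents the models, conventions and numerical choices behind
`smmipseq`, in the order the pipeline runs. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and panel model

All coordinates are 0-based half-open on **transcript** (cDNA) space, never
genome space: smMIPs capture cDNA, and every downstream computation
(gap-fill extraction, pileups, junction k-mers) is interval arithmetic on
the transcript. Exons are numbered 1-based, as in common usage ("exon 9 of
CA12"); exon structure travels in the reference FASTA header as cumulative
end offsets (`exons=...`), with `gene=SYMBOL` naming the gene.

A probe is defined by its two arm sequences, its ROI `[roi_start, roi_end)`
and optional junction targets `(u, d, label)` declaring that the probe
discriminates the isoform joining exon `u` directly to exon `d`
(`d == u + 1` is the canonical junction). Junction-probe ROIs are stored in
canonical coordinates, so an EGFRvIII-style exon-1/8 probe has a raw ROI far
longer than the capture reaction's gap-fill capacity; what must fit is the
**effective gap-fill** — the ROI after excising the skipped exons — and that
is what validation checks (minimised over the probe's compatible splice
forms). A splice form whose excised region clips an arm or a ROI edge is
not capturable by that probe at all; this is exactly how the exon-1/8 probe
captures only EGFRvIII molecules while ordinary EGFR probes, placed on
retained exons, measure total EGFR.

Arm pairs must be unique in a panel (assignment keys on them; duplicates are
a validation error, not a warning), and transcripts covered by fewer than
five probes are warned about — five evenly spaced probes per transcript is
the design floor for a robust per-transcript mean.

## Read simulator

The simulator emulates the assay's quantitative chemistry:

* **Capture**: per probe, the number of captured molecules is
  `Poisson(abundance)`, with abundance expressed as expected molecules per
  probe — capture is linear in transcript abundance. Isoform identity is
  drawn per molecule from per-gene fractions; molecules whose splice form a
  probe cannot capture are lost to that probe.
* **Variants**: planted per molecule as `Bernoulli(allele fraction)`
  (substitutions or short VCF-style indels applied to the gap-fill). An
  `exact` mode plants `floor(af × n)` alt molecules deterministically; it
  exists to verify strict decision boundaries, where binomial sampling at a
  boundary fraction would make the expected decision itself a coin flip.
* **UMIs**: each molecule draws a uniform random 8-mer; collisions are
  simulated, not prevented (≈ n²/2·4⁻⁸ expected per probe). A
  `collision_free_umis` run option draws per-probe UMIs without replacement;
  like `exact`, it provides the deterministic-depth regime needed when a
  measured fraction must land exactly on a filter boundary. Both switches
  are off by default.
* **Amplification and errors**: an iid geometric duplication factor per
  molecule (mean configurable, 1 = none) and a uniform per-base substitution
  error on each emitted read. No quality-score model, no indel sequencing
  errors, no RNA degradation or fragmentation model — passing tests say
  nothing about those axes of real data.
* **Layout**: `barcode(8) | ligation arm | gap-fill | extension arm |
  UMI(8)`, 266 nt total at the defaults (25-nt arms, 200-nt ROIs), emitted
  as overlapping 2×151 pairs; read 2 is the reverse complement of the
  amplicon's tail. Amplicons longer than `2×read − min_overlap` or shorter
  than one read length are errors.
* **Barcodes**: codewords of a shortened Hamming-type linear code over
  GF(4) (minimum distance 3, 1024 words for length 8), so pooled runs of up
  to several hundred samples demultiplex unambiguously at one mismatch.
* **Randomness**: everything descends from one seed through numpy seed
  sequences. Molecule-level draws and amplification-level draws use separate
  child streams, so changing duplication or error settings never changes
  which molecules exist — the property the deduplication contract is tested
  against. Repeated runs are byte-identical down to the gzip output.

The default three-group cohort design (`three_group_design`) emulates a
glioma-style study: 10 samples per group, base abundance 60 molecules per
probe, 5-fold marker-gene programmes per group, a heterozygous IDH1-like
hotspot confined to group B, CA12v1 absent from group B, EGFRvIII present
only in group A, exponential survival with a hazard ratio of 4 between the
long- and short-surviving groups, light independent exponential censoring,
and a per-sample log-normal abundance jitter (σ = 0.15). These sizes keep
every end-to-end study well under a few minutes on one CPU while leaving
the recovery margins (clustering ARI, association q-values, log-rank p)
wide.

## Capture: demultiplexing, assignment, merging

The sample barcode occupies the first 8 bases of read 1 and is matched
exactly (hash) or to the nearest barcode within a tolerance (default 1
mismatch); the barcode table must have pairwise Hamming distance
> 2×tolerance or it is rejected up front. Probe assignment is **arm
anchored**: the ligation arm sits directly after the barcode on read 1 and
the extension arm directly before the UMI at the amplicon end (read from
the reverse-complemented mate). A pair is assigned iff both arms match one
probe within the per-arm tolerance (default 1) and no other probe matches
equally well; ties are ambiguous and counted as unassigned. Fixed-offset
Hamming matching replaces alignment because the arms are anchored by the
capture chemistry itself.

Mates are merged by maximising overlap agreement over the candidate
amplicon lengths implied by the assigned probe's splice forms, extended by
±6 nt for short indels; a merge needs ≥ 80% agreement over ≥ 10 overlapping
bases. Overlap positions where the mates disagree are masked to `N` and
carry no variant evidence. Accounting is conservative and conserving:
`assigned + unassigned-by-arms + unmerged + malformed = input`, per sample,
plus a run-level undetermined-barcode count.

## Quantification

Molecules are `(sample, probe, UMI)` groups with a per-position weighted
majority consensus (reads of the modal gap-fill length vote; `N` never
votes; voting ties mask to `N`). Collapse is idempotent. Two consequences
of real UMI behaviour are worth knowing: UMI *collisions* merge two true
molecules (a v1/v2 collision at a junction probe resolves to the shorter
modal length), and UMI *read errors* spawn spurious singleton molecules
(≈ 0.8% per read pair at the default error rate). Both effects are small at
panel-scale depths but measurably widen the isoform-fraction sampling
distribution beyond pure binomial — the isoform calibration study finds
~94–95% coverage of the exact 95% binomial interval rather than the nominal
95.5%.

FPM is per-sample: `unique / total_unique × 10⁶`, so each sample's FPM sums
to one million by construction. Transcript expression is the arithmetic
mean FPM over all of the transcript's probes, with two documented choices
where the convention is genuinely open: zero-count probes contribute zeros
(dropout is signal; excluding it would inflate means), and junction-specific
probes count like any other probe of their transcript. Both are arguments
one could make differently; they are defaults, not hard-coded assumptions.

Isoform classification matches the 2k-mer (k = 10) straddling each
candidate junction boundary against the molecule's consensus gap-fill;
exactly one hit classifies the molecule, zero or several are ambiguous and
reported. k = 10 is chosen so both CA12 junctions fit a single ROI and are
separable — exon 9 is 33 nt, so a 20-mer spans a boundary without reaching
the neighbouring junction. Isoform FPM shares the sample's total-unique
denominator. EGFRvIII status is negative below 5 FPM (positive at ≥ 5).

## Variant calling

Calls come from a per-position pileup of molecule consensus sequences.
Depth at a position is the number of molecules covering it with a
determinate (non-`N`) base; the pass rule is **strictly** `fraction > 0.10`
of unique molecules at that position. The denominator is per-position
unique-molecule depth (not per-probe totals) — the natural per-locus
reading, configurable, and documented as interpretive. Junction-probe
molecules are compared against the splice form their junction k-mer
identifies; ambiguous molecules are excluded from evidence.

Length-deviating gap-fills are realigned by common prefix/suffix into one
anchored VCF-style indel per molecule; remaining mismatches after removing
the indel are counted as substitutions. Two independent indels in the same
ROI on the same molecule are not decomposed (the molecule is dropped as
complex) — a known limitation of prefix/suffix realignment. Repetitive
context resolves to the leftmost placement.

The strict rule has an honest low-depth consequence: at depth 9, a single
consensus-error molecule is 1/9 > 10% and passes. The filter is a fraction
rule, not an error model; downstream interpretation should weigh depth
(reported on every call). Protein-level names (IDH1-R132H, BRAF-V600E, …)
are catalog lookups only; everything else carries a transcript-coordinate
c.-style description.

## Cohort statistics

* **Transform**: `log10(FPM + 0.01)` (zero FPM → −2 exactly), then
  per-transcript z-score across samples; the order (log, then z, then
  distances) is the natural reading where the convention is not fixed.
  Constant transcripts become all-zero and are flagged rather than dropped.
* **Clustering**: Manhattan distances between sample profiles, UPGMA
  (group-average) agglomeration via scipy, labels from a k-cut (default
  k = 3, with a height-cut alternative since no cut rule is canonical).
  UPGMA heights are monotone; the merge tree is oracle-checked against an
  independent O(n³) implementation in the tests.
* **Differential expression**: two-sided Mann–Whitney U per transcript —
  exact null when the smaller group has ≤ 8 samples and the pooled values
  are tie-free, otherwise the normal approximation with tie and continuity
  correction (within 0.01 of exact at sizes 9–20 in the tests). BH step-up
  at FDR < 0.05. Fold changes are computed on raw mean FPM (largest over
  smallest, with an orientation flag), since expression ratios are reported
  on the FPM scale, not the transformed one.
* **Mutation association**: each hotspot × each cluster-vs-rest 2×2 table,
  two-sided Fisher exact (point-probability rule — the conventional
  two-sided definition; doubling rules exist and would differ), BH over all
  contrasts at the stricter FDR < 0.01. Only passing calls reach the status
  columns. Isoform-presence associations (e.g. CA12v1 carriage vs a
  survival dichotomy) run through the same machinery by encoding presence
  as a mut/wt status column.
* **Survival**: Kaplan–Meier product-limit per group with right censoring;
  medians report "not reached" when the curve never crosses 0.5; two-group
  Mantel–Haenszel log-rank (simultaneous risk-set evaluation at tied times),
  k-sample extension beyond two groups.
* **Correlation**: Spearman with tie-averaged ranks; a constant vector has
  no rank ordering and reports NaN rather than a fabricated value.
* **Actionable flags**: strict `> 2×` the cohort mean per target; EGFRvIII
  ≥ 5 FPM; CA12v1 strictly > 50 FPM. Boundary values (exactly 2-fold,
  exactly 50 FPM) do not flag; the thresholds' wording is "higher than".

## Verification studies and their sizes

The acceptance studies (`scripts/acceptance.py`, mirrored by
`tests/test_acceptance.py`) use: 50 transcripts × 5 probes at a 2× paired
abundance ladder for linearity; 100 replicates of a 1000-molecule 70/30
CA12 mixture for isoform calibration; 100 seeds of four planted fractions
at ~500-molecule depth for the filter boundary (run in the deterministic
`exact` + `collision_free_umis` regime, since the 10% boundary decision is
only well-defined when the measured depth equals the planted count); 100
random matrices (n ≤ 12) for the UPGMA oracle, every group-size pair ≤ 8
for Mann–Whitney enumeration, and all 135,751 2×2 tables with n ≤ 40 for
Fisher; 200 all-null 30×100 cohorts for FDR control; and one full 30-sample
three-group cohort (~380k read pairs) for end-to-end recovery. Together
they run in a few minutes on one CPU.

## Known limitations

* No quality-aware base calling, no sequencing-indel error model, no UMI
  edit-distance clustering (8-mer space is large relative to per-probe
  depth; a directional mode would mitigate UMI-read-error singletons at
  high duplication).
* One indel per ROI per molecule; complex molecules are dropped from
  evidence rather than realigned.
* The strict >10% rule passes single-molecule noise at depth < 10.
* FPM is the only normalization (no TMM/quantile, no batch correction), and
  probe-level capture efficiency differences are not modelled or corrected —
  within-assay comparisons across samples are the intended use.
* The simulator's cohort designs are stylized (clean group structure,
  exponential survival); they demonstrate the pipeline's correctness, not
  the biological variability of real tumour cohorts.
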