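# smmipseq

Analysis of targeted RNA sequencing with **single-molecule molecular
inversion probes (smMIPs)** — from pooled, barcoded paired-end reads to
UMI-deduplicated molecule counts, FPM expression values, junction-resolved
splice isoforms, RNA-level variant calls, and cohort-level statistics
(clustering, differential expression, mutation association, survival,
actionable-marker flags). A truth-annotated read simulator makes every stage
testable without any external data.

The package is written for groups running smMIP-based targeted RNA panels on
tumour cohorts (the motivating application is diffuse glioma), and for
anyone who wants a fully seeded, end-to-end reference implementation of the
UMI-counting analysis model behind such assays.

## The assay and its analysis model

An smMIP hybridizes two arms (extension and ligation) flanking a region of
interest (ROI) on a cDNA; gap-filling and ligation circularize the probe,
capturing the intervening sequence together with a random 8-nt **unique
molecular identifier (UMI)**. The number of circularized probes is linearly
related to the number of RNA molecules in the sample, so after PCR and
2×151 nt sequencing:

* reads sharing `(sample, probe, UMI)` derive from one capture event and are
  collapsed to a single molecule with a per-position majority consensus —
  this removes PCR amplification bias entirely;
* per-probe unique counts are normalized within each sample to **FPM**
  (fragments per million): `FPM = unique / total_unique × 10⁶`;
* a transcript's expression is the mean FPM over all of its probes
  (zero-count probes included);
* junction-spanning probes classify each molecule by the 20-mer straddling
  an exon boundary, quantifying splice isoforms such as EGFRvIII (exons 1/8)
  and the CA12 variants — one probe resolves both the exon 8–9 and 8–10
  junctions because exon 9 is only 33 nt;
* variants are called from a per-position pileup of molecule consensus
  sequences; a call is reported as passing iff its alt fraction strictly
  exceeds 10% of the unique molecules at that position.

Cohort statistics follow standard practice for targeted expression panels:
per-transcript `z(log10(FPM + 0.01))`, Manhattan-distance UPGMA clustering,
two-sided Wilcoxon–Mann–Whitney differential expression with
Benjamini–Hochberg control (FDR < 0.05), Fisher's exact mutation–cluster
association (FDR < 0.01), Kaplan–Meier curves with the log-rank test, and
per-sample actionable flags (> 2-fold over the cohort mean; EGFRvIII ≥ 5
FPM; CA12v1 > 50 FPM as a poor-prognosis mark). See `docs/methods.md` for
the full model description and every default.

## Worked example

```python
from smmipseq import simulate, capture, quantify, variants, cohort
import tempfile, pathlib

# a small synthetic panel: 4 regular genes plus IDH1, EGFR and CA12
panel = simulate.synthetic_panel(genes=["G001", "G002", "G003", "G004", "IDH1"], seed=0)
catalog = simulate.hotspot_catalog(panel)
design = simulate.three_group_design(panel, n_per_group=(4, 4, 4), hotspot=catalog)
run = simulate.RunConfig(mean_duplication=2.0, error_rate=0.001)

with tempfile.TemporaryDirectory() as d:
    sim = simulate.simulate_cohort(design, panel, run, seed=11, outdir=d)
    d = pathlib.Path(d)
    captured, stats = capture.capture_run(
        d / "pooled_R1.fastq.gz", d / "pooled_R2.fastq.gz", sim.barcode_table, panel
    )
print(f"assigned {sum(s.assigned for s in stats.per_sample.values())} "
      f"of {stats.input_pairs} read pairs")

molecules = quantify.collapse_molecules(captured)
table = quantify.fpm_normalize(molecules, samples=sim.sample_ids)
expression = quantify.gene_expression(table, panel)
isoforms = quantify.isoform_quantify(molecules, panel)

calls = variants.annotate_hotspots(variants.call_variants(molecules, panel), catalog)
profiles = variants.integrate_profile(expression, calls, catalog)
clusters = cohort.upgma_cluster(cohort.preprocess_matrix(expression), k=3)
assoc = cohort.mutation_assoc(profiles, clusters.labels)
surv = cohort.survival_compare(
    sim.clinical.set_index("sample_id")[["survival_days", "event"]],
    profiles["IDH_status"],
)
```

Printing the intermediate results of this exact session gives (seeded, so
reproducible):

```
assigned 80803 of 80853 read pairs
40903 unique molecules; EGFRvIII-positive samples: ['S001', 'S002', 'S003', 'S004']
sample_id annotation  depth  fraction
     S005 IDH1-R132H     59  0.423729
     S006 IDH1-R132H     56  0.464286
     S007 IDH1-R132H     51  0.549020
     S008 IDH1-R132H     74  0.405405
cluster sizes: {1: 4, 2: 4, 3: 4}
   hotspot  cluster       p        q  significant
IDH1-R132H        3 0.00202 0.006061         True
median survival (mut): 659.022 days
median survival (wt): 444.11 days
log-rank p = 0.3786
```

Reading the output: 99.9% of read pairs are assigned to their probe by
arm matching; the four group-A samples are EGFRvIII-positive (their isoform
FPM is ≥ 5); the planted heterozygous IDH1 hotspot is called at ~0.4–0.55
alt fraction in all four group-B carriers and passes the >10% filter; UPGMA
recovers the three 4-sample groups exactly, and the hotspot associates with
its cluster at q < 0.01. With only 12 patients the IDH-stratified log-rank
comparison is (correctly) not significant — survival separation needs the
larger cohorts exercised in the verification studies below.

The same pipeline is available as CLI subcommands
(`smmipseq simulate | validate | capture | quantify | variants | cluster |
de | assoc | survival | report`); run `smmipseq --help`.

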