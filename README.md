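# rtarch

Toolkit for linking DNA replication timing (RT) to nuclear architecture:
RT profiling and switch classification, broad occupancy-domain calling with
interval algebra, meta-domain clustering, sequence-feature stratification of
replication origins, and 4C-seq viewpoint contact analysis — plus a seeded
synthetic-genome simulator that generates every input with a planted-truth
record, so the whole pipeline is testable without external data.

## Modules

| module | what it does |
| --- | --- |
| `rtarch.core` | genomic intervals, interval-set algebra, fixed-bin tracks |
| `rtarch.genome_model` | synthetic genome / assay / 4C simulator with planted truth |
| `rtarch.timing` | RT = log2(early/late), loess smoothing, bimodality, domain segmentation, EtoE/EtoL/LtoE/LtoL switch calls (±1 ΔRT) |
| `rtarch.domain_arch` | broad enriched-domain caller (binarize → maximal segments → permutation FDR), base-pair Venn overlaps, lamin-coverage partition, late-genome coverage |
| `rtarch.profiles` | scaled meta-domain and point-centered signal matrices, k-means row clustering, per-cluster RT summaries |
| `rtarch.seqfeatures` | GC content, CpG observed/expected ratio CpG/(GC/2)², G4 and G-rich motif scans (both strands), SNS/TSS stratification |
| `rtarch.contacts` | in-silico digestion, RPM normalization with viewpoint exclusion, replicate-consistent contact calling against a distance-decay background, RPM-range genotype comparison (paired t-test), intra/inter-RT-domain scope, TAD-level RT specificity |
| `rtarch.io` / `rtarch.pipeline` / `rtarch.cli` | BED/bedGraph/FASTA/TSV formats, config, end-to-end driver |

## CLI

```bash
rtarch run --outdir out --seed 1            # full pipeline on the synthetic genome
rtarch simulate --outdir sim --seed 1       # inputs + planted truth only
rtarch timing --early early.bedgraph --late late.bedgraph --out rt.bedgraph
rtarch switches --rt-wt rt_wt.bedgraph --rt-ko rt_ko.bedgraph --out switches.bed
rtarch domains --enrichment chip.bedgraph --out rads.bed
rtarch overlap --a rads.bed --b lads.bed
rtarch partition --rads rads.bed --lads lads.bed --out-prefix rad
rtarch metaprofile --domains lads.bed --track chip.bedgraph --out meta.tsv
rtarch cluster --matrix meta.tsv -k 4 --out clusters.tsv
rtarch seqfeat --fasta genome.fa --out-prefix motifs
rtarch stratify --sns sns.bed --tss tss.bed --rt rt.bedgraph --out strata.tsv
rtarch digest --fasta genome.fa --out fragments.bed
rtarch contacts --rep1 rep1.tsv --rep2 rep2.tsv --viewpoint chr1:5000000 --out contacts.bed
```

Thresholds (RT class cutoffs −0.5/+0.5, switch threshold ±1, RPM edges
10/200, loess span, flank sizes, cluster k, …) are all exposed as CLI
options and `PipelineConfig` fields with one set of auditable defaults; a
YAML config can override any of them (`rtarch run --config cfg.yaml`).

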