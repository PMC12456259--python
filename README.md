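# metaprotdb

Tools for integrating metaproteomics with metagenomics and
metatranscriptomics through the search database. Given per-sample assembly
contigs, gene calls and predicted proteins, `metaprotdb` builds
size-budgeted protein search databases for metaproteomics, post-processes
the resulting peptide-spectrum-match (PSM) reports with target-decoy FDR
control and parsimonious protein grouping, and emits a GFF3
"metaproteomics evidence" track that places every expressed protein back
on its assembly contig. It is aimed at microbiome researchers who have
paired multi-omics data and want the protein evidence mapped onto the
metagenome without running anything heavier than a search engine in
between.

## What it computes

**Database construction.** The sensitivity of a metaproteomics search
depends on the search database (DB): too small misses proteins, too large
dilutes sensitivity and inflates the FDR. The preferred DB pools the
predicted proteins of all samples in a study, but that can exceed a
practical size. `metaprotdb` therefore:

1. sketches every sample assembly with FracMinHash: the sketch keeps all
   canonical k-mer hashes `h < 2^64 / scaled` (defaults `k = 31`,
   `scaled = 1000`), giving unbiased Jaccard/containment estimates of
   k-mer-set similarity;
2. builds a dendrogram over samples by agglomerative clustering on
   `d = 1 − J(s_i, s_j)` (average linkage by default);
3. cuts the tree top-down: any subtree whose pooled protein FASTA fits
   the byte budget (default 1 GiB) becomes one sample group; oversized
   subtrees are split recursively, so closely related samples share a
   DB. A group report records which assemblies stand behind each DB;
4. optionally pulls in catalogue genomes whose sketch containment in any
   sample assembly reaches a threshold (default 0.5), as a stand-in for
   biome-specific genome catalogues;
5. assembles each group's DB: length-filtered contigs (strict >500 bp
   metagenomic, >200 bp metatranscriptomic), pooled proteins with exact
   duplicates collapsed, host and contaminant standards appended, and one
   reversed-sequence decoy per target entry.

**Post-processing.** PSM report tables are validated by target-decoy
q-values (`FDR(t) = #decoys ≥ t / #targets ≥ t`, q = running minimum;
1% protein-level FDR by default). Proteins with identical matched-peptide
sets merge into one group and strict-subset proteins are absorbed
(Occam's-razor inference). Groups are then filtered: (i) keep only groups
with validated PSMs; (ii) strip host/contaminant members and drop groups
that relied on them; (iii) remove proteins claimed by more than one
surviving validated group. Semi-quantification uses spectral counting:
`NSAF_g = (count_g / L_g) / Σ_h (count_h / L_h)`.

**Evidence track.** Each surviving protein maps back, through its
provenance, to its gene call: one GFF3 `CDS` feature per protein with
unique/ambiguous peptide lists, PSM count and NSAF. The `unique` track
variant keeps only features backed by at least one unique peptide.

A synthetic-fixture module generates complete study inputs — planted
genomes, fragmenting assemblies, gene calls, proteins, catalogues and PSM
tables with known true/false score structure — so the whole pipeline is
testable offline.

## Worked example

```bash
metaprotdb make-fixtures --out demo/fixtures --seed 7 \
    --n-samples 3 --n-genomes 4 --genes-per-genome 15 --genome-length 25000
metaprotdb build-db --samples-dir demo/fixtures/samples --out demo/dbs \
    --budget-bytes 20000 \
    --host-fasta demo/fixtures/standards/host.fasta \
    --contaminants-fasta demo/fixtures/standards/contaminants.fasta
cat demo/dbs/group_report.tsv
```

```
group_id  sample_ids  assembly_ids  estimated_db_bytes  overflow_flag
group001  sample01    sample01      18703               false
group002  sample02    sample02      14185               false
group003  sample03    sample03      9513                false
```

With a 20 kB budget the three samples are too large to pool (their joint
estimate exceeds the budget), so the tree traversal emits three
sample-specific databases, each within budget and none overflow-flagged.
Post-processing the simulated PSM table against the pooled fixture DB:

```bash
metaprotdb postprocess --psms demo/fixtures/psms.tsv \
    --db demo/fixtures/fixture_db.fasta \
    --samples-dir demo/fixtures/samples --out demo/post --analysis-id demo
# -> 60 protein group(s), 1040 peptide(s), 60 track feature(s) written to demo/post
head -3 demo/post/demo.proteins.tsv
```

```
group_id  members                 representative          n_peptides  validated_psm_count  spectral_count_raw  nsaf           q_value
PG00001   sample01.genome04_g014  sample01.genome04_g014  35          47                   47                  0.02247814996  0
PG00002   sample01.genome04_g001  sample01.genome04_g001  34          40                   40                  0.0238927458   0
```

Each row is one validated, filtered protein group: its members, distinct
peptide count, validated PSM support, raw spectral count, NSAF (summing
to 1 over all 60 groups) and q-value. The matching
`demo.metaproteomics.gff` places each protein at its gene call's
coordinates on the assembly contig:

```
##gff-version 3
sample01.genome01.c001  metaproteomics  CDS  194  913  .  -  0  ID=sample01.genome01_g001;...;psm_count=...;spectral_count=...
```

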