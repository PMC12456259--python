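# Methods

This note documents the models, parameters and design choices behind
`metaprotdb`, and what the synthetic fixtures do and do not establish
about real data.

## Assembly similarity: FracMinHash sketches

A sketch of a sequence set is the subset of canonical k-mer hashes below
`2^64 / scaled`. Because a well-mixed hash makes this a uniform random
subsample of the k-mer space, `|A∩B| / |A∪B|` over two sketches is an
unbiased estimator of the exact k-mer Jaccard index, and
`|Q∩S| / |Q|` estimates containment of a query genome in a subject
assembly. Estimator error scales like `O(1/√m)` with `m` the smaller
sketch size; tests require ≤0.05 absolute error at `m ≥ 200`.

* **k = 31** (default): the conventional size for genome-scale nucleotide
  comparison — long enough that random collisions across unrelated
  genomes are negligible, short enough to tolerate fragmented
  assemblies. The 2-bit packing used for hashing bounds `k ≤ 31`.
* **scaled = 1000** (default): about one k-mer in a thousand retained,
  adequate for multi-megabase assemblies. Tests and the acceptance
  script use `scaled` of 50–100 because their synthetic assemblies are
  only tens of kilobases; with the production default those sketches
  would hold too few hashes to estimate anything. This is an instance of
  scaling the conditions to the data, not a change of method.
* **Hashing** packs each canonical k-mer (lexicographic minimum of the
  k-mer and its reverse complement) into a 64-bit integer and applies
  the splitmix64 finalizer, XOR-seeded from `hash_seed` (default 42).
  The hash is fixed and platform-independent, so sketches are
  reproducible; no compatibility with any external sketching tool's hash
  values is intended or needed — only estimator equivalence, which the
  tests check against exact k-mer enumeration. Windows containing
  non-ACGT characters are skipped.
* Sample–sample similarity uses Jaccard (symmetric); catalogue-genome
  matching uses containment (a genome can be fully contained in a much
  larger assembly while sharing little of the assembly's total content).
  Both choices are configurable.

## Sample hierarchy and budget partitioning

Agglomerative clustering on `d = 1 − similarity` with single, complete
or average linkage (default average). The implementation is an explicit
O(n³) agglomeration rather than a library call so that ties in the
minimum inter-cluster distance break deterministically on the
lexicographically smallest member id; sample counts are small enough
that the cubic cost is irrelevant. On tie-free inputs the merges agree
with scipy's linkage to floating-point accuracy (tested).

Partitioning walks the tree from the root: a subtree whose pooled
database estimate fits the budget is emitted whole; otherwise both
children are visited. A single sample over budget becomes an
overflow-flagged singleton with a warning — the traversal always
terminates with a partition of the samples into complete subtrees.
Consequences tested as invariants: groups are disjoint subtrees covering
all samples, every non-overflow group fits the budget, and raising the
budget never increases the group count.

**What counts against the budget:** only the sample and catalogue
(target) partitions. Host proteome, contaminants and decoys are constant
add-ons shared by every database; including them would make the
effective budget depend on fixed overhead rather than on the data. The
estimate is the exact byte size of the FASTA serialization (header +
wrapped sequence lines), so estimated and realized sizes agree exactly;
both are reported in the group report. "Fits" means `≤ budget` in bytes;
the default budget is 2^30 bytes (1 GiB).

## Database assembly

* Contig length filters are strict inequalities: >500 bp for metagenomic
  and >200 bp for metatranscriptomic contigs; gene calls on dropped
  contigs are dropped with them, and only proteins tracing to a
  surviving contig enter the database.
* Exact-duplicate protein sequences within one database collapse to the
  first-seen record (samples visited in sorted order, so the outcome is
  deterministic); origins are merged and a sidecar TSV maps each kept
  accession to the accessions folded into it. Deduplication is on by
  default and switchable — pooling related samples otherwise inflates
  the database with identical entries and distorts the size budget.
* Decoys are exact sequence reversals, one per target entry including
  host and contaminant standards, tagged with the accession prefix
  `DECOY_`. Reversal preserves amino-acid composition and peptide length
  structure, which is what the target-decoy estimator assumes; it is an
  involution, so decoy databases are self-checking. An input accession
  already containing the tag is rejected rather than silently
  disambiguated. Palindromic sequences produce self-identical decoys;
  they are logged and kept (vanishingly rare at protein length).
* Accession collisions between standards and sample records are resolved
  by prefixing the standard (`HOST_`/`CONT_`) and logging.

## Identification post-processing

* **q-values.** Entries are sorted by decreasing score, decoys before
  targets at equal score (the conservative tie order). The FDR at each
  threshold is `#decoys / #targets` among entries at or above it; the
  q-value is the running minimum from the bottom up, hence monotone.
  The estimator omits the +1 numerator correction by default, mirroring
  the common practice of the upstream tools this replaces; `(D+1)/T` is
  a configuration switch. An all-decoy input is an error.
* **PSM gate.** PSMs at q ≤ `psm_fdr` (default 0.01) are "validated".
  Decoy PSMs passing the score threshold are retained at this stage:
  protein-level FDR control needs decoy groups to compete against, and
  discarding them would leave the group-level estimate without a null.
* **Protein inference.** Validated PSMs aggregate by exact peptide
  sequence (modifications are carried as opaque strings and ignored;
  mass-based grouping is out of scope). Proteins with identical peptide
  sets merge; a protein whose set is a strict subset of another's is
  absorbed into a maximal superset group. The group score is the sum
  over distinct peptides of the best PSM score — additive in the
  evidence, cheap, and symmetric between targets and decoys. Decoy
  groups are formed identically from decoy-matched PSMs. Groups at
  q ≤ `protein_fdr` (default 0.01) are validated.
* **Filters** (in order, idempotent): (i) drop groups without validated
  PSMs; (ii) remove host/contaminant members, dropping groups left
  empty or whose peptides all came from removed members; (iii) remove
  proteins claimed by more than one surviving validated group (the
  protein-removal reading of the ambiguity rule), dropping emptied
  groups. Removed shared proteins are logged.
* **Uniqueness.** A peptide is unique when exactly one protein group
  contains a protein in which it occurs as a tryptic peptide (or as a
  plain substring, configurable). I/L can be equated (`equate_I_L`,
  default off) — documented because uniqueness flips on it. Peptides
  matching no database protein are orphans: logged, excluded from the
  track.
* **Spectral counting.** Raw count = validated PSMs whose peptide
  belongs to the group; NSAF divides by the representative protein's
  length and normalizes to sum 1 over surviving groups. Zero total
  counts yield NSAF 0 with a warning rather than an error.
* **Digestion** (used for uniqueness classification and simulation):
  cleavage after K/R not followed by P, up to 2 missed cleavages,
  peptide length 7–60 — delegated to pyteomics' cleavage routine and
  verified in tests against exhaustive cut enumeration.

## Evidence track

One GFF3 `CDS` feature (source `metaproteomics`) per surviving group
member that resolves, through its provenance triple, to a gene call;
coordinates and strand are copied from the gene call. Attributes carry
the accession, unique and ambiguous peptide lists, the summed PSM count
of the listed peptides, and NSAF — both raw and normalized counts are
emitted because consumers differ on which they want. The `unique`
variant (features with ≥1 unique peptide) is the uploadable track; `all`
keeps everything. Output is sorted by (seqid, start) and percent-encodes
reserved attribute characters; tests re-parse every track with an
independent GFF3 parser.

## Synthetic fixtures

The community generator emulates the *structure* of a paired multi-omics
study: a genome panel, a boolean presence matrix controlling
cross-sample protein overlap (protein-set Jaccard between samples equals
the presence-row Jaccard by construction), assemblies produced by
fragmenting genomes only at intergenic positions (every gene survives
intact, so provenance invariants are exact), ORF-like genes built by
reverse-translating random proteins with a fixed codon per amino acid
(ATG start, single stop, no introns or partials by default), and an
optional catalogue of planted plus novel genomes. One integer seed fixes
everything; identical spec + seed gives byte-identical files.

The PSM simulator plants a two-component normal score mixture: true
matches draw real tryptic peptides of the database and score
`N(μ_t = 25, σ = 3)`; false matches carry random peptides absent from
the target digest and score `N(μ_d = 16, σ)` — a 3σ separation. Half of
the false matches land on decoy entries and half on wrong targets, the
symmetry the target-decoy estimator relies on; the ground-truth table
records each PSM's planted correctness for calibration tests. Default
`identified_fraction = 0.3` reflects that only a minority of spectra in
a metaproteomics run yield a confident match.

**What passing tests show — and don't.** The fixtures validate the
estimators, the combinatorics (partitioning, grouping, filtering) and
the bookkeeping end to end. They do not model sequencing error, chimeric
assembly, abundance structure, homologous peptide sharing across
genomes, post-translational modifications or real spectral scoring — so
calibration results transfer to real data only to the extent that real
score distributions resemble a well-separated mixture and real databases
resemble the planted one. The headline identification counts of
published reanalyses depend on external raw data and search engines and
are out of reach of desk-scale fixtures; acceptance is therefore
property-based.

## Numerical and degenerate-input choices

* Jaccard of two empty sketches is 0 by convention (logged), as is the
  containment of an empty query.
* The empty PSM table yields empty reports and pragma-only tracks, not
  errors.
* Problem sizes in tests and the acceptance script (3 samples, ~5
  genomes of 35–60 kb, 25–40 genes each, 1500–2000 simulated PSMs,
  20 calibration seeds) are chosen so every stochastic check has enough
  mass for its tolerance while the full suite stays fast; they are the
  package's own test conditions, not claims about study scale.
* Exit codes of the CLI: 0 ok, 1 input error (click-reported), 2
  internal error.

## Known limitations

* Sample-level metadata grouping (as an alternative to sketch
  similarity) is supported only as a user-supplied grouping file; no
  metadata clustering algorithm is provided.
* Protein-level scores ignore modification state; two-step searches,
  rescoring and mass-grouped peptides are out of scope.
* The catalogue path takes catalogue proteins as given FASTA input;
  pan-genome construction is not performed.
* Realized database bytes equal the estimate only for the package's own
  FASTA writer (60-column wrap); foreign rewrites of the FASTA may
  differ without affecting record-level content.
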