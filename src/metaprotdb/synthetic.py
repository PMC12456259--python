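"""Synthetic multi-omics fixtures: a planted microbial community and
search-report simulation with controlled true/false score structure.

The community generator emulates the structure of a paired multi-omics
study: a panel of genomes, a boolean genome-by-sample presence matrix that
controls cross-sample protein overlap, per-sample assemblies (genome
fragments broken only at intergenic positions, so every gene survives
fragmentation intact), gene calls in GFF3 and predicted proteins whose
headers carry provenance back to their contig coordinates. A configurable
subset of the genome panel doubles as a reference catalogue with known
planted membership, standing in for a biome-specific genome catalogue.

The PSM simulator writes search-report tables with planted ground truth:
true matches draw real tryptic peptides of the database's sample proteins
and score around ``mu_true``; false matches pair never-seen random
peptides with either a decoy entry or a wrong target, scoring around
``mu_false``. The score gap (in units of sigma) is the lever that
calibration tests turn.

Everything is driven by one integer seed; identical spec + seed gives
byte-identical outputs. The generator deliberately omits sequencing
error, abundance structure and real spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .config import Config
from .formats_io import (
    FastaRecord,
    protein_description,
    write_fasta,
    write_gene_calls,
    write_psm_table,
)
from .models import (
    CATEGORY_CATALOGUE,
    CATEGORY_DECOY,
    CATEGORY_SAMPLE,
    METAGENOMIC,
    METATRANSCRIPTOMIC,
    CdsFeature,
    Contig,
    ProteinRecord,
    PsmRecord,
    SearchDatabase,
    psm_is_decoy,
)
from .postprocess import digest

logger = logging.getLogger(__name__)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# one codon per amino acid keeps reverse translation simple; the standard
# genetic code maps each of these back to its amino acid
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


@dataclass
class CommunitySpec:
    """Conditions of the synthetic study.

    ``presence`` (samples x genomes boolean) may be given explicitly;
    otherwise each genome is present in each sample with probability
    ``presence_prob`` (resampled until every sample has a genome).
    ``fragmentation_rate`` is the probability of a contig break at each
    intergenic gap. ``metat_fraction`` labels that fraction of contigs as
    metatranscriptomic.
    """

    n_samples: int = 3
    n_genomes: int = 5
    genome_length_bp: int = 60_000
    genes_per_genome: int = 40
    presence: np.ndarray | None = None
    presence_prob: float = 0.6
    fragmentation_rate: float = 0.3
    metat_fraction: float = 0.0
    n_catalogue_planted: int = 0
    n_catalogue_novel: int = 0
    protein_len_min: int = 80
    protein_len_max: int = 300
    intergenic_min: int = 60
    intergenic_max: int = 200
    seed: int = 0


@dataclass
class PsmSimSpec:
    """Conditions of the simulated search output.

    Scores are normal: true matches ~ N(mu_true, sigma), false matches
    ~ N(mu_false, sigma); ``mu_true - mu_false`` defaults to 3 sigma.
    ``identified_fraction`` reflects that only a minority of spectra in a
    real metaproteomics run yield a PSM. Of the false matches,
    ``decoy_fraction_of_false`` are assigned to decoy entries (the lever
    giving target-decoy estimation its signal); the rest go to wrong
    targets.
    """

    n_spectra: int = 2000
    identified_fraction: float = 0.3
    true_fraction: float = 0.8
    mu_true: float = 25.0
    mu_false: float = 16.0
    sigma: float = 3.0
    decoy_fraction_of_false: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_true <= self.mu_false:
            raise ValueError("mu_true must exceed mu_false")
        for name in ("identified_fraction", "true_fraction", "decoy_fraction_of_false"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Gene:
    gene_id: str
    start: int  # 1-based inclusive on the genome
    end: int
    strand: str
    protein: str


@dataclass
class Genome:
    genome_id: str
    sequence: str
    genes: list[Gene]
    gaps: list[int]  # 0-based breakpoints lying between genes


@dataclass
class SampleData:
    sample_id: str
    contigs: list[Contig]
    cds: list[CdsFeature]
    proteins: list[ProteinRecord]


@dataclass
class Community:
    spec: CommunitySpec
    genomes: list[Genome]
    samples: dict[str, SampleData]
    presence: np.ndarray
    catalogue_genomes: list[FastaRecord]
    catalogue_proteins: list[ProteinRecord]
    planted_catalogue_ids: set[str]
    novel_catalogue_ids: set[str]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _random_protein(rng: np.random.Generator, n: int) -> str:
    body = "".join(np.array(list(_AA20))[rng.integers(0, 20, size=n - 1)])
    return "M" + body


def _gene_dna(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein) + _STOP


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _make_genome(rng: np.random.Generator, spec: CommunitySpec, genome_id: str) -> Genome:
    genes: list[Gene] = []
    parts: list[str] = []
    gaps: list[int] = []
    pos = 0  # 0-based running length
    for j in range(spec.genes_per_genome):
        gap = int(rng.integers(spec.intergenic_min, spec.intergenic_max + 1))
        parts.append(_random_dna(rng, gap))
        pos += gap
        plen = int(rng.integers(spec.protein_len_min, spec.protein_len_max + 1))
        protein = _random_protein(rng, plen)
        dna = _gene_dna(protein)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = dna if strand == "+" else _revcomp(dna)
        genes.append(
            Gene(
                gene_id=f"{genome_id}_g{j + 1:03d}",
                start=pos + 1,
                end=pos + len(dna),
                strand=strand,
                protein=protein,
            )
        )
        parts.append(placed)
        pos += len(dna)
        gaps.append(pos)  # a breakpoint candidate right after this gene
    tail = int(rng.integers(spec.intergenic_min, spec.intergenic_max + 1))
    parts.append(_random_dna(rng, tail))
    pos += tail
    if pos > spec.genome_length_bp:
        raise ValueError(
            f"infeasible spec: {spec.genes_per_genome} genes need {pos} bp "
            f"> genome_length_bp={spec.genome_length_bp}"
        )
    parts.append(_random_dna(rng, spec.genome_length_bp - pos))
    sequence = "".join(parts)
    return Genome(genome_id=genome_id, sequence=sequence, genes=genes, gaps=gaps[:-1])


def _fragment(
    rng: np.random.Generator,
    genome: Genome,
    sample_id: str,
    rate: float,
    metat_fraction: float,
):
    """Cut the genome at a random subset of intergenic gaps."""
    cuts = [g for g in genome.gaps if rng.random() < rate]
    bounds = [0] + cuts + [len(genome.sequence)]
    contigs: list[Contig] = []
    cds: list[CdsFeature] = []
    proteins: list[ProteinRecord] = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        contig_id = f"{sample_id}.{genome.genome_id}.c{i + 1:03d}"
        atype = (
            METATRANSCRIPTOMIC if rng.random() < metat_fraction else METAGENOMIC
        )
        contigs.append(
            Contig(
                contig_id=contig_id,
                sample_id=sample_id,
                assembly_type=atype,
                sequence=genome.sequence[lo:hi],
            )
        )
        for gene in genome.genes:
            if gene.start > lo and gene.end <= hi:
                protein_id = f"{sample_id}.{gene.gene_id}"
                start = gene.start - lo
                end = gene.end - lo
                cds.append(
                    CdsFeature(
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        strand=gene.strand,
                        protein_id=protein_id,
                    )
                )
                proteins.append(
                    ProteinRecord(
                        accession=protein_id,
                        sequence=gene.protein,
                        category=CATEGORY_SAMPLE,
                        origins=frozenset({(sample_id, contig_id, protein_id)}),
                    )
                )
    return contigs, cds, proteins


def gen_community(spec: CommunitySpec) -> Community:
    """Generate the full synthetic study from one seed."""
    rng = np.random.default_rng(spec.seed)
    genomes = [
        _make_genome(rng, spec, f"genome{g + 1:02d}") for g in range(spec.n_genomes)
    ]

    if spec.presence is not None:
        presence = np.asarray(spec.presence, dtype=bool)
        if presence.shape != (spec.n_samples, spec.n_genomes):
            raise ValueError(
                f"presence matrix shape {presence.shape} != "
                f"({spec.n_samples}, {spec.n_genomes})"
            )
        if not presence.any(axis=1).all():
            raise ValueError("every sample needs at least one genome")
    else:
        while True:
            presence = rng.random((spec.n_samples, spec.n_genomes)) < spec.presence_prob
            if presence.any(axis=1).all():
                break

    samples: dict[str, SampleData] = {}
    for s in range(spec.n_samples):
        sample_id = f"sample{s + 1:02d}"
        contigs: list[Contig] = []
        cds: list[CdsFeature] = []
        proteins: list[ProteinRecord] = []
        for g, genome in enumerate(genomes):
            if not presence[s, g]:
                continue
            c, f, p = _fragment(
                rng, genome, sample_id, spec.fragmentation_rate, spec.metat_fraction
            )
            contigs.extend(c)
            cds.extend(f)
            proteins.extend(p)
        samples[sample_id] = SampleData(sample_id, contigs, cds, proteins)

    # catalogue: planted genomes are drawn from those present somewhere;
    # novel genomes are freshly generated and absent from every sample
    present_ids = [
        genomes[g].genome_id for g in range(spec.n_genomes) if presence[:, g].any()
    ]
    if spec.n_catalogue_planted > len(present_ids):
        raise ValueError("not enough present genomes for the requested catalogue")
    planted = set(present_ids[: spec.n_catalogue_planted])
    novel_genomes = [
        _make_genome(rng, spec, f"novel{g + 1:02d}")
        for g in range(spec.n_catalogue_novel)
    ]
    catalogue_genomes: list[FastaRecord] = []
    catalogue_proteins: list[ProteinRecord] = []
    for genome in genomes:
        if genome.genome_id not in planted:
            continue
        catalogue_genomes.append(
            FastaRecord(genome.genome_id, "category=catalogue", genome.sequence)
        )
        for gene in genome.genes:
            catalogue_proteins.append(
                ProteinRecord(
                    accession=f"cat.{gene.gene_id}",
                    sequence=gene.protein,
                    category=CATEGORY_CATALOGUE,
                )
            )
    for genome in novel_genomes:
        catalogue_genomes.append(
            FastaRecord(genome.genome_id, "category=catalogue", genome.sequence)
        )
        for gene in genome.genes:
            catalogue_proteins.append(
                ProteinRecord(
                    accession=f"cat.{gene.gene_id}",
                    sequence=gene.protein,
                    category=CATEGORY_CATALOGUE,
                )
            )
    return Community(
        spec=spec,
        genomes=genomes,
        samples=samples,
        presence=presence,
        catalogue_genomes=catalogue_genomes,
        catalogue_proteins=catalogue_proteins,
        planted_catalogue_ids=planted,
        novel_catalogue_ids={g.genome_id for g in novel_genomes},
    )


def gen_standards(seed: int = 0, n_host: int = 5, n_contaminant: int = 3):
    """Small random host and contaminant protein stand-ins.

    Synthetic placeholders shaped like the real standards (a host
    proteome and a lab-contaminant collection) for tests and examples;
    production runs supply the real FASTA files instead.
    """
    rng = np.random.default_rng(seed + 7_000_003)
    host = [
        ProteinRecord(
            accession=f"HUMAN{i + 1:03d}",
            sequence=_random_protein(rng, int(rng.integers(100, 400))),
            category="host",
        )
        for i in range(n_host)
    ]
    cont = [
        ProteinRecord(
            accession=f"CONTAM{i + 1:03d}",
            sequence=_random_protein(rng, int(rng.integers(100, 300))),
            category="contaminant",
        )
        for i in range(n_contaminant)
    ]
    return host, cont


# ---------------------------------------------------------------------------
# PSM simulation


def gen_psm_table(
    db: SearchDatabase,
    spec: PsmSimSpec,
    config: Config | None = None,
):
    """Simulate a search report against ``db``.

    Returns ``(psms, truth)`` where truth maps spectrum_id -> bool
    (planted correctness). True PSMs draw uniformly from the tryptic
    peptides of the database's sample/catalogue targets and match every
    target containing the peptide. False PSMs carry a random peptide
    absent from the target digest, attached to one wrong target or one
    decoy accession.
    """
    cfg = config or Config()
    rng = np.random.default_rng(spec.seed)

    target_recs = [
        r for r in db.records if r.category in (CATEGORY_SAMPLE, CATEGORY_CATALOGUE)
    ]
    decoy_accs = sorted(r.accession for r in db.records if r.category == CATEGORY_DECOY)
    pep_to_accs: dict[str, set[str]] = {}
    for rec in target_recs:
        for pep in digest(rec.sequence, cfg):
            pep_to_accs.setdefault(pep, set()).add(rec.accession)
    peptides = sorted(pep_to_accs)
    if not peptides:
        raise ValueError("database yields no digestible peptides")
    target_accs = sorted(r.accession for r in target_recs)

    def random_false_peptide() -> str:
        while True:
            n = int(rng.integers(cfg.peptide_length_min, 21))
            pep = "".join(np.array(list(_AA20))[rng.integers(0, 20, size=n)])
            if pep not in pep_to_accs:
                return pep

    psms: list[PsmRecord] = []
    truth: dict[str, bool] = {}
    n_ident = int(round(spec.n_spectra * spec.identified_fraction))
    for sample_id in sorted(db.group.sample_ids):
        raw_file = f"{sample_id}.raw"
        for i in range(n_ident):
            spectrum_id = f"{sample_id}.scan{i + 1:06d}"
            if rng.random() < spec.true_fraction:
                pep = peptides[int(rng.integers(len(peptides)))]
                accs = frozenset(pep_to_accs[pep])
                score = float(rng.normal(spec.mu_true, spec.sigma))
                is_true = True
            else:
                pep = random_false_peptide()
                score = float(rng.normal(spec.mu_false, spec.sigma))
                if decoy_accs and rng.random() < spec.decoy_fraction_of_false:
                    accs = frozenset({decoy_accs[int(rng.integers(len(decoy_accs)))]})
                else:
                    accs = frozenset({target_accs[int(rng.integers(len(target_accs)))]})
                is_true = False
            psms.append(
                PsmRecord(
                    spectrum_id=spectrum_id,
                    raw_file=raw_file,
                    sample_id=sample_id,
                    peptide_sequence=pep,
                    score=score,
                    matched_accessions=accs,
                    is_decoy=psm_is_decoy(accs, cfg.decoy_tag),
                )
            )
            truth[spectrum_id] = is_true
    return psms, truth


# ---------------------------------------------------------------------------
# materialization


def write_community(community: Community, outdir: str | Path) -> dict:
    """Write the community as the file layout the CLI consumes.

    ``<outdir>/samples/<sample>/{contigs.fasta,genes.gff3,proteins.fasta}``
    plus ``catalogue/{genomes,proteins}.fasta`` and
    ``standards/{host,contaminants}.fasta``. Returns the path map.
    """
    outdir = Path(outdir)
    paths: dict[str, dict | Path] = {"samples": {}}
    for sample_id, data in sorted(community.samples.items()):
        sdir = outdir / "samples" / sample_id
        sdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [
                FastaRecord(c.contig_id, f"assembly_type={c.assembly_type}", c.sequence)
                for c in data.contigs
            ],
            sdir / "contigs.fasta",
        )
        write_gene_calls(data.cds, sdir / "genes.gff3")
        write_fasta(
            [
                FastaRecord(p.accession, protein_description(p), p.sequence)
                for p in data.proteins
            ],
            sdir / "proteins.fasta",
        )
        paths["samples"][sample_id] = sdir
    if community.catalogue_genomes:
        cdir = outdir / "catalogue"
        cdir.mkdir(parents=True, exist_ok=True)
        write_fasta(community.catalogue_genomes, cdir / "genomes.fasta")
        write_fasta(
            [
                FastaRecord(p.accession, protein_description(p), p.sequence)
                for p in community.catalogue_proteins
            ],
            cdir / "proteins.fasta",
        )
        paths["catalogue"] = cdir
    host, cont = gen_standards(seed=community.spec.seed)
    stddir = outdir / "standards"
    stddir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [FastaRecord(r.accession, "category=host", r.sequence) for r in host],
        stddir / "host.fasta",
    )
    write_fasta(
        [FastaRecord(r.accession, "category=contaminant", r.sequence) for r in cont],
        stddir / "contaminants.fasta",
    )
    paths["standards"] = stddir
    return paths


def write_truth_table(truth: dict, path: str | Path) -> None:
    lines = ["spectrum_id\tis_true"]
    for sid in sorted(truth):
        lines.append(f"{sid}\t{str(truth[sid]).lower()}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_psms(psms, path: str | Path) -> None:
    write_psm_table(psms, path)
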