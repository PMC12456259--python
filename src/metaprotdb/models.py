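"""Core domain types shared across the workflow.

The sequence layer (:class:`Contig`, :class:`CdsFeature`,
:class:`ProteinRecord`) links assemblies, gene calls and predicted
proteins; the grouping layer (:class:`SampleGroup`, :class:`SearchDatabase`)
carries database provenance and size accounting; the identification layer
(:class:`PsmRecord`, :class:`PeptideEvidence`, :class:`ProteinGroup`)
carries scores, q-values, uniqueness and spectral counts; and
:class:`EvidenceFeature` is one row of the metaproteomics GFF3 track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

METAGENOMIC = "metagenomic"
METATRANSCRIPTOMIC = "metatranscriptomic"

#: protein record categories
CATEGORY_SAMPLE = "sample"
CATEGORY_CATALOGUE = "catalogue"
CATEGORY_HOST = "host"
CATEGORY_CONTAMINANT = "contaminant"
CATEGORY_DECOY = "decoy"

#: categories counted against the database size budget
TARGET_BUDGET_CATEGORIES = (CATEGORY_SAMPLE, CATEGORY_CATALOGUE)


@dataclass
class Contig:
    """An assembled sequence fragment from one sample."""

    contig_id: str
    sample_id: str
    assembly_type: str  # METAGENOMIC or METATRANSCRIPTOMIC
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id}: empty sequence")
        if any(c.isspace() for c in self.contig_id):
            raise ValueError(f"contig id {self.contig_id!r} contains whitespace")
        if self.assembly_type not in (METAGENOMIC, METATRANSCRIPTOMIC):
            raise ValueError(f"unknown assembly_type {self.assembly_type!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CdsFeature:
    """A protein-coding gene call on a contig (1-based, inclusive)."""

    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str
    caller: str = "prodigal-like"
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"CDS {self.protein_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"CDS {self.protein_id}: bad strand {self.strand!r}")
        if not self.partial and (self.end - self.start + 1) % 3 != 0:
            raise ValueError(
                f"CDS {self.protein_id}: length not divisible by 3 and not partial"
            )


@dataclass
class ProteinRecord:
    """One entry of a protein search database.

    ``origins`` holds (sample_id, contig_id, protein_id) provenance
    triples; empty for host/contaminant standards. ``merged_from`` lists
    accessions of exact-duplicate records collapsed into this one.
    """

    accession: str
    sequence: str
    category: str = CATEGORY_SAMPLE
    origins: frozenset = frozenset()
    merged_from: tuple = ()
    decoy_of: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession}: empty sequence")
        self.origins = frozenset(self.origins)


@dataclass
class SampleGroup:
    """A set of samples whose pooled proteins form one search database."""

    group_id: str
    sample_ids: frozenset
    estimated_db_bytes: int = 0
    overflow_flag: bool = False

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ValueError(f"group {self.group_id}: empty sample set")
        self.sample_ids = frozenset(self.sample_ids)


@dataclass
class SearchDatabase:
    """An assembled target+standards+decoy protein set with provenance."""

    db_id: str
    group: SampleGroup
    records: list  # ordered ProteinRecords, targets then decoys
    realized_bytes: int = 0

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.category] = out.get(rec.category, 0) + 1
        return out

    def targets(self) -> list:
        return [r for r in self.records if r.category != CATEGORY_DECOY]

    def decoys(self) -> list:
        return [r for r in self.records if r.category == CATEGORY_DECOY]


@dataclass
class PsmRecord:
    """One peptide-spectrum match from a search report (higher score = better)."""

    spectrum_id: str
    raw_file: str
    sample_id: str
    peptide_sequence: str
    score: float
    matched_accessions: frozenset
    is_decoy: bool = False

    def __post_init__(self) -> None:
        self.matched_accessions = frozenset(self.matched_accessions)
        if not self.matched_accessions:
            raise ValueError(f"PSM {self.spectrum_id}: no matched accessions")


def psm_is_decoy(accessions, decoy_tag: str) -> bool:
    """A PSM is decoy only if *all* matched accessions carry the decoy tag."""
    return all(a.startswith(decoy_tag) for a in accessions)


@dataclass
class PeptideEvidence:
    """Aggregated evidence for one peptide sequence."""

    sequence: str
    psm_count: int
    accessions: frozenset  # target accessions containing the peptide
    uniqueness: str  # "unique" or "ambiguous"

    def __post_init__(self) -> None:
        self.accessions = frozenset(self.accessions)


@dataclass
class ProteinGroup:
    """Proteins indistinguishable (or subsumed) by their matched peptides."""

    group_id: str
    members: frozenset
    representative: str
    peptides: frozenset
    member_peptides: dict = field(default_factory=dict)
    score: float = 0.0
    q_value: float = 1.0
    validated: bool = False
    is_decoy: bool = False
    validated_psm_count: int = 0
    spectral_count_raw: int = 0
    nsaf: float = 0.0

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        self.peptides = frozenset(self.peptides)
        if not self.members:
            raise ValueError(f"protein group {self.group_id}: no members")


@dataclass
class EvidenceFeature:
    """One feature of the metaproteomics GFF3 evidence track."""

    contig_id: str
    start: int
    end: int
    strand: str
    accession: str
    unique_peptides: tuple = ()
    ambiguous_peptides: tuple = ()
    psm_count: int = 0
    spectral_count: float = 0.0
    pride_dataset: str = ""
    source: str = "metaproteomics"
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"feature {self.accession}: bad interval")
        if not (self.unique_peptides or self.ambiguous_peptides):
            raise ValueError(f"feature {self.accession}: no peptide evidence")
        if self.psm_count < 1:
            raise ValueError(f"feature {self.accession}: psm_count must be >= 1")
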