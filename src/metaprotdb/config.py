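"""Shared run configuration.

One flat configuration object travels through every stage: sketching
parameters, database size budget, digestion rules and identification
thresholds. Defaults follow common practice for shotgun metaproteomics
against assembly-derived databases (trypsin, 7-60 aa peptides, two missed
cleavages, 1% protein-level FDR, reversed decoys, 1 GiB database budget).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Config:
    """Workflow-wide parameters.

    Attributes
    ----------
    k :
        k-mer size for assembly sketching. 31 is the conventional choice
        for genome-scale nucleotide comparison.
    scaled :
        FracMinHash scale factor: a sketch retains hashes below
        ``2**64 // scaled``, i.e. roughly one k-mer in ``scaled``.
    hash_seed :
        Seed mixed into the k-mer hash so sketches are reproducible.
    budget_bytes :
        Maximum size of the target (sample + catalogue) partition of one
        search database FASTA. Default 1 GiB.
    linkage :
        Agglomeration rule for the sample dendrogram: ``single``,
        ``complete`` or ``average``.
    containment_threshold :
        Minimum containment of a catalogue genome in any sample assembly
        for it to be pulled into the search databases.
    use_containment_for_samples :
        If true, sample-sample similarity uses containment instead of
        Jaccard (Jaccard is the default for symmetric comparison).
    """

    # sketching / partitioning
    k: int = 31
    scaled: int = 1000
    hash_seed: int = 42
    budget_bytes: int = 2**30
    linkage: str = "average"
    containment_threshold: float = 0.5
    use_containment_for_samples: bool = False
    per_group_catalogue: bool = False

    # contig filters (assembly-type specific, bp, strict >)
    contig_min_metag: int = 500
    contig_min_metat: int = 200

    # digestion
    enzyme: str = "trypsin"
    max_missed_cleavages: int = 2
    peptide_length_min: int = 7
    peptide_length_max: int = 60

    # identification
    protein_fdr: float = 0.01
    psm_fdr: float = 0.01
    decoy_tag: str = "DECOY_"
    fdr_plus_one: bool = False
    equate_I_L: bool = False
    peptide_match_mode: str = "tryptic"  # or "substring"

    # database assembly
    dedup_sequences: bool = True
    fasta_line_width: int = 60

    # provenance carried into the evidence track
    pride_dataset: str = ""

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > 31:
            raise ValueError("k must be in [1, 31] (2-bit packed hashing)")
        if self.scaled < 1:
            raise ValueError("scaled must be >= 1")
        if self.linkage not in ("single", "complete", "average"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if not 0 < self.peptide_length_min < self.peptide_length_max:
            raise ValueError("need 0 < peptide_length_min < peptide_length_max")
        if not 0 < self.protein_fdr <= 1:
            raise ValueError("protein_fdr must be in (0, 1]")
        if self.peptide_match_mode not in ("tryptic", "substring"):
            raise ValueError(f"unknown peptide_match_mode {self.peptide_match_mode!r}")
        if not self.decoy_tag:
            raise ValueError("decoy_tag must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
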