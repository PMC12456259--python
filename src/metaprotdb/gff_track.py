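"""The metaproteomics evidence track: one GFF3 CDS feature per expressed
protein, placed at its gene call's coordinates on the assembly contig and
annotated with peptide evidence (unique and ambiguous peptide lists), PSM
counts and NSAF spectral counts, plus a link to the reanalysed proteomics
dataset when one exists.

Two variants are emitted: ``unique`` keeps only features supported by at
least one unique peptide (the uploadable track), ``all`` keeps everything.
"""

from __future__ import annotations

import logging

from .formats_io import Gff3Record, write_gff3
from .models import (
    CATEGORY_CATALOGUE,
    CATEGORY_SAMPLE,
    EvidenceFeature,
)

logger = logging.getLogger(__name__)


def build_cds_index(cds_by_sample):
    """Index gene calls as (sample_id, contig_id, protein_id) -> CdsFeature."""
    index = {}
    for sample_id, features in cds_by_sample.items():
        for f in features:
            index[(sample_id, f.contig_id, f.protein_id)] = f
    return index


def map_groups_to_contigs(
    groups,
    peptide_evidence,
    database_records,
    cds_index,
    pride_dataset: str = "",
) -> list[EvidenceFeature]:
    """One evidence feature per group member with resolvable coordinates.

    Coordinates and strand are copied from the member's gene call, found
    through the protein record's provenance triples. Host and contaminant
    members have no provenance and are silently unresolvable; a sample
    member whose gene call is missing from the index is skipped with a
    warning. Each feature's psm_count is the sum of the PSM counts of the
    peptides listed on it, so the track reconciles with the peptide report.
    """
    by_acc = {r.accession: r for r in database_records}
    pep_by_seq = {p.sequence: p for p in peptide_evidence}
    features: list[EvidenceFeature] = []
    for g in groups:
        for acc in sorted(g.members):
            rec = by_acc.get(acc)
            if rec is None or rec.category not in (CATEGORY_SAMPLE, CATEGORY_CATALOGUE):
                continue
            cds = None
            for origin in sorted(rec.origins):
                cds = cds_index.get(tuple(origin))
                if cds is not None:
                    break
            if cds is None:
                logger.warning(
                    "no gene call resolves accession %s; feature skipped", acc
                )
                continue
            member_peps = sorted(
                pep
                for pep in g.member_peptides.get(acc, g.peptides)
                if pep in pep_by_seq
            )
            unique = tuple(
                p for p in member_peps if pep_by_seq[p].uniqueness == "unique"
            )
            ambiguous = tuple(
                p for p in member_peps if pep_by_seq[p].uniqueness == "ambiguous"
            )
            if not (unique or ambiguous):
                continue
            psm_count = sum(pep_by_seq[p].psm_count for p in unique + ambiguous)
            features.append(
                EvidenceFeature(
                    contig_id=cds.contig_id,
                    start=cds.start,
                    end=cds.end,
                    strand=cds.strand,
                    accession=acc,
                    unique_peptides=unique,
                    ambiguous_peptides=ambiguous,
                    psm_count=psm_count,
                    spectral_count=g.nsaf,
                    pride_dataset=pride_dataset,
                )
            )
    return features


def _to_gff3(f: EvidenceFeature) -> Gff3Record:
    attrs = {
        "ID": f.accession,
        "protein": f.accession,
        "unique_peptides": ",".join(f.unique_peptides),
        "ambiguous_peptides": ",".join(f.ambiguous_peptides),
        "psm_count": str(f.psm_count),
        "spectral_count": f"{f.spectral_count:.10g}",
    }
    if f.pride_dataset:
        attrs["pride_dataset"] = f.pride_dataset
    return Gff3Record(
        seqid=f.contig_id,
        source=f.source,
        type=f.feature_type,
        start=f.start,
        end=f.end,
        strand=f.strand,
        phase="0",
        attributes=attrs,
    )


def emit_track(features, path, variant: str = "all") -> list[EvidenceFeature]:
    """Write the evidence track, sorted by (seqid, start).

    ``variant="unique"`` keeps only features with at least one unique
    peptide; ``variant="all"`` writes everything. Returns the features
    written.
    """
    if variant not in ("all", "unique"):
        raise ValueError(f"unknown track variant {variant!r}")
    selected = [
        f for f in features if variant == "all" or len(f.unique_peptides) > 0
    ]
    selected.sort(key=lambda f: (f.contig_id, f.start, f.end, f.accession))
    write_gff3([_to_gff3(f) for f in selected], path)
    return selected
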