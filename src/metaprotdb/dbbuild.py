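"""Search-database assembly: contig filtering, protein aggregation,
standards concatenation, reversed decoys and size accounting.

A search database is built per sample group as: length-filtered sample
proteins (pooled over member samples, exact duplicates collapsed) +
optional catalogue proteins + host proteome + contaminant standards,
followed by one reversed-sequence decoy per target entry. Only the sample
and catalogue partitions count against the size budget; host, contaminant
and decoy entries are constant add-ons shared by every database.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .formats_io import (
    FastaRecord,
    protein_description,
    read_fasta,
    write_fasta,
)
from .models import (
    CATEGORY_CATALOGUE,
    CATEGORY_CONTAMINANT,
    CATEGORY_DECOY,
    CATEGORY_HOST,
    METAGENOMIC,
    METATRANSCRIPTOMIC,
    ProteinRecord,
    SampleGroup,
    SearchDatabase,
)

logger = logging.getLogger(__name__)


def filter_contigs(contigs, cds_features=None, min_metag: int = 500, min_metat: int = 200):
    """Drop short contigs (strict >500 bp metagenomic, >200 bp
    metatranscriptomic by default); gene calls on dropped contigs go too.

    Returns the kept contigs, or ``(contigs, cds_features)`` when gene
    calls are supplied.
    """
    thresholds = {METAGENOMIC: min_metag, METATRANSCRIPTOMIC: min_metat}
    kept = [c for c in contigs if len(c) > thresholds[c.assembly_type]]
    if cds_features is None:
        return kept
    kept_ids = {(c.sample_id, c.contig_id) for c in kept}
    kept_contig_ids = {c.contig_id for c in kept}
    kept_cds = [f for f in cds_features if f.contig_id in kept_contig_ids]
    dropped = len(cds_features) - len(kept_cds)
    if dropped:
        logger.info("filter_contigs: dropped %d gene calls on short contigs", dropped)
    return kept, kept_cds


def aggregate_group_proteins(
    group: SampleGroup,
    per_sample_records,
    catalogue_records=(),
    dedup: bool = True,
) -> list[ProteinRecord]:
    """Pool member samples' proteins (plus catalogue entries) into one set.

    Samples are visited in sorted order, preserving each sample's record
    order, so output order is deterministic. With ``dedup`` (default),
    exact-duplicate sequences collapse to the first-seen record; origins
    are merged and absorbed accessions recorded in ``merged_from``.
    """
    unknown = [s for s in group.sample_ids if s not in per_sample_records]
    if unknown:
        raise ValueError(f"group {group.group_id}: unknown sample(s) {sorted(unknown)}")
    stream: list[ProteinRecord] = []
    for sample in sorted(group.sample_ids):
        stream.extend(per_sample_records[sample])
    stream.extend(catalogue_records)

    if not dedup:
        return list(stream)
    by_seq: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in stream:
        if rec.sequence in by_seq:
            kept = by_seq[rec.sequence]
            by_seq[rec.sequence] = ProteinRecord(
                accession=kept.accession,
                sequence=kept.sequence,
                category=kept.category,
                origins=kept.origins | rec.origins,
                merged_from=kept.merged_from + (rec.accession,) + rec.merged_from,
                description=kept.description,
            )
        else:
            by_seq[rec.sequence] = rec
            order.append(rec.sequence)
    return [by_seq[s] for s in order]


def add_standards(records, host_records=(), contaminant_records=()) -> list[ProteinRecord]:
    """Append host and contaminant standards with category tags.

    An accession collision between a standard and an existing record is
    resolved by prefixing the standard (``HOST_`` / ``CONT_``) and logged.
    """
    out = list(records)
    taken = {r.accession for r in out}
    for recs, category, prefix in (
        (host_records, CATEGORY_HOST, "HOST_"),
        (contaminant_records, CATEGORY_CONTAMINANT, "CONT_"),
    ):
        for rec in recs:
            accession = rec.accession
            if accession in taken:
                renamed = prefix + accession
                logger.warning(
                    "standard accession %s collides with an existing record; "
                    "renamed to %s",
                    accession,
                    renamed,
                )
                accession = renamed
            taken.add(accession)
            out.append(
                ProteinRecord(
                    accession=accession,
                    sequence=rec.sequence,
                    category=category,
                    origins=frozenset(),
                )
            )
    return out


def make_decoys(records, decoy_tag: str = "DECOY_") -> list[ProteinRecord]:
    """Append one reversed-sequence decoy per record (targets first).

    Every entry — sample, catalogue, host and contaminant alike — gets a
    decoy whose sequence is the exact reversal and whose accession is the
    decoy tag prefixed to the original. Reversal is an involution and
    preserves amino-acid composition, which the target-decoy estimator
    relies on. Palindromic sequences yield self-identical decoys (logged).
    """
    offenders = [r.accession for r in records if decoy_tag in r.accession]
    if offenders:
        raise ValueError(
            f"decoy tag {decoy_tag!r} already present in accession(s) "
            f"{offenders[:5]} — would make labels ambiguous"
        )
    decoys = []
    for rec in records:
        rev = rec.sequence[::-1]
        if rev == rec.sequence:
            logger.info(
                "decoy of %s is self-identical (palindromic sequence)", rec.accession
            )
        decoys.append(
            ProteinRecord(
                accession=decoy_tag + rec.accession,
                sequence=rev,
                category=CATEGORY_DECOY,
                origins=frozenset(),
                decoy_of=rec.accession,
            )
        )
    return list(records) + decoys


def estimate_fasta_bytes(records, line_width: int = 60) -> int:
    """Exact byte size of the FASTA serialization of ``records``.

    Accounts for ``>``, accession, one space plus the provenance
    description when present, newline, and sequence lines wrapped at
    ``line_width``. Matches :func:`write_search_db` byte for byte, so the
    partitioner's budget check is an exact accounting, not a heuristic.
    """
    total = 0
    for rec in records:
        desc = protein_description(rec) if isinstance(rec, ProteinRecord) else ""
        header = 1 + len(rec.accession) + (1 + len(desc) if desc else 0) + 1
        n = len(rec.sequence)
        n_lines = (n + line_width - 1) // line_width if n else 0
        total += header + n + n_lines
    return total


def build_search_db(
    db_id: str,
    group: SampleGroup,
    per_sample_records,
    catalogue_records=(),
    host_records=(),
    contaminant_records=(),
    decoy_tag: str = "DECOY_",
    dedup: bool = True,
) -> SearchDatabase:
    """Assemble the full database for one group: targets then decoys."""
    targets = aggregate_group_proteins(
        group, per_sample_records, catalogue_records, dedup=dedup
    )
    targets = add_standards(targets, host_records, contaminant_records)
    records = make_decoys(targets, decoy_tag=decoy_tag)
    accs = [r.accession for r in records]
    if len(set(accs)) != len(accs):
        raise ValueError(f"db {db_id}: duplicate accessions after assembly")
    return SearchDatabase(db_id=db_id, group=group, records=records)


def write_search_db(db: SearchDatabase, path: str | Path, line_width: int = 60) -> int:
    """Write the database FASTA; returns and records the on-disk size.

    A sidecar ``<path>.dedup.tsv`` maps each kept accession to the
    exact-duplicate accessions collapsed into it, preserving provenance.
    """
    fasta = [
        FastaRecord(r.accession, protein_description(r), r.sequence)
        for r in db.records
    ]
    realized = write_fasta(fasta, path, width=line_width)
    db.realized_bytes = realized

    sidecar = Path(str(path) + ".dedup.tsv")
    lines = ["accession\tmerged_accessions"]
    for rec in db.records:
        if rec.merged_from:
            lines.append(f"{rec.accession}\t{';'.join(rec.merged_from)}")
    sidecar.write_text("\n".join(lines) + "\n")
    return realized


def read_search_db(path: str | Path) -> list[ProteinRecord]:
    """Rehydrate ProteinRecords (categories, provenance) from a DB FASTA."""
    from .formats_io import protein_from_fasta

    return [protein_from_fasta(rec) for rec in read_fasta(path)]
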