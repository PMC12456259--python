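"""Readers and writers for FASTA, GFF3 and the PSM/report TSV dialects.

FASTA goes through Biopython; GFF3 is read through gffutils and written
directly (nine tab-separated columns, attribute values percent-encoded);
tables go through pandas. Protein provenance travels in FASTA descriptions
as ``key=value`` pairs (``sample= contig= protein= start= end= strand=
category=``) so that protein-to-contig mapping survives serialization.

Coordinates are 1-based inclusive everywhere, the GFF3 convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CATEGORY_SAMPLE,
    CdsFeature,
    ProteinRecord,
    PsmRecord,
    psm_is_decoy,
)

logger = logging.getLogger(__name__)

PSM_COLUMNS = [
    "spectrum_id",
    "raw_file",
    "sample_id",
    "peptide_sequence",
    "score",
    "protein_accessions",
]


@dataclass
class FastaRecord:
    """A raw FASTA entry: id = header token before the first whitespace."""

    id: str
    description: str
    sequence: str


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA preserving order; multi-line sequences are concatenated.

    An empty file yields an empty list; sequence data before any header is
    a format error (raised by the underlying parser).
    """
    out = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            out.append(FastaRecord(rec.id, desc, str(rec.seq)))
    return out


def write_fasta(records, path: str | Path, width: int = 60) -> int:
    """Write (id, description, sequence) records; returns bytes written."""
    seqs = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        seqs.append(sr)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)
    return Path(path).stat().st_size


def protein_description(rec: ProteinRecord) -> str:
    """Serialize category and (first) provenance triple as key=value pairs."""
    parts = [f"category={rec.category}"]
    if rec.origins:
        sample, contig, protein = sorted(rec.origins)[0]
        parts += [f"sample={sample}", f"contig={contig}", f"protein={protein}"]
    if rec.decoy_of:
        parts.append(f"decoy_of={rec.decoy_of}")
    return " ".join(parts)


def parse_description(description: str) -> dict:
    """Parse ``key=value`` tokens from a FASTA description."""
    out = {}
    for token in description.split():
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value
    return out


def protein_from_fasta(rec: FastaRecord) -> ProteinRecord:
    """Rehydrate a ProteinRecord from a provenance-carrying FASTA entry."""
    meta = parse_description(rec.description)
    category = meta.get("category", CATEGORY_SAMPLE)
    origins = []
    if "sample" in meta and "contig" in meta and "protein" in meta:
        origins.append((meta["sample"], meta["contig"], meta["protein"]))
    return ProteinRecord(
        accession=rec.id,
        sequence=rec.sequence,
        category=category,
        origins=frozenset(origins),
        decoy_of=meta.get("decoy_of"),
        description=rec.description,
    )


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class Gff3Record:
    """One generic GFF3 feature row."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str = "."
    strand: str = "."
    phase: str = "."
    attributes: dict = field(default_factory=dict)


_GFF3_ESCAPES = [
    ("%", "%25"),  # must come first
    (";", "%3B"),
    ("=", "%3D"),
    ("&", "%26"),
    (",", "%2C"),
    ("\t", "%09"),
    ("\n", "%0A"),
]


def _escape(value: str) -> str:
    for raw, enc in _GFF3_ESCAPES:
        value = value.replace(raw, enc)
    return value


def _unescape(value: str) -> str:
    for raw, enc in reversed(_GFF3_ESCAPES):
        value = value.replace(enc, raw)
    return value


def write_gff3(features, path: str | Path) -> None:
    """Serialize :class:`Gff3Record` rows; starts with the version pragma.

    Reserved characters in attribute values (``; = & ,`` and tab) are
    percent-encoded per the GFF3 specification.
    """
    lines = ["##gff-version 3"]
    for f in features:
        if f.start > f.end:
            raise ValueError(f"feature on {f.seqid}: start {f.start} > end {f.end}")
        if f.strand not in ("+", "-", ".", "?"):
            raise ValueError(f"feature on {f.seqid}: unknown strand {f.strand!r}")
        attrs = ";".join(
            f"{_escape(str(k))}={_escape(str(v))}" for k, v in f.attributes.items()
        )
        lines.append(
            "\t".join(
                [
                    f.seqid,
                    f.source,
                    f.type,
                    str(f.start),
                    str(f.end),
                    str(f.score),
                    f.strand,
                    str(f.phase),
                    attrs or ".",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[Gff3Record]:
    """Parse a GFF3 file through gffutils (order preserved)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=False,
    )
    out = []
    for f in db.all_features(order_by=None):
        attrs = {k: ",".join(v) if isinstance(v, list) else v
                 for k, v in f.attributes.items()}
        out.append(
            Gff3Record(
                seqid=f.seqid,
                source=f.source,
                type=f.featuretype,
                start=f.start,
                end=f.end,
                score=f.score if f.score is not None else ".",
                strand=f.strand or ".",
                phase=f.frame if f.frame is not None else ".",
                attributes=attrs,
            )
        )
    return out


def read_gene_calls(path: str | Path) -> list[CdsFeature]:
    """Read CDS gene calls from a GFF3 file into :class:`CdsFeature` rows."""
    out = []
    for rec in read_gff3(path):
        if rec.type != "CDS":
            continue
        attrs = rec.attributes
        out.append(
            CdsFeature(
                contig_id=rec.seqid,
                start=rec.start,
                end=rec.end,
                strand=rec.strand,
                protein_id=attrs.get("ID", f"{rec.seqid}:{rec.start}"),
                caller=attrs.get("caller", rec.source),
                partial=attrs.get("partial", "false").lower() == "true",
            )
        )
    return out


def write_gene_calls(cds_features, path: str | Path) -> None:
    rows = [
        Gff3Record(
            seqid=c.contig_id,
            source=c.caller,
            type="CDS",
            start=c.start,
            end=c.end,
            strand=c.strand,
            phase="0",
            attributes={"ID": c.protein_id, "partial": str(c.partial).lower()},
        )
        for c in cds_features
    ]
    write_gff3(rows, path)


# ---------------------------------------------------------------------------
# PSM tables


def read_psm_table(path: str | Path, decoy_tag: str = "DECOY_") -> list[PsmRecord]:
    """Read a PSM report TSV.

    Mandatory columns: spectrum_id, raw_file, sample_id, peptide_sequence,
    score, protein_accessions (";"-separated, deduplicated on read). A PSM
    matching both target and decoy accessions is treated as target.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path}: missing mandatory column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            score = float(row.score)
        except ValueError:
            raise ValueError(
                f"PSM table {path}, line {i}: non-numeric score {row.score!r}"
            ) from None
        accessions = frozenset(a for a in row.protein_accessions.split(";") if a)
        records.append(
            PsmRecord(
                spectrum_id=row.spectrum_id,
                raw_file=row.raw_file,
                sample_id=row.sample_id,
                peptide_sequence=row.peptide_sequence,
                score=score,
                matched_accessions=accessions,
                is_decoy=psm_is_decoy(accessions, decoy_tag),
            )
        )
    return records


def write_psm_table(psms, path: str | Path) -> None:
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "raw_file": p.raw_file,
            "sample_id": p.sample_id,
            "peptide_sequence": p.peptide_sequence,
            "score": repr(p.score),
            "protein_accessions": ";".join(sorted(p.matched_accessions)),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report tables


def write_protein_report(groups, path: str | Path) -> None:
    """Filtered protein-group report (one row per surviving group)."""
    rows = []
    for g in groups:
        unique_peps = [p for p in sorted(g.peptides)]
        rows.append(
            {
                "group_id": g.group_id,
                "members": ";".join(sorted(g.members)),
                "representative": g.representative,
                "n_peptides": len(g.peptides),
                "validated_psm_count": g.validated_psm_count,
                "spectral_count_raw": g.spectral_count_raw,
                "nsaf": f"{g.nsaf:.10g}",
                "q_value": f"{g.q_value:.10g}",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "members",
            "representative",
            "n_peptides",
            "validated_psm_count",
            "spectral_count_raw",
            "nsaf",
            "q_value",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_peptide_report(peptides, path: str | Path) -> None:
    rows = [
        {
            "sequence": p.sequence,
            "uniqueness": p.uniqueness,
            "accessions": ";".join(sorted(p.accessions)),
            "psm_count": p.psm_count,
        }
        for p in peptides
    ]
    pd.DataFrame(
        rows, columns=["sequence", "uniqueness", "accessions", "psm_count"]
    ).to_csv(path, sep="\t", index=False)


def write_group_report(groups, sample_assemblies, path: str | Path) -> None:
    """Group report: which samples/assemblies stand behind each search DB."""
    rows = []
    for g in sorted(groups, key=lambda g: g.group_id):
        samples = sorted(g.sample_ids)
        assemblies = sorted(
            a for s in samples for a in sample_assemblies.get(s, [s])
        )
        rows.append(
            {
                "group_id": g.group_id,
                "sample_ids": ";".join(samples),
                "assembly_ids": ";".join(assemblies),
                "estimated_db_bytes": g.estimated_db_bytes,
                "overflow_flag": str(g.overflow_flag).lower(),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "sample_ids",
            "assembly_ids",
            "estimated_db_bytes",
            "overflow_flag",
        ],
    ).to_csv(path, sep="\t", index=False)
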