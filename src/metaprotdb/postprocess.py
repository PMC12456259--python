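"""Identification post-processing: target-decoy q-values, parsimonious
protein grouping, the three-stage group filter, peptide uniqueness and
NSAF spectral counting.

The stages mirror a conventional shotgun-proteomics pipeline downstream of
the search engine. PSM reports come in with raw scores and matched
accessions; everything from validation on is recomputed here:

1. PSM-level q-values gate which spectra count as validated.
2. Validated PSMs are aggregated by peptide sequence; proteins with
   identical peptide sets merge, strict-subset proteins are absorbed
   (Occam's-razor protein inference).
3. Group-level q-values use an additive protein score (sum over distinct
   peptides of the best PSM score); decoy groups are formed symmetrically
   from decoy-matched PSMs. Groups at q <= protein_fdr are validated.
4. A three-part filter removes groups without validated PSMs, strips host
   and contaminant members (dropping groups that relied on them), and
   removes proteins claimed by more than one surviving validated group.
5. Raw spectral counts and NSAF (spectral count / protein length,
   normalized to sum 1 over surviving groups) provide semi-quantification.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
from pyteomics import parser as pyt_parser

from .config import Config
from .models import (
    CATEGORY_CONTAMINANT,
    CATEGORY_DECOY,
    CATEGORY_HOST,
    PeptideEvidence,
    ProteinGroup,
    PsmRecord,
)

logger = logging.getLogger(__name__)

#: cleave after K or R except before P
TRYPSIN_RULE = r"[KR](?!P)"


# ---------------------------------------------------------------------------
# digestion


def digest(sequence: str, config: Config | None = None) -> set[str]:
    """In-silico tryptic peptides of a protein.

    Cleaves after K/R not followed by P, allows up to
    ``max_missed_cleavages`` internal missed sites and keeps peptides with
    length in ``[peptide_length_min, peptide_length_max]``.
    """
    cfg = config or Config()
    if not sequence:
        raise ValueError("empty protein sequence")
    return set(
        pyt_parser.cleave(
            sequence,
            TRYPSIN_RULE,
            missed_cleavages=cfg.max_missed_cleavages,
            min_length=cfg.peptide_length_min,
            max_length=cfg.peptide_length_max,
        )
    )


# ---------------------------------------------------------------------------
# q-values


def compute_qvalues(scores, is_decoy, plus_one: bool = False):
    """Target-decoy q-values for a scored list (higher score = better).

    Sorts by decreasing score (decoys before targets on ties, the
    conservative choice); the FDR at each threshold is
    ``#decoys >= t / #targets >= t`` (optionally ``(#decoys+1)/#targets``)
    and the q-value is the running minimum of FDR from the bottom of the
    list upward, which makes q non-decreasing down the sorted list.

    Returns an array of q-values aligned with the input order.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.shape != is_decoy.shape or scores.ndim != 1:
        raise ValueError("scores and is_decoy must be 1-D and aligned")
    n = scores.size
    if n == 0:
        return np.zeros(0)
    if is_decoy.all():
        raise ValueError("all-decoy input: no targets to validate")
    # decoys first on ties: sort key (-score, is_target)
    order = np.lexsort((~is_decoy, -scores))
    dec_sorted = is_decoy[order]
    cum_dec = np.cumsum(dec_sorted)
    cum_tar = np.cumsum(~dec_sorted)
    num = cum_dec + 1 if plus_one else cum_dec
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(cum_tar > 0, num / np.maximum(cum_tar, 1), np.inf)
    qvals_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    qvals_sorted = np.clip(qvals_sorted, 0.0, None)
    out = np.empty(n)
    out[order] = qvals_sorted
    return out


def validate_psms(psms: list[PsmRecord], config: Config) -> list[PsmRecord]:
    """PSMs passing the PSM-level q-value gate.

    Decoy PSMs above the score threshold are kept in the returned list:
    downstream protein-group inference forms decoy groups from them, and
    that symmetric competition is what calibrates the group-level FDR.
    """
    if not psms:
        return []
    q = compute_qvalues(
        [p.score for p in psms],
        [p.is_decoy for p in psms],
        plus_one=config.fdr_plus_one,
    )
    return [p for p, qv in zip(psms, q) if qv <= config.psm_fdr]


# ---------------------------------------------------------------------------
# protein inference


def _group_side(psms, decoy_side: bool, decoy_tag: str):
    """Build (accession -> peptide set, peptide -> best score, peptide -> psm count)."""
    acc_peps: dict[str, set[str]] = defaultdict(set)
    best_score: dict[str, float] = {}
    psm_count: dict[str, int] = defaultdict(int)
    for p in psms:
        if p.is_decoy != decoy_side:
            continue
        if decoy_side:
            accs = {a for a in p.matched_accessions if a.startswith(decoy_tag)}
        else:
            accs = {a for a in p.matched_accessions if not a.startswith(decoy_tag)}
        if not accs:
            continue
        pep = p.peptide_sequence
        psm_count[pep] += 1
        if pep not in best_score or p.score > best_score[pep]:
            best_score[pep] = p.score
        for a in accs:
            acc_peps[a].add(pep)
    return acc_peps, best_score, psm_count


def _parsimony_groups(acc_peps, best_score, is_decoy: bool, prefix: str):
    """Merge identical peptide sets, absorb strict subsets, score groups."""
    by_set: dict[frozenset, list[str]] = defaultdict(list)
    for acc, peps in acc_peps.items():
        by_set[frozenset(peps)].append(acc)
    # absorb strict subsets into the (unique largest) superset group
    sets = sorted(by_set, key=len, reverse=True)
    absorbed_into: dict[frozenset, frozenset] = {}
    for i, s in enumerate(sets):
        for larger in sets[:i]:
            if len(larger) > len(s) and s < larger:
                target = larger
                # follow chains so absorption lands on a maximal set
                while target in absorbed_into:
                    target = absorbed_into[target]
                absorbed_into[s] = target
                break
    merged: dict[frozenset, dict[str, frozenset]] = {}
    for s, accs in by_set.items():
        top = s
        while top in absorbed_into:
            top = absorbed_into[top]
        merged.setdefault(top, {})
        for a in accs:
            merged[top][a] = frozenset(s)
    groups = []
    for peps, member_map in merged.items():
        members = frozenset(member_map)
        rep = min(members)
        score = sum(best_score[p] for p in peps)
        groups.append(
            ProteinGroup(
                group_id="",
                members=members,
                representative=rep,
                peptides=frozenset(peps),
                member_peptides=dict(member_map),
                score=score,
                is_decoy=is_decoy,
            )
        )
    groups.sort(key=lambda g: (-g.score, g.representative))
    for i, g in enumerate(groups, start=1):
        g.group_id = f"{prefix}{i:05d}"
    return groups


def infer_protein_groups(
    validated_psms: list[PsmRecord], config: Config
) -> list[ProteinGroup]:
    """Parsimonious protein groups with group-level q-values.

    Target groups are built from target PSMs, decoy groups symmetrically
    from decoy PSMs; both enter one competition scored by the sum over
    distinct peptides of the best PSM score. Target groups with
    ``q <= protein_fdr`` are flagged validated.
    """
    tgt = _parsimony_groups(
        *(_group_side(validated_psms, False, config.decoy_tag)[:2]),
        is_decoy=False,
        prefix="PG",
    )
    dec = _parsimony_groups(
        *(_group_side(validated_psms, True, config.decoy_tag)[:2]),
        is_decoy=True,
        prefix="DPG",
    )
    combined = tgt + dec
    if not combined:
        return []
    if tgt:
        q = compute_qvalues(
            [g.score for g in combined],
            [g.is_decoy for g in combined],
            plus_one=config.fdr_plus_one,
        )
        for g, qv in zip(combined, q):
            g.q_value = float(qv)
            g.validated = (not g.is_decoy) and qv <= config.protein_fdr
    # validated PSM counts per group
    _, _, counts = _group_side(validated_psms, False, config.decoy_tag)
    for g in tgt:
        g.validated_psm_count = sum(counts.get(p, 0) for p in g.peptides)
    return combined


# ---------------------------------------------------------------------------
# group filtering


def filter_groups(groups, categories, config: Config | None = None):
    """Quality filter for validated protein groups; idempotent.

    ``categories`` maps accession -> record category. Three criteria:
    (i) keep only groups with at least one validated PSM; (ii) remove
    host/contaminant members and drop groups whose identification rested
    solely on them; (iii) remove proteins claimed by more than one
    surviving validated group, dropping groups emptied by the removal.
    """
    standards = {CATEGORY_HOST, CATEGORY_CONTAMINANT}
    survivors = []
    for g in groups:
        if g.is_decoy or not g.validated:
            continue
        # (i) validated PSM support
        if g.validated_psm_count < 1:
            continue
        # (ii) strip host/contaminant members
        kept = {
            a: peps
            for a, peps in g.member_peptides.items()
            if categories.get(a) not in standards
        }
        if not kept:
            continue
        peptides = frozenset().union(*kept.values())
        if not peptides:
            continue
        survivors.append(
            ProteinGroup(
                group_id=g.group_id,
                members=frozenset(kept),
                representative=min(kept),
                peptides=peptides,
                member_peptides=kept,
                score=g.score,
                q_value=g.q_value,
                validated=True,
                is_decoy=False,
                validated_psm_count=g.validated_psm_count,
                spectral_count_raw=g.spectral_count_raw,
                nsaf=g.nsaf,
            )
        )
    # (iii) proteins in more than one surviving validated group
    claims: dict[str, int] = defaultdict(int)
    for g in survivors:
        for a in g.members:
            claims[a] += 1
    shared = {a for a, c in claims.items() if c > 1}
    if shared:
        logger.info(
            "filter_groups: removing %d protein(s) shared by multiple "
            "validated groups: %s",
            len(shared),
            sorted(shared)[:10],
        )
    out = []
    for g in survivors:
        kept = {a: p for a, p in g.member_peptides.items() if a not in shared}
        if not kept:
            continue
        peptides = frozenset().union(*kept.values())
        out.append(
            ProteinGroup(
                group_id=g.group_id,
                members=frozenset(kept),
                representative=min(kept),
                peptides=peptides,
                member_peptides=kept,
                score=g.score,
                q_value=g.q_value,
                validated=True,
                is_decoy=False,
                validated_psm_count=g.validated_psm_count,
                spectral_count_raw=g.spectral_count_raw,
                nsaf=g.nsaf,
            )
        )
    return out


# ---------------------------------------------------------------------------
# peptide uniqueness


def _norm(pep: str, equate_I_L: bool) -> str:
    return pep.replace("I", "J").replace("L", "J") if equate_I_L else pep


def classify_uniqueness(
    peptide_psm_counts,
    groups,
    target_records,
    config: Config | None = None,
) -> list[PeptideEvidence]:
    """Classify observed peptides as unique or ambiguous against the DB.

    A peptide is *unique* when exactly one protein group (over the
    supplied groups) contains a protein in which the peptide occurs — as
    a tryptic peptide by default, or as a plain substring when
    ``peptide_match_mode = "substring"``. I and L are equated when
    configured. Peptides matching no database protein are orphans:
    logged and excluded.
    """
    cfg = config or Config()
    pep_to_accs: dict[str, set[str]] = defaultdict(set)
    if cfg.peptide_match_mode == "tryptic":
        for rec in target_records:
            for pep in digest(rec.sequence, cfg):
                pep_to_accs[_norm(pep, cfg.equate_I_L)].add(rec.accession)
    acc_to_group: dict[str, set[str]] = defaultdict(set)
    for g in groups:
        for a in g.members:
            acc_to_group[a].add(g.group_id)
    out = []
    for pep, count in sorted(peptide_psm_counts.items()):
        key = _norm(pep, cfg.equate_I_L)
        if cfg.peptide_match_mode == "substring":
            nkey = key
            accs = {
                r.accession
                for r in target_records
                if nkey in _norm(r.sequence, cfg.equate_I_L)
            }
        else:
            accs = pep_to_accs.get(key, set())
        if not accs:
            logger.warning("orphan peptide %s matches no database protein", pep)
            continue
        group_ids = set().union(*(acc_to_group.get(a, set()) for a in accs))
        # peptides hitting proteins outside any group still count those
        # proteins as distinct mapping targets
        ungrouped = {a for a in accs if not acc_to_group.get(a)}
        n_targets = len(group_ids) + len(ungrouped)
        uniqueness = "unique" if n_targets == 1 else "ambiguous"
        out.append(
            PeptideEvidence(
                sequence=pep,
                psm_count=count,
                accessions=frozenset(accs),
                uniqueness=uniqueness,
            )
        )
    return out


# ---------------------------------------------------------------------------
# spectral counting


def spectral_counting(groups, protein_lengths, validated_psms):
    """Raw spectral counts and NSAF over the surviving groups.

    raw(g) = number of validated PSMs whose peptide belongs to g;
    NSAF(g) = (raw(g)/L(g)) / sum_h raw(h)/L(h) with L the representative
    protein length. NSAF sums to 1 over the groups unless every count is
    zero (then all NSAF are 0, with a warning).
    """
    pep_counts: dict[str, int] = defaultdict(int)
    for p in validated_psms:
        pep_counts[p.peptide_sequence] += 1
    rates = []
    for g in groups:
        raw = sum(pep_counts.get(pep, 0) for pep in g.peptides)
        g.spectral_count_raw = raw
        length = protein_lengths[g.representative]
        rates.append(raw / length)
    total = sum(rates)
    if total == 0:
        if groups:
            logger.warning("spectral_counting: zero total counts; NSAF set to 0")
        for g in groups:
            g.nsaf = 0.0
    else:
        for g, rate in zip(groups, rates):
            g.nsaf = rate / total
    return groups


# ---------------------------------------------------------------------------
# pipeline convenience


def postprocess_psms(psms: list[PsmRecord], database_records, config: Config):
    """Full identification post-processing for one PSM collection.

    Returns ``(surviving_groups, peptide_evidence, validated_psms)``.
    """
    categories = {r.accession: r.category for r in database_records}
    lengths = {r.accession: len(r.sequence) for r in database_records}
    targets = [r for r in database_records if r.category != CATEGORY_DECOY]

    validated = validate_psms(psms, config)
    groups = infer_protein_groups(validated, config)
    surviving = filter_groups(groups, categories, config)
    surviving = spectral_counting(surviving, lengths, validated)

    pep_counts: dict[str, int] = defaultdict(int)
    for p in validated:
        if not p.is_decoy:
            pep_counts[p.peptide_sequence] += 1
    observed = {
        pep: c
        for pep, c in pep_counts.items()
        if any(pep in g.peptides for g in surviving)
    }
    peptides = classify_uniqueness(observed, surviving, targets, config)
    return surviving, peptides, validated
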