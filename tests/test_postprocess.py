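"""Identification post-processing: digestion vs an exhaustive-cut oracle,
target-decoy q-values vs hand computation, parsimony grouping vs a
brute-force closure, the three-criteria group filter and NSAF counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaprotdb.config import Config
from metaprotdb.models import ProteinGroup, ProteinRecord, PsmRecord
from metaprotdb.postprocess import (
    classify_uniqueness,
    compute_qvalues,
    digest,
    filter_groups,
    infer_protein_groups,
    spectral_counting,
    validate_psms,
)

AAS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def brute_force_digest(seq, max_missed=2, min_len=7, max_len=60):
    """Exhaustive enumeration over all cut combinations (independent oracle)."""
    cuts = [
        i + 1
        for i in range(len(seq))
        if seq[i] in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P")
    ]
    bounds = [0] + [c for c in cuts if c != len(seq)] + [len(seq)]
    peptides = set()
    for a in range(len(bounds) - 1):
        for b in range(a + 1, len(bounds)):
            internal = b - a - 1
            if internal > max_missed:
                break
            pep = seq[bounds[a] : bounds[b]]
            if min_len <= len(pep) <= max_len:
                peptides.add(pep)
    return peptides


# ---------------------------------------------------------------------------
# digestion


def test_digest_no_cleavage_site_returns_whole_sequence():
    assert digest("MAEDNSVHWG") == {"MAEDNSVHWG"}


def test_digest_all_fragments_below_length_floor():
    assert digest("MKR") == set()


def test_digest_proline_blocks_cleavage():
    # K before P is not cut: KPEPTIDE stays fused to the N-terminal part
    assert "MAKPEPTIDE" in digest("MAKPEPTIDE")
    assert digest("MAKPEPTIDE") == {"MAKPEPTIDE"}


def test_digest_fixed_sequence_matches_exhaustive_cuts():
    seq = "MAAAKEEEERGGGGKPHHHHRDDDDDDK"  # 3 effective sites (KP blocked)
    assert digest(seq) == brute_force_digest(seq)


def test_digest_random_proteins_match_exhaustive_cuts(rng):
    for _ in range(100):
        n = int(rng.integers(10, 120))
        seq = "".join(AAS[rng.integers(0, 20, n)])
        assert digest(seq) == brute_force_digest(seq), seq


def test_digest_respects_config_bounds(rng):
    cfg = Config(peptide_length_min=5, peptide_length_max=12, max_missed_cleavages=1)
    seq = "".join(AAS[rng.integers(0, 20, 80)])
    assert digest(seq, cfg) == brute_force_digest(seq, 1, 5, 12)


# ---------------------------------------------------------------------------
# q-values


def test_qvalues_no_decoys_all_zero():
    q = compute_qvalues([5.0, 3.0, 1.0], [False, False, False])
    assert np.all(q == 0)


def test_qvalues_hand_computed_oracle():
    """Scores T:10 T:9 D:8 T:7 -> FDR per rank (0, 0, 1/2, 1/3); running
    minimum from the bottom gives target q-values (0, 0, 1/3)."""
    q = compute_qvalues([10, 9, 8, 7], [False, False, True, False])
    assert q[0] == pytest.approx(0.0)
    assert q[1] == pytest.approx(0.0)
    assert q[3] == pytest.approx(1 / 3)


def test_qvalues_all_decoy_rejected():
    with pytest.raises(ValueError, match="all-decoy"):
        compute_qvalues([1.0, 2.0], [True, True])


def test_qvalues_plus_one_correction():
    q = compute_qvalues([10, 9, 8, 7], [False, False, True, False], plus_one=True)
    assert q[0] == pytest.approx(1 / 2)  # (0+1)/1 then running min -> 1/2
    assert q[3] == pytest.approx(2 / 3)


@settings(max_examples=60, derandomize=True)
@given(
    st.lists(
        st.tuples(st.floats(-100, 100), st.booleans()),
        min_size=1,
        max_size=60,
    ).filter(lambda rows: any(not d for _, d in rows))
)
def test_qvalue_monotonicity_and_prefix_validation(rows):
    """q is non-decreasing down the sorted score list and the validated
    set is a prefix of the sorted targets."""
    scores = [s for s, _ in rows]
    decoys = [d for _, d in rows]
    q = compute_qvalues(scores, decoys)
    order = np.lexsort((np.logical_not(decoys), -np.asarray(scores)))
    q_sorted = q[order]
    assert np.all(np.diff(q_sorted) >= -1e-12)
    for thr in (0.01, 0.1, 0.5):
        tgt = [(s, qv) for s, d, qv in zip(scores, decoys, q) if not d]
        tgt.sort(key=lambda t: -t[0])
        flags = [qv <= thr for _, qv in tgt]
        # once invalid, never valid again at lower score
        assert flags == sorted(flags, reverse=True)


# ---------------------------------------------------------------------------
# protein inference


def psm(pep, accs, score=30.0, sid=None, decoy=False):
    return PsmRecord(
        spectrum_id=sid or f"sp_{pep}_{score}",
        raw_file="f.raw",
        sample_id="s1",
        peptide_sequence=pep,
        score=score,
        matched_accessions=frozenset(accs),
        is_decoy=decoy,
    )


def test_disjoint_peptide_sets_give_two_groups(config):
    psms = [psm("AAAAAAAK", {"P1"}), psm("CCCCCCCK", {"P2"})]
    groups = [g for g in infer_protein_groups(psms, config) if not g.is_decoy]
    assert sorted(sorted(g.members) for g in groups) == [["P1"], ["P2"]]


def test_strict_subset_protein_absorbed(config):
    psms = [
        psm("AAAAAAAK", {"A", "B"}),
        psm("CCCCCCCK", {"A"}),
    ]
    groups = [g for g in infer_protein_groups(psms, config) if not g.is_decoy]
    assert len(groups) == 1
    assert groups[0].members == frozenset({"A", "B"})
    assert groups[0].representative == "A"
    assert groups[0].peptides == frozenset({"AAAAAAAK", "CCCCCCCK"})


def test_identical_peptide_sets_merge(config):
    psms = [psm("AAAAAAAK", {"X", "Y"}), psm("CCCCCCCK", {"X", "Y"})]
    groups = [g for g in infer_protein_groups(psms, config) if not g.is_decoy]
    assert len(groups) == 1 and groups[0].members == frozenset({"X", "Y"})


def test_group_score_is_sum_of_best_peptide_scores(config):
    psms = [
        psm("AAAAAAAK", {"P"}, score=10.0, sid="a1"),
        psm("AAAAAAAK", {"P"}, score=12.0, sid="a2"),
        psm("CCCCCCCK", {"P"}, score=5.0, sid="b1"),
    ]
    (g,) = [g for g in infer_protein_groups(psms, config) if not g.is_decoy]
    assert g.score == pytest.approx(17.0)
    assert g.validated_psm_count == 3


def test_random_fixture_matches_bruteforce_closure(config, rng):
    """30 proteins with random peptide subsets: the emitted groups must be
    exactly the distinct maximal peptide sets, every protein lands in one
    group whose peptide set contains its own, and identical-set proteins
    share a group."""
    pool = ["".join(AAS[rng.integers(0, 20, 9)]) for _ in range(25)]
    acc_peps = {}
    for i in range(30):
        size = int(rng.integers(1, 6))
        acc_peps[f"P{i:02d}"] = frozenset(
            pool[j] for j in rng.choice(25, size=size, replace=False)
        )
    psms = []
    k = 0
    for acc, peps in acc_peps.items():
        for pep in peps:
            psms.append(psm(pep, {a for a, s in acc_peps.items() if pep in s},
                            score=20 + (k % 7), sid=f"sp{k}"))
            k += 1
    groups = [g for g in infer_protein_groups(psms, config) if not g.is_decoy]

    # oracle: peptide set per accession as implied by the PSMs
    implied = {a: frozenset(p for p in pool if any(
        ps.peptide_sequence == p and a in ps.matched_accessions for ps in psms))
        for a in acc_peps}
    maximal = {
        s for s in set(implied.values())
        if not any(s < t for t in implied.values())
    }
    assert {g.peptides for g in groups} == maximal
    membership = {a: [g for g in groups if a in g.members] for a in implied}
    for a, gs in membership.items():
        assert len(gs) == 1  # each protein in exactly one group
        assert implied[a] <= gs[0].peptides
    for a, b in [(a, b) for a in implied for b in implied if a < b]:
        if implied[a] == implied[b]:
            assert membership[a][0] is membership[b][0]


def test_decoy_groups_compete_in_qvalue_estimation(config):
    psms = [psm(f"AAAAAA{c}K", {f"T{i}"}, score=30 - i, sid=f"t{i}")
            for i, c in enumerate("CDEFG")]
    psms += [psm("WWWWWWWK", {"DECOY_X"}, score=27.5, sid="d1", decoy=True)]
    groups = infer_protein_groups(psms, config)
    decoy_groups = [g for g in groups if g.is_decoy]
    assert len(decoy_groups) == 1
    assert not decoy_groups[0].validated
    # targets scoring below the decoy carry a nonzero q
    worst_target = min((g for g in groups if not g.is_decoy), key=lambda g: g.score)
    assert worst_target.q_value > 0


# ---------------------------------------------------------------------------
# filter_groups


def make_group(gid, member_peptides, validated=True, psm_count=5, q=0.001):
    members = frozenset(member_peptides)
    return ProteinGroup(
        group_id=gid,
        members=members,
        representative=min(members),
        peptides=frozenset().union(*member_peptides.values()),
        member_peptides={a: frozenset(p) for a, p in member_peptides.items()},
        q_value=q,
        validated=validated,
        validated_psm_count=psm_count,
    )


@pytest.fixture()
def six_group_fixture():
    categories = {
        "A1": "sample", "B1": "sample", "CONT1": "contaminant",
        "D1": "sample", "HUM1": "host", "E1": "sample", "F1": "sample",
        "SHARED": "sample",
    }
    groups = [
        make_group("G1", {"A1": {"p1", "p2"}}),                      # survives
        make_group("G2", {"B1": {"p3"}}, psm_count=0),               # (i)
        make_group("G3", {"CONT1": {"p4"}}),                         # (ii)
        make_group("G4", {"D1": {"p5"}, "HUM1": {"p6"}}),            # host stripped
        make_group("G5", {"E1": {"p7"}, "SHARED": {"p8"}}),          # (iii) on SHARED
        make_group("G6", {"F1": {"p9"}, "SHARED": {"p8"}}),
    ]
    return groups, categories


def test_six_group_fixture_hand_derived_survivors(six_group_fixture):
    groups, categories = six_group_fixture
    out = filter_groups(groups, categories)
    by_id = {g.group_id: g for g in out}
    assert set(by_id) == {"G1", "G4", "G5", "G6"}
    assert by_id["G1"].members == frozenset({"A1"})
    assert by_id["G4"].members == frozenset({"D1"})  # host removed
    assert by_id["G5"].members == frozenset({"E1"})  # SHARED removed
    assert by_id["G6"].members == frozenset({"F1"})


def test_group_of_only_contaminants_removed(six_group_fixture):
    groups, categories = six_group_fixture
    out = filter_groups([groups[2]], categories)
    assert out == []


def test_filter_is_idempotent(six_group_fixture):
    groups, categories = six_group_fixture
    once = filter_groups(groups, categories)
    twice = filter_groups(once, categories)
    assert [(g.group_id, g.members, g.peptides) for g in twice] == [
        (g.group_id, g.members, g.peptides) for g in once
    ]


def test_unvalidated_and_decoy_groups_never_survive():
    g1 = make_group("G1", {"A": {"p"}}, validated=False)
    g2 = make_group("G2", {"DECOY_B": {"q"}})
    g2.is_decoy = True
    assert filter_groups([g1, g2], {"A": "sample", "DECOY_B": "decoy"}) == []


# ---------------------------------------------------------------------------
# spectral counting


def count_psms(spec):
    """spec: list of (peptide, n) -> that many validated PSMs."""
    out = []
    for pep, n in spec:
        for i in range(n):
            out.append(psm(pep, {"X"}, sid=f"{pep}.{i}"))
    return out


def test_single_group_nsaf_is_one():
    g = make_group("G1", {"A": {"PEPTIDEK"}})
    spectral_counting([g], {"A": 100}, count_psms([("PEPTIDEK", 4)]))
    assert g.nsaf == pytest.approx(1.0)
    assert g.spectral_count_raw == 4


def test_equal_counts_equal_lengths_split_evenly():
    g1 = make_group("G1", {"A": {"AAAAAAAK"}})
    g2 = make_group("G2", {"B": {"CCCCCCCK"}})
    spectral_counting(
        [g1, g2], {"A": 80, "B": 80},
        count_psms([("AAAAAAAK", 3), ("CCCCCCCK", 3)]),
    )
    assert g1.nsaf == pytest.approx(0.5)
    assert g2.nsaf == pytest.approx(0.5)


def test_closed_form_nsaf_counts_10_5_5_lengths_100_50_50():
    g1 = make_group("G1", {"A": {"AAAAAAAK"}})
    g2 = make_group("G2", {"B": {"CCCCCCCK"}})
    g3 = make_group("G3", {"C": {"DDDDDDDK"}})
    spectral_counting(
        [g1, g2, g3],
        {"A": 100, "B": 50, "C": 50},
        count_psms([("AAAAAAAK", 10), ("CCCCCCCK", 5), ("DDDDDDDK", 5)]),
    )
    assert [g.nsaf for g in (g1, g2, g3)] == pytest.approx([1 / 3, 1 / 3, 1 / 3])
    assert sum(g.nsaf for g in (g1, g2, g3)) == pytest.approx(1.0, abs=1e-9)


def test_zero_total_counts_reports_zero_nsaf():
    g = make_group("G1", {"A": {"PEPTIDEK"}})
    spectral_counting([g], {"A": 100}, [])
    assert g.nsaf == 0.0


# ---------------------------------------------------------------------------
# uniqueness classification


def test_peptide_in_single_protein_is_unique():
    recs = [ProteinRecord("P1", "MAAAAAAAKCCC"), ProteinRecord("P2", "MWWWWWWWK")]
    out = classify_uniqueness({"MAAAAAAAK": 2}, [], recs)
    (ev,) = out
    assert ev.uniqueness == "unique" and ev.accessions == frozenset({"P1"})


def test_shared_peptide_is_ambiguous():
    recs = [
        ProteinRecord("P1", "MAAAAAAAKCCCCCCCK"),
        ProteinRecord("P2", "MAAAAAAAKWWWWWWWK"),
    ]
    out = classify_uniqueness({"MAAAAAAAK": 1}, [], recs)
    assert out[0].uniqueness == "ambiguous"


def test_orphan_peptides_excluded():
    recs = [ProteinRecord("P1", "MAAAAAAAK")]
    assert classify_uniqueness({"NOTTHERE": 1}, [], recs) == []


def test_grouping_collapses_shared_peptides_to_unique():
    """A peptide shared only within one protein group is unique."""
    recs = [
        ProteinRecord("P1", "MAAAAAAAKCCCCCCCK"),
        ProteinRecord("P2", "MAAAAAAAKCCCCCCCK"),
    ]
    g = make_group("G1", {"P1": {"MAAAAAAAK"}, "P2": {"MAAAAAAAK"}})
    out = classify_uniqueness({"MAAAAAAAK": 1}, [g], recs)
    assert out[0].uniqueness == "unique"


def test_substring_mode_matches_bruteforce_scan(rng):
    cfg = Config(peptide_match_mode="substring")
    proteins = [
        ProteinRecord(f"P{i:02d}", "".join(AAS[rng.integers(0, 20, 120)]))
        for i in range(50)
    ]
    peptides = {}
    for i in range(200):
        if rng.random() < 0.5:
            src = proteins[int(rng.integers(50))].sequence
            start = int(rng.integers(0, len(src) - 9))
            peptides[src[start : start + 9]] = 1
        else:
            peptides["".join(AAS[rng.integers(0, 20, 9)])] = 1
    out = classify_uniqueness(peptides, [], proteins, cfg)
    by_seq = {e.sequence: e for e in out}
    for pep in peptides:
        hits = {p.accession for p in proteins if pep in p.sequence}
        if not hits:
            assert pep not in by_seq
        else:
            assert by_seq[pep].accessions == hits
            expected = "unique" if len(hits) == 1 else "ambiguous"
            assert by_seq[pep].uniqueness == expected


def test_equate_I_L_flips_uniqueness():
    recs = [
        ProteinRecord("P1", "MAAAIAAAKCC"),
        ProteinRecord("P2", "MAAALAAAKDD"),
    ]
    strict = classify_uniqueness({"MAAAIAAAK": 1}, [], recs, Config(equate_I_L=False))
    loose = classify_uniqueness({"MAAAIAAAK": 1}, [], recs, Config(equate_I_L=True))
    assert strict[0].uniqueness == "unique"
    assert loose[0].uniqueness == "ambiguous"


# ---------------------------------------------------------------------------
# PSM validation


def test_validate_psms_keeps_passing_decoys_for_group_competition(config):
    psms = [psm(f"AAAAAA{c}K", {"T"}, score=s, sid=f"t{s}")
            for s, c in zip((30, 29, 28, 27), "CDEF")]
    psms.append(psm("WWWWWWWK", {"DECOY_T"}, score=29.5, sid="d", decoy=True))
    out = validate_psms(psms, Config(psm_fdr=0.5))
    assert any(p.is_decoy for p in out)
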