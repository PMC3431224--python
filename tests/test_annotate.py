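"""Hierarchical classification, miRBase matching, family assignment."""

import numpy as np
import pytest

from srna._seq import random_seq, revcomp
from srna.annotate import (
    CATEGORY_ORDER,
    ReferenceSet,
    assign_family,
    classify_library,
    family_name,
    match_mirbase,
    match_read,
)
from srna.preprocess import collapse


@pytest.fixture()
def small_refs():
    rng = np.random.default_rng(42)
    genome = random_seq(rng, 4000)
    rrna = random_seq(rng, 100)
    mrna = random_seq(rng, 200)
    repeat = random_seq(rng, 80)
    mature_a = random_seq(rng, 21)
    mature_b = mature_a[:10] + ("A" if mature_a[10] != "A" else "C") + mature_a[11:]
    refs = {
        "ncRNA": ReferenceSet("ncRNA", {"rrna_1": rrna}),
        "miRBase": ReferenceSet(
            "miRBase", {"ath-miR166a": mature_a, "ath-miR165a": mature_b}
        ),
        "mRNA": ReferenceSet("mRNA", {"mrna_1": mrna}),
        "repeats": ReferenceSet("repeats", {"rep_1": repeat}),
        "genome": ReferenceSet("genome", {"chr1": genome + rrna + mrna + repeat}),
    }
    return refs, {"rrna": rrna, "mrna": mrna, "repeat": repeat,
                  "mature_a": mature_a, "mature_b": mature_b, "genome": genome}


def test_substring_hit_reports_offset(small_refs):
    refs, seqs = small_refs
    read = seqs["rrna"][10:31]
    hits = match_read(read, refs["ncRNA"])
    assert hits and hits[0].offset == 10 and hits[0].strand == "+"


def test_genome_hit_on_minus_strand(small_refs):
    refs, seqs = small_refs
    read = revcomp(seqs["genome"][100:124])
    hits = match_read(read, refs["genome"])
    assert hits and hits[0].strand == "-"


def test_mirbase_mismatch_threshold_matches_exhaustive_comparison():
    rng = np.random.default_rng(7)
    mature = random_seq(rng, 21)
    matures = {"ath-miR156a": mature}
    for n_sub in (1, 2, 3):
        read = list(mature)
        for pos in rng.choice(21, size=n_sub, replace=False):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        # exhaustive oracle: direct positional comparison
        mm = sum(1 for a, b in zip(read, mature) if a != b)
        assert mm == n_sub
        hits = match_mirbase(read, matures, max_mismatch=2)
        assert bool(hits) == (n_sub <= 2)


def test_mirbase_length_slack_and_end_to_end():
    mature = "ACGTACGTACGTACGTACGTA"
    matures = {"ath-miR156a": mature}
    assert match_mirbase(mature[:-1], matures)  # 1 nt shorter
    assert match_mirbase(mature + "GG", matures)  # 2 nt longer
    assert not match_mirbase(mature + "GGG", matures)  # 3 nt longer


def test_precedence_ncrna_beats_mirbase(small_refs):
    refs, seqs = small_refs
    # a read that is both an rRNA fragment and (by construction) a mature
    read = seqs["rrna"][:21]
    refs = dict(refs)
    refs["miRBase"] = ReferenceSet("miRBase", {"ath-miR999a": read})
    library = collapse([read])
    assignment, summary = classify_library(library, refs)
    assert assignment[read] == "ncRNA"
    assert summary.categories["ncRNA"] == (1, 1)


def test_partition_is_exact(small_refs):
    refs, seqs = small_refs
    rng = np.random.default_rng(8)
    reads = (
        [seqs["rrna"][i : i + 21] for i in range(5)]
        + [seqs["mature_a"]] * 3
        + [seqs["mrna"][i : i + 22] for i in range(4)]
        + [seqs["repeat"][i : i + 24] for i in range(3)]
        + [seqs["genome"][i * 7 : i * 7 + 24] for i in range(6)]
        + [random_seq(rng, 25) for _ in range(4)]  # unclassified w.h.p.
    )
    library = collapse(reads)
    assignment, summary = classify_library(library, refs)
    assert len(assignment) == library.unique_count
    u_sum = sum(v[0] for v in summary.categories.values()) + summary.unclassified[0]
    t_sum = sum(v[1] for v in summary.categories.values()) + summary.unclassified[1]
    assert u_sum == library.unique_count
    assert t_sum == library.total_reads


def test_classification_equals_brute_force_scan(small_refs):
    refs, seqs = small_refs
    reads = [seqs["mrna"][0:21], seqs["repeat"][5:29], seqs["genome"][50:74]]
    library = collapse(reads)
    assignment, _ = classify_library(library, refs)
    for read in reads:
        expected = None
        for cat in CATEGORY_ORDER:
            if cat == "miRBase":
                if match_mirbase(read, refs[cat].sequences):
                    expected = cat
                    break
            elif match_read(read, refs[cat]):
                expected = cat
                break
        assert assignment[read] == expected


def test_missing_reference_set_is_an_error(small_refs):
    refs, seqs = small_refs
    refs = {k: v for k, v in refs.items() if k != "repeats"}
    with pytest.raises(ValueError, match="repeats"):
        classify_library(collapse(["ACGT" * 6]), refs)


def test_empty_reference_set_is_an_error():
    with pytest.raises(ValueError):
        ReferenceSet("ncRNA", {})


def test_family_name_parsing():
    assert family_name("ath-miR156a") == "miR156"
    assert family_name("cuc-miR390b") == "miR390"
    assert family_name("miR166a") == "miR166"
    assert family_name("ath-miR166a", merge=True) == "miR165/166"


def test_assign_family_prefers_fewest_mismatches(small_refs):
    refs, seqs = small_refs
    # one mismatch from miR166a means two from miR165a (they differ at pos 11)
    read = list(seqs["mature_a"])
    read[0] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[0]]
    fa = assign_family("".join(read), refs["miRBase"].sequences)
    assert fa.family == "miR166"
    assert fa.mismatches == 1


def test_assign_family_tie_breaks_lexicographically():
    m = "ACGTACGTACGTACGTACGTA"
    fa = assign_family(m, {"ath-miR200b": m, "ath-miR200a": m})
    assert fa.reference_id == "ath-miR200a"


def test_assign_family_requires_a_hit():
    with pytest.raises(ValueError):
        assign_family("A" * 21, {"ath-miR1a": "C" * 21})
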