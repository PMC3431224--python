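"""Hairpin screen: candidate filtering, flanks, structural verdicts,
cross-genus support."""

import numpy as np
import pytest

from srna._seq import random_seq, revcomp
from srna.fold import fold
from srna.hairpin import (
    candidate_filter,
    cross_species_support,
    discover_candidates,
    evaluate_candidate,
    evaluate_hairpin,
    extract_flanks,
    find_genomic_loci,
)
from srna.preprocess import SmallRNALibrary, UniqueRead, collapse
from srna.simulate import hairpin_sequence


def test_perfect_engineered_stem_passes_fully_paired():
    rng = np.random.default_rng(0)
    mature = random_seq(rng, 21)
    precursor, offset = hairpin_sequence(rng, mature, bulges=0)
    verdict = evaluate_hairpin(fold(precursor), offset, 21)
    assert verdict.passed
    assert verdict.paired == 21
    assert verdict.arm == "5p"


def test_mature_on_3prime_arm_passes_symmetrically():
    rng = np.random.default_rng(1)
    mature = random_seq(rng, 21)
    precursor, offset = hairpin_sequence(rng, mature, bulges=0, mature_arm="3p")
    verdict = evaluate_hairpin(fold(precursor), offset, 21)
    assert verdict.passed
    assert verdict.arm == "3p"


def test_read_straddling_terminal_loop_fails():
    rng = np.random.default_rng(2)
    mature = random_seq(rng, 21)
    precursor, offset = hairpin_sequence(rng, mature, bulges=0)
    # a window centred on the terminal loop
    loop_centre = len(precursor) // 2
    verdict = evaluate_hairpin(fold(precursor), loop_centre - 10, 21)
    assert not verdict.passed
    assert "straddles_loop" in verdict.reasons or verdict.unpaired > 6


def test_find_loci_both_strands():
    rng = np.random.default_rng(3)
    read = random_seq(rng, 22)
    genome = random_seq(rng, 500) + read + random_seq(rng, 300) + revcomp(read)
    loci = find_genomic_loci(genome, read)
    strands = {s for _, _, s in loci}
    assert len(loci) == 2 and strands == {"+", "-"}


def test_candidate_filter_locus_cap_and_annotation():
    rng = np.random.default_rng(4)
    read_multi = random_seq(rng, 21)
    read_single = random_seq(rng, 21)
    read_ncrna = random_seq(rng, 21)
    genome = "".join([read_multi + random_seq(rng, 9) for _ in range(11)])
    genome += read_single + read_ncrna + random_seq(rng, 200)
    library = collapse([read_multi, read_single, read_ncrna, random_seq(rng, 27)])
    assignment = {
        read_multi: "genome",
        read_single: "genome",
        read_ncrna: "ncRNA",
    }
    kept = candidate_filter(library, assignment, genome)
    assert read_single in kept
    assert read_multi not in kept  # 11 loci > 10
    assert read_ncrna not in kept  # annotated above genome


def test_extract_flanks_clipping_and_strand():
    genome = "ACGTACGTAACCGGTTACGTACGTAACCGGTT"
    # locus at the contig start: upstream window clipped, no error
    flanks = extract_flanks(genome, (0, 8, "+"), window=10)
    assert flanks[0] == (genome[:18], 0)
    assert flanks[1] == (genome[:8], 0)
    # minus strand: flanks are reverse complements of plus-strand slices
    minus = extract_flanks(genome, (10, 18, "-"), window=5)
    assert minus[0][0] == revcomp(genome[5:18])
    assert minus[0][1] == 0
    assert minus[1][0] == revcomp(genome[10:23])
    assert minus[1][1] == 5


def test_flank_window_covers_the_opposing_arm(preset, genome_seq):
    """The downstream fold window of a 5'-arm mature contains everything
    from the mature through the loop and the full opposing arm."""
    rec = next(
        r for r in preset.world.truth
        if r.feature_class == "mirna_precursor" and r.attr("mature_arm") == "5p"
    )
    mature = next(
        r for r in preset.world.truth
        if r.feature_id == f"{rec.feature_id}_mature"
    )
    locus = (mature.start, mature.end, "+")
    down, up = extract_flanks(genome_seq, locus)
    stem_to_end = genome_seq[mature.start : rec.end]
    assert stem_to_end in down[0]


def test_shuffled_precursor_decoys_rarely_pass(preset):
    """Shuffling an embedded precursor destroys its stem: reads placed at
    the mature offset of shuffled precursors pass at well under 10%."""
    rng = np.random.default_rng(99)
    precursors = [
        r for r in preset.world.truth if r.feature_class == "mirna_precursor"
    ]
    n = passed = 0
    for rec in precursors:
        for _ in range(5):
            shuffled = "".join(
                np.array(list(rec.payload))[rng.permutation(len(rec.payload))]
            )
            verdict = evaluate_hairpin(fold(shuffled), 6, 21)
            passed += verdict.passed
            n += 1
    assert passed / n < 0.10


def test_cross_species_support_requires_two_genera():
    rng = np.random.default_rng(5)
    seq = random_seq(rng, 21)
    genome = random_seq(rng, 100) + seq + random_seq(rng, 100)
    cand = evaluate_candidate(genome, seq)
    # force a passing verdict irrelevant to this contract test
    cand.verdict = type(cand.verdict)(True, 21, 0, True, "5p", 21)
    genus_map = {"moschata": "Cucurbita", "pepo": "Cucurbita", "wm": "Citrullus"}
    libs_same_genus = {
        "moschata": SmallRNALibrary("moschata", [UniqueRead(seq, 3)]),
        "pepo": SmallRNALibrary("pepo", [UniqueRead(seq, 2)]),
        "wm": SmallRNALibrary("wm", [UniqueRead(random_seq(rng, 21), 1)]),
    }
    table = cross_species_support({seq: cand}, libs_same_genus, genus_map)
    assert not table.iloc[0]["retained"]  # moschata+pepo are one genus
    libs_cross = dict(libs_same_genus)
    libs_cross["wm"] = SmallRNALibrary("wm", [UniqueRead(seq, 1)])
    table = cross_species_support({seq: cand}, libs_cross, genus_map)
    assert bool(table.iloc[0]["retained"])


def test_discover_candidates_folds_each_sequence_once(genome_seq, preset):
    """Shared candidate sequences across libraries reuse one evaluation."""
    calls = []

    def counting_folder(seq):
        calls.append(seq)
        return fold(seq)

    lib_id = "bottle_gourd"
    library = collapse(
        [r.payload for r in preset.world.truth if r.feature_class == "mature_mirna"][:3]
    )
    assignment = {r.sequence: "genome" for r in library.unique_reads}
    discover_candidates(
        {"a": (library, assignment), "b": (library, assignment)},
        genome_seq,
        folder=counting_folder,
    )
    assert len(calls) == len(set(calls))
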