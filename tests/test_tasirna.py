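"""TAS locus detection, site scoring, phasing registers, correlation."""

import numpy as np
import pytest

from oracles import perfect_window, weighted_site_penalty_by_enumeration
from srna._seq import random_seq, to_dna
from srna.preprocess import SmallRNALibrary, UniqueRead
from srna.simulate import MIR390, tas3_locus_sequence, tas_register_starts
from srna.tasirna import (
    detect_loci,
    pair_sites,
    phased_registers,
    register_name,
    register_sequences,
    scan_sites,
    site_penalty,
    trigger_tasirna_correlation,
)

TRIGGER = MIR390


def _embed(transcript_len: int, spacing: int, seed: int = 0):
    rng = np.random.default_rng(seed)
    locus, layout, unit = tas3_locus_sequence(rng, TRIGGER, spacing)
    pad5 = random_seq(rng, 60)
    pad3 = random_seq(rng, max(0, transcript_len - len(locus) - 60))
    return pad5 + locus + pad3, len(pad5), layout, unit


def test_perfect_site_scores_zero_and_is_central():
    score = site_penalty(TRIGGER, perfect_window(TRIGGER))
    assert score.penalty == 0.0
    assert score.central_match(9, 12)


def test_single_wobble_outside_seed_region_is_half():
    # trigger position 15 (a U in miR390) is outside the doubled span 2-13
    window = list(perfect_window(TRIGGER))
    q = TRIGGER[14]
    assert q in "GT"
    window[21 - 15] = "T" if q == "G" else "G"
    assert site_penalty(TRIGGER, "".join(window)).penalty == 0.5


def test_site_penalty_matches_enumeration_on_substituted_windows():
    rng = np.random.default_rng(1)
    for _ in range(40):
        window = list(perfect_window(TRIGGER))
        for pos in rng.choice(21, size=int(rng.integers(1, 3)), replace=False):
            window[pos] = "ACGT"[int(rng.integers(0, 4))]
        w = "".join(window)
        assert site_penalty(TRIGGER, w).penalty == pytest.approx(
            weighted_site_penalty_by_enumeration(TRIGGER, w)
        )


def test_scan_finds_embedded_perfect_site():
    rng = np.random.default_rng(2)
    transcript = random_seq(rng, 120) + perfect_window(TRIGGER) + random_seq(rng, 120)
    sites = scan_sites(transcript, TRIGGER, max_penalty=2.0)
    assert len(sites) == 1
    assert sites[0].start == 120
    assert sites[0].central_match


def test_engineered_5prime_site_is_noncleavable():
    """Two mismatches plus a G:U inside positions 9-12 break the central
    match required for cleavage."""
    rng = np.random.default_rng(3)
    locus, layout, _ = tas3_locus_sequence(rng, TRIGGER, 250)
    site5 = locus[: layout["site5_end"]]
    site3 = locus[layout["site3_start"] : layout["site3_end"]]
    assert not site_penalty(TRIGGER, site5).central_match(9, 12)
    assert site_penalty(TRIGGER, site3).central_match(9, 12)
    assert site_penalty(TRIGGER, site3).penalty == 0.0


def test_scan_equals_bruteforce_full_scan():
    rng = np.random.default_rng(4)
    transcript = random_seq(rng, 400)
    sites = scan_sites(transcript, TRIGGER, max_penalty=14.0)
    found = {s.start: s.score.penalty for s in sites}
    for off in range(len(transcript) - 21 + 1):
        window = transcript[off : off + 21]
        pen = weighted_site_penalty_by_enumeration(TRIGGER, window)
        if pen <= 14.0:
            assert found[off] == pytest.approx(pen)
        else:
            assert off not in found


@pytest.mark.parametrize("spacing,expected", [(250, 1), (150, 0), (320, 0)])
def test_spacing_window_gates_locus_detection(spacing, expected):
    transcript, _, _, _ = _embed(700, spacing)
    loci = detect_loci({"t1": transcript}, TRIGGER)
    assert len(loci) == expected
    if expected:
        assert loci[0].spacing == spacing
        assert loci[0].canonical  # 5' site non-cleavable, 3' cleavable


def test_pair_sites_requires_cleavable_3prime_site():
    from srna.tasirna import Mir390Site
    from srna.duplex import duplex_score

    perfect = duplex_score(TRIGGER, perfect_window(TRIGGER))
    imperfect_window = list(perfect_window(TRIGGER))
    imperfect_window[21 - 10] = "A" if TRIGGER[9] != "T" else "C"  # break pos 10
    broken = duplex_score(TRIGGER, "".join(imperfect_window))
    cleavable = lambda start, score: Mir390Site(
        "t", start, start + 21, score, score.central_match(9, 12)
    )
    s5, s3 = cleavable(0, perfect), cleavable(271, broken)
    assert not s3.central_match
    assert pair_sites([s5, s3]) == []
    # swapped: cleavable 3' site pairs, and a cleavable 5' site is
    # explicitly not flagged canonical
    loci = pair_sites([cleavable(0, broken), cleavable(271, perfect)])
    assert len(loci) == 1 and loci[0].canonical
    loci = pair_sites([cleavable(0, perfect), cleavable(271, perfect)])
    assert len(loci) == 1 and not loci[0].canonical


def test_register_naming_and_arithmetic():
    assert register_name(1000, 1000 - 147) == "D8(+)"
    assert register_name(1000, 1000) == "D1(+)"
    starts = [1000 - 21 * (k - 1) for k in range(1, 9)]
    for k, s in enumerate(starts, start=1):
        assert register_name(1000, s) == f"D{k}(+)"
    assert all(starts[i] - starts[i + 1] == 21 for i in range(len(starts) - 1))
    with pytest.raises(ValueError):
        register_name(1000, 1000 - 20)


def test_register_sequences_equal_embedded_tandem_repeats():
    transcript, offset, layout, unit = _embed(700, 250)
    loci = detect_loci({"t1": transcript}, TRIGGER)
    regs = register_sequences(loci[0], transcript)
    assert len(regs) >= 10
    assert set(regs.values()) == {unit}


def test_phased_reads_give_fraction_one():
    """Reads cut exactly on the registers of a non-repetitive spacer are
    all in phase and named D2..D7 (D1 sits on the cleaved 3' fragment)."""
    rng = np.random.default_rng(5)
    site3 = perfect_window(TRIGGER)
    locus_seq, layout, _ = tas3_locus_sequence(np.random.default_rng(5), TRIGGER, 250)
    site5 = locus_seq[: layout["site5_end"]]
    transcript = (
        random_seq(rng, 60) + site5 + random_seq(rng, 250) + site3 + random_seq(rng, 60)
    )
    locus = detect_loci({"t1": transcript}, TRIGGER)[0]
    origin = locus.origin
    reads = [
        UniqueRead(transcript[origin - 21 * k : origin - 21 * k + 21], k + 1)
        for k in range(1, 7)
    ]
    library = SmallRNALibrary("phased", reads)
    result = phased_registers(locus, library, transcript)
    assert result.in_phase_fraction == 1.0
    names = set(result.table["register"])
    assert names == {f"D{k + 1}(+)" for k in range(1, 7)}


def test_uniform_reads_give_binomial_fraction():
    """Uniformly placed reads land in phase about 1/21 of the time."""
    transcript, offset, layout, unit = _embed(700, 250, seed=9)
    locus = detect_loci({"t1": transcript}, TRIGGER)[0]
    rng = np.random.default_rng(123)
    lo, hi = locus.site5.start, locus.site3.end - 21
    starts = rng.integers(lo, hi, size=4000)
    # collapse into unique reads by start position
    reads = {}
    for s in starts:
        seq = transcript[s : s + 21]
        reads[seq] = reads.get(seq, 0) + 1
    library = SmallRNALibrary(
        "uniform", [UniqueRead(s, c) for s, c in reads.items()]
    )
    result = phased_registers(locus, library, transcript)
    p = 1 / 21
    se = np.sqrt(p * (1 - p) / 4000)
    assert abs(result.in_phase_fraction - p) < 3 * se + 1e-9


def test_correlation_signs():
    proportional = {"a": (10.0, 100.0), "b": (20.0, 200.0), "c": (30.0, 300.0)}
    rho, _ = trigger_tasirna_correlation(proportional)
    assert rho == pytest.approx(1.0)
    anti = {"a": (10.0, 300.0), "b": (20.0, 200.0), "c": (30.0, 100.0)}
    rho, _ = trigger_tasirna_correlation(anti)
    assert rho == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        trigger_tasirna_correlation({"a": (1, 1), "b": (2, 2)})


def test_noisy_proportional_correlation_usually_positive():
    """Lognormal noise around a proportional relationship keeps the rank
    correlation positive in nearly all seeded replicates."""
    rng = np.random.default_rng(7)
    positive = 0
    n_rep = 100
    for _ in range(n_rep):
        trig = rng.uniform(5, 50, size=4)
        tas = trig * 10 * rng.lognormal(0, 0.3, size=4)
        rho, _ = trigger_tasirna_correlation(
            {f"lib{i}": (trig[i], tas[i]) for i in range(4)}
        )
        positive += rho > 0
    assert positive >= 95


def test_preset_locus_registers_and_correlation(preset, bundle):
    rec = next(r for r in preset.world.truth if r.feature_class == "tas_locus")
    unit = rec.attr("repeat_unit")
    assert len(bundle.tas_loci) == 1
    locus = bundle.tas_loci[0]
    assert locus.spacing == preset.world.spec.tas_spacing
    assert set(locus.registers.values()) == {unit}
    assert bundle.tas_correlation is not None and bundle.tas_correlation > 0
    # truth register starts are in phase with the detected cleavage origin
    starts = tas_register_starts(rec)
    for s in starts:
        assert (int(rec.attr("origin")) - s) % 21 == 0
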