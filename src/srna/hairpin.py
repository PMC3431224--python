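"""Novel miRNA discovery: locus filtering, flank folding, hairpin criteria.

A candidate novel miRNA is an unannotated genome-matched read of miRNA-like
length mapping to few genomic loci.  The genomic flank on each side of each
locus is folded with the internal maximum-base-pairing folder and the read
is required to sit on one arm of a stem-loop, pairing most of its bases to
a compact opposing arm.  Candidates passing the structural screen are then
required to be recovered in libraries from at least two genera, the
cross-species support criterion that separates real young miRNAs from
single-library folding artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

from ._seq import revcomp, to_dna, to_rna
from .fold import FoldResult, fold
from .preprocess import SmallRNALibrary

DEFAULT_MAX_LOCI = 10
DEFAULT_LEN_RANGE = (20, 24)
DEFAULT_FLANK_WINDOW = 160
MIN_PAIRED = 16
MAX_UNPAIRED = 6
ARM_SPAN_SLACK = 4


@dataclass(frozen=True)
class HairpinVerdict:
    """Structural metrics of one read within one folded flank."""

    passed: bool
    paired: int
    unpaired: int
    one_arm: bool
    arm: str  # '5p', '3p' or '' when undetermined
    arm_span: int
    reasons: tuple[str, ...] = ()


def evaluate_hairpin(
    fold_result: FoldResult,
    read_start: int,
    read_len: int,
    min_paired: int = MIN_PAIRED,
    max_unpaired: int = MAX_UNPAIRED,
    arm_span_slack: int = ARM_SPAN_SLACK,
) -> HairpinVerdict:
    """Score a read against the fold of its flank.

    Pass requires: >= ``min_paired`` read bases paired, <= ``max_unpaired``
    unpaired, all partners on a single side of the read (one arm; a partner
    inside the read or partners on both sides means the read straddles the
    terminal loop), and a compact opposing arm whose span exceeds the read
    length by at most ``arm_span_slack`` (one dominant stem, small bulges).
    """
    read_end = read_start + read_len
    if not 0 <= read_start <= read_end <= len(fold_result.sequence):
        raise ValueError("read window outside the folded sequence")
    partners = [
        p for p in fold_result.partner[read_start:read_end] if p is not None
    ]
    paired = len(partners)
    unpaired = read_len - paired
    reasons = []
    if paired < min_paired:
        reasons.append("too_few_paired")
    if unpaired > max_unpaired:
        reasons.append("too_many_unpaired")
    upstream = [p for p in partners if p < read_start]
    downstream = [p for p in partners if p >= read_end]
    inside = paired - len(upstream) - len(downstream)
    one_arm = paired > 0 and inside == 0 and (not upstream or not downstream)
    if not one_arm:
        reasons.append("straddles_loop")
    arm = ""
    arm_span = 0
    if one_arm:
        arm = "5p" if downstream else "3p"
        arm_span = max(partners) - min(partners) + 1
        if arm_span > read_len + arm_span_slack:
            reasons.append("arm_not_compact")
    return HairpinVerdict(
        passed=not reasons,
        paired=paired,
        unpaired=unpaired,
        one_arm=one_arm,
        arm=arm,
        arm_span=arm_span,
        reasons=tuple(reasons),
    )


def find_genomic_loci(
    genome_seq: str, read: str, max_loci: int | None = None
) -> list[tuple[int, int, str]]:
    """All exact occurrences of ``read`` in the genome, both strands.

    Stops early after ``max_loci + 1`` hits when a cap is given (the caller
    only needs to know the cap was exceeded).
    """
    genome_seq = to_dna(genome_seq)
    loci: list[tuple[int, int, str]] = []
    for query, strand in ((to_dna(read), "+"), (revcomp(read), "-")):
        start = genome_seq.find(query)
        while start != -1:
            loci.append((start, start + len(query), strand))
            if max_loci is not None and len(loci) > max_loci:
                return loci
            start = genome_seq.find(query, start + 1)
    return loci


def candidate_filter(
    library: SmallRNALibrary,
    assignment: dict[str, str],
    genome_seq: str,
    max_loci: int = DEFAULT_MAX_LOCI,
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
) -> list[str]:
    """Reads eligible for hairpin evaluation.

    Keeps unique reads classified ``genome`` (unannotated above it), of
    miRNA-like length, with 1..``max_loci`` genomic loci; reads hitting
    more loci are dropped as probable repeat products.
    """
    out = []
    for r in library.unique_reads:
        if assignment.get(r.sequence) != "genome":
            continue
        if not len_range[0] <= len(r.sequence) <= len_range[1]:
            continue
        loci = find_genomic_loci(genome_seq, r.sequence, max_loci=max_loci)
        if 1 <= len(loci) <= max_loci:
            out.append(r.sequence)
    return out


def extract_flanks(
    genome_seq: str,
    locus: tuple[int, int, str],
    window: int = DEFAULT_FLANK_WINDOW,
) -> list[tuple[str, int]]:
    """Two fold windows for one locus: read+downstream and upstream+read.

    Returned as ``(flank_sequence, read_offset)`` on the locus strand;
    windows are clipped at contig ends.
    """
    start, end, strand = locus
    n = len(genome_seq)
    if not 0 <= start < end <= n:
        raise ValueError("locus outside genome")
    read_len = end - start
    down_plus = genome_seq[start : min(n, end + window)]
    up_plus = genome_seq[max(0, start - window) : end]
    if strand == "+":
        return [(down_plus, 0), (up_plus, len(up_plus) - read_len)]
    # on the minus strand the read-orientation downstream flank is the
    # reverse complement of the plus-strand upstream slice
    return [(revcomp(up_plus), 0), (revcomp(down_plus), len(down_plus) - read_len)]


@dataclass
class HairpinCandidate:
    """One unique read with its best structural evidence across loci."""

    sequence: str
    loci: list[tuple[int, int, str]]
    verdict: HairpinVerdict
    flank: str = ""
    read_offset: int = 0
    fold_result: FoldResult | None = None
    supporting_libraries: list[str] = field(default_factory=list)

    @property
    def locus_count(self) -> int:
        return len(self.loci)


def evaluate_candidate(
    genome_seq: str,
    read: str,
    loci: list[tuple[int, int, str]] | None = None,
    window: int = DEFAULT_FLANK_WINDOW,
    folder: Callable[[str], FoldResult] = fold,
    fold_cache: dict[str, FoldResult] | None = None,
) -> HairpinCandidate:
    """Fold every flank of every locus; keep the first passing structure
    (or the most-paired failing one for reporting)."""
    read = to_dna(read)
    if loci is None:
        loci = find_genomic_loci(genome_seq, read)
    best: HairpinCandidate | None = None
    for locus in loci:
        for flank, offset in extract_flanks(genome_seq, locus, window=window):
            if fold_cache is not None and flank in fold_cache:
                fr = fold_cache[flank]
            else:
                fr = folder(flank)
                if fold_cache is not None:
                    fold_cache[flank] = fr
            verdict = evaluate_hairpin(fr, offset, len(read))
            cand = HairpinCandidate(read, loci, verdict, flank, offset, fr)
            if verdict.passed:
                return cand
            if best is None or verdict.paired > best.verdict.paired:
                best = cand
    if best is None:
        best = HairpinCandidate(
            read, loci, HairpinVerdict(False, 0, len(read), False, "", 0, ("no_locus",))
        )
    return best


def discover_candidates(
    libraries: dict[str, tuple[SmallRNALibrary, dict[str, str]]],
    genome_seq: str,
    max_loci: int = DEFAULT_MAX_LOCI,
    len_range: tuple[int, int] = DEFAULT_LEN_RANGE,
    window: int = DEFAULT_FLANK_WINDOW,
    folder: Callable[[str], FoldResult] = fold,
) -> dict[str, HairpinCandidate]:
    """Structural evaluation of the union of candidate reads across
    libraries; each distinct sequence is folded once."""
    genome_seq = to_dna(genome_seq)
    per_lib: dict[str, list[str]] = {}
    for lib_id, (library, assignment) in libraries.items():
        per_lib[lib_id] = candidate_filter(
            library, assignment, genome_seq, max_loci=max_loci, len_range=len_range
        )
    cache: dict[str, FoldResult] = {}
    results: dict[str, HairpinCandidate] = {}
    for lib_id, seqs in per_lib.items():
        for seq in seqs:
            if seq not in results:
                results[seq] = evaluate_candidate(
                    genome_seq, seq, window=window, folder=folder, fold_cache=cache
                )
            if results[seq].verdict.passed:
                results[seq].supporting_libraries.append(lib_id)
    return results


def cross_species_support(
    candidates: dict[str, HairpinCandidate],
    libraries: dict[str, SmallRNALibrary],
    genus_map: dict[str, str],
    min_genera: int = 2,
) -> pd.DataFrame:
    """Cross-genus recovery filter and per-library abundance report.

    A candidate is retained iff it passed the hairpin screen in >= 1
    library and its exact sequence is present in libraries of
    ``min_genera`` distinct genera.  Returns a table (one row per passing
    candidate, normalized per-library counts) with a ``retained`` column.
    """
    if len({genus_map[lib] for lib in libraries}) < 2 and min_genera >= 2:
        raise ValueError("need libraries spanning >= 2 genera")
    counts = {lib: library.counts() for lib, library in libraries.items()}
    totals = {lib: library.total_reads for lib, library in libraries.items()}
    rows = []
    for seq, cand in sorted(candidates.items()):
        if not cand.verdict.passed:
            continue
        present = [lib for lib in libraries if seq in counts[lib]]
        genera = {genus_map[lib] for lib in present}
        row = {
            "sequence": to_rna(seq),
            "length": len(seq),
            "locus_count": cand.locus_count,
            "paired": cand.verdict.paired,
            "arm": cand.verdict.arm,
            "n_genera": len(genera),
            "retained": len(genera) >= min_genera,
        }
        for lib in libraries:
            c = counts[lib].get(seq, 0)
            row[f"count_{lib}"] = c
            row[f"tpm_{lib}"] = c / totals[lib] * 1e6 if totals[lib] else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
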