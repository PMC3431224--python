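"""TAS3-like locus detection and phased siRNA (tasiRNA) extraction.

A TAS3 locus is a transcript region bounded by two complementary sites for
a 21-nt trigger miRNA (miR390), 200-300 nt apart.  Site scoring reuses the
duplex penalty with penalties doubled at trigger positions 2-13, the
seed-proximal region whose pairing licenses cleavage; a site is cleavable
when trigger positions 9-12 are perfectly paired.  Cleavage at the 3' site
falls between the transcript bases facing trigger positions 10 and 11 and
sets the 21-nt phase.  Registers are named Dk(+): the register whose 5' end
lies 21*(k-1) nt upstream of the cleavage origin, so a read starting 147 nt
upstream of the origin is D8(+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import to_dna, to_rna
from .duplex import DuplexScore, duplex_score, scan_penalties
from .preprocess import SmallRNALibrary

DEFAULT_MAX_PENALTY = 6.0
WEIGHTED_SPAN = (2, 13)
MIN_SPACING = 200
MAX_SPACING = 300
PHASE = 21


def site_penalty(trigger: str, window: str) -> DuplexScore:
    """Seed-weighted duplex penalty of the trigger against one window."""
    return duplex_score(trigger, window, weighted_span=WEIGHTED_SPAN)


@dataclass(frozen=True)
class Mir390Site:
    transcript_id: str
    start: int  # 0-based half-open on the transcript, sense strand
    end: int
    score: DuplexScore
    central_match: bool

    @property
    def cleavage_origin(self) -> int:
        """Transcript index just 3' of the cut between trigger pos 10/11."""
        return self.start + (self.end - self.start) - 10


def scan_sites(
    transcript: str,
    trigger: str,
    max_penalty: float = DEFAULT_MAX_PENALTY,
    transcript_id: str = "transcript",
) -> list[Mir390Site]:
    """All trigger-complementary windows with penalty <= ``max_penalty``."""
    transcript = to_dna(transcript)
    trigger = to_dna(trigger)
    if len(transcript) < len(trigger):
        raise ValueError("transcript shorter than trigger")
    penalties = scan_penalties(trigger, transcript, weighted_span=WEIGHTED_SPAN)
    sites = []
    for off in np.flatnonzero(penalties <= max_penalty + 1e-9):
        off = int(off)
        window = transcript[off : off + len(trigger)]
        score = site_penalty(trigger, window)
        sites.append(
            Mir390Site(
                transcript_id=transcript_id,
                start=off,
                end=off + len(trigger),
                score=score,
                central_match=score.central_match(9, 12),
            )
        )
    return sites


@dataclass
class TasLocus:
    transcript_id: str
    site5: Mir390Site
    site3: Mir390Site
    spacing: int  # nt strictly between the two site intervals
    canonical: bool  # 3' site cleavable, 5' site not
    registers: dict[str, str] = field(default_factory=dict)
    in_phase_fraction: float | None = None

    @property
    def origin(self) -> int:
        return self.site3.cleavage_origin


def pair_sites(
    sites: list[Mir390Site],
    min_spacing: int = MIN_SPACING,
    max_spacing: int = MAX_SPACING,
) -> list[TasLocus]:
    """Pair 5'/3' sites on one transcript into candidate TAS loci.

    The 3' site must be cleavable (central positions 9-12 perfectly
    paired); loci whose 5' site is additionally non-cleavable are flagged
    canonical, the configuration in which only the 3' cut sets the phase.
    """
    tids = {s.transcript_id for s in sites}
    if len(tids) > 1:
        raise ValueError("sites must come from a single transcript")
    loci = []
    ordered = sorted(sites, key=lambda s: s.start)
    for i, s5 in enumerate(ordered):
        for s3 in ordered[i + 1 :]:
            gap = s3.start - s5.end
            if not min_spacing <= gap <= max_spacing:
                continue
            if not s3.central_match:
                continue
            loci.append(
                TasLocus(
                    transcript_id=s5.transcript_id,
                    site5=s5,
                    site3=s3,
                    spacing=gap,
                    canonical=not s5.central_match,
                )
            )
    return loci


def detect_loci(
    transcripts: dict[str, str],
    trigger: str,
    max_penalty: float = DEFAULT_MAX_PENALTY,
    min_spacing: int = MIN_SPACING,
    max_spacing: int = MAX_SPACING,
) -> list[TasLocus]:
    """Scan every transcript for dual-site TAS loci."""
    loci = []
    for tid, seq in transcripts.items():
        if len(to_dna(seq)) < len(trigger):
            continue
        sites = scan_sites(seq, trigger, max_penalty=max_penalty, transcript_id=tid)
        loci.extend(pair_sites(sites, min_spacing=min_spacing, max_spacing=max_spacing))
    return loci


def register_name(origin: int, read_start: int, phase: int = PHASE) -> str:
    """Dk(+) name of an in-phase read 5' end; raises if off-phase."""
    offset = origin - read_start
    if offset % phase != 0:
        raise ValueError(f"read start {read_start} is not on the {phase}-nt phase")
    return f"D{offset // phase + 1}(+)"


def register_sequences(locus: TasLocus, transcript: str, phase: int = PHASE) -> dict[str, str]:
    """Phased register sequences lying fully within the inter-site spacer."""
    transcript = to_dna(transcript)
    out = {}
    k = 2  # D1 sits on the 3' cleavage fragment, outside the spacer
    while True:
        start = locus.origin - phase * (k - 1)
        if start < locus.site5.end:
            break
        if start + phase <= locus.site3.start:
            out[f"D{k}(+)"] = transcript[start : start + phase]
        k += 1
    return out


@dataclass
class PhasingResult:
    locus: TasLocus
    table: pd.DataFrame  # per unique locus-overlapping read
    in_phase_fraction: float
    in_phase_total: int
    overlapping_total: int


def phased_registers(
    locus: TasLocus,
    library: SmallRNALibrary,
    transcript: str,
    phase: int = PHASE,
    variant_tolerance: int = 1,
) -> PhasingResult:
    """Classify locus-overlapping library reads into phase registers.

    A read is in phase when its 5' end on the transcript falls exactly on a
    register boundary (21-nt steps upstream from the cleavage origin).
    Off-by-``variant_tolerance`` reads are reported as near-phase variants
    but do not count as in phase.  The in-phase fraction is the count-
    weighted share of in-phase reads among all locus-overlapping reads.
    """
    transcript = to_dna(transcript)
    origin = locus.origin
    lo, hi = locus.site5.start, locus.site3.end
    rows = []
    in_phase_total = overlapping_total = 0
    for r in library.unique_reads:
        seq = r.sequence
        start = transcript.find(seq)
        hits = []
        while start != -1:
            if start < hi and start + len(seq) > lo:
                hits.append(start)
            start = transcript.find(seq, start + 1)
        if not hits:
            continue
        overlapping_total += r.count
        in_phase = False
        register = ""
        variant = False
        for o in hits:
            rem = (origin - o) % phase
            if rem == 0 and o <= origin:
                in_phase = True
                register = register_name(origin, o, phase)
                break
            if min(rem, phase - rem) <= variant_tolerance:
                variant = True
        if in_phase:
            in_phase_total += r.count
        rows.append(
            {
                "sequence": to_rna(seq),
                "count": r.count,
                "start": hits[0],
                "in_phase": in_phase,
                "register": register,
                "near_phase_variant": variant and not in_phase,
            }
        )
    locus.registers = register_sequences(locus, transcript, phase)
    fraction = in_phase_total / overlapping_total if overlapping_total else 0.0
    locus.in_phase_fraction = fraction
    return PhasingResult(
        locus=locus,
        table=pd.DataFrame(rows),
        in_phase_fraction=fraction,
        in_phase_total=in_phase_total,
        overlapping_total=overlapping_total,
    )


def trigger_tasirna_correlation(
    abundances: dict[str, tuple[float, float]],
) -> tuple[float, pd.DataFrame]:
    """Spearman rank correlation between trigger-family tpm and summed
    in-phase tasiRNA tpm across libraries.

    ``abundances`` maps library id -> (trigger_tpm, tasirna_tpm);
    needs >= 3 libraries.
    """
    if len(abundances) < 3:
        raise ValueError("need >= 3 libraries for a rank correlation")
    df = pd.DataFrame(
        [
            {"library": lib, "trigger_tpm": a, "tasirna_tpm": b}
            for lib, (a, b) in abundances.items()
        ]
    )
    rho = stats.spearmanr(df["trigger_tpm"], df["tasirna_tpm"]).statistic
    return float(rho), df
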