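"""Plant miRNA target prediction by complementarity penalty.

Every same-length window of every transcript is scored against each query
miRNA with the flat duplex penalty (mismatch 1, G:U wobble 0.5, no gaps, no
position weighting) and reported when the penalty does not exceed the
cutoff; the conventional plant cutoff of 3.5 admits e.g. 3 mismatches plus
one wobble but rejects 4 mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import to_dna, to_rna
from .duplex import DuplexScore, duplex_score, scan_penalties

DEFAULT_CUTOFF = 3.5

logger = logging.getLogger(__name__)


def duplex_penalty(mirna: str, window: str) -> DuplexScore:
    """Flat (unweighted) duplex penalty of a miRNA against one window."""
    return duplex_score(mirna, window, weighted_span=None)


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open window on the transcript
    end: int
    score: DuplexScore
    verdict: bool  # penalty <= cutoff
    best: bool = False  # best site for this (miRNA, transcript) pair


def scan_transcriptome(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
) -> list[TargetSite]:
    """All target sites with penalty <= ``cutoff``.

    The minimum-penalty site per (miRNA, transcript) pair is flagged
    ``best`` (left-most on ties).
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    sites: list[TargetSite] = []
    for mid, mseq in mirnas.items():
        mseq = to_dna(mseq)
        for tid, tseq in transcripts.items():
            tseq = to_dna(tseq)
            if len(tseq) < len(mseq):
                continue
            penalties = scan_penalties(mseq, tseq)
            hits = np.flatnonzero(penalties <= cutoff + 1e-9)
            if len(hits) == 0:
                continue
            best_off = int(hits[np.argmin(penalties[hits])])
            for off in hits:
                off = int(off)
                score = duplex_penalty(mseq, tseq[off : off + len(mseq)])
                sites.append(
                    TargetSite(
                        mirna_id=mid,
                        transcript_id=tid,
                        start=off,
                        end=off + len(mseq),
                        score=score,
                        verdict=score.penalty <= cutoff,
                        best=off == best_off,
                    )
                )
    return sites


def annotate_targets(
    sites: list[TargetSite],
    descriptions: dict[str, str] | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join predicted sites to a transcript-description table.

    Transcripts without a supplied description are labeled
    ``unknown protein``; duplicate transcript ids in a table keep the first
    entry with a warning.
    """
    desc: dict[str, str] = {}
    if isinstance(descriptions, pd.DataFrame):
        for tid, d in zip(descriptions.iloc[:, 0], descriptions.iloc[:, 1]):
            if tid in desc:
                logger.warning("duplicate description for %s; keeping the first", tid)
                continue
            desc[tid] = d
    elif descriptions:
        desc = dict(descriptions)
    rows = [
        {
            "mirna": s.mirna_id,
            "transcript": s.transcript_id,
            "start": s.start,
            "end": s.end,
            "penalty": s.score.penalty,
            "match_string": s.score.match_string,
            "best": s.best,
            "description": desc.get(s.transcript_id, "unknown protein"),
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "transcript", "start", "end", "penalty", "match_string",
            "best", "description",
        ],
    )


def targets_table(sites: list[TargetSite]) -> pd.DataFrame:
    """miRNA -> comma-joined target transcript ids (best sites only)."""
    rows: dict[str, list[str]] = {}
    for s in sites:
        if s.best:
            rows.setdefault(s.mirna_id, []).append(s.transcript_id)
    return pd.DataFrame(
        [
            {"mirna": m, "targets": ",".join(sorted(set(t)))}
            for m, t in sorted(rows.items())
        ]
    )


def perfect_complement(mirna: str) -> str:
    """Sense-strand window perfectly complementary to a miRNA (penalty 0)."""
    from ._seq import revcomp

    return revcomp(to_dna(mirna))
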