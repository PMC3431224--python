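"""Ungapped miRNA:target duplex penalty scoring.

A small RNA (5'->3') is aligned antisense to a same-length window of a
transcript given 5'->3' on the sense strand: query position ``i`` (0-based)
faces window position ``L-1-i``.  Each opposed base pair is scored by class:

* Watson-Crick pair (A:U, G:C)  -> 0 penalty
* G:U wobble                    -> 0.5 penalty
* anything else (mismatch)      -> 1.0 penalty

Target prediction uses the flat score with a 3.5 cutoff; TAS-site scanning
additionally doubles penalties falling at query positions 2-13 (1-based,
the seed-proximal region that licenses cleavage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import check_nucleotides, encode

# DNA alphabet internally: the wobble pair G:U appears as G:T.
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}

MATCH, WOBBLE, MISMATCH = "|", "o", "x"

#: penalty per pair class
_CLASS_PENALTY = {MATCH: 0.0, WOBBLE: 0.5, MISMATCH: 1.0}


def pair_class(query_base: str, target_base: str) -> str:
    """Classify one opposed base pair (both bases given 5'->3' sense)."""
    pair = (query_base, target_base)
    if pair in _WC:
        return MATCH
    if pair in _WOBBLE:
        return WOBBLE
    return MISMATCH


@dataclass(frozen=True)
class DuplexScore:
    """Score of one ungapped query/window duplex.

    ``match_string`` is indexed by query position from the 5' end:
    '|' perfect pair, 'o' G:U wobble, 'x' mismatch.  ``mismatches`` and
    ``gu_positions`` are 1-based query positions.
    """

    penalty: float
    match_string: str
    mismatches: tuple[int, ...] = field(default=())
    gu_positions: tuple[int, ...] = field(default=())

    def central_match(self, start: int = 9, end: int = 12) -> bool:
        """True iff query positions ``start..end`` (1-based) are all perfect."""
        return all(c == MATCH for c in self.match_string[start - 1 : end])


def duplex_score(
    query: str,
    window: str,
    weighted_span: tuple[int, int] | None = None,
    weight: float = 2.0,
) -> DuplexScore:
    """Score ``query`` against a same-length sense-strand ``window``.

    ``weighted_span`` is an inclusive 1-based query-position range whose
    penalties are multiplied by ``weight`` (used for seed-region weighting
    in TAS-site scanning); ``None`` scores flat.
    """
    q = check_nucleotides(query)
    w = check_nucleotides(window)
    if len(q) != len(w):
        raise ValueError("query and window must have equal length")
    classes = [pair_class(q[i], w[len(w) - 1 - i]) for i in range(len(q))]
    penalty = 0.0
    mism: list[int] = []
    gu: list[int] = []
    for i, c in enumerate(classes):
        p = _CLASS_PENALTY[c]
        pos = i + 1
        if weighted_span is not None and weighted_span[0] <= pos <= weighted_span[1]:
            p *= weight
        penalty += p
        if c == MISMATCH:
            mism.append(pos)
        elif c == WOBBLE:
            gu.append(pos)
    return DuplexScore(
        penalty=penalty,
        match_string="".join(classes),
        mismatches=tuple(mism),
        gu_positions=tuple(gu),
    )


def scan_penalties(
    query: str,
    transcript: str,
    weighted_span: tuple[int, int] | None = None,
    weight: float = 2.0,
) -> np.ndarray:
    """Penalty of ``query`` against every window of ``transcript``.

    Vectorized equivalent of calling :func:`duplex_score` at each offset;
    returns an array of length ``len(transcript) - len(query) + 1``.
    """
    q = encode(check_nucleotides(query))
    t = encode(check_nucleotides(transcript))
    L = len(q)
    if len(t) < L:
        return np.empty(0)
    # per-position penalty lookup: S[i, target_base]
    S = np.empty((L, 4))
    bases = "ACGT"
    for i in range(L):
        row = [_CLASS_PENALTY[pair_class(bases[q[i]], b)] for b in bases]
        if weighted_span is not None and weighted_span[0] <= i + 1 <= weighted_span[1]:
            row = [weight * p for p in row]
        S[i] = row
    windows = np.lib.stride_tricks.sliding_window_view(t, L)[:, ::-1]
    return S[np.arange(L)[None, :], windows].sum(axis=1)
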