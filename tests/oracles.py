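"""Independent brute-force references the tests check the package against.

These share no code with the implementation: the folding oracle is a plain
O(n^3) interval recursion on Python strings, and the duplex oracle counts
pair classes by literal enumeration.
"""

from __future__ import annotations

from functools import lru_cache

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs (plain interval recursion)."""
    seq = seq.upper().replace("U", "T")

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        # j unpaired, or j paired with some k in [i, j - min_loop - 1]
        result = best(i, j - 1)
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in _PAIRS:
                left = best(i, k - 1) if k > i else 0
                result = max(result, left + 1 + best(k + 1, j - 1))
        return result

    out = best(0, len(seq) - 1) if seq else 0
    best.cache_clear()
    return out


def duplex_penalty_by_enumeration(mirna: str, window: str) -> float:
    """Penalty by literal pair-class counting (mismatch 1, G:U 0.5)."""
    mirna = mirna.upper().replace("U", "T")
    window = window.upper().replace("U", "T")
    assert len(mirna) == len(window)
    penalty = 0.0
    for i, q in enumerate(mirna):
        t = window[len(window) - 1 - i]
        if (q, t) in _WC:
            continue
        penalty += 0.5 if (q, t) in _WOBBLE else 1.0
    return penalty


def weighted_site_penalty_by_enumeration(trigger: str, window: str) -> float:
    """Seed-weighted variant: penalties at trigger positions 2-13 doubled."""
    trigger = trigger.upper().replace("U", "T")
    window = window.upper().replace("U", "T")
    penalty = 0.0
    for i, q in enumerate(trigger):
        t = window[len(window) - 1 - i]
        if (q, t) in _WC:
            p = 0.0
        elif (q, t) in _WOBBLE:
            p = 0.5
        else:
            p = 1.0
        if 2 <= i + 1 <= 13:
            p *= 2
        penalty += p
    return penalty


def perfect_window(mirna: str) -> str:
    """The sense-strand window pairing every miRNA base (reverse complement)."""
    mirna = mirna.upper().replace("U", "T")
    return "".join(_COMP[b] for b in reversed(mirna))
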