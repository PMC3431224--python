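"""Maximum-base-pairing RNA secondary structure (Nussinov dynamic program).

Precursor hairpin assessment only needs the pairing pattern, not free
energies, so the folder maximizes the number of base pairs over the pair
set {A:U, G:C, G:U} with a minimum hairpin loop of 3 nt and no pseudoknots.
Plain pair-count maximization is massively degenerate on natural sequence,
so ties are broken lexicographically toward the structure with the most
stacked pair adjacencies (helix contiguity), which recovers clean stems
instead of scattered long-range pairs; remaining ties resolve by a
deterministic 5'-most traceback.  Both objectives are exact, not greedy:
the fill optimizes ``pairs * B + stacks`` with ``B`` larger than any
possible stack count, on anti-diagonals as vectorized numpy recurrences.

An external thermodynamic folder can be substituted anywhere a fold result
is consumed: any callable ``str -> FoldResult`` is accepted by the hairpin
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import check_nucleotides, encode

MIN_LOOP = 3  # unpaired nt enclosed by any pair
MAX_FOLD_LEN = 1000

# pairable[a, b] for encoded bases (DNA alphabet: U==T): AT, GC, GT
_PAIRABLE = np.zeros((4, 4), dtype=bool)
for _x, _y in [("A", "T"), ("G", "C"), ("G", "T")]:
    _i, _j = "ACGT".index(_x), "ACGT".index(_y)
    _PAIRABLE[_i, _j] = _PAIRABLE[_j, _i] = True

_NEG = np.int32(-(10**8))


@dataclass(frozen=True)
class FoldResult:
    """A nested secondary structure for one sequence.

    ``partner[i]`` is the 0-based partner of position ``i`` or ``None``;
    ``structure`` is the same information in dot-bracket form.
    """

    sequence: str
    structure: str
    paired: int
    partner: tuple[int | None, ...]

    def __post_init__(self) -> None:
        assert len(self.structure) == len(self.sequence)


def fold(sequence: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Fold ``sequence`` to a maximum-base-pairing nested structure.

    Accepts DNA or RNA alphabet; raises ``ValueError`` on other characters
    or on sequences longer than ``MAX_FOLD_LEN``.  Deterministic: identical
    inputs give identical structures.
    """
    seq = check_nucleotides(sequence)
    n = len(seq)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    if n == 0:
        return FoldResult("", "", 0, ())
    s = encode(seq)
    pair_ok = _PAIRABLE[s[:, None], s[None, :]]
    B = np.int32(n + 1)  # > max stacks, so pair count dominates the score

    # W[i, j]: best combined score on s[i..j];
    # V[i, j]: best combined score given (i, j) paired (_NEG if impossible).
    W = np.zeros((n, n), dtype=np.int32)
    V = np.full((n, n), _NEG, dtype=np.int32)
    for d in range(min_loop + 1, n):
        m = n - d
        i_idx = np.arange(m)
        j_idx = i_idx + d
        # closing pair (i, j): stack bonus when (i+1, j-1) is also paired
        inner_w = W[i_idx + 1, j_idx - 1]
        inner_v = V[i_idx + 1, j_idx - 1]
        v = B + np.maximum(inner_w, inner_v + 1)
        V[i_idx, j_idx] = np.where(pair_ok[i_idx, j_idx], v, _NEG)
        # best structure: either close (i, j) or split [i..i+k][i+k+1..j]
        best = V[i_idx, j_idx].copy()
        np.maximum(best, 0, out=best)
        for k in range(d):
            cand = W[i_idx, i_idx + k] + W[i_idx + k + 1, j_idx]
            np.maximum(best, cand, out=best)
        W[i_idx, j_idx] = best

    partner: list[int | None] = [None] * n
    # traceback states: ('W', i, j) unconstrained, ('V', i, j) with (i,j) paired
    stack: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if state == "V":
            partner[i], partner[j] = j, i
            if V[i, j] == B + V[i + 1, j - 1] + 1:
                stack.append(("V", i + 1, j - 1))
            else:
                stack.append(("W", i + 1, j - 1))
            continue
        if W[i, j] == 0:
            continue
        if W[i, j] == V[i, j]:
            stack.append(("V", i, j))
            continue
        for k in range(d_ := j - i):
            if W[i, j] == W[i, i + k] + W[i + k + 1, j]:
                stack.append(("W", i, i + k))
                stack.append(("W", i + k + 1, j))
                break

    paired = sum(1 for p in partner if p is not None)
    assert paired == 2 * (int(W[0, n - 1]) // int(B)) if n > 1 else paired == 0
    structure = "".join(
        "." if p is None else ("(" if p > i else ")") for i, p in enumerate(partner)
    )
    return FoldResult(seq, structure, paired, tuple(partner))
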