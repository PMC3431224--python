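"""Raw-read preprocessing: adapter removal, length window, collapsing.

Adapter-ligated reads carry the insert between a 5' and a 3' adapter.  The
5' adapter is matched as a full-length prefix; the 3' adapter is located as
the left-most, fewest-mismatch occurrence of its prefix downstream of the
insert (the occurrence may be truncated at the read end, so at least
``min_overlap`` adapter bases are required).  Reads missing either adapter
are discarded and counted, never raised.

Collapsing replaces the redundant read multiset with unique sequences plus
counts; "unique" and "total" throughout the package refer to this contrast.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._seq import to_dna

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30


@dataclass(frozen=True)
class UniqueRead:
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.sequence:
            raise ValueError("empty sequence")


@dataclass
class SmallRNALibrary:
    """A collapsed small RNA library for one species/sample."""

    library_id: str
    unique_reads: list[UniqueRead] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.unique_reads)

    @property
    def unique_count(self) -> int:
        return len(self.unique_reads)

    def counts(self) -> dict[str, int]:
        return {r.sequence: r.count for r in self.unique_reads}


@dataclass(frozen=True)
class TrimReport:
    kept: int
    no5: int
    no3: int

    @property
    def raw(self) -> int:
        return self.kept + self.no5 + self.no3


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def trim_adapters(
    reads: list[str],
    adapter5: str,
    adapter3: str,
    min_overlap: int = 8,
    max_mismatch: int = 1,
) -> tuple[list[str], TrimReport]:
    """Extract inserts between the adapters.

    Returns ``(inserts, report)`` with ``report.kept + report.no5 +
    report.no3`` equal to the raw read count.
    """
    if not adapter5 or not adapter3:
        raise ValueError("adapters must be non-empty")
    a5 = to_dna(adapter5)
    a3 = to_dna(adapter3)
    n5 = len(a5)
    inserts: list[str] = []
    no5 = no3 = 0
    for raw in reads:
        read = to_dna(raw)
        if len(read) < n5 or _mismatches(read[:n5], a5) > max_mismatch:
            no5 += 1
            continue
        # best 3' adapter start: fewest mismatches over the available
        # overlap, left-most on ties
        best_pos, best_mm = None, None
        for pos in range(n5, len(read) - min_overlap + 1):
            overlap = min(len(a3), len(read) - pos)
            mm = _mismatches(read[pos : pos + overlap], a3[:overlap])
            if mm <= max_mismatch and (best_mm is None or mm < best_mm):
                best_pos, best_mm = pos, mm
                if mm == 0:
                    break
        if best_pos is None:
            no3 += 1
            continue
        inserts.append(read[n5:best_pos])
    return inserts, TrimReport(kept=len(inserts), no5=no5, no3=no3)


def filter_by_length(
    inserts: list[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[str]:
    """Keep inserts with ``min_len <= len <= max_len`` (both inclusive)."""
    return [s for s in inserts if min_len <= len(s) <= max_len]


def collapse(inserts: list[str], library_id: str = "library") -> SmallRNALibrary:
    """Collapse a read multiset to unique sequences with counts.

    Idempotent in the sense that re-collapsing the unique sequences of an
    already-collapsed library with their counts reproduces it.
    """
    tally = Counter(to_dna(s) for s in inserts)
    uniques = [UniqueRead(seq, c) for seq, c in sorted(tally.items())]
    return SmallRNALibrary(library_id=library_id, unique_reads=uniques)


@dataclass
class SizeDistribution:
    """Per-length (unique, total) counts over 18..28 plus an overflow bin."""

    rows: dict[int, tuple[int, int]]
    overflow: tuple[int, int]

    def mode(self, which: str = "total") -> int:
        idx = 1 if which == "total" else 0
        return max(sorted(self.rows), key=lambda ln: self.rows[ln][idx])


def size_distribution(
    library: SmallRNALibrary, min_len: int = 18, max_len: int = 28
) -> SizeDistribution:
    rows = {ln: [0, 0] for ln in range(min_len, max_len + 1)}
    over = [0, 0]
    for r in library.unique_reads:
        bucket = rows.get(len(r.sequence))
        if bucket is None:
            if len(r.sequence) > max_len:
                over[0] += 1
                over[1] += r.count
            continue
        bucket[0] += 1
        bucket[1] += r.count
    return SizeDistribution(
        rows={ln: (u, t) for ln, (u, t) in rows.items()},
        overflow=(over[0], over[1]),
    )
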