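"""Hierarchical annotation of unique small RNAs.

Each unique read is assigned to exactly one of five categories, in fixed
precedence order mirroring the removal hierarchy of a small RNA census:

1. ``ncRNA``    - degradation products of rRNA/tRNA/snRNA/snoRNA
2. ``miRBase``  - homologs of known mature miRNAs
3. ``mRNA``     - fragments of coding transcripts / unigenes
4. ``repeats``  - repeat-derived siRNAs
5. ``genome``   - genome-matched but otherwise unannotated

Reads hitting nothing are ``unclassified``.  ncRNA and mRNA references are
searched sense-strand only (they are transcripts); repeats and genome on
both strands.  miRBase matching is ungapped and end-to-end with a small
substitution and length tolerance, since conserved-family members differ by
one or two nucleotides across species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._seq import revcomp, to_dna
from .preprocess import SmallRNALibrary

CATEGORY_ORDER = ("ncRNA", "miRBase", "mRNA", "repeats", "genome")
UNCLASSIFIED = "unclassified"

#: categories searched on both strands
_BOTH_STRANDS = {"repeats", "genome"}


@dataclass(frozen=True)
class Hit:
    reference_id: str
    offset: int
    strand: str = "+"
    mismatches: int = 0


class ReferenceSet:
    """One category's reference sequences with a fast substring index."""

    def __init__(self, category: str, sequences: dict[str, str]):
        if category not in CATEGORY_ORDER:
            raise ValueError(f"unknown category {category!r}")
        if not sequences:
            raise ValueError(f"empty reference set for category {category!r}")
        self.category = category
        self.precedence = CATEGORY_ORDER.index(category) + 1
        self.sequences = {name: to_dna(s) for name, s in sequences.items()}
        self.both_strands = category in _BOTH_STRANDS
        # membership scan over a separator-joined concatenation is C-speed
        self._blob = "#" + "#".join(self.sequences.values()) + "#"

    def contains(self, read: str) -> bool:
        read = to_dna(read)
        if read in self._blob:
            return True
        return self.both_strands and revcomp(read) in self._blob

    def find_hits(self, read: str) -> list[Hit]:
        """All per-reference substring occurrences (with strand)."""
        read = to_dna(read)
        hits: list[Hit] = []
        queries = [(read, "+")]
        if self.both_strands:
            queries.append((revcomp(read), "-"))
        for query, strand in queries:
            for name, seq in self.sequences.items():
                start = seq.find(query)
                while start != -1:
                    hits.append(Hit(name, start, strand))
                    start = seq.find(query, start + 1)
        return hits


def match_mirbase(
    read: str,
    matures: dict[str, str],
    max_mismatch: int = 2,
    max_len_diff: int = 2,
) -> list[Hit]:
    """End-to-end ungapped matches of ``read`` against mature miRNAs.

    The shorter of read/reference slides along the longer; mismatches are
    substitutions over the full shorter length.  Hits require
    ``mismatches <= max_mismatch`` and ``|len diff| <= max_len_diff``.
    """
    read = to_dna(read)
    hits: list[Hit] = []
    for name, ref in matures.items():
        ref = to_dna(ref)
        diff = len(read) - len(ref)
        if abs(diff) > max_len_diff:
            continue
        short, long_ = (read, ref) if diff <= 0 else (ref, read)
        best = None
        for off in range(len(long_) - len(short) + 1):
            mm = sum(1 for a, b in zip(short, long_[off : off + len(short)]) if a != b)
            if mm <= max_mismatch and (best is None or mm < best[1]):
                best = (off, mm)
        if best is not None:
            hits.append(Hit(name, best[0], "+", best[1]))
    return hits


def match_read(
    read: str,
    refset: ReferenceSet | dict[str, str],
    max_mismatch: int = 2,
    category: str | None = None,
) -> list[Hit]:
    """Hits of one read in one reference set (see module docstring rules)."""
    if isinstance(refset, dict):
        refset = ReferenceSet(category or "genome", refset)
    if refset.category == "miRBase":
        return match_mirbase(read, refset.sequences, max_mismatch=max_mismatch)
    return refset.find_hits(read)


@dataclass
class AnnotationSummary:
    """Per-category (unique, total) tallies; Table-1 shaped."""

    library_id: str
    categories: dict[str, tuple[int, int]]
    unclassified: tuple[int, int] = (0, 0)

    @property
    def total(self) -> tuple[int, int]:
        u = sum(v[0] for v in self.categories.values())
        t = sum(v[1] for v in self.categories.values())
        return (u, t)


def classify_library(
    library: SmallRNALibrary,
    references: dict[str, ReferenceSet],
    max_mirna_mismatch: int = 2,
) -> tuple[dict[str, str], AnnotationSummary]:
    """Assign every unique read its highest-precedence category.

    ``references`` must supply all five categories.  Returns the per-read
    category map and the summary; category unique/total tallies plus the
    unclassified ones partition the library exactly.
    """
    missing = [c for c in CATEGORY_ORDER if c not in references]
    if missing:
        raise ValueError(f"missing reference sets: {missing}")
    mirbase = references["miRBase"].sequences
    assignment: dict[str, str] = {}
    tallies = {c: [0, 0] for c in CATEGORY_ORDER}
    unclassified = [0, 0]
    for r in library.unique_reads:
        category = None
        for cat in CATEGORY_ORDER:
            if cat == "miRBase":
                if match_mirbase(r.sequence, mirbase, max_mismatch=max_mirna_mismatch):
                    category = cat
                    break
            elif references[cat].contains(r.sequence):
                category = cat
                break
        if category is None:
            assignment[r.sequence] = UNCLASSIFIED
            unclassified[0] += 1
            unclassified[1] += r.count
        else:
            assignment[r.sequence] = category
            tallies[category][0] += 1
            tallies[category][1] += r.count
    return assignment, AnnotationSummary(
        library_id=library.library_id,
        categories={c: (u, t) for c, (u, t) in tallies.items()},
        unclassified=(unclassified[0], unclassified[1]),
    )


@dataclass(frozen=True)
class FamilyAssignment:
    sequence: str
    family: str
    reference_id: str
    mismatches: int


_FAMILY_RE = re.compile(r"^(?:[a-z]{3,4}-)?mir(\d+)", re.IGNORECASE)

#: families merged by default when requested (near-identical mature sequences)
DEFAULT_MERGES = {"miR165": "miR165/166", "miR166": "miR165/166",
                  "miR170": "miR170/171", "miR171": "miR170/171"}


def family_name(reference_id: str, merge: bool = False) -> str:
    """Family from a miRBase-style id: ``ath-miR156a`` -> ``miR156``."""
    m = _FAMILY_RE.match(reference_id)
    if not m:
        raise ValueError(f"cannot parse family from id {reference_id!r}")
    fam = f"miR{m.group(1)}"
    if merge:
        fam = DEFAULT_MERGES.get(fam, fam)
    return fam


def assign_family(
    read: str,
    matures: dict[str, str],
    max_mismatch: int = 2,
    merge_families: bool = False,
) -> FamilyAssignment:
    """Best-family assignment for a read already classified ``miRBase``.

    Minimum mismatches win; ties broken by smaller length difference, then
    lexicographically smaller reference id.
    """
    read = to_dna(read)
    hits = match_mirbase(read, matures, max_mismatch=max_mismatch)
    if not hits:
        raise ValueError("read has no qualifying miRBase hit; misclassified input")
    best = min(
        hits,
        key=lambda h: (
            h.mismatches,
            abs(len(read) - len(to_dna(matures[h.reference_id]))),
            h.reference_id,
        ),
    )
    return FamilyAssignment(
        sequence=read,
        family=family_name(best.reference_id, merge=merge_families),
        reference_id=best.reference_id,
        mismatches=best.mismatches,
    )
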