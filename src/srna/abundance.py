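"""Abundance normalization (tpm), expression tiers, family profiles.

Counts are normalized to transcripts per million (tpm), ``count /
library_total * 1e6``, with the preprocessed (length-filtered) library total
as denominator.  Families are then binned into the three descriptive tiers
used for conserved miRNAs: abundant (> 1000 tpm), moderate (100-1000 tpm,
inclusive) and low (< 100 tpm).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotate import FamilyAssignment
from .preprocess import SmallRNALibrary

TIER_ABUNDANT = "abundant"
TIER_MODERATE = "moderate"
TIER_LOW = "low"

#: pseudo-tpm replacing zeros in fold-change ratios
PSEUDO_TPM = 0.5


def tpm(count: float, library_total: int) -> float:
    """Reads-per-million normalization of one count."""
    if library_total <= 0:
        raise ZeroDivisionError("library_total must be positive for tpm")
    if not 0 <= count <= library_total:
        raise ValueError("count must lie in [0, library_total]")
    return count / library_total * 1_000_000


def tier(tpm_value: float) -> str:
    """Expression tier of a tpm value; 1000 is moderate, 100 is moderate."""
    if tpm_value < 0:
        raise ValueError("tpm must be >= 0")
    if tpm_value > 1000:
        return TIER_ABUNDANT
    if tpm_value >= 100:
        return TIER_MODERATE
    return TIER_LOW


@dataclass
class FamilyProfile:
    family: str
    members: dict[str, int]  # variant sequence -> raw count
    raw_count: int
    tpm: float
    tier: str
    share: float  # fraction of miRBase-category total reads


def family_profile(
    library: SmallRNALibrary,
    assignments: list[FamilyAssignment],
) -> list[FamilyProfile]:
    """Aggregate per-family counts/tpm/tier, sorted by tpm descending.

    ``assignments`` are the library's miRBase-classified unique reads;
    shares are fractions of the summed miRBase-category counts.
    """
    counts = library.counts()
    per_family: dict[str, dict[str, int]] = {}
    for a in assignments:
        per_family.setdefault(a.family, {})[a.sequence] = counts[a.sequence]
    mirna_total = sum(sum(m.values()) for m in per_family.values())
    profiles = []
    for fam, members in per_family.items():
        raw = sum(members.values())
        t = tpm(raw, library.total_reads)
        profiles.append(
            FamilyProfile(
                family=fam,
                members=members,
                raw_count=raw,
                tpm=t,
                tier=tier(t),
                share=raw / mirna_total if mirna_total else 0.0,
            )
        )
    profiles.sort(key=lambda p: (-p.tpm, p.family))
    return profiles


def compare_libraries(
    profiles: dict[str, list[FamilyProfile]],
    flag_ratio: float = 10.0,
) -> pd.DataFrame:
    """Cross-library family tpm table with max/min fold change.

    Zero tpm cells are replaced by ``PSEUDO_TPM`` before forming ratios so
    fold changes stay finite while preserving ordering.  Families whose
    max/min ratio reaches ``flag_ratio`` are flagged.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 libraries to compare")
    libs = list(profiles)
    families = sorted({p.family for ps in profiles.values() for p in ps})
    table = pd.DataFrame(0.0, index=families, columns=libs)
    for lib, ps in profiles.items():
        for p in ps:
            table.loc[p.family, lib] = p.tpm
    padded = table.where(table > 0, PSEUDO_TPM)
    table["max_min_ratio"] = padded.max(axis=1) / padded.min(axis=1)
    table["flagged"] = table["max_min_ratio"] >= flag_ratio
    return table
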