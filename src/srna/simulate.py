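"""Synthetic small-RNA study generator.

Builds a toy genome with embedded features (conserved and novel miRNA
precursor hairpins, a TAS3-like locus with dual trigger-complementary sites,
tRNA/rRNA decoys, an interspersed repeat, mRNAs), the matching category
reference sets, and adapter-ligated reads whose statistical structure
mirrors a plant small RNA library: a dominant 24-nt size class, a highly
redundant 19-nt class of 5' tRNA fragments, and high-redundancy mature
miRNAs at 20-22 nt.  Every embedded feature and every simulated read is
recorded in machine-readable truth tables so downstream calls can be scored
against ground truth.

Reads per library are drawn multinomially over feature classes and
uniformly within a class (mature miRNAs optionally weighted by family).
Identical spec + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import random_seq, revcomp, to_dna
from .fold import fold
from .hairpin import evaluate_hairpin

#: real mature miR390 (miRBase dialect), the TAS3 trigger; DNA alphabet
MIR390 = to_dna("AAGCUCAGGAGGGAUAGCGCC")

ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

FEATURE_CLASSES = (
    "mirna_precursor",
    "mature_mirna",
    "tas_locus",
    "trna",
    "rrna",
    "repeat",
    "background",
)

READ_CLASSES = (
    "conserved_mirna",
    "novel_mirna",
    "trna",
    "rrna",
    "repeat",
    "mrna",
    "background",
    "tasirna",
)

#: conserved families embedded by default (miR390 uses the real sequence)
CONSERVED_FAMILIES = (
    "miR156", "miR159", "miR164", "miR166", "miR167", "miR168", "miR172", "miR390",
)

GENUS_MAP = {
    "bottle_gourd": "Lagenaria",
    "moschata": "Cucurbita",
    "pepo": "Cucurbita",
    "watermelon": "Citrullus",
}


class PlacementError(RuntimeError):
    """A feature could not be placed without overlap."""


class ConfigurationError(ValueError):
    """Abundance model requests reads from an absent feature class."""


@dataclass(frozen=True)
class TruthRecord:
    feature_id: str
    feature_class: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    payload: str
    attrs: tuple[tuple[str, str], ...] = ()

    def attr(self, key: str, default=None):
        return dict(self.attrs).get(key, default)


def _default_abundance() -> dict[str, float]:
    return {
        "conserved_mirna": 2500,
        "novel_mirna": 120,
        "trna": 2000,
        "rrna": 850,
        "repeat": 2000,
        "mrna": 700,
        "background": 2300,
        "tasirna": 150,
    }


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome + library.

    ``abundance_model`` maps read class to expected read count; realized
    counts are one multinomial draw of ``read_count`` reads over the
    normalized weights.
    """

    genome_length: int = 60_000
    n_mirna_precursors: int = 10  # novel precursors
    n_tas_loci: int = 1
    n_trna_decoys: int = 4
    n_rrna_decoys: int = 2
    n_repeat_copies: int = 12
    abundance_model: dict[str, float] = field(default_factory=_default_abundance)
    read_count: int = 10_000
    adapter5: str = ADAPTER5
    adapter3: str = ADAPTER3
    seed: int = 0
    # study-shape knobs beyond the core contract
    n_conserved_families: int = 8
    n_mrna: int = 6
    n_background_loci: int = 100
    tas_spacing: int = 250
    family_weights: dict[str, float] | None = None
    novel_emitted: tuple[str, ...] | None = None  # None = all novel matures
    mirna_variant_prob: float = 0.15
    adapter3_truncate_prob: float = 0.3
    #: (index, n_parts): which slice of the feature-free space this library's
    #: background siRNA loci come from; species have disjoint background loci
    background_partition: tuple[int, int] = (0, 1)

    def validate(self) -> None:
        counts = [
            self.genome_length, self.n_mirna_precursors, self.n_tas_loci,
            self.n_trna_decoys, self.n_rrna_decoys, self.n_repeat_copies,
            self.read_count,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if any(w < 0 for w in self.abundance_model.values()):
            raise ValueError("abundance weights must be >= 0")
        if not (200 <= self.tas_spacing <= 300) and self.n_tas_loci:
            # permitted: out-of-range spacing builds negative controls
            pass


class GenomeBuilder:
    """Mutable genome under construction with non-overlap bookkeeping."""

    PAD = 10  # clearance between features
    MAX_TRIES = 1000

    def __init__(self, length: int, rng: np.random.Generator, contig: str = "chr1"):
        self.contig = contig
        self.rng = rng
        self.chars = list(random_seq(rng, length))
        self.occupied: list[tuple[int, int]] = []
        self.truth: list[TruthRecord] = []

    def _free(self, start: int, end: int) -> bool:
        return all(end + self.PAD <= s or start >= e + self.PAD for s, e in self.occupied)

    def place(
        self,
        sequence: str,
        feature_id: str,
        feature_class: str,
        attrs: tuple[tuple[str, str], ...] = (),
        clearance: int = 0,
    ) -> TruthRecord:
        """Place a feature at a random free position.

        ``clearance`` reserves that many extra nt on each side against
        later placements (precursors keep their fold flanks feature-free).
        """
        n = len(sequence)
        if n > len(self.chars):
            raise PlacementError(f"{feature_class} longer than genome")
        for _ in range(self.MAX_TRIES):
            start = int(self.rng.integers(0, len(self.chars) - n + 1))
            zone = (max(0, start - clearance), min(len(self.chars), start + n + clearance))
            if self._free(*zone):
                break
        else:
            raise PlacementError(
                f"could not place feature of class {feature_class!r} without overlap"
            )
        self._undo = (zone, self.chars[start : start + n])
        self.chars[start : start + n] = list(sequence)
        self.occupied.append(zone)
        rec = TruthRecord(
            feature_id, feature_class, self.contig, start, start + n, "+",
            sequence, attrs,
        )
        self.truth.append(rec)
        return rec

    def rollback(self, rec: TruthRecord) -> None:
        """Undo the most recent :meth:`place` call."""
        zone, original = self._undo
        self.chars[rec.start : rec.end] = original
        assert self.occupied[-1] == zone
        self.occupied.pop()
        assert self.truth[-1] is rec
        self.truth.pop()

    def record_sub(
        self,
        parent: TruthRecord,
        offset: int,
        length: int,
        feature_id: str,
        feature_class: str,
        attrs: tuple[tuple[str, str], ...] = (),
    ) -> TruthRecord:
        start = parent.start + offset
        rec = TruthRecord(
            feature_id, feature_class, self.contig, start, start + length, "+",
            parent.payload[offset : offset + length], attrs,
        )
        self.truth.append(rec)
        return rec

    def sequence(self) -> str:
        return "".join(self.chars)

    def free_intervals(self, min_len: int = 30) -> list[tuple[int, int]]:
        """Background intervals (with clearance) not covered by any feature."""
        spans = sorted(self.occupied)
        out, cursor = [], 0
        for s, e in spans:
            if s - self.PAD - cursor >= min_len:
                out.append((cursor, s - self.PAD))
            cursor = max(cursor, e + self.PAD)
        if len(self.chars) - cursor >= min_len:
            out.append((cursor, len(self.chars)))
        return out


# ---------------------------------------------------------------------------
# feature construction


def hairpin_sequence(
    rng: np.random.Generator,
    mature: str,
    arm_pad: int = 6,
    loop_len: int = 9,
    bulges: int = 0,
    mature_arm: str = "5p",
) -> tuple[str, int]:
    """A stem-loop precursor embedding ``mature`` on one arm.

    The opposing arm is the reverse complement of the mature-bearing arm
    with up to ``bulges`` single-nucleotide insertions; the terminal loop
    is >= 8 nt.  Returns ``(precursor, mature_offset)``.
    """
    if not 20 <= len(mature) <= 24:
        raise ValueError("mature length must be 20-24 nt")
    if loop_len < 8:
        raise ValueError("terminal loop must be >= 8 nt")
    core = random_seq(rng, arm_pad) + to_dna(mature) + random_seq(rng, arm_pad)
    opposite = list(revcomp(core))
    for _ in range(bulges):
        pos = int(rng.integers(1, len(opposite) - 1))
        opposite.insert(pos, random_seq(rng, 1))
    loop = random_seq(rng, loop_len)
    if mature_arm == "5p":
        precursor = core + loop + "".join(opposite)
        offset = arm_pad
    elif mature_arm == "3p":
        precursor = "".join(opposite) + loop + core
        offset = len(opposite) + loop_len + arm_pad
    else:
        raise ValueError("mature_arm must be '5p' or '3p'")
    return precursor, offset


def embed_hairpin(
    builder: GenomeBuilder,
    mature: str,
    feature_id: str,
    bulges: int = 0,
    mature_arm: str = "5p",
    kind: str = "novel",
    family: str = "",
    max_tries: int = 25,
) -> TruthRecord:
    """Place a precursor whose fold passes the hairpin criteria in context.

    Construction and placement are retried with fresh pads/loops/positions
    until the mature read, folded within its genomic flank windows, passes
    :func:`srna.hairpin.evaluate_hairpin`; the flank windows are reserved
    against later placements so the validated structure stays valid.
    """
    from .hairpin import DEFAULT_FLANK_WINDOW, extract_flanks

    mature = to_dna(mature)
    attrs = (("kind", kind), ("family", family), ("mature_arm", mature_arm))
    for _ in range(max_tries):
        precursor, offset = hairpin_sequence(
            builder.rng, mature, bulges=bulges, mature_arm=mature_arm
        )
        if not evaluate_hairpin(fold(precursor), offset, len(mature)).passed:
            continue
        rec = builder.place(
            precursor, feature_id, "mirna_precursor", attrs,
            clearance=DEFAULT_FLANK_WINDOW,
        )
        gseq = builder.sequence()
        locus = (rec.start + offset, rec.start + offset + len(mature), "+")
        if any(
            evaluate_hairpin(fold(flank), off, len(mature)).passed
            for flank, off in extract_flanks(gseq, locus)
        ):
            builder.record_sub(
                rec, offset, len(mature), f"{feature_id}_mature", "mature_mirna", attrs
            )
            return rec
        builder.rollback(rec)
    raise PlacementError(f"could not engineer a passing hairpin for {feature_id}")


def _mutate_site(window: list[str], trigger: str, pos1: int, kind: str) -> None:
    """Introduce a mismatch or G:U wobble at trigger position ``pos1`` (1-based)."""
    L = len(trigger)
    w_idx = L - pos1
    q = trigger[pos1 - 1]
    if kind == "wobble":
        if q == "G":
            window[w_idx] = "T"
        elif q == "T":
            window[w_idx] = "G"
        else:
            raise ValueError(f"no wobble partner for trigger base {q}")
    else:
        complement = {"A": "T", "T": "A", "G": "C", "C": "G"}[q]
        wobble = {"G": "T", "T": "G"}.get(q)
        choices = [b for b in "ACGT" if b not in {complement, wobble}]
        window[w_idx] = choices[0]


def tas3_locus_sequence(
    rng: np.random.Generator, trigger: str, spacing: int
) -> tuple[str, dict[str, int], str]:
    """Build ``site5 + spacer + site3`` with phased tandem 21-nt repeats.

    The 5' site carries 2 mismatches and one G:U wobble within trigger
    positions 9-12 (non-cleavable); the 3' site is perfectly complementary.
    Tandem repeats in the spacer are laid on the 21-nt phase defined by the
    cleavage point of the 3' site, truncated at the spacer limits.
    """
    trigger = to_dna(trigger)
    L = len(trigger)
    site3 = revcomp(trigger)
    site5_chars = list(revcomp(trigger))
    wobble_candidates = [p for p in (9, 10, 11, 12) if trigger[p - 1] in "GT"]
    if not wobble_candidates:
        raise ValueError("trigger has no wobble-capable base at positions 9-12")
    wob = wobble_candidates[0]
    mm = [p for p in (9, 10, 11, 12) if p != wob][:2]
    _mutate_site(site5_chars, trigger, wob, "wobble")
    for p in mm:
        _mutate_site(site5_chars, trigger, p, "mismatch")
    site5 = "".join(site5_chars)

    spacer = list(random_seq(rng, spacing))
    unit = random_seq(rng, 21)
    # cleavage point: between the spacer-side bases facing trigger 10/11
    origin_local = L + spacing + (L - 10)  # index just 3' of the cut in the locus
    spacer_start, spacer_end = L, L + spacing
    j = 1
    while origin_local - 21 * j + 21 > spacer_start:
        start = origin_local - 21 * j
        lo = max(start, spacer_start)
        hi = min(start + 21, spacer_end)
        if hi > lo:
            spacer[lo - spacer_start : hi - spacer_start] = list(
                unit[lo - start : hi - start]
            )
        j += 1
    locus = site5 + "".join(spacer) + site3
    layout = {
        "site5_start": 0,
        "site5_end": L,
        "site3_start": L + spacing,
        "site3_end": L + spacing + L,
        "origin": origin_local,
        "spacing": spacing,
    }
    return locus, layout, unit


def embed_tas3(
    builder: GenomeBuilder,
    trigger: str,
    spacing: int,
    feature_id: str = "tas3_1",
) -> TruthRecord:
    """Embed a TAS3-like locus; spacing outside 200-300 nt builds a negative
    control that the locus detector must reject."""
    locus, layout, unit = tas3_locus_sequence(builder.rng, to_dna(trigger), spacing)
    attrs = tuple(
        [(k, str(v)) for k, v in layout.items()]
        + [("repeat_unit", unit), ("trigger", to_dna(trigger))]
    )
    return builder.place(locus, feature_id, "tas_locus", attrs)


def tas_register_starts(rec: TruthRecord) -> list[int]:
    """Locus-local 5' start offsets of the full in-spacer phased registers."""
    origin = int(rec.attr("origin"))
    spacer_start = int(rec.attr("site5_end"))
    spacer_end = int(rec.attr("site3_start"))
    starts = []
    j = 1
    while origin - 21 * j >= spacer_start:
        start = origin - 21 * j
        if start + 21 <= spacer_end:
            starts.append(start)
        j += 1
    return starts


# ---------------------------------------------------------------------------
# genome + references


@dataclass
class SyntheticWorld:
    """A genome, its truth table, references, and family definitions."""

    spec: SyntheticSpec
    genome: dict[str, str]
    truth: list[TruthRecord]
    references: dict[str, dict[str, str]]
    families: dict[str, list[str]]  # family -> member reference ids

    @property
    def contig(self) -> str:
        return next(iter(self.genome))


def make_genome(spec: SyntheticSpec) -> tuple[dict[str, str], list[TruthRecord]]:
    """Genome with all requested features at non-overlapping positions."""
    spec.validate()
    world = build_world(spec)
    return world.genome, world.truth


def build_world(spec: SyntheticSpec) -> SyntheticWorld:
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    builder = GenomeBuilder(spec.genome_length, rng)

    # conserved families: 1-2 members each; miR390 keeps its real sequence
    families: dict[str, list[str]] = {}
    mirbase: dict[str, str] = {}
    fam_names = list(CONSERVED_FAMILIES[: spec.n_conserved_families])
    for fam in fam_names:
        if fam == "miR390":
            members = [MIR390]
        else:
            base = random_seq(rng, 21)
            members = [base]
            if rng.random() < 0.5:
                variant = list(base)
                pos = int(rng.integers(0, len(variant)))
                variant[pos] = "ACGT"["ACGT".index(variant[pos]) - 1]
                members.append("".join(variant))
        ids = []
        for i, mat in enumerate(members):
            ref_id = f"cuc-{fam}{'ab'[i]}"
            mirbase[ref_id] = mat
            ids.append(ref_id)
            embed_hairpin(
                builder, mat, f"{fam}{'ab'[i]}_precursor",
                bulges=int(rng.integers(0, 2)),
                mature_arm="5p" if rng.random() < 0.5 else "3p",
                kind="conserved", family=fam,
            )
        families[fam] = ids

    for i in range(spec.n_mirna_precursors):
        mature = random_seq(rng, 21 if i % 2 == 0 else 22)
        embed_hairpin(
            builder, mature, f"novel_{i + 1}",
            bulges=int(rng.integers(0, 3)),
            mature_arm="5p" if rng.random() < 0.5 else "3p",
            kind="novel",
        )

    tas_records = []
    for i in range(spec.n_tas_loci):
        tas_records.append(
            embed_tas3(builder, MIR390, spec.tas_spacing, f"tas3_{i + 1}")
        )

    ncrna: dict[str, str] = {}
    for i in range(spec.n_trna_decoys):
        rec = builder.place(random_seq(rng, 75), f"trna_{i + 1}", "trna")
        ncrna[rec.feature_id] = rec.payload
    for i in range(spec.n_rrna_decoys):
        rec = builder.place(random_seq(rng, 120), f"rrna_{i + 1}", "rrna")
        ncrna[rec.feature_id] = rec.payload

    repeats: dict[str, str] = {}
    if spec.n_repeat_copies:
        consensus = random_seq(rng, 150)
        repeats["repeat_consensus"] = consensus
        for i in range(spec.n_repeat_copies):
            builder.place(consensus, f"repeat_copy_{i + 1}", "repeat")

    mrna: dict[str, str] = {}
    for i in range(spec.n_mrna):
        seq = list(random_seq(rng, 400))
        # two transcripts carry engineered miRNA target sites
        if i == 0 and "miR156" in families:
            site = revcomp(mirbase[families["miR156"][0]])
            seq[150 : 150 + len(site)] = list(site)
        if i == 1 and "miR159" in families:
            site = list(revcomp(mirbase[families["miR159"][0]]))
            # 3 mismatches + 1 wobble: right at the conventional 3.5 cutoff
            trigger = mirbase[families["miR159"][0]]
            wcand = [
                p for p in range(1, 22)
                if trigger[p - 1] in "GT" and p not in (7, 12, 16)
            ]
            _mutate_site(site, trigger, wcand[0], "wobble")
            for p in (7, 12, 16):
                _mutate_site(site, trigger, p, "mismatch")
            seq[200 : 200 + len(site)] = list(site)
        rec = builder.place("".join(seq), f"mrna_{i + 1}", "mrna")
        mrna[rec.feature_id] = rec.payload
    for rec in tas_records:
        mrna[rec.feature_id.upper()] = rec.payload  # TAS unigene transcript

    genome_seq = builder.sequence()
    references = {
        "ncRNA": ncrna,
        "miRBase": mirbase,
        "mRNA": mrna,
        "repeats": repeats if repeats else {"repeat_consensus": "N" * 10},
        "genome": {builder.contig: genome_seq},
    }
    return SyntheticWorld(
        spec=spec,
        genome={builder.contig: genome_seq},
        truth=builder.truth,
        references=references,
        families=families,
    )


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genome: dict[str, str],
    truth: list[TruthRecord],
    spec: SyntheticSpec,
    library_id: str = "library",
) -> tuple[list[str], pd.DataFrame]:
    """Adapter-ligated reads drawn under ``spec.abundance_model``.

    Returns ``(reads, read_truth)`` where ``read_truth`` has one row per
    read: read index, feature class, source feature id and the exact insert.
    """
    rng = np.random.default_rng(spec.seed)
    contig = next(iter(genome))
    gseq = genome[contig]

    by_class: dict[str, list[TruthRecord]] = {}
    for rec in truth:
        by_class.setdefault(rec.feature_class, []).append(rec)

    matures = by_class.get("mature_mirna", [])
    conserved = [r for r in matures if r.attr("kind") == "conserved"]
    novel = [r for r in matures if r.attr("kind") == "novel"]
    if spec.novel_emitted is not None:
        wanted = set(spec.novel_emitted)
        novel = [r for r in novel if r.feature_id.removesuffix("_mature") in wanted]
    tas = by_class.get("tas_locus", [])
    mrna_recs = by_class.get("mrna", []) or [
        r for r in truth if r.feature_class == "mrna"
    ]

    sources = {
        "conserved_mirna": conserved,
        "novel_mirna": novel,
        "trna": by_class.get("trna", []),
        "rrna": by_class.get("rrna", []),
        "repeat": by_class.get("repeat", []),
        "mrna": mrna_recs,
        "tasirna": tas,
        "background": [None],  # sampled from free space below
    }
    model = {c: w for c, w in spec.abundance_model.items() if w > 0}
    for cls in model:
        if cls not in READ_CLASSES:
            raise ConfigurationError(f"unknown read class {cls!r}")
        if cls != "background" and not sources[cls]:
            raise ConfigurationError(
                f"abundance model requests class {cls!r} but no such feature exists"
            )

    classes = sorted(model)
    weights = np.array([model[c] for c in classes], dtype=float)
    counts = rng.multinomial(spec.read_count, weights / weights.sum()) if classes else []

    # background pool: discrete siRNA-producing loci in feature-free space
    part, n_parts = spec.background_partition
    free = [
        iv
        for i, iv in enumerate(_free_intervals_from_truth(truth, len(gseq)))
        if i % n_parts == part
    ]
    bg_pool: list[int] = []
    if "background" in model:
        if not free:
            raise ConfigurationError("no feature-free space for background reads")
        lens = np.array([e - s - 24 for s, e in free], dtype=float)
        lens = np.maximum(lens, 0)
        for _ in range(spec.n_background_loci):
            k = int(rng.choice(len(free), p=lens / lens.sum()))
            s, e = free[k]
            bg_pool.append(int(rng.integers(s, e - 24 + 1)))

    fam_weights = None
    if spec.family_weights is not None and conserved:
        fam_weights = np.array(
            [spec.family_weights.get(r.attr("family"), 0.0) for r in conserved]
        )
        if fam_weights.sum() <= 0:
            raise ConfigurationError("family_weights assign zero weight everywhere")
        fam_weights = fam_weights / fam_weights.sum()

    reads: list[str] = []
    rows: list[dict] = []
    for cls, n_cls in zip(classes, counts):
        for _ in range(int(n_cls)):
            insert, feature_id = _draw_insert(
                rng, cls, sources, gseq, bg_pool, fam_weights, spec
            )
            reads.append(_ligate(rng, insert, spec))
            rows.append({"read_class": cls, "feature_id": feature_id, "insert": insert})
    # deterministic shuffle so classes are interleaved as in a real run
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    rows = [rows[i] for i in order]
    df = pd.DataFrame(rows, columns=["read_class", "feature_id", "insert"])
    df.insert(0, "read_id", [f"{library_id}_read_{i}" for i in range(len(df))])
    return reads, df


def _free_intervals_from_truth(
    truth: list[TruthRecord], genome_len: int, pad: int = 10, min_len: int = 30
) -> list[tuple[int, int]]:
    spans = sorted((r.start, r.end) for r in truth if r.feature_class != "mature_mirna")
    out, cursor = [], 0
    for s, e in spans:
        if s - pad - cursor >= min_len:
            out.append((cursor, s - pad))
        cursor = max(cursor, e + pad)
    if genome_len - cursor >= min_len:
        out.append((cursor, genome_len))
    return out


def _draw_insert(rng, cls, sources, gseq, bg_pool, fam_weights, spec):
    if cls == "background":
        pos = bg_pool[int(rng.integers(0, len(bg_pool)))]
        length = int(rng.choice([24, 23, 22], p=[0.7, 0.2, 0.1]))
        return gseq[pos : pos + length], f"background_{pos}"
    recs = sources[cls]
    if cls == "conserved_mirna" and fam_weights is not None:
        rec = recs[int(rng.choice(len(recs), p=fam_weights))]
    else:
        rec = recs[int(rng.integers(0, len(recs)))]
    if cls in ("conserved_mirna", "novel_mirna"):
        insert = rec.payload
        if cls == "conserved_mirna" and rng.random() < spec.mirna_variant_prob:
            if rng.random() < 0.5 and rec.end < len(gseq):
                insert = gseq[rec.start : rec.end + 1]  # 3' templated extension
            else:
                insert = insert[:-1]
        return insert, rec.feature_id
    if cls == "trna":
        return rec.payload[:19], rec.feature_id
    if cls == "rrna" or cls == "repeat":
        start = int(rng.integers(0, len(rec.payload) - 24 + 1))
        return rec.payload[start : start + 24], rec.feature_id
    if cls == "mrna":
        length = int(rng.integers(21, 25))
        start = int(rng.integers(0, len(rec.payload) - length + 1))
        return rec.payload[start : start + length], rec.feature_id
    if cls == "tasirna":
        starts = tas_register_starts(rec)
        s = starts[int(rng.integers(0, len(starts)))]
        return rec.payload[s : s + 21], rec.feature_id
    raise ConfigurationError(f"unknown read class {cls!r}")


def _ligate(rng, insert: str, spec: SyntheticSpec) -> str:
    a3 = spec.adapter3
    if rng.random() < spec.adapter3_truncate_prob:
        a3 = a3[: int(rng.integers(8, len(a3) + 1))]
    return spec.adapter5 + insert + a3


# ---------------------------------------------------------------------------
# truth serialization


def write_truth_tsv(path: str | Path, truth: list[TruthRecord]) -> None:
    rows = []
    for r in truth:
        rows.append(
            {
                "feature_id": r.feature_id,
                "feature_class": r.feature_class,
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "payload": r.payload,
                "attrs": ";".join(f"{k}={v}" for k, v in r.attrs),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_gff3(path: str | Path, truth: list[TruthRecord]) -> None:
    """Truth features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in truth:
            attrs = ";".join(
                [f"ID={r.feature_id}", f"feature_class={r.feature_class}"]
                + [f"{k}={v}" for k, v in r.attrs if k != "repeat_unit"]
            )
            fh.write(
                f"{r.contig}\tsrna_sim\t{r.feature_class}\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# the default four-library study preset


@dataclass
class Preset:
    world: SyntheticWorld
    libraries: dict[str, tuple[list[str], pd.DataFrame]]
    genus_map: dict[str, str]
    novel_emission: dict[str, tuple[str, ...]]


#: which novel matures each preset library expresses (cross-genus structure:
#: novel_1..novel_4 span >= 2 genera; novel_5..novel_10 stay within one)
NOVEL_EMISSION = {
    "bottle_gourd": ("novel_1", "novel_2", "novel_3", "novel_4", "novel_8"),
    "moschata": ("novel_1", "novel_2", "novel_3", "novel_4", "novel_5", "novel_6",
                 "novel_7", "novel_9"),
    "pepo": ("novel_1", "novel_2", "novel_3", "novel_4", "novel_5", "novel_6",
             "novel_7"),
    "watermelon": ("novel_1", "novel_4", "novel_10"),
}

_BASE_FAMILY_WEIGHTS = {
    "miR156": 0.4, "miR159": 5, "miR164": 6, "miR166": 75, "miR167": 4,
    "miR168": 5, "miR172": 3, "miR390": 1.2,
}

_PRESET_MODELS = {
    "bottle_gourd": {
        "conserved_mirna": 3000, "novel_mirna": 120, "trna": 1300, "rrna": 900,
        "repeat": 2000, "mrna": 700, "background": 2300, "tasirna": 150,
    },
    "moschata": {
        "conserved_mirna": 1700, "novel_mirna": 110, "trna": 2600, "rrna": 800,
        "repeat": 1900, "mrna": 700, "background": 2200, "tasirna": 90,
    },
    "pepo": {
        "conserved_mirna": 1800, "novel_mirna": 110, "trna": 2500, "rrna": 800,
        "repeat": 1900, "mrna": 700, "background": 2200, "tasirna": 120,
    },
    "watermelon": {
        "conserved_mirna": 2400, "novel_mirna": 60, "trna": 3100, "rrna": 800,
        "repeat": 1800, "mrna": 700, "background": 2100, "tasirna": 450,
    },
}

_PRESET_FAMILY_WEIGHTS = {
    "bottle_gourd": {**_BASE_FAMILY_WEIGHTS, "miR390": 1.2},
    "moschata": {**_BASE_FAMILY_WEIGHTS, "miR390": 1.0},
    "pepo": {**_BASE_FAMILY_WEIGHTS, "miR390": 1.4},
    "watermelon": {
        "miR156": 20, "miR159": 5, "miR164": 8, "miR166": 15, "miR167": 30,
        "miR168": 2, "miR172": 8, "miR390": 4,
    },
}


def four_library_preset(seed: int = 0) -> Preset:
    """The default synthetic study: one genome, four species libraries.

    Reproduces the qualitative library contrasts the pipeline is built to
    resolve: 24-nt modal size class, redundant 19-nt tRNA fragments, one
    dominant miRNA family in three libraries with a ~50x family boost in the
    fourth, four cross-genus novel matures among ten embedded precursors,
    and tasiRNA output proportional to the trigger family abundance.
    """
    base = SyntheticSpec(seed=seed)
    world = build_world(base)
    libraries = {}
    for i, lib in enumerate(GENUS_MAP):
        lib_spec = dataclasses.replace(
            base,
            read_count=sum(_PRESET_MODELS[lib].values()),
            abundance_model=dict(_PRESET_MODELS[lib]),
            family_weights=dict(_PRESET_FAMILY_WEIGHTS[lib]),
            novel_emitted=NOVEL_EMISSION[lib],
            background_partition=(i, len(GENUS_MAP)),
            seed=seed + i + 1,
        )
        libraries[lib] = simulate_reads(world.genome, world.truth, lib_spec, lib)
    return Preset(
        world=world,
        libraries=libraries,
        genus_map=dict(GENUS_MAP),
        novel_emission=dict(NOVEL_EMISSION),
    )


def make_qpcr_table(
    rng_or_seed: int | np.random.Generator = 0,
    genes: tuple[str, ...] = ("miR156", "miR164"),
    species: tuple[str, ...] = tuple(GENUS_MAP),
    n_replicates: int = 3,
    effect: float = 1.0,
) -> pd.DataFrame:
    """Toy qPCR Ct table: leaf vs fruit with a fruit-shifted target Ct."""
    rng = (
        np.random.default_rng(rng_or_seed)
        if isinstance(rng_or_seed, int)
        else rng_or_seed
    )
    rows = []
    for sp in species:
        for gene in genes:
            for tissue in ("leaf", "fruit"):
                shift = -effect if tissue == "fruit" else 0.0
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "species": sp,
                            "tissue": tissue,
                            "gene": gene,
                            "replicate": rep,
                            "ct_target": 24.0 + shift + rng.normal(0, 0.2),
                            "ct_reference": 18.0 + rng.normal(0, 0.2),
                        }
                    )
    return pd.DataFrame(rows)
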