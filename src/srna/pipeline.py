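"""End-to-end orchestration: preprocess -> annotate -> abundance -> novel
miRNA discovery -> TAS/tasiRNA -> targets (-> optional qPCR).

Every stage logs its input/output counts so the conservation identities
(raw = discarded + out-of-window + classified + unclassified) can be
audited from the run log; all tabular outputs are TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abundance, annotate, expression, hairpin, tasirna
from ._seq import to_dna
from .config import PipelineConfig
from .io import read_fasta, read_reads, write_collapsed_tsv, write_fasta
from .preprocess import (
    SmallRNALibrary,
    collapse,
    filter_by_length,
    size_distribution,
    trim_adapters,
)
from .targets import annotate_targets, scan_transcriptome

logger = logging.getLogger("srna.pipeline")

#: Table-1 row labels in report order, mapped from internal category names
TABLE1_ROWS = [
    ("ncRNA", "ncRNAs"),
    ("miRBase", "miRBase"),
    ("mRNA", "mRNAs"),
    ("repeats", "Repeats"),
    ("genome", "Genome"),
]


def render_table1(summaries: dict[str, annotate.AnnotationSummary]) -> pd.DataFrame:
    """Per-library (Unique, Total) counts by category plus a computed Total.

    The Total row is always the column sum, never copied from the input; it
    reproduces the library counts exactly when nothing is unclassified.
    """
    if not summaries:
        raise ValueError("need >= 1 library summary")
    data: dict[str, list[int]] = {}
    for lib, summary in summaries.items():
        for idx, kind in ((0, "Unique"), (1, "Total")):
            col = [summary.categories.get(cat, (0, 0))[idx] for cat, _ in TABLE1_ROWS]
            col.append(sum(col))
            data[f"{lib} {kind}"] = col
    index = [label for _, label in TABLE1_ROWS] + ["Total"]
    return pd.DataFrame(data, index=index)


@dataclass
class LibraryResult:
    library: SmallRNALibrary
    trim_report: object
    out_of_window: int
    assignment: dict[str, str]
    summary: annotate.AnnotationSummary
    families: list[annotate.FamilyAssignment]
    profiles: list[abundance.FamilyProfile]
    sizes: object


@dataclass
class ReportBundle:
    out_dir: Path
    per_library: dict[str, LibraryResult]
    table1: pd.DataFrame
    novel_table: pd.DataFrame
    tas_loci: list[tasirna.TasLocus]
    tas_correlation: float | None
    target_table: pd.DataFrame
    qpcr_table: pd.DataFrame | None = None
    comparison: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def _load_references(config: PipelineConfig) -> dict[str, annotate.ReferenceSet]:
    refs = {}
    for cat in annotate.CATEGORY_ORDER:
        path = config.references.get(cat)
        if path is None:
            raise FileNotFoundError(f"missing reference set for category {cat!r}")
        seqs = read_fasta(path)
        if not seqs:
            raise ValueError(f"reference FASTA for {cat!r} is empty or malformed")
        refs[cat] = annotate.ReferenceSet(cat, seqs)
    return refs


def process_library(
    lib_id: str, raw_reads: list[str], refs, config: PipelineConfig
) -> LibraryResult:
    inserts, report = trim_adapters(
        raw_reads,
        config.adapter5,
        config.adapter3,
        min_overlap=config.adapter_min_overlap,
        max_mismatch=config.adapter_max_mismatch,
    )
    kept = filter_by_length(inserts, config.min_len, config.max_len)
    out_of_window = len(inserts) - len(kept)
    library = collapse(kept, library_id=lib_id)
    assignment, summary = annotate.classify_library(
        library, refs, max_mirna_mismatch=config.mirna_max_mismatch
    )
    families = [
        annotate.assign_family(
            seq, refs["miRBase"].sequences,
            max_mismatch=config.mirna_max_mismatch,
            merge_families=config.merge_families,
        )
        for seq, cat in assignment.items()
        if cat == "miRBase"
    ]
    profiles = abundance.family_profile(library, families)
    logger.info(
        "%s: raw=%d kept=%d no5=%d no3=%d out_of_window=%d unique=%d total=%d",
        lib_id, report.raw, report.kept, report.no5, report.no3,
        out_of_window, library.unique_count, library.total_reads,
    )
    return LibraryResult(
        library=library,
        trim_report=report,
        out_of_window=out_of_window,
        assignment=assignment,
        summary=summary,
        families=families,
        profiles=profiles,
        sizes=size_distribution(library),
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages and write the report bundle under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs = _load_references(config)
    genome_seq = to_dna("".join(refs["genome"].sequences.values()))
    transcripts = refs["mRNA"].sequences

    per_library: dict[str, LibraryResult] = {}
    for lib_id, fastq in config.libraries.items():
        raw = read_reads(fastq)
        if not raw:
            raise ValueError(f"no reads parsed from {fastq}")
        per_library[lib_id] = process_library(lib_id, raw, refs, config)
        write_collapsed_tsv(out / f"collapsed_{lib_id}.tsv", per_library[lib_id].library)
        sizes = per_library[lib_id].sizes
        pd.DataFrame(
            [(ln, u, t) for ln, (u, t) in sizes.rows.items()],
            columns=["length", "unique", "total"],
        ).to_csv(out / f"sizes_{lib_id}.tsv", sep="\t", index=False)

    table1 = render_table1({lib: r.summary for lib, r in per_library.items()})
    table1.to_csv(out / "table1.tsv", sep="\t")

    profiles = {lib: r.profiles for lib, r in per_library.items()}
    for lib, ps in profiles.items():
        pd.DataFrame(
            [
                {"family": p.family, "count": p.raw_count, "tpm": p.tpm,
                 "tier": p.tier, "share": p.share}
                for p in ps
            ]
        ).to_csv(out / f"families_{lib}.tsv", sep="\t", index=False)
    comparison = (
        abundance.compare_libraries(profiles, flag_ratio=config.fold_change_flag)
        if len(profiles) >= 2
        else None
    )
    if comparison is not None:
        comparison.to_csv(out / "family_comparison.tsv", sep="\t")

    # novel miRNA discovery
    candidates = hairpin.discover_candidates(
        {lib: (r.library, r.assignment) for lib, r in per_library.items()},
        genome_seq,
        max_loci=config.max_genomic_loci,
        len_range=config.candidate_len_range,
        window=config.flank_window,
    )
    novel_table = (
        hairpin.cross_species_support(
            candidates,
            {lib: r.library for lib, r in per_library.items()},
            config.genus_map or {lib: lib for lib in per_library},
            min_genera=config.min_genera,
        )
        if len(per_library) >= 2
        else pd.DataFrame()
    )
    if len(novel_table):
        novel_table.to_csv(out / "novel_candidates.tsv", sep="\t", index=False)
    logger.info(
        "novel discovery: %d candidates, %d passed, %d retained",
        len(candidates),
        sum(1 for c in candidates.values() if c.verdict.passed),
        int(novel_table["retained"].sum()) if len(novel_table) else 0,
    )

    # TAS loci + phasing + trigger correlation
    trigger = to_dna(config.trigger)
    tas_loci = tasirna.detect_loci(
        transcripts, trigger,
        max_penalty=config.tas_max_penalty,
        min_spacing=config.tas_min_spacing,
        max_spacing=config.tas_max_spacing,
    )
    tas_rows = []
    tas_correlation = None
    lib_tas_tpm: dict[str, float] = {}
    for locus in tas_loci:
        registers = {}
        for lib, r in per_library.items():
            phasing = tasirna.phased_registers(
                locus, r.library, transcripts[locus.transcript_id]
            )
            registers = locus.registers
            lib_tas_tpm[lib] = lib_tas_tpm.get(lib, 0.0) + abundance.tpm(
                phasing.in_phase_total, r.library.total_reads
            )
            tas_rows.append(
                {
                    "transcript": locus.transcript_id,
                    "library": lib,
                    "spacing": locus.spacing,
                    "canonical": locus.canonical,
                    "in_phase_fraction": phasing.in_phase_fraction,
                }
            )
        if registers:
            write_fasta(
                out / f"tas_registers_{locus.transcript_id}.fa",
                {k.replace("(+)", "_plus"): v for k, v in registers.items()},
            )
    if tas_rows:
        pd.DataFrame(tas_rows).to_csv(out / "tas_loci.tsv", sep="\t", index=False)
    if tas_loci and len(per_library) >= 3:
        trig_tpm = {
            lib: sum(p.tpm for p in r.profiles if p.family == config.trigger_family)
            for lib, r in per_library.items()
        }
        tas_correlation, corr_df = tasirna.trigger_tasirna_correlation(
            {lib: (trig_tpm[lib], lib_tas_tpm.get(lib, 0.0)) for lib in per_library}
        )
        corr_df.to_csv(out / "tas_trigger_correlation.tsv", sep="\t", index=False)
    logger.info("TAS: %d loci, trigger correlation %s", len(tas_loci), tas_correlation)

    # target prediction for the known mature miRNAs
    sites = scan_transcriptome(
        refs["miRBase"].sequences, transcripts, cutoff=config.target_cutoff
    )
    target_table = annotate_targets(sites)
    target_table.to_csv(out / "targets.tsv", sep="\t", index=False)

    qpcr_df = None
    if config.qpcr_table:
        qpcr_df = expression.analyze_qpcr(expression.load_qpcr_table(config.qpcr_table))
        qpcr_df.to_csv(out / "qpcr.tsv", sep="\t", index=False)

    return ReportBundle(
        out_dir=out,
        per_library=per_library,
        table1=table1,
        novel_table=novel_table,
        tas_loci=tas_loci,
        tas_correlation=tas_correlation,
        target_table=target_table,
        qpcr_table=qpcr_df,
        comparison=comparison,
    )


def materialize_preset(preset, out_dir: str | Path) -> PipelineConfig:
    """Write a synthetic preset (genome, references, reads, truth) to disk
    and return a ready-to-run configuration pointing at it."""
    from .io import write_fastq
    from .simulate import write_truth_gff3, write_truth_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref_paths = {}
    for cat, seqs in preset.world.references.items():
        path = out / f"ref_{cat}.fa"
        write_fasta(path, seqs)
        ref_paths[cat] = str(path)
    libraries = {}
    for lib, (reads, read_truth) in preset.libraries.items():
        fastq = out / f"reads_{lib}.fastq"
        write_fastq(fastq, reads)
        read_truth.to_csv(out / f"read_truth_{lib}.tsv", sep="\t", index=False)
        libraries[lib] = str(fastq)
    write_truth_gff3(out / "truth.gff3", preset.world.truth)
    write_truth_tsv(out / "truth.tsv", preset.world.truth)
    spec = preset.world.spec
    config = PipelineConfig(
        libraries=libraries,
        genus_map=dict(preset.genus_map),
        references=ref_paths,
        out_dir=str(out / "reports"),
        adapter5=spec.adapter5,
        adapter3=spec.adapter3,
        seed=spec.seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
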