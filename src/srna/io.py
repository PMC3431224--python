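"""FASTA/FASTQ/TSV readers and writers used across the pipeline."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import SmallRNALibrary, UniqueRead
from ._seq import to_rna


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered mapping id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_reads(path: str | Path) -> list[str]:
    """Raw read sequences from FASTQ or FASTA (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def write_fastq(path: str | Path, reads: list[str], quality: str = "I") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read_{i}\n{seq}\n+\n{quality * len(seq)}\n")


def write_collapsed_fasta(path: str | Path, library: SmallRNALibrary) -> None:
    """Collapsed library as FASTA with ``>id_count`` headers (RNA alphabet)."""
    with open(path, "w") as fh:
        for i, r in enumerate(library.unique_reads):
            fh.write(f">{library.library_id}_{i}_{r.count}\n{to_rna(r.sequence)}\n")


def write_collapsed_tsv(path: str | Path, library: SmallRNALibrary) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for r in library.unique_reads:
            fh.write(f"{to_rna(r.sequence)}\t{r.count}\n")


def read_collapsed_tsv(path: str | Path, library_id: str = "library") -> SmallRNALibrary:
    uniques = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{path}: expected a 'sequence\\tcount' header")
        for line in fh:
            seq, count = line.rstrip("\n").split("\t")
            uniques.append(UniqueRead(seq.upper().replace("U", "T"), int(count)))
    return SmallRNALibrary(library_id=library_id, unique_reads=uniques)
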