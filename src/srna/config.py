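"""Pipeline configuration: one document holding every tunable threshold."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import ADAPTER3, ADAPTER5


@dataclass
class PipelineConfig:
    """Paths and thresholds for an end-to-end run.

    ``libraries`` maps library id to its raw FASTQ/FASTA; ``references``
    maps the five annotation categories (ncRNA, miRBase, mRNA, repeats,
    genome) to FASTA paths.  Defaults record the package's documented
    choices wherever the analysis convention is a declared decision.
    """

    libraries: dict[str, str] = field(default_factory=dict)
    genus_map: dict[str, str] = field(default_factory=dict)
    references: dict[str, str] = field(default_factory=dict)
    out_dir: str = "srna_out"
    adapter5: str = ADAPTER5
    adapter3: str = ADAPTER3
    adapter_min_overlap: int = 8
    adapter_max_mismatch: int = 1
    min_len: int = 18
    max_len: int = 30
    mirna_max_mismatch: int = 2
    merge_families: bool = False
    max_genomic_loci: int = 10
    candidate_len_range: tuple[int, int] = (20, 24)
    flank_window: int = 160
    min_genera: int = 2
    trigger: str = "AAGCUCAGGAGGGAUAGCGCC"  # miR390
    trigger_family: str = "miR390"
    tas_max_penalty: float = 6.0
    tas_min_spacing: int = 200
    tas_max_spacing: int = 300
    target_cutoff: float = 3.5
    fold_change_flag: float = 10.0
    qpcr_table: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("invalid length window")
        if self.adapter_min_overlap < 1:
            raise ValueError("adapter_min_overlap must be >= 1")
        if self.max_genomic_loci < 1:
            raise ValueError("max_genomic_loci must be >= 1")
        if self.tas_min_spacing > self.tas_max_spacing:
            raise ValueError("invalid TAS spacing window")
        if self.target_cutoff < 0 or self.tas_max_penalty < 0:
            raise ValueError("penalty cutoffs must be >= 0")
        if self.flank_window < 20:
            raise ValueError("flank_window too small to hold a precursor arm")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["candidate_len_range"] = list(self.candidate_len_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "candidate_len_range" in data:
            data["candidate_len_range"] = tuple(data["candidate_len_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg
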