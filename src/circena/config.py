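"""Pipeline configuration.

All tunables of the pipeline in one flat record.  The defaults are the
published operating point of the analysis: back-splice segments must lie
on the same chromosome no more than 1 Mb apart; a junction is reported
with >= 2 supporting reads and a splice-strength score >= 10; junction
reads need >= 6 nt overhang; differential expression calls require fold
change > 2 at FDR < 0.05; the internal aligner seeds with 16-mers and
keeps segments scoring >= 20 (match +1 / mismatch -1).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # back-splice junction geometry and reporting filters
    max_junction_span_bp: int = 1_000_000
    min_support_reads: int = 2
    min_splice_score: float = 10.0
    min_overhang_nt: int = 6
    # internal aligner
    seed_kmer: int = 16
    min_segment_score: int = 20
    max_seed_hits: int = 50          # k-mers with more genomic hits are ambiguous, dropped
    max_read_gap_nt: int = 2         # tolerated gap on the read between the two segments
    max_junction_overlap_nt: int = 35  # tolerated read overlap (micro-homology) at the junction
    refine_radius_nt: int = 15       # micro-homology search window around a raw junction
    min_contiguous_identity: float = 0.95  # full-length placement identity to call a read linear
    # differential expression
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    # co-expression network
    correlation_p_threshold: float = 0.05
    correlation_r_threshold: float = 0.9
    # MRE prediction
    min_seed_class: str = "7mer"
    min_duplex_score: float = 80.0
    # reproducibility
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_junction_span_bp",
            "min_support_reads",
            "min_splice_score",
            "min_overhang_nt",
            "seed_kmer",
            "min_segment_score",
            "fc_threshold",
            "fdr_threshold",
            "correlation_p_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be strictly positive")
        if self.min_seed_class not in ("6mer", "7mer", "8mer"):
            raise ValueError(
                f"min_seed_class must be one of 6mer/7mer/8mer, got {self.min_seed_class!r}"
            )

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat key: value YAML file; unknown keys are errors."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        known = set(cls.field_names())
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}: {getattr(self, f.name)}\n")

    def replace(self, **kwargs) -> "PipelineConfig":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update(kwargs)
        return PipelineConfig(**data)
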