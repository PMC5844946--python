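"""Pipeline configuration.

A single :class:`PipelineConfig` carries every threshold the pipeline uses
(read-assignment overlap, expression filter, DE selection rule, editing-site
filters, qPCR defaults) plus the one RNG seed from which all randomness flows.
Configs round-trip through YAML and expose a short content hash so every
output table can record exactly which settings produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and defaults for every pipeline stage.

    Attributes
    ----------
    min_overlap
        Minimum ungapped, mismatch-free overlap (nt) between a read and a
        mature miRNA for assignment.
    min_mirna_count
        Expression filter: a miRNA must reach this many reads to be kept.
    lfc_threshold
        DE selection requires \\|log2FC\\| strictly greater than this.
    alpha_de
        DE selection requires BH-adjusted p strictly below this.
    fdr_editing
        BH false-discovery-rate level for per-site differential editing
        (significant iff padj <= fdr_editing, inclusive).
    min_samples_per_group
        A recoding site must be covered (total > 0) in at least this many
        samples of *each* group to be tested.
    min_median_editing
        A recoding site's pooled median editing level must be strictly above
        this to be tested.
    pseudocount
        Added to normalized expression before any log2 ratio.
    rng_seed
        Seed for all simulation / randomized steps.
    """

    min_overlap: int = 17
    min_mirna_count: int = 10
    lfc_threshold: float = 1.0
    alpha_de: float = 0.05
    fdr_editing: float = 0.10
    min_samples_per_group: int = 3
    min_median_editing: float = 0.10
    pseudocount: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_overlap <= 0 or self.min_mirna_count < 0:
            raise ValueError("min_overlap must be positive and min_mirna_count nonnegative")
        for name in ("lfc_threshold", "min_median_editing", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha_de", "fdr_editing"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.min_samples_per_group < 1:
            raise ValueError("min_samples_per_group must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Short stable digest of the configuration contents."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
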