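"""Pipeline configuration: defaults, validation, YAML round-trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """All tunables of the inference pipeline.

    k: seed k-mer length (10 does not exceed the length of known D genes).
    num_seeds: number m of most abundant k-mers used as seeds (species
        dependent; 600 suits human-scale repertoires, 300 mouse-scale).
    alpha / branch_alpha: significance thresholds of the extension and
        branching chi-square tests; very small by design so that only
        extreme departures from uniformity extend a string.
    max_dist: similarity-graph edge threshold on Dist(e1, e2).
    k_min: minimal unique-substring length for usage assignment.
    extension: extra-nucleotide allowance of the in-database relation.
    identity_threshold: percent identity separating novel variations from
        novel genes.
    min_dataset_size: datasets with fewer distinct CDR3s are skipped.
    max_len: hard cap on extension length (longest known D gene is 42 nt).
    consensus_mismatches: Hamming radius for consensus grouping; 0 disables.
    """

    k: int = 10
    num_seeds: int = 600
    alpha: float = 1e-30
    branch_alpha: float | None = None
    max_dist: int = 2
    k_min: int = 8
    extension: int = 3
    identity_threshold: float = 75.0
    min_dataset_size: int = 15000
    max_len: int = 50
    keep_unidirectional: bool = False
    consensus_mismatches: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            (self.k >= 1, "k must be >= 1"),
            (self.num_seeds >= 1, "num_seeds must be >= 1"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (
                self.branch_alpha is None or 0 < self.branch_alpha < 1,
                "branch_alpha must be in (0, 1)",
            ),
            (self.max_dist >= 0, "max_dist must be >= 0"),
            (self.k_min >= 1, "k_min must be >= 1"),
            (self.extension >= 0, "extension must be >= 0"),
            (0 < self.identity_threshold < 100, "identity_threshold in (0, 100)"),
            (self.min_dataset_size >= 0, "min_dataset_size must be >= 0"),
            (self.max_len >= self.k, "max_len must be >= k"),
            (self.consensus_mismatches >= 0, "consensus_mismatches must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
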