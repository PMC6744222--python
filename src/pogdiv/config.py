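"""Run configuration: a serialisable record of every knob a run uses."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Configuration of a single-pair analysis run.

    ``pairing`` selects how ortholog pairs are formed: ``"rbh"`` runs the
    reciprocal-best-hit scorer (real transcript sets); ``"by_id"`` pairs
    records with identical ids across the two FASTA files (pre-paired data,
    e.g. simulated cohorts, where all-vs-all scoring is redundant).
    """

    fasta_a: str = ""
    fasta_b: str = ""
    pair_id: str = "pair"
    out_dir: str = "pogdiv_out"

    min_len: int = 30
    max_stop_frac: float = 0.20
    min_score: float = 50.0
    pairing: str = "rbh"  # "rbh" | "by_id"
    cds_mode: str = "extract"  # "extract" | "passthrough"

    estimator: str = "YN00"  # "YN00" | "NG86"
    default_kappa: float = 2.0

    bin_width: float = 0.01
    #: Ka/Ks threshold above which genes enter the cluster test
    cluster_ratio_threshold: float = 2.0
    n_perm: int = 999
    alpha: float = 0.05

    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.min_len < 3:
            raise ValueError("min_len must be >= 3")
        if not 0.0 <= self.max_stop_frac <= 1.0:
            raise ValueError("max_stop_frac must be in [0, 1]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.pairing not in ("rbh", "by_id"):
            raise ValueError(f"unknown pairing mode {self.pairing!r}")
        if self.estimator not in ("YN00", "NG86"):
            raise ValueError(f"unknown estimator {self.estimator!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def config_hash(self) -> str:
        """Stable hash of the full configuration; identical hash implies
        identical outputs."""
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
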