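"""Run configuration: every tunable the pipeline exposes, with the assay's
stated defaults, serializable next to the outputs it produced."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Configuration for an end-to-end run.

    Defaults mirror the assay's stated analysis constants: read filter of 5
    input / 1 output reads with no pseudocounts, hexamer (k = 6) effect
    tables, shuffle policy of Hamming distance >= half the motif length with
    at most 50 shuffles, 5 enrichment bins for arrangement analysis, and a
    50,000-sequence subsample for per-position base statistics.
    """

    seed: int = 0
    # simulation (used when no count table is supplied)
    n_variants: int = 590_000
    length: int = 50
    depth_pre: int = 20_000_000
    depth_post: int = 20_000_000
    skew_sd: float = 0.5
    # read filter
    min_pre: int = 5
    min_post: int = 1
    # analyses
    k_list: tuple[int, ...] = (6,)
    motifs: tuple[str, ...] = ("UAUAUA", "AAWAAA")
    motif_file: str | None = None
    max_shuffles: int = 50
    n_bins: int = 5
    subsample: int = 50_000
    kplogo_two_sided: bool = True
    # optional inputs
    counts_path: str | None = None
    halflife_path: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from (seed, stage name), < 2**31."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") & 0x7FFFFFFF

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for key in ("k_list", "motifs"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def digest(self) -> str:
        """Short hash identifying this configuration."""
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
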