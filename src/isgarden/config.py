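"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run.

    Every analysis output embeds this config (and the seed) so results are
    reproducible from the report alone.
    """

    seed: int = 0
    coordinate_convention: str = "tss_1based_closed"
    strand: str = "forward"  # motif-scan strand policy: 'forward' or 'both'
    large_threshold: int = 100  # bp over expected amplicon => large insertion
    utr_len: int = 88
    cds_len: int = 1422
    k: int = 2  # number of subsets for delineation (2 or 3)
    n_perm: int = 1000
    n_events: int = 150  # simulated events when no catalog is supplied
    enrichment_scope: str = "replicon"
    events_path: str | None = None
    env_path: str | None = None
    abundance_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "both"):
            raise ValueError(f"unknown strand policy {self.strand!r}")
        if self.k not in (2, 3):
            raise ValueError("k must be 2 or 3")
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
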