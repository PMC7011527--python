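"""Pipeline configuration shared by all stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    """Tunable parameters of the bin-mapping / linkage / QTL pipeline.

    Attributes
    ----------
    window_size
        Number of consecutive parent-specific SNPs per sliding window.
    vote_threshold
        Vote cut on the per-window sum of 1/0 codes for a full window:
        sum above it calls the Longgu7-type parent, below it the
        Yugu1-type parent.  With 15 SNPs the default 10.5 is asymmetric
        (>= 11 vs <= 10) and is applied literally; ``symmetric=True``
        replaces it with window_size / 2.
    window_step
        Step between window starts in SNPs; the default equals
        window_size (non-overlapping windows).
    min_window_informative
        Windows with fewer non-missing SNPs than this are called missing.
    lod_threshold
        Minimum LOD for declaring a QTL.
    map_function
        'kosambi' or 'haldane'.
    sdr_min_run
        Minimum number of consecutive distorted bins (same favoured
        parent) forming a segregation distortion region.
    cluster_window_cM
        Window width for QTL-cluster detection.
    het_policy
        How heterozygous RIL calls are encoded: 'missing' (default),
        'drop_snp', or 'major'.
    """

    window_size: int = 15
    vote_threshold: float = 10.5
    window_step: int | None = None  # None -> window_size
    min_window_informative: int = 8
    lod_threshold: float = 2.0
    map_function: str = "kosambi"
    sdr_min_run: int = 5
    cluster_window_cM: float = 20.0
    het_policy: str = "missing"
    symmetric: bool = False
    paper_literal: bool = False
    support_lod_drop: float = 1.0
    stable_min_envs: int = 3
    cofactor_mode: bool = False
    cofactor_window_cM: float = 10.0
    max_cofactors: int = 5
    min_class_n: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        step = self.step
        if not (0 < self.vote_threshold < self.window_size):
            raise ValueError("vote_threshold must lie strictly inside (0, window_size)")
        if not (1 <= step <= self.window_size):
            raise ValueError("window_step must lie in [1, window_size]")
        if self.map_function not in ("kosambi", "haldane"):
            raise ValueError(f"unknown map function: {self.map_function!r}")
        if self.het_policy not in ("missing", "drop_snp", "major"):
            raise ValueError(f"unknown het policy: {self.het_policy!r}")

    @property
    def step(self) -> int:
        return self.window_size if self.window_step is None else self.window_step

    @property
    def effective_vote_threshold(self) -> float:
        return self.window_size / 2 if self.symmetric else self.vote_threshold

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the analysis parameters.

        Covers every PipelineConfig field (changing any changes the
        hash) but not I/O paths, so reruns of the same analysis in
        different directories share a hash.
        """
        fields = [f.name for f in dataclasses.fields(PipelineConfig)]
        payload = json.dumps(
            {k: getattr(self, k) for k in fields}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunConfig(PipelineConfig):
    """PipelineConfig plus I/O paths and run mode for the CLI pipeline."""

    mode: str = "simulate"
    out_dir: str = "binmapqtl_out"
    parent1_variants: str | None = None
    parent2_variants: str | None = None
    ril_calls: str | None = None
    trait_file: str | None = None
    n_lines: int = 164
    n_selfing_generations: int = 7
    error_rate: float = 0.01
    missing_rate: float = 0.10
    verbosity: str = "info"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mode not in ("simulate", "real"):
            raise ValueError(f"unknown mode: {self.mode!r}")
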