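"""Pipeline configuration: defaults, validation, YAML round trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .genome import Chromosome
from .replication import NoiseModel, OriginSpec, ProbeDesign, ReplicationParams

# Default study conditions: a 2.9-Mb circular chromosome with three active
# origins of unequal efficiency plus one dormant origin, half the
# population cycling, and fork kinetics such that the longest replication
# path takes 80% of a doubling time.
DEFAULT_CHROM_LENGTH = 2_900_000
DEFAULT_ORIGINS = [
    {"id": "oriC1", "position": 300_000, "efficiency": 0.9},
    {"id": "oriC2", "position": 1_300_000, "efficiency": 0.5},
    {"id": "oriC3", "position": 2_200_000, "efficiency": 0.3},
    {"id": "oriC4", "position": 2_600_000, "efficiency": 0.0},
]
DEFAULT_FORK_SPEED = 1000.0  # bp/min
DEFAULT_DOUBLING_TIME = DEFAULT_CHROM_LENGTH / 2 / DEFAULT_FORK_SPEED / 0.8  # min
DEFAULT_CYCLING_FRACTION = 0.5
DEFAULT_CHANNEL_LOG_SD = 0.07
DEFAULT_PROBE_DENSITY = 34.0


@dataclass
class PipelineConfig:
    """All simulator, MFA, caller, and predictor parameters, plus the seed.

    Serializes losslessly to/from YAML; the config hash stamped on outputs
    is the SHA-256 of the canonical YAML dump.
    """

    chrom_name: str = "chr"
    chrom_length: int = DEFAULT_CHROM_LENGTH
    circular: bool = True
    origins: list = field(default_factory=lambda: [dict(o) for o in DEFAULT_ORIGINS])
    fork_speed: float = DEFAULT_FORK_SPEED
    doubling_time: float = DEFAULT_DOUBLING_TIME
    cycling_fraction: float = DEFAULT_CYCLING_FRACTION
    channel_log_sd: float = DEFAULT_CHANNEL_LOG_SD
    probe_density: float = DEFAULT_PROBE_DENSITY
    probe_length: int = 50
    # MFA parameters
    outlier_upper: float = 2.0
    outlier_lower: float = 0.5
    bin_probes: int = 30
    smooth_window: int = 5
    smooth_slide: int = 1
    read_window_bp: int = 1000
    # caller parameters
    min_prominence: float | None = None  # None -> 5 x MAD adaptive
    min_separation: int = 100_000
    match_tolerance: int = 20_000
    kernel_halfwidth_bp: int = 60_000
    # orb_finder parameters
    motif_min_len: int = 18
    motif_max_len: int = 35
    g_run: int = 4
    max_mismatch: int = 3
    identity_threshold: float = 80.0
    upstream_max_span: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if not 0 <= self.cycling_fraction <= 1:
            raise ValueError("cycling_fraction must be in [0, 1]")
        if self.outlier_upper <= self.outlier_lower:
            raise ValueError("outlier_upper must exceed outlier_lower")
        if self.bin_probes < 1:
            raise ValueError("bin_probes must be >= 1")
        if self.smooth_window % 2 == 0 or self.smooth_window < 3:
            raise ValueError("smooth_window must be an odd integer >= 3")
        if not 0 < self.motif_min_len <= self.motif_max_len:
            raise ValueError("motif length bounds must satisfy 0 < min <= max")
        for o in self.origins:
            if not 0 <= o["position"] < self.chrom_length:
                raise ValueError(f"origin {o['id']}: position out of range")
            if not 0 <= o["efficiency"] <= 1:
                raise ValueError(f"origin {o['id']}: efficiency out of [0, 1]")

    # -- conversions ----------------------------------------------------

    def chromosome(self, sequence: str | None = None) -> Chromosome:
        return Chromosome(self.chrom_name, self.chrom_length, self.circular, sequence)

    def origin_specs(self, overrides: dict[str, float] | None = None) -> list[OriginSpec]:
        """Origin list, optionally with per-id efficiency overrides (used to
        express deletion strains: efficiency 0 removes an origin's firing)."""
        overrides = overrides or {}
        return [
            OriginSpec(o["id"], o["position"], overrides.get(o["id"], o["efficiency"]))
            for o in self.origins
        ]

    def replication_params(self) -> ReplicationParams:
        return ReplicationParams(self.fork_speed, self.doubling_time, self.cycling_fraction)

    def probe_design(self) -> ProbeDesign:
        return ProbeDesign.tile(self.chrom_length, self.probe_density, self.probe_length)

    def noise_model(self, seed: int | None = None) -> NoiseModel:
        return NoiseModel(self.channel_log_sd, self.seed if seed is None else seed)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
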