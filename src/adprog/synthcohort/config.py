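"""Simulation configuration with validity checks and a one-seed RNG contract."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults emulate the study conditions the package targets: ~900 patients,
    a SNP panel with subpopulation structure and LD blocks, ~70 mixed clinical
    variables, and right-censored conversion times over a 96-month horizon
    with roughly a third of patients converting (dropout plus administrative
    censoring make up the rest).
    """

    n_patients: int = 900
    n_snps: int = 5000
    n_subpops: int = 2
    fst: float = 0.1
    ld_block_size: int = 5
    ld_flip_prob: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_clinical: int = 70
    n_informative: int = 5
    true_coefficients: dict[str, float] = field(default_factory=dict)
    baseline_shape: float = 1.5
    baseline_scale: float = 120.0
    censor_rate: float = 0.65  # fraction censored; ~27% of the emulated cohort converts
    horizon_months: float = 96.0
    missing_rate: float = 0.0
    damaging_fraction: float = 0.2
    n_genes: int | None = None
    n_pathways: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_snps <= 0:
            raise ValueError("n_patients and n_snps must be positive")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_clinical < 0:
            raise ValueError("n_clinical must be >= 0")
        if self.n_informative > self.n_snps + self.n_clinical:
            raise ValueError("n_informative exceeds available features")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    # one-seed contract: each operation receives its own derived stream
    def rng(self, stream: str) -> np.random.Generator:
        tag = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)
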