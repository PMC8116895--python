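"""Run configuration shared by the CLI and the pipeline orchestrator.

Every tunable of the read pipeline has a config key whose default equals the
study value (minimum merged length 160 nt, max expected errors 1.0, UNOISE
alpha 2, 99% clustering identity, >=75 reads in >=3 samples).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .amplicon import PipelineParams

# amplicon PCR primers (IUPAC; R = A/G)
FORWARD_PRIMER = "GTTAGAGTTCCAGTGCCACAA"
REVERSE_PRIMER = "GGTTGTTGTGGTTGCGRATA"

IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class PrimerPair:
    forward: str = FORWARD_PRIMER
    reverse: str = REVERSE_PRIMER

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if not set(p) <= IUPAC:
                raise ValueError(f"primer {p} contains non-IUPAC symbols")


@dataclass
class RunConfig:
    out_dir: str = "results/pipeline"
    seed: int = 42
    family: str = "bw208_like"
    depth_per_sample: int = 52_000
    per_base_error: float = 0.001
    chimera_rate: float = 0.005
    n_dna_samples: int = 4
    epitope_table: str | None = None  # None -> packaged default
    noise_cv: float = 0.25
    qpcr_noise_sd: float = 3.0
    params: PipelineParams = field(default_factory=PipelineParams)
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = PipelineParams(**raw.pop("params", {}))
        known = {f for f in cls.__dataclass_fields__ if f != "params"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(params=params, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
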