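"""Pipeline configuration: every threshold in one place.

Defaults follow the method's standard operating point: coarse filter at
entropy difference 0.2 and MI rank 100, Joint N-Best at ratio 0.5, helix
extension at 85% canonical pairs, neighbor effects at ratio 0.85 / CPE 25%
/ 10 events.  The MIp Z-score cutoff (4.0) is a configurable stand-in; the
original recommendation does not pin a value.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    entropy_tol: float = 0.2       # coarse filter: max |H(x) - H(y)| in bits
    top_k: int = 100               # coarse filter: MI rank cutoff per column
    nbest_threshold: float = 0.5   # Joint N-Best ratio cutoff
    min_total_events: int = 10     # PEC total-event floor
    canonical_fraction: float = 0.85   # helix extension
    neighbor_ratio_min: float = 0.85   # neighbor effects: N-Best ratio floor
    cpe_min: float = 0.25              # neighbor effects: CPE floor
    events_min: int = 10               # neighbor effects: event floor
    mip_z_cutoff: float = 4.0          # MIp/Z calling cutoff

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
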