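"""Run configuration: every dial of the pipeline in one nested, serialisable
structure, so no stage uses numbers that are not reachable from here."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .conditioning import AmplifierModel, ScalerConfig
from .ecg_gate import ECGGateConfig
from .errors import InvalidParameterError
from .magnetization import SequenceParams, TissueParams
from .physio import PhysioParams
from .resp_gate import RespGateConfig
from .scan_control import ScanParams

__all__ = ["NoiseConfig", "RunConfig"]


@dataclass
class NoiseConfig:
    """Gradient-burst injection dials (burst every TR, ms)."""

    burst_period: float = 4.0
    burst_width: float = 1.0
    enabled: bool = True


@dataclass
class RunConfig:
    """Nested configuration of the full simulate→condition→gate→scan pipeline."""

    physio: PhysioParams = field(default_factory=PhysioParams)
    ecg_amplifier: AmplifierModel = field(default_factory=AmplifierModel.ecg_default)
    resp_amplifier: AmplifierModel = field(default_factory=AmplifierModel.resp_default)
    scaler: ScalerConfig = field(default_factory=ScalerConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    resp_gate: RespGateConfig = field(default_factory=RespGateConfig)
    ecg_gate: ECGGateConfig = field(default_factory=ECGGateConfig)
    scan: ScanParams = field(default_factory=ScanParams)
    tissue: TissueParams = field(default_factory=TissueParams)
    sequence: SequenceParams = field(default_factory=SequenceParams)
    duration: float = 40000.0   # simulated signal length, ms
    seed: int = 0
    output_dir: str = "cinegate_run"

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")

    # ------------------------------------------------------------- serialising
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, typ in [
            ("physio", PhysioParams), ("ecg_amplifier", AmplifierModel),
            ("resp_amplifier", AmplifierModel), ("scaler", ScalerConfig),
            ("noise", NoiseConfig), ("resp_gate", RespGateConfig),
            ("ecg_gate", ECGGateConfig), ("scan", ScanParams),
            ("tissue", TissueParams), ("sequence", SequenceParams),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable hash of the full configuration, stamped on every artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
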