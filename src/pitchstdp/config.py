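"""Run configuration: one serializable object holding every model parameter.

Defaults equal the published parameter tables; the scaling block
(eta_scale) selects the desk-scale training mode in which the learning
rate is multiplied and the learning time divided by the same factor,
leaving eta*T unchanged.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .network import LIFParams
from .plasticity import STDPParams, presentations_for
from .ranking import RankingExperiment
from .spikes import DEFAULT_PEAK_RATE


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/default"
    # stimuli
    ladder_low_hz: float = 98.0
    ladder_high_hz: float = 493.0
    # periphery
    n_channels: int = 200
    # spikes
    peak_rate: float = DEFAULT_PEAK_RATE
    # network / plasticity
    lif: LIFParams = dataclasses.field(default_factory=LIFParams)
    stdp: STDPParams = dataclasses.field(default_factory=STDPParams)
    training_mode: str = "single-type"
    training_type: str = "tone"
    eta_scale: float = 100.0
    n_presentations: int | None = None  # derived from t_learn/eta_scale when None
    # analysis
    vs_interval_s: float = 5.0
    isih_reps: int = 10
    # ranking
    ranking: RankingExperiment = dataclasses.field(default_factory=RankingExperiment)

    def __post_init__(self) -> None:
        if self.eta_scale <= 0:
            raise ValueError("eta_scale must be positive")

    def presentations(self) -> int:
        if self.n_presentations is not None:
            return self.n_presentations
        return presentations_for(self.stdp, self.eta_scale)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("lif"), dict):
            d["lif"] = LIFParams(**d["lif"])
        if isinstance(d.get("stdp"), dict):
            d["stdp"] = STDPParams(**d["stdp"])
        if isinstance(d.get("ranking"), dict):
            d["ranking"] = RankingExperiment(**d["ranking"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def provenance(self) -> dict:
        from . import __version__

        blob = json.dumps(self.to_dict(), sort_keys=True)
        import hashlib

        return {
            "config_sha1": hashlib.sha1(blob.encode()).hexdigest(),
            "seed": self.seed,
            "package_version": __version__,
        }
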