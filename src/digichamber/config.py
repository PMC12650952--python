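"""Run configuration: one YAML document covering simulation and analysis.

Every constant of the analysis protocol is a named key here rather than a
literal in the code: 10-px circular ROI, 16-px crop, mean + 15 SD
intensity threshold, ROG threshold 5.5 px, 2-min frame interval,
detection trigger of 10 positives, 20% settling rule.  Configs round-trip
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .features import DEFAULT_K_SD, DEFAULT_ROG_THRESHOLD_PX
from .synthetic import ChipGeometry, KineticsModel, NoiseModel

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ThresholdConfig:
    k_sd: float = DEFAULT_K_SD              # intensity threshold = mu + k_sd * sigma
    rog_threshold: float = DEFAULT_ROG_THRESHOLD_PX  # px, for 16x16 crops


@dataclass(frozen=True)
class AnalysisConfig:
    roi_diameter_px: float = 10.0
    crop_size_px: int = 16
    frame_interval_min: float = 2.0
    min_separation_factor: float = 0.6      # min peak separation = factor * pitch_px
    detection_trigger: int = 10             # detection: count must exceed this
    detection_initial_max: int = 2          # expected first-frame ceiling
    quantification_rel_change: float = 0.2  # settling rule on consecutive counts


@dataclass(frozen=True)
class SimulationConfig:
    concentration_M: float = 3.6e-12
    amplification_efficiency: float = 1.0
    endpoint_time_min: float = 30.0
    times_min: tuple[float, ...] | None = None  # None -> single endpoint frame


@dataclass(frozen=True)
class RunConfig:
    geometry: ChipGeometry = field(default_factory=ChipGeometry)
    kinetics: KineticsModel = field(default_factory=KineticsModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0

    @property
    def min_separation_px(self) -> float:
        return self.analysis.min_separation_factor * self.geometry.pitch_px

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @staticmethod
    def from_yaml(source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" in text or text.strip().startswith("{"):
                data = yaml.safe_load(text)
            else:
                with open(text) as fh:
                    data = yaml.safe_load(fh)
        return RunConfig.from_dict(data)

    @staticmethod
    def from_dict(data: dict) -> "RunConfig":
        data = dict(data)
        data.pop("schema_version", None)

        def build(cls, key):
            sub = dict(data.get(key) or {})
            for name in list(sub):
                if isinstance(sub[name], list):
                    sub[name] = tuple(sub[name])
            return cls(**sub)

        return RunConfig(
            geometry=build(ChipGeometry, "geometry"),
            kinetics=build(KineticsModel, "kinetics"),
            noise=build(NoiseModel, "noise"),
            thresholds=build(ThresholdConfig, "thresholds"),
            analysis=build(AnalysisConfig, "analysis"),
            simulation=build(SimulationConfig, "simulation"),
            seed=int(data.get("seed", 0)),
        )


def _plain(obj):
    """Recursively convert tuples/numpy scalars so yaml.safe_dump accepts them."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
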