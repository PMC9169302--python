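"""Run configuration: every knob of a pipeline run in one YAML-serializable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from wingbeat.sensor_sim import ClassProfile, NoiseModel, SensorSpec, default_profiles


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, with explicit seeds throughout.

    Round-trips losslessly through YAML so a run can be reproduced from its
    config file alone.
    """

    sensor: SensorSpec = field(default_factory=SensorSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    profiles: list[ClassProfile] = field(default_factory=default_profiles)
    n_per_class: int = 150
    invalid_fraction: float = 0.023
    quota: int | str = "min"
    seed: int = 0
    train_fraction: float = 0.75
    k_folds: int = 4
    features: list[str] = field(default_factory=lambda: [
        "fundamental_frequency", "fundamental_peak_power", "frequency_and_power",
        "psd", "spectrogram", "mfcc",
    ])
    algorithms: list[str] = field(default_factory=lambda: ["LR", "GB", "RF", "SVM", "DNN"])
    algorithm_grids: dict = field(default_factory=dict)  # name -> param grid
    tasks: list[str] = field(default_factory=lambda: ["genus", "sex_aedes", "sex_culex"])
    output_dir: str = "wingbeat_out"

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["sensor"]["amplitude_range"] = list(self.sensor.amplitude_range)
        for p in payload["profiles"]:
            p["harmonic_ratios"] = list(p["harmonic_ratios"])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        sensor = payload.pop("sensor", {})
        sensor["amplitude_range"] = tuple(sensor.get("amplitude_range", (-1.0, 1.0)))
        noise = payload.pop("noise", {})
        profiles = payload.pop("profiles", None)
        cfg = cls(
            sensor=SensorSpec(**sensor),
            noise=NoiseModel(**noise),
            profiles=default_profiles() if profiles is None else [
                ClassProfile(**{**p, "harmonic_ratios": tuple(p["harmonic_ratios"])})
                for p in profiles
            ],
            **payload,
        )
        return cfg
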