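"""YAML configuration for the optical train and acquisition defaults."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .lightsculpt import OpticalTrain, SLMGeometry
from .synthetic_movies import AcquisitionSpec, SensorModel

__all__ = ["load_config", "dump_default_config", "SystemConfig"]


@dataclasses.dataclass
class SystemConfig:
    """Bundle of the instrument/sensor defaults.

    Defaults mirror the reference system: 600 x 800 px, 20 um pitch SLM at
    940 nm; lens train (400, 300, 500, 500, 300) mm with a 40x/0.8 NA,
    f = 5 mm objective and a 600 lines/mm grating; 0.1625 um camera pixels
    with 0.02 ms readout.
    """

    slm: SLMGeometry = dataclasses.field(default_factory=SLMGeometry)
    train: OpticalTrain = dataclasses.field(default_factory=OpticalTrain)
    acquisition: AcquisitionSpec = dataclasses.field(default_factory=AcquisitionSpec)
    sensor: SensorModel = dataclasses.field(default_factory=SensorModel)


def load_config(path=None) -> SystemConfig:
    """Load a SystemConfig from YAML; missing keys keep their defaults."""
    if path is None:
        return SystemConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for name, cls in (
        ("slm", SLMGeometry),
        ("train", OpticalTrain),
        ("acquisition", AcquisitionSpec),
        ("sensor", SensorModel),
    ):
        block = raw.get(name, {})
        if "focal_lengths" in block:
            block["focal_lengths"] = tuple(block["focal_lengths"])
        kwargs[name] = cls(**block)
    return SystemConfig(**kwargs)


def dump_default_config(path) -> Path:
    cfg = SystemConfig()
    payload = {
        "slm": dataclasses.asdict(cfg.slm),
        "train": dataclasses.asdict(cfg.train),
        "acquisition": dataclasses.asdict(cfg.acquisition),
        "sensor": dataclasses.asdict(cfg.sensor),
    }
    payload["train"]["focal_lengths"] = list(payload["train"]["focal_lengths"])
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
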