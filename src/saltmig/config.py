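"""Run configuration: one serialisable object embedded in every output."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    """Everything that parameterises an analysis run.

    The defaults are the reference acquisition/analysis settings: 3-min
    frames, 6 μm NK threshold, 2 μm CK threshold, 30 min minimum tracked
    duration, four radar dials.  ``nk_merge`` and ``ck_frame`` are
    sensitivity switches for the two under-determined analysis choices
    (whether consecutive supra-threshold steps form one NK; whether CK is
    measured nucleus-relative or along the migration axis).
    """

    dt: float = 3.0
    nk_threshold: float = 6.0
    ck_threshold: float = 2.0
    min_duration: float = 30.0
    n_dials: int = 4
    reference_vector: tuple[float, float] = (1.0, 0.0)
    nk_merge: bool = True
    ck_frame: str = "relative"
    group: str = ""
    seed: int = 0
    input: str = ""
    outdir: str = ""

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.nk_threshold <= 0 or self.ck_threshold <= 0:
            raise ParameterError("dt and thresholds must be > 0")
        if self.min_duration < 0:
            raise ParameterError("min_duration must be >= 0")
        if self.ck_frame not in ("relative", "absolute"):
            raise ParameterError("ck_frame must be 'relative' or 'absolute'")
        self.reference_vector = tuple(float(v) for v in self.reference_vector)
        if len(self.reference_vector) != 2:
            raise ParameterError("reference_vector must have 2 components")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["reference_vector"] = list(self.reference_vector)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterError(f"{path}: config file must contain a mapping")
        return cls.from_dict(data)
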