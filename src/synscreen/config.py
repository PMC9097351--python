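"""Run configuration: every analysis threshold in one validated object.

Defaults follow the screen's conventions: Z' > 0.6 for primary 96-well
plates and > 0.5 for secondary 384-well plates; ExcessHSA thresholds
±20; fa usable-range clip ε = 0.005; TGI responder > 60%, regression
> 100%.  A YAML file may override any subset of keys.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import InputFormatError


@dataclass
class RunConfig:
    z_min_primary: float = 0.6
    z_min_secondary: float = 0.5
    synergy_lo: float = -20.0
    synergy_hi: float = 20.0
    fa_eps: float = 0.005
    ci_form: str = "mutually_exclusive"
    tgi_responder_min: float = 60.0
    tgi_regression_min: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.synergy_lo < self.synergy_hi:
            raise InputFormatError(
                f"synergy thresholds must satisfy lo < hi, got "
                f"({self.synergy_lo}, {self.synergy_hi})"
            )
        if not 0 < self.fa_eps < 0.5:
            raise InputFormatError(f"fa_eps must lie in (0, 0.5), got {self.fa_eps}")
        if self.ci_form not in ("mutually_exclusive", "mutually_nonexclusive"):
            raise InputFormatError(f"unknown ci_form {self.ci_form!r}")

    @property
    def synergy_thresholds(self) -> tuple[float, float]:
        return (self.synergy_lo, self.synergy_hi)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputFormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
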