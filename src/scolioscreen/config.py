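"""Pipeline configuration with YAML overrides.

Every user-facing constant of the pipeline lives here with its default:
the dense-grid size used to discretise the fitted spine curve, the
sliding-window settings (window = length/10 of the sampled curve, step =
2 samples), the triangle-grading thresholds, the edge operator and its
Gaussian scale, the AMPD seed (recorded in outputs; results do not depend
on it) and the profile conditioning parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    n_samples: int = 200
    window_frac: float = 0.1
    step: int = 2
    triangle_thresholds: tuple = (2.0, 5.0, 10.0)
    edge_operator: str = "prewitt"
    log_sigma: float = 1.4
    profile_smooth_sigma: float = 2.0
    min_sep_frac: float = 0.1
    flat_win_frac: float = 0.05
    ampd_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ConfigError("n_samples must be >= 20")
        if not 0 < self.window_frac <= 0.5:
            raise ConfigError("window_frac must be in (0, 0.5]")
        if self.step < 1:
            raise ConfigError("step must be >= 1")
        t = tuple(float(x) for x in self.triangle_thresholds)
        if len(t) != 3 or not (t[0] < t[1] < t[2]):
            raise ConfigError("triangle_thresholds must be 3 ascending values")
        self.triangle_thresholds = t
        if self.edge_operator not in ("roberts", "prewitt", "log"):
            raise ConfigError(f"unknown edge operator {self.edge_operator!r}")
        if self.log_sigma <= 0:
            raise ConfigError("log_sigma must be positive")

    @classmethod
    def load(cls, path=None, **overrides) -> "PipelineConfig":
        """Defaults, optionally updated from a YAML file, then kwargs."""
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            if not isinstance(data, dict):
                raise ConfigError("config file must contain a mapping")
            unknown = set(data) - set(cls.__dataclass_fields__)
            if unknown:
                raise ConfigError(f"unknown config keys: {sorted(unknown)}")
            values.update(data)
        values.update(overrides)
        return cls(**values)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["triangle_thresholds"] = list(d["triangle_thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
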