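"""Scenario configuration for the synthetic-data generators."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

__all__ = ["SCENARIOS", "GUV_PRESETS", "ScenarioConfig"]

SCENARIOS = (
    "phantom2d",
    "phantom2d_pe_s1p",
    "guv",
    "cells_sm",
    "cells_control",
    "cells_chol",
)

#: Nominal vesicle compositions (molar fractions).
GUV_PRESETS: dict[str, dict[str, float]] = {
    "guv1": {"SM": 0.5, "Chol": 0.5},
    "guv2": {"DOPC": 0.4, "SM": 0.4, "Chol": 0.2},
    "guv3": {"DOPC": 1.0},
}

#: Injected enrichment (percent AUC change at the last time point) per scenario.
_DEFAULT_EFFECT = {"cells_sm": 117.0, "cells_control": 23.0, "cells_chol": 161.0}


@dataclass
class ScenarioConfig:
    """Generator parameters with stored defaults; the seed drives all randomness."""

    scenario: str
    seed: int = 0
    composition: dict[str, float] = field(default_factory=dict)
    n_samples: int = 10
    effect_percent: float = 0.0
    noise_sigma: float = 0.02
    drift_range: tuple[float, float] = (0.7, 1.3)
    composition_jitter: float = 0.15
    heterogeneity: float = 0.1
    sucrose_level: float = 0.2
    image_size: int = 160
    well_radius: int | None = None  # default: image_size // 4 - 2
    pixel_size: float = 25.0
    spacing: float = 2.0

    def __post_init__(self) -> None:
        if self.well_radius is None:
            self.well_radius = self.image_size // 4 - 2
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid: {', '.join(SCENARIOS)}"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.drift_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("drift_range bounds must be positive with high >= low")
        if self.composition:
            if any(f < 0 for f in self.composition.values()):
                raise ValueError("molar fractions must be >= 0")
            total = sum(self.composition.values())
            if total <= 0:
                raise ValueError("composition must not be all zero")
            if abs(total - 1.0) > 1e-9:
                self.composition = {
                    k: v / total for k, v in self.composition.items()
                }

    @classmethod
    def defaults(cls, scenario: str, seed: int = 0, **overrides: Any) -> "ScenarioConfig":
        """Scenario defaults: GUV 2:2:1 mix, 50 cells, published effect sizes."""
        kwargs: dict[str, Any] = {"scenario": scenario, "seed": seed}
        if scenario == "guv":
            kwargs.update(
                composition=dict(GUV_PRESETS["guv2"]), n_samples=10, spacing=4.0
            )
        elif scenario in _DEFAULT_EFFECT:
            kwargs.update(
                n_samples=50, effect_percent=_DEFAULT_EFFECT[scenario]
            )
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["drift_range"] = list(self.drift_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        if "drift_range" in d:
            d["drift_range"] = tuple(d["drift_range"])
        return cls(**d)
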