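"""Cell time-series spectrum generator.

A clean cell spectrum is medium + baseline bands (protein amide and
generic lipid content) plus a scenario marker band: the 1464 cm^-1
acyl-chain band for the SM-enrichment and control scenarios, the
1048 cm^-1 sterol-complex band (shifted 8 cm^-1 from the 1056 cm^-1
cellular sterol band) for the cholesterol-loading scenario.

The marker scale at each later time point is calibrated by root-finding so
that the band AUC measured by the full preprocessing chain on clean
spectra increases by exactly the configured effect percentage; noise and
per-cell heterogeneity then perturb individual cells around that
population effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from ..core import Spectrum, WavenumberGrid
from ..preprocess import preprocess_cell_spectrum
from ..stats import CHOL_AUC_WINDOW, SM_AUC_WINDOW, band_auc
from .config import ScenarioConfig
from .endmembers import EndmemberSpec, synthesize_endmember

__all__ = ["CellSeries", "generate_cell_series"]


@dataclass(frozen=True)
class _CellScenario:
    grid_range: tuple[float, float]  # (low, high)
    timepoints: tuple[tuple[str, float], ...]  # (label, hours)
    window: tuple[float, float]
    baseline: EndmemberSpec
    marker: EndmemberSpec
    medium: EndmemberSpec


_SM_BASELINE = EndmemberSpec(
    "cell_baseline_sm",
    bands=(
        (1645.0, 0.8, 12.0),  # amide I tail
        (1540.0, 3.5, 12.0),  # amide II, anchors the max normalization
        (1464.0, 0.6, 12.0),  # endogenous acyl-chain content
        (1430.0, 0.8, 80.0),  # broad generic lipid bending background
    ),
)
_CHOL_BASELINE = EndmemberSpec(
    "cell_baseline_chol",
    bands=(
        (1056.0, 2.2, 12.0),  # endogenous sterol ring
        (1023.0, 0.8, 12.0),
        (964.0, 3.0, 12.0),  # choline band, anchors the max normalization
        (958.0, 0.5, 12.0),
        (940.0, 0.5, 100.0),  # broad background
    ),
)

_SCENARIOS: dict[str, _CellScenario] = {
    "cells_sm": _CellScenario(
        grid_range=(1400.0, 1600.0),
        timepoints=(("T0", 0.0), ("T48", 48.0), ("T72", 72.0)),
        window=SM_AUC_WINDOW,
        baseline=_SM_BASELINE,
        marker=EndmemberSpec("sm_marker", bands=((1464.0, 1.0, 12.0),)),
        medium=EndmemberSpec("medium_sm", bands=((1380.0, 1.5, 100.0),)),
    ),
    "cells_chol": _CellScenario(
        grid_range=(900.0, 1070.0),
        timepoints=(("T0", 0.0), ("T16", 16.0)),
        window=CHOL_AUC_WINDOW,
        baseline=_CHOL_BASELINE,
        marker=EndmemberSpec("chol_complex_marker", bands=((1048.0, 1.0, 16.0),)),
        medium=EndmemberSpec("medium_chol", bands=((880.0, 1.5, 120.0),)),
    ),
}
_SCENARIOS["cells_control"] = _SCENARIOS["cells_sm"]


@dataclass
class CellSeries:
    """Generated cell spectra per time point, plus the medium spectrum."""

    timepoints: dict[str, list[Spectrum]]
    medium: Spectrum
    truth: dict
    config: ScenarioConfig

    def __getitem__(self, label: str) -> list[Spectrum]:
        return self.timepoints[label]


def _measured_auc(
    clean: np.ndarray, medium: Spectrum, grid: WavenumberGrid, window
) -> float:
    pre = preprocess_cell_spectrum(Spectrum(grid, clean), medium, grid)
    return band_auc(pre.spectrum, window)


@lru_cache(maxsize=32)
def _calibrate_marker(scenario: str, spacing: float, effect_percent: float):
    """Marker scales per time point so the clean pipeline AUC ramps linearly
    in time up to ``effect_percent`` at the final time point."""
    sc = _SCENARIOS[scenario]
    lo, hi = sc.grid_range
    grid = WavenumberGrid.from_segments([(lo, hi, spacing)])
    base = synthesize_endmember(sc.baseline, grid).intensity
    marker = synthesize_endmember(sc.marker, grid).intensity
    medium = synthesize_endmember(sc.medium, grid)
    clean0 = medium.intensity + base
    auc0 = _measured_auc(clean0, medium, grid, sc.window)

    t_final = sc.timepoints[-1][1]
    scales = {}
    for label, hours in sc.timepoints:
        target = auc0 * (1.0 + (effect_percent / 100.0) * (hours / t_final))
        if hours == 0.0 or effect_percent == 0.0:
            scales[label] = 0.0
            continue

        def gap(k: float) -> float:
            return _measured_auc(clean0 + k * marker, medium, grid, sc.window) - target

        k_hi = 1.0
        while gap(k_hi) < 0:
            k_hi *= 2.0
            if k_hi > 64.0:
                raise RuntimeError(
                    f"cannot calibrate a {effect_percent}% effect for {scenario}"
                )
        scales[label] = float(brentq(gap, 0.0, k_hi, xtol=1e-12))
    return grid, base, marker, medium, scales


def generate_cell_series(config: ScenarioConfig) -> CellSeries:
    """Generate seeded per-cell spectra for each time point of a cell scenario."""
    if config.scenario not in _SCENARIOS:
        raise ValueError(
            f"scenario {config.scenario!r} is not a cell scenario; valid: "
            f"{sorted(_SCENARIOS)}"
        )
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sc = _SCENARIOS[config.scenario]
    grid, base, marker, medium, scales = _calibrate_marker(
        config.scenario, config.spacing, config.effect_percent
    )

    rng = np.random.default_rng(config.seed)
    # per-cell multiplicative heterogeneity, constant across time (paired cells)
    cell_scale = np.clip(
        1.0 + config.heterogeneity * rng.standard_normal(config.n_samples), 0.1, None
    )
    clean_final = medium.intensity + base + scales[sc.timepoints[-1][0]] * marker
    noise_scale = config.noise_sigma * clean_final.max()

    timepoints: dict[str, list[Spectrum]] = {}
    for label, _hours in sc.timepoints:
        clean = medium.intensity + base + scales[label] * marker
        spectra = []
        for c in cell_scale:
            y = c * clean
            if noise_scale > 0:
                y = y + rng.normal(0.0, noise_scale, size=y.shape)
            spectra.append(Spectrum(grid, y))
        timepoints[label] = spectra

    return CellSeries(
        timepoints=timepoints,
        medium=medium,
        truth={
            "marker_scales": dict(scales),
            "effect_percent": config.effect_percent,
            "window": sc.window,
            "marker_center": sc.marker.bands[0][0],
            "cell_scale": cell_scale.tolist(),
        },
        config=config,
    )
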