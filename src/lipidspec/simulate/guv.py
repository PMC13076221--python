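"""Vesicle mixture-spectrum generator.

Each vesicle spectrum is a fraction-weighted combination of L1-normalized
lipid endmember shapes plus a sucrose contribution near 1000 cm^-1 (the
encapsulated medium) and additive noise.  Per-vesicle composition jitter
models production variability; the realized fractions are recorded as
ground truth.
"""

from __future__ import annotations

import numpy as np

from ..core import Spectrum, WavenumberGrid
from .config import ScenarioConfig
from .endmembers import load_endmember_spec, synthesize_endmember

__all__ = ["generate_guv_spectra"]

_LIPIDS = ("DOPC", "SM", "Chol")


def _l1_shape(species: str, grid: WavenumberGrid) -> np.ndarray:
    intensity = synthesize_endmember(load_endmember_spec(species), grid).intensity
    return intensity / np.abs(intensity).sum()


def generate_guv_spectra(
    config: ScenarioConfig, grid: WavenumberGrid | None = None
) -> list[tuple[Spectrum, dict[str, float]]]:
    """Generate ``n_samples`` vesicle spectra with true lipid fractions."""
    if config.scenario != "guv":
        raise ValueError(f"scenario {config.scenario!r} is not 'guv'")
    unknown = set(config.composition) - set(_LIPIDS)
    if unknown:
        raise ValueError(f"composition keys must be lipids {_LIPIDS}, got {unknown}")
    if not config.composition:
        raise ValueError("composition must not be empty")
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    if grid is None:
        grid = WavenumberGrid.full(config.spacing)
    shapes = {sp: _l1_shape(sp, grid) for sp in _LIPIDS}
    sucrose = _l1_shape("sucrose", grid)

    nominal = np.array([config.composition.get(sp, 0.0) for sp in _LIPIDS])
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_samples):
        fracs = nominal * np.clip(
            1.0 + config.composition_jitter * rng.standard_normal(len(_LIPIDS)),
            0.0,
            None,
        )
        fracs /= fracs.sum()
        clean = sum(f * shapes[sp] for f, sp in zip(fracs, _LIPIDS))
        clean = clean + config.sucrose_level * sucrose
        intensity = clean
        if config.noise_sigma > 0:
            intensity = clean + rng.normal(
                0.0, config.noise_sigma * clean.max(), size=clean.shape
            )
        out.append(
            (Spectrum(grid, intensity), dict(zip(_LIPIDS, map(float, fracs))))
        )
    return out
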