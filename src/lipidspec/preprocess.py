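"""Preprocessing chains.

Two chains are implemented: cube normalization for unmixing
(reference-region normalization per band, then per-pixel L1
normalization), and the five-step single-spectrum chain used for the cell
statistics (offset subtraction, endpoint normalization, spline resampling,
medium subtraction, max normalization).

Spectra are stored with ascending wavenumbers but acquired scanning from
high to low wavenumber, so the "first spectral value" is the one at the
highest wavenumber and the "final point" the one at the lowest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.interpolate import CubicSpline

from .core import HyperCube, Spectrum, WavenumberGrid

__all__ = [
    "ReferenceMask",
    "PreprocessedSpectrum",
    "normalize_cube_by_reference",
    "l1_normalize_pixels",
    "preprocess_cell_spectrum",
    "differential_spectrum",
    "replay_log",
]


@dataclass(frozen=True)
class ReferenceMask:
    """Boolean pixel mask selecting the spectrally flat reference material."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("reference mask must be a non-empty 2-D pixel set")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_truth(cls, cube: HyperCube, name: str = "carbon_tape") -> "ReferenceMask":
        if cube.truth is None:
            raise ValueError("cube carries no ground truth to build a mask from")
        return cls(cube.truth.mask(name))

    @classmethod
    def from_coords(
        cls, coords: list[tuple[int, int]], shape: tuple[int, int]
    ) -> "ReferenceMask":
        mask = np.zeros(shape, dtype=bool)
        for r, c in coords:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"coordinate ({r}, {c}) outside image {shape}")
            mask[r, c] = True
        return cls(mask)


def normalize_cube_by_reference(cube: HyperCube, mask: ReferenceMask) -> HyperCube:
    """Divide every band by its mean intensity over the reference region.

    Removes per-band multiplicative gain drift exactly (up to reference
    noise); the reference region has per-band mean 1 afterwards.
    """
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube image shape")
    means = cube.data[mask.mask].mean(axis=0)
    bad = ~np.isfinite(means) | (means <= 0)
    if bad.any():
        offenders = cube.grid.values[bad]
        raise ValueError(
            f"reference mean non-positive or non-finite at bands {offenders.tolist()}"
        )
    return HyperCube(
        data=cube.data / means,
        grid=cube.grid,
        pixel_size=cube.pixel_size,
        provenance={**cube.provenance, "reference_normalized": True},
        truth=cube.truth,
        background=cube.background,
    )


def l1_normalize_pixels(cube: HyperCube, on_zero: str = "flag") -> HyperCube:
    """Normalize each pixel spectrum by its L1 norm along the band axis.

    Pixels with zero L1 norm are flagged as background (default) or raise,
    per ``on_zero`` ("flag" | "error").
    """
    if on_zero not in ("flag", "error"):
        raise ValueError("on_zero must be 'flag' or 'error'")
    norms = np.abs(cube.data).sum(axis=2)
    zero = norms == 0
    if zero.any() and on_zero == "error":
        r, c = np.argwhere(zero)[0]
        raise ValueError(f"pixel ({r}, {c}) has zero L1 norm")
    safe = np.where(zero, 1.0, norms)
    background = zero if cube.background is None else (cube.background | zero)
    return HyperCube(
        data=cube.data / safe[:, :, None],
        grid=cube.grid,
        pixel_size=cube.pixel_size,
        provenance={**cube.provenance, "l1_normalized": True},
        truth=cube.truth,
        background=background,
    )


@dataclass
class PreprocessedSpectrum:
    """A spectrum plus the append-only log of processing steps applied to it."""

    spectrum: Spectrum
    log: list[dict[str, Any]] = field(default_factory=list)

    @property
    def grid(self) -> WavenumberGrid:
        return self.spectrum.grid

    @property
    def intensity(self) -> np.ndarray:
        return self.spectrum.intensity


def _offset_endpoint_spline(
    s: Spectrum, target_grid: WavenumberGrid, what: str
) -> tuple[np.ndarray, list[dict[str, Any]]]:
    """Steps 1-3: offset subtraction, endpoint normalization, spline resample."""
    y = s.intensity - s.intensity[-1]  # first acquired point = highest wavenumber
    divisor = y[0]  # final acquired point = lowest wavenumber
    if divisor == 0:
        raise ValueError(
            f"endpoint normalization of {what}: value at the final point is zero"
        )
    y = y / divisor
    lo, hi = s.grid.values[0], s.grid.values[-1]
    if target_grid.values[0] < lo or target_grid.values[-1] > hi:
        raise ValueError(
            f"target grid [{target_grid.values[0]}, {target_grid.values[-1]}] "
            f"extends outside the {what} range [{lo}, {hi}]; extrapolation is forbidden"
        )
    spline = CubicSpline(s.grid.values, y, bc_type="natural")
    resampled = spline(target_grid.values)
    log = [
        {"step": "subtract_offset", "value": float(s.intensity[-1])},
        {"step": "endpoint_normalize", "divisor": float(divisor)},
        {
            "step": "spline_resample",
            "target_grid": target_grid.values.tolist(),
            "kind": "cubic-natural",
        },
    ]
    return resampled, log


def preprocess_cell_spectrum(
    s: Spectrum, medium: Spectrum, target_grid: WavenumberGrid
) -> PreprocessedSpectrum:
    """Five-step cell-spectrum chain.

    1. subtract the first acquired spectral value;
    2. divide by the (offset-subtracted) value at the final point;
    3. cubic-spline resample onto ``target_grid``;
    4. subtract the medium spectrum processed by steps 1-3;
    5. divide by the maximum of the result.
    """
    y, log = _offset_endpoint_spline(s, target_grid, "spectrum")
    m, _ = _offset_endpoint_spline(medium, target_grid, "medium")
    y = y - m
    log.append({"step": "subtract_medium", "medium_processed": True})
    peak = y.max()
    if peak <= 0:
        raise ValueError("maximum after medium subtraction is non-positive")
    y = y / peak
    log.append({"step": "max_normalize", "divisor": float(peak)})
    return PreprocessedSpectrum(Spectrum(target_grid, y), log)


def replay_log(
    s: Spectrum, medium: Spectrum, log: list[dict[str, Any]]
) -> PreprocessedSpectrum:
    """Re-run a recorded five-step chain on raw inputs; output is bit-identical."""
    resample = next(e for e in log if e["step"] == "spline_resample")
    target = WavenumberGrid(np.asarray(resample["target_grid"]))
    return preprocess_cell_spectrum(s, medium, target)


def differential_spectrum(
    late: PreprocessedSpectrum | Spectrum, early: PreprocessedSpectrum | Spectrum
) -> Spectrum:
    """Pointwise late - early on identical grids."""
    s_late = late.spectrum if isinstance(late, PreprocessedSpectrum) else late
    s_early = early.spectrum if isinstance(early, PreprocessedSpectrum) else early
    if s_late.grid != s_early.grid:
        raise ValueError("differential spectrum requires identical grids")
    return Spectrum(s_late.grid, s_late.intensity - s_early.intensity)
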