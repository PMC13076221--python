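"""Shared domain types: wavenumber grids, spectra and hyperspectral cubes.

Wavenumbers are always stored ascending (in cm^-1); acquisition-order
semantics (scans run from high to low wavenumber) are handled only where
they matter, in :func:`lipidspec.preprocess.preprocess_cell_spectrum`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "PhantomTruth",
    "HyperCube",
    "FINGERPRINT_RANGE",
    "CH_STRETCH_RANGE",
]

#: Scanned fingerprint window (cm^-1).
FINGERPRINT_RANGE = (900.0, 1730.0)
#: Scanned C-H stretching window (cm^-1).
CH_STRETCH_RANGE = (2770.0, 2932.0)


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending wavenumber sample points, possibly in two segments."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("wavenumber grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("wavenumber grid contains non-finite values")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.values.tobytes())

    @classmethod
    def from_segments(
        cls, segments: Sequence[tuple[float, float, float]]
    ) -> "WavenumberGrid":
        """Build a grid from ``(low, high, spacing)`` segments (inclusive ends)."""
        parts = []
        for low, high, step in segments:
            if high <= low or step <= 0:
                raise ValueError(f"invalid segment ({low}, {high}, {step})")
            n = int(round((high - low) / step))
            parts.append(low + step * np.arange(n + 1))
        return cls(np.concatenate(parts))

    @classmethod
    def fingerprint(cls, spacing: float = 2.0) -> "WavenumberGrid":
        lo, hi = FINGERPRINT_RANGE
        return cls.from_segments([(lo, hi, spacing)])

    @classmethod
    def full(cls, spacing: float = 2.0) -> "WavenumberGrid":
        """Fingerprint plus C-H stretching segments at one spacing."""
        return cls.from_segments(
            [FINGERPRINT_RANGE + (spacing,), CH_STRETCH_RANGE + (spacing,)]
        )


@dataclass
class Spectrum:
    """A single spectrum: intensity sampled on a wavenumber grid."""

    grid: WavenumberGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if inten.shape != (len(self.grid),):
            raise ValueError(
                f"intensity length {inten.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(inten)):
            raise ValueError("spectrum intensity contains non-finite values")
        self.intensity = inten

    def value_at(self, wavenumber: float) -> float:
        """Intensity at an exact grid point (no interpolation)."""
        idx = np.searchsorted(self.grid.values, wavenumber)
        if idx >= len(self.grid) or self.grid.values[idx] != wavenumber:
            raise KeyError(f"{wavenumber} cm^-1 is not a grid point")
        return float(self.intensity[idx])

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid, self.intensity.copy())


@dataclass
class PhantomTruth:
    """Ground truth stored with a synthetic cube."""

    labels: np.ndarray  # (H, W) int codes into `names`
    names: list[str]
    gain: np.ndarray  # per-band multiplicative gain applied to the clean cube

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.names.index(name)


@dataclass
class HyperCube:
    """Hyperspectral image cube indexed (row, col, band)."""

    data: np.ndarray
    grid: WavenumberGrid
    pixel_size: float = 25.0
    provenance: Mapping[str, Any] = field(default_factory=dict)
    truth: PhantomTruth | None = None
    background: np.ndarray | None = None  # bool (H, W), flagged by L1 normalization

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("cube data must be 3-D (row, col, band)")
        if data.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {data.shape[2]} bands but grid has {len(self.grid)}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.data = data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixel_spectrum(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.grid, self.data[row, col].copy())

    def band_index(self, wavenumber: float) -> int:
        idx = int(np.searchsorted(self.grid.values, wavenumber))
        if idx >= len(self.grid) or self.grid.values[idx] != wavenumber:
            raise KeyError(f"{wavenumber} cm^-1 is not a cube band")
        return idx

    def band_image(self, wavenumber: float) -> np.ndarray:
        return self.data[:, :, self.band_index(wavenumber)]
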