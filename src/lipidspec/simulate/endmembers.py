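"""Endmember spectra built from Lorentzian band stacks.

Band positions follow the packaged assignment catalog; amplitudes and
widths are illustrative defaults stored in editable CSV spec files
(``lipidspec/data/endmembers/``) so they can be re-fit to measured
libraries.  Each band is a unit-peak Lorentzian; the carbon-tape reference
is a band-free constant profile.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from ..core import Spectrum, WavenumberGrid

__all__ = [
    "EndmemberSpec",
    "lorentzian",
    "load_endmember_spec",
    "available_species",
    "synthesize_endmember",
]


@dataclass(frozen=True)
class EndmemberSpec:
    """Parametric description of one endmember: bands plus a constant baseline."""

    species: str
    bands: tuple[tuple[float, float, float], ...]  # (center, amplitude, fwhm)
    baseline: float = 0.0

    def __post_init__(self) -> None:
        for center, amplitude, fwhm in self.bands:
            if amplitude < 0:
                raise ValueError(f"{self.species}: negative amplitude at {center}")
            if fwhm <= 0:
                raise ValueError(f"{self.species}: non-positive FWHM at {center}")

    def shift_band(self, center: float, new_center: float) -> "EndmemberSpec":
        """Return a copy with one band moved to a new center."""
        bands = tuple(
            (new_center if c == center else c, a, w) for c, a, w in self.bands
        )
        if bands == self.bands:
            raise KeyError(f"{self.species} has no band at {center} cm^-1")
        return EndmemberSpec(self.species, bands, self.baseline)


def lorentzian(nu: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-peak Lorentzian line shape."""
    half = fwhm / 2.0
    return 1.0 / (1.0 + ((np.asarray(nu, dtype=float) - center) / half) ** 2)


def _read_spec_csv(text: str, species: str, baseline: float) -> EndmemberSpec:
    rows = list(csv.DictReader(text.splitlines()))
    bands = tuple(
        (float(r["center_cm1"]), float(r["amplitude"]), float(r["fwhm_cm1"]))
        for r in rows
    )
    return EndmemberSpec(species=species, bands=bands, baseline=baseline)


def _load_index(directory: Path | None) -> dict:
    if directory is None:
        base = resources.files("lipidspec.data").joinpath("endmembers")
        return json.loads(base.joinpath("index.json").read_text(encoding="utf-8"))
    return json.loads((directory / "index.json").read_text(encoding="utf-8"))


def available_species(directory: str | Path | None = None) -> list[str]:
    """Species names defined in the endmember index."""
    return list(_load_index(Path(directory) if directory else None))


def load_endmember_spec(
    species: str, directory: str | Path | None = None
) -> EndmemberSpec:
    """Load one endmember spec by species name from the index + CSV files."""
    directory = Path(directory) if directory else None
    index = _load_index(directory)
    if species not in index:
        raise KeyError(
            f"unknown endmember species {species!r}; available: {sorted(index)}"
        )
    entry = index[species]
    if directory is None:
        base = resources.files("lipidspec.data").joinpath("endmembers")
        text = base.joinpath(entry["file"]).read_text(encoding="utf-8")
    else:
        text = (directory / entry["file"]).read_text(encoding="utf-8")
    return _read_spec_csv(text, species, float(entry.get("baseline", 0.0)))


def synthesize_endmember(spec: EndmemberSpec, grid: WavenumberGrid) -> Spectrum:
    """Evaluate an endmember spec on a grid: baseline + sum of Lorentzian bands."""
    nu = grid.values
    intensity = np.full(nu.shape, spec.baseline, dtype=float)
    for center, amplitude, fwhm in spec.bands:
        intensity += amplitude * lorentzian(nu, center, fwhm)
    return Spectrum(grid, intensity)
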