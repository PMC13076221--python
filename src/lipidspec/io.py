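"""Plain-text readers and writers for spectra and cubes.

Spectra are two-column CSVs (``wavenumber_cm1,intensity``).  Cubes are
directories holding ``manifest.json`` plus one matrix CSV per band, named
``band_<wavenumber printed with two decimals>.csv``.  Everything written
carries provenance sufficient to regenerate it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .core import HyperCube, PhantomTruth, Spectrum, WavenumberGrid

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_cube",
    "write_cube",
    "write_abundance_channels",
]

FORMAT_VERSION = 1
_SPECTRUM_HEADER = "wavenumber_cm1,intensity"


def write_spectrum(s: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    lines = [_SPECTRUM_HEADER]
    lines += [
        f"{float(nu)!r},{float(val)!r}"
        for nu, val in zip(s.grid.values, s.intensity)
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum CSV; wavenumbers are sorted ascending (with a warning
    if the file was stored descending)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != _SPECTRUM_HEADER:
        raise ValueError(
            f"{path}: line 1: expected header {_SPECTRUM_HEADER!r}"
        )
    nus, vals = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {lineno}: expected two columns")
        try:
            nus.append(float(parts[0]))
            vals.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
    nus_arr = np.asarray(nus)
    if nus_arr.size != np.unique(nus_arr).size:
        ordered = np.sort(nus_arr)
        dup = ordered[:-1][np.diff(ordered) == 0][0]
        raise ValueError(f"{path}: duplicate wavenumber {dup}")
    if np.all(np.diff(nus_arr) < 0):
        warnings.warn(f"{path}: wavenumbers stored descending; sorting ascending")
    order = np.argsort(nus_arr)
    return Spectrum(WavenumberGrid(nus_arr[order]), np.asarray(vals)[order])


def _band_name(nu: float) -> str:
    return f"band_{nu:.2f}.csv"


def write_cube(cube: HyperCube, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "wavenumbers": cube.grid.values.tolist(),
        "shape": list(cube.shape[:2]),
        "pixel_size_um": cube.pixel_size,
        "provenance": dict(cube.provenance),
    }
    for nu, band in zip(cube.grid.values, np.moveaxis(cube.data, 2, 0)):
        np.savetxt(directory / _band_name(nu), band, delimiter=",", fmt="%.17g")
    if cube.background is not None:
        np.savetxt(
            directory / "background.csv", cube.background.astype(int),
            delimiter=",", fmt="%d",
        )
        manifest["background"] = "background.csv"
    if cube.truth is not None:
        np.savetxt(
            directory / "truth_labels.csv", cube.truth.labels,
            delimiter=",", fmt="%d",
        )
        manifest["truth"] = {
            "labels": "truth_labels.csv",
            "names": cube.truth.names,
            "gain": cube.truth.gain.tolist(),
        }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1), encoding="utf-8"
    )
    return directory


def read_cube(directory: str | Path) -> HyperCube:
    """Read a cube directory, validating the manifest against files present."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"{directory}: missing manifest.json")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    wavenumbers = manifest["wavenumbers"]
    expected = {_band_name(nu) for nu in wavenumbers}
    present = {p.name for p in directory.glob("band_*.csv")}
    missing, extra = sorted(expected - present), sorted(present - expected)
    if missing or extra:
        raise ValueError(
            f"{directory}: band files do not match manifest; "
            f"missing {missing}, extra {extra}"
        )
    shape = tuple(manifest["shape"])
    data = np.empty((*shape, len(wavenumbers)))
    for i, nu in enumerate(wavenumbers):
        band = np.loadtxt(directory / _band_name(nu), delimiter=",", ndmin=2)
        if band.shape != shape:
            raise ValueError(
                f"{directory}/{_band_name(nu)}: shape {band.shape} != {shape}"
            )
        data[:, :, i] = band
    background = None
    if "background" in manifest:
        background = (
            np.loadtxt(directory / manifest["background"], delimiter=",", ndmin=2)
            .astype(bool)
        )
    truth = None
    if "truth" in manifest:
        t = manifest["truth"]
        truth = PhantomTruth(
            labels=np.loadtxt(directory / t["labels"], delimiter=",", ndmin=2).astype(int),
            names=list(t["names"]),
            gain=np.asarray(t["gain"], dtype=float),
        )
    return HyperCube(
        data=data,
        grid=WavenumberGrid(np.asarray(wavenumbers, dtype=float)),
        pixel_size=float(manifest.get("pixel_size_um", 25.0)),
        provenance=manifest.get("provenance", {}),
        truth=truth,
        background=background,
    )


def write_abundance_channels(
    data: np.ndarray,
    names: list[str],
    directory: str | Path,
    provenance: dict | None = None,
) -> Path:
    """Write an abundance stack as one CSV per named channel plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(names):
        np.savetxt(
            directory / f"channel_{name}.csv", data[:, :, i],
            delimiter=",", fmt="%.17g",
        )
    manifest = {
        "format_version": FORMAT_VERSION,
        "channels": names,
        "shape": list(data.shape[:2]),
        "provenance": provenance or {},
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1), encoding="utf-8"
    )
    return directory
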