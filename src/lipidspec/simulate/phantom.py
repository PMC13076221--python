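"""Four-well phantom hypercube generator.

The phantom mimics a well plate on a spectrally flat carbon-tape
background: four disjoint circular wells (three lipids plus water) sampled
at the catalog wavenumbers.  Per-band multiplicative gain drift (constant
across pixels within a band) models source-power instability; additive
Gaussian noise is scaled to the clean-signal maximum.  Ground truth (label
map and gain vector) rides along on the cube.
"""

from __future__ import annotations

import numpy as np

from ..bands import load_catalog
from ..core import HyperCube, PhantomTruth, WavenumberGrid
from .config import ScenarioConfig
from .endmembers import load_endmember_spec, synthesize_endmember

__all__ = ["PHANTOM_WELLS", "generate_phantom_cube", "well_centers", "canonical_rois"]

PHANTOM_WELLS = {
    "phantom2d": ("Chol", "DOPC", "SM", "water"),
    "phantom2d_pe_s1p": ("DOPC", "DOPE", "S1P", "water"),
}


def well_centers(image_size: int) -> list[tuple[int, int]]:
    """Quadrant centers of the four wells for a square image."""
    q, t = image_size // 4, 3 * image_size // 4
    return [(q, q), (q, t), (t, q), (t, t)]


def _catalog_grid() -> WavenumberGrid:
    return WavenumberGrid(np.sort(np.asarray(load_catalog().positions)))


def generate_phantom_cube(config: ScenarioConfig) -> HyperCube:
    """Generate a seeded phantom cube with stored ground truth."""
    if config.scenario not in PHANTOM_WELLS:
        raise ValueError(
            f"scenario {config.scenario!r} is not a phantom scenario"
        )
    size, radius = config.image_size, config.well_radius
    if radius <= 0 or radius >= size // 4 + 1:
        raise ValueError(
            f"well radius {radius} does not fit four disjoint wells in a "
            f"{size}x{size} image"
        )

    grid = _catalog_grid()
    species = PHANTOM_WELLS[config.scenario]
    names = ["carbon_tape", *species]
    spectra = {
        name: synthesize_endmember(load_endmember_spec(name), grid).intensity
        for name in names
    }

    labels = np.zeros((size, size), dtype=int)
    rr, cc = np.mgrid[0:size, 0:size]
    for code, (name, (r0, c0)) in enumerate(
        zip(species, well_centers(size)), start=1
    ):
        inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
        labels[inside] = code

    clean = np.empty((size, size, len(grid)), dtype=float)
    for code, name in enumerate(names):
        clean[labels == code] = spectra[name]

    rng = np.random.default_rng(config.seed)
    gain = rng.uniform(*config.drift_range, size=len(grid))
    data = clean * gain
    if config.noise_sigma > 0:
        data = data + rng.normal(
            0.0, config.noise_sigma * clean.max(), size=data.shape
        )

    return HyperCube(
        data=data,
        grid=grid,
        pixel_size=config.pixel_size,
        provenance={"config": config.to_dict()},
        truth=PhantomTruth(labels=labels, names=names, gain=gain),
    )


def canonical_rois(
    cube: HyperCube, roi_size: int = 50
) -> list[tuple[str, tuple[int, int], int]]:
    """Square ROIs centered on each lipid well, as (label, top-left, size).

    Requires ground truth; the water well is excluded.
    """
    if cube.truth is None:
        raise ValueError("cube carries no ground truth; supply ROIs explicitly")
    half = roi_size // 2
    rois = []
    for name in cube.truth.names:
        if name in ("carbon_tape", "water"):
            continue
        rows, cols = np.nonzero(cube.truth.mask(name))
        r0 = int(round(rows.mean())) - half
        c0 = int(round(cols.mean())) - half
        inside = cube.truth.labels[r0 : r0 + roi_size, c0 : c0 + roi_size]
        if inside.shape != (roi_size, roi_size) or not np.all(
            inside == cube.truth.names.index(name)
        ):
            raise ValueError(
                f"a {roi_size}x{roi_size} ROI does not fit inside the {name} well"
            )
        rois.append((name, (r0, c0), roi_size))
    return rois
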