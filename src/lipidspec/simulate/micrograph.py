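"""Synthetic single-wavenumber micrographs: disks of cells on a flat
background, used to exercise segmentation and CNR measurements."""

from __future__ import annotations

import numpy as np

__all__ = ["generate_disk_micrograph"]


def generate_disk_micrograph(
    shape: tuple[int, int] = (128, 128),
    centers: list[tuple[int, int]] | None = None,
    radius: float = 10.0,
    intensity: float = 1.0,
    background: float = 0.1,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (image, truth mask) for disks of a set intensity on background.

    ``noise_sigma`` is the additive Gaussian s.d. relative to the clean
    maximum.  Default centers place four disks on a 2x2 grid.
    """
    h, w = shape
    if centers is None:
        centers = [(h // 4, w // 4), (h // 4, 3 * w // 4),
                   (3 * h // 4, w // 4), (3 * h // 4, 3 * w // 4)]
    rr, cc = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for r0, c0 in centers:
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    clean = np.where(mask, intensity, background).astype(float)
    rng = np.random.default_rng(seed)
    image = clean
    if noise_sigma > 0:
        image = clean + rng.normal(0.0, noise_sigma * clean.max(), size=shape)
    return image, mask
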