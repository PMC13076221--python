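"""Scalar spectral statistics: CNR, band AUC, enrichment, paired t-test,
violin/box summaries, spectral correlation and micrograph intensity
extraction."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from skimage.filters import threshold_otsu

from .core import Spectrum

__all__ = [
    "BandWindow",
    "DistributionSummary",
    "Micrograph",
    "TTestResult",
    "SM_AUC_WINDOW",
    "CHOL_AUC_WINDOW",
    "cnr",
    "peak_to_peak",
    "band_auc",
    "percent_change",
    "paired_ttest",
    "violin_summary",
    "spectral_correlation",
    "extract_cell_intensity",
]

#: AUC integration window around the 1464 cm^-1 acyl-chain band.
SM_AUC_WINDOW = (1484.0, 1424.0)
#: AUC integration window around the 1048 cm^-1 sterol-complex band.
CHOL_AUC_WINDOW = (1062.0, 1026.0)


@dataclass(frozen=True)
class BandWindow:
    """Integration window given as (high, low) wavenumber bounds."""

    high: float
    low: float

    def __post_init__(self) -> None:
        if self.high <= self.low:
            raise ValueError("window requires high > low")

    @classmethod
    def coerce(cls, w: "BandWindow | tuple[float, float]") -> "BandWindow":
        if isinstance(w, BandWindow):
            return w
        a, b = w
        return cls(high=max(a, b), low=min(a, b))


def cnr(oa_sample: float, oa_background: float, noise_pkpk: float) -> float:
    """Contrast-to-noise ratio |sample - background| / peak-to-peak noise."""
    if noise_pkpk <= 0:
        raise ValueError("noise peak-to-peak amplitude must be positive")
    return abs(oa_sample - oa_background) / noise_pkpk


def peak_to_peak(values: np.ndarray | Sequence[float]) -> float:
    """Peak-to-peak amplitude (max - min) of a noise region."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty noise region")
    return float(values.max() - values.min())


def band_auc(s: Spectrum, window: BandWindow | tuple[float, float]) -> float:
    """Trapezoidal area under the spectrum over a wavenumber window."""
    w = BandWindow.coerce(window)
    nu = s.grid.values
    if w.low < nu[0] or w.high > nu[-1]:
        raise ValueError(
            f"window [{w.low}, {w.high}] outside grid range [{nu[0]}, {nu[-1]}]"
        )
    sel = (nu >= w.low) & (nu <= w.high)
    return float(np.trapezoid(s.intensity[sel], nu[sel]))


def percent_change(late: Sequence[float], early: Sequence[float]) -> float:
    """Percent change of the late mean relative to the early mean."""
    late = np.asarray(late, dtype=float)
    early = np.asarray(early, dtype=float)
    if late.size == 0 or early.size == 0:
        raise ValueError("both value lists must be non-empty")
    base = early.mean()
    if base <= 0:
        raise ValueError("early mean must be positive")
    return float(100.0 * (late.mean() - base) / base)


@dataclass(frozen=True)
class TTestResult:
    n: int
    t: float
    df: int
    p: float


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on equal-length samples.

    t = mean(d) * sqrt(n) / sd(d) with d = x - y and the n-1 sample s.d.;
    p from the t distribution with n-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    n = d.size
    t = float(d.mean() * math.sqrt(n) / sd)
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return TTestResult(n=n, t=t, df=n - 1, p=p)


@dataclass
class DistributionSummary:
    """Violin/box ingredients: KDE curve plus location and spread statistics."""

    grid: np.ndarray
    density: np.ndarray
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.empty(0))


def violin_summary(values: Sequence[float], n_grid: int = 512) -> DistributionSummary:
    """Gaussian-KDE summary (Silverman bandwidth) with mean +/- 1 s.d. whiskers."""
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("violin summary needs at least 5 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("violin summary of zero-variance data")
    kde = sps.gaussian_kde(values, bw_method="silverman")
    bw = kde.factor * sd
    grid = np.linspace(values.min() - 5 * bw, values.max() + 5 * bw, n_grid)
    density = kde(grid)
    mean = float(values.mean())
    lo, hi = mean - sd, mean + sd
    return DistributionSummary(
        grid=grid,
        density=density,
        mean=mean,
        sd=float(sd),
        median=float(np.median(values)),
        q1=float(np.percentile(values, 25)),
        q3=float(np.percentile(values, 75)),
        whisker_low=float(lo),
        whisker_high=float(hi),
        outliers=values[(values < lo) | (values > hi)],
    )


def spectral_correlation(s1: Spectrum, s2: Spectrum) -> float:
    """Pearson correlation of two spectra on a common grid."""
    if s1.grid != s2.grid:
        raise ValueError("spectral correlation requires a common grid")
    if s1.intensity.std() == 0 or s2.intensity.std() == 0:
        raise ValueError("spectral correlation of a zero-variance spectrum")
    return float(np.corrcoef(s1.intensity, s2.intensity)[0, 1])


@dataclass
class Micrograph:
    """Single-wavenumber intensity image with a background reference."""

    image: np.ndarray
    background: np.ndarray | float
    pixel_size: float = 5.0

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2 or not np.all(np.isfinite(img)):
            raise ValueError("micrograph must be a finite 2-D image")
        if isinstance(self.background, np.ndarray):
            if self.background.shape != img.shape:
                raise ValueError("background image shape must match micrograph")
        self.image = img


def extract_cell_intensity(
    m: Micrograph, threshold: float | None = None
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Background-subtract, segment cells and summarize their intensity.

    Foreground is segmented by Otsu's threshold on the subtracted image
    (or a fixed ``threshold`` override).  Returns the mask, the masked
    pixel intensities, and a box summary (mean, median, s.e.m. box, mean
    +/- 1 s.d. whiskers).
    """
    sub = m.image - m.background
    if sub.max() == sub.min():
        raise ValueError("no foreground pixels after thresholding")
    thr = threshold_otsu(sub) if threshold is None else threshold
    mask = sub > thr
    if not mask.any():
        raise ValueError("no foreground pixels after thresholding")
    pixels = sub[mask]
    mean = float(pixels.mean())
    sd = float(pixels.std(ddof=1)) if pixels.size > 1 else 0.0
    sem = sd / math.sqrt(pixels.size) if pixels.size > 1 else 0.0
    summary = {
        "n_pixels": int(pixels.size),
        "mean": mean,
        "median": float(np.median(pixels)),
        "sd": sd,
        "sem": sem,
        "box_low": mean - sem,
        "box_high": mean + sem,
        "whisker_low": mean - sd,
        "whisker_high": mean + sd,
        "threshold": float(thr),
    }
    return mask, pixels, summary
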