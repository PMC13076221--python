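"""Per-pixel non-negative least-squares unmixing against an endmember
library, crosstalk quantification along well profiles, and ternary
composition estimation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls as _nnls

from .core import HyperCube, Spectrum, WavenumberGrid
from .simulate.endmembers import load_endmember_spec, synthesize_endmember

__all__ = [
    "EndmemberLibrary",
    "AbundanceCube",
    "LineProfile",
    "CrosstalkEntry",
    "TernaryPoint",
    "nnls_unmix",
    "unmix_cube",
    "canonical_profile",
    "crosstalk_profile",
    "ternary_composition",
    "ternary_xy",
    "fractions_from_xy",
]

_LIPID_SPECIES = frozenset(
    {"Chol", "DOPC", "SM", "DOPE", "S1P", "MbCD_Chol_complex"}
)


@dataclass
class EndmemberLibrary:
    """Design matrix of L1-normalized endmember spectra on a common grid."""

    names: list[str]
    matrix: np.ndarray  # (n_bands, n_endmembers), columns L1-normalized
    grid: WavenumberGrid
    lipid_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("endmember names must be unique")
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.shape != (len(self.grid), len(self.names)):
            raise ValueError("matrix shape must be (n_bands, n_endmembers)")
        norms = np.abs(matrix).sum(axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("library columns must be L1-normalized")
        if not self.lipid_names:
            self.lipid_names = [n for n in self.names if n in _LIPID_SPECIES]
        unknown = set(self.lipid_names) - set(self.names)
        if unknown:
            raise ValueError(f"lipid subset {unknown} not in library")
        self.matrix = matrix

    @classmethod
    def build(
        cls,
        species: Sequence[str],
        grid: WavenumberGrid,
        directory: str | None = None,
        lipid_names: Sequence[str] | None = None,
    ) -> "EndmemberLibrary":
        """Synthesize endmembers on a grid and L1-normalize the columns."""
        cols = []
        for name in species:
            spec = load_endmember_spec(name, directory)
            intensity = synthesize_endmember(spec, grid).intensity
            norm = np.abs(intensity).sum()
            if norm == 0:
                raise ValueError(f"endmember {name} is zero on this grid")
            cols.append(intensity / norm)
        return cls(
            names=list(species),
            matrix=np.column_stack(cols),
            grid=grid,
            lipid_names=list(lipid_names) if lipid_names else [],
        )

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def nnls_unmix(
    s: Spectrum | np.ndarray, lib: EndmemberLibrary
) -> tuple[np.ndarray, float]:
    """Solve ``argmin_{x >= 0} ||A x - s||_2`` for one spectrum.

    Returns the non-negative abundance vector and the attained residual
    norm.  Deterministic (Lawson-Hanson active set).
    """
    if isinstance(s, Spectrum):
        if s.grid != lib.grid:
            raise ValueError("spectrum grid does not match library grid")
        b = s.intensity
    else:
        b = np.asarray(s, dtype=float)
        if b.shape != (len(lib.grid),):
            raise ValueError("spectrum length does not match library grid")
    if not np.all(np.isfinite(b)):
        raise ValueError("spectrum contains non-finite values")
    x, rnorm = _nnls(lib.matrix, b)
    return x, float(rnorm)


@dataclass
class AbundanceCube:
    """Per-pixel NNLS coefficients and residual norms."""

    data: np.ndarray  # (H, W, n_endmembers), >= 0
    names: list[str]
    residual: np.ndarray  # (H, W)
    lipid_names: list[str]
    truth: object | None = None

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, :, self.names.index(name)]


def unmix_cube(cube: HyperCube, lib: EndmemberLibrary) -> AbundanceCube:
    """Apply NNLS unmixing pixel by pixel; background pixels get zeros."""
    if cube.grid != lib.grid:
        raise ValueError("cube grid does not match library grid")
    h, w, _ = cube.shape
    abundances = np.zeros((h, w, len(lib.names)))
    residual = np.zeros((h, w))
    background = (
        cube.background
        if cube.background is not None
        else np.zeros((h, w), dtype=bool)
    )
    for r in range(h):
        for c in range(w):
            if background[r, c]:
                continue
            try:
                abundances[r, c], residual[r, c] = nnls_unmix(cube.data[r, c], lib)
            except ValueError as exc:
                raise ValueError(f"pixel ({r}, {c}): {exc}") from exc
    return AbundanceCube(
        data=abundances,
        names=list(lib.names),
        residual=residual,
        lipid_names=list(lib.lipid_names),
        truth=cube.truth,
    )


@dataclass(frozen=True)
class LineProfile:
    """Ordered pixel coordinates tracing a path across a well."""

    points: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a line profile needs at least 2 points")

    def __len__(self) -> int:
        return len(self.points)


def canonical_profile(ab_or_cube: AbundanceCube | HyperCube, well: str) -> LineProfile:
    """Horizontal profile through a well's centroid row, from ground truth."""
    truth = ab_or_cube.truth
    if truth is None:
        raise ValueError("no ground truth available; supply a profile explicitly")
    mask = truth.mask(well)
    if not mask.any():
        raise ValueError(f"well {well!r} not present in the truth map")
    rows, cols = np.nonzero(mask)
    row = int(round(rows.mean()))
    in_row = np.sort(cols[rows == row])
    return LineProfile(tuple((row, int(c)) for c in in_row))


@dataclass(frozen=True)
class CrosstalkEntry:
    """Mean lipid abundances along one well profile and the crosstalk percent."""

    well: str
    target: str
    means: dict[str, float]
    crosstalk_pct: float


def crosstalk_profile(
    ab: AbundanceCube,
    profile: LineProfile,
    target: str,
    well: str | None = None,
) -> CrosstalkEntry:
    """Crosstalk of a well profile: share of off-target lipid signal.

    ``crosstalk% = 100 * (1 - mean_target / sum over lipid means)``; the
    water and carbon-tape channels are excluded from the denominator.
    """
    if target not in ab.lipid_names:
        raise ValueError(
            f"target {target!r} is not a lipid endmember {ab.lipid_names}"
        )
    h, w = ab.residual.shape
    for r, c in profile.points:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"profile point ({r}, {c}) outside image {(h, w)}")
    idx = tuple(np.array(profile.points).T)
    means = {
        name: float(ab.channel(name)[idx].mean()) for name in ab.lipid_names
    }
    total = sum(means.values())
    if total == 0:
        raise ValueError("all lipid means are zero along the profile")
    crosstalk = 100.0 * (1.0 - means[target] / total)
    return CrosstalkEntry(
        well=well or target, target=target, means=means,
        crosstalk_pct=float(np.clip(crosstalk, 0.0, 100.0)),
    )


@dataclass(frozen=True)
class TernaryPoint:
    """Lipid fraction triple with its equilateral-triangle embedding."""

    fractions: dict[str, float]
    x: float
    y: float


#: Vertex order: first at (0,0), second at (1,0), third at the apex.
DEFAULT_VERTEX_ORDER = ("DOPC", "SM", "Chol")


def ternary_xy(
    fractions: Sequence[float],
) -> tuple[float, float]:
    """Planar embedding of a simplex triple (f_origin, f_right, f_apex)."""
    f0, f1, f2 = fractions
    return f1 + f2 / 2.0, (np.sqrt(3.0) / 2.0) * f2


def fractions_from_xy(x: float, y: float) -> tuple[float, float, float]:
    """Inverse of :func:`ternary_xy` (affine bijection of the simplex)."""
    f2 = 2.0 * y / np.sqrt(3.0)
    f1 = x - f2 / 2.0
    return 1.0 - f1 - f2, f1, f2


def ternary_composition(
    abundances: np.ndarray | dict[str, float],
    names: Sequence[str] | AbundanceCube | EndmemberLibrary | None = None,
    vertex_order: tuple[str, str, str] = DEFAULT_VERTEX_ORDER,
) -> TernaryPoint:
    """Normalize lipid abundances to fractions and embed them in the triangle."""
    if isinstance(abundances, dict):
        values = abundances
    else:
        if isinstance(names, (AbundanceCube, EndmemberLibrary)):
            names = names.names
        if names is None:
            raise ValueError("names required when abundances is an array")
        values = dict(zip(names, np.asarray(abundances, dtype=float)))
    missing = [v for v in vertex_order if v not in values]
    if missing:
        raise ValueError(f"abundances missing lipid channels {missing}")
    raw = np.array([values[v] for v in vertex_order], dtype=float)
    total = raw.sum()
    if total <= 0:
        raise ValueError("lipid abundance sum is zero")
    fracs = raw / total
    x, y = ternary_xy(fracs)
    return TernaryPoint(
        fractions=dict(zip(vertex_order, map(float, fracs))), x=float(x), y=float(y)
    )
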