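"""Vibrational band catalog and wavenumber-subset presets.

The default catalog ships as a CSV data file
(``lipidspec/data/band_catalog.csv``) with one row per assigned band, so it
can be extended or replaced without touching code.  Bands split into a C-H
stretching block and a fingerprint block; the split boundary defaults to
2000 cm^-1, which sits in the gap between the two scanned windows.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "BandAssignment",
    "BandCatalog",
    "SPECIES_TAGS",
    "SUBSET_PRESETS",
    "load_catalog",
    "partition_bands",
    "select_subset",
]

#: Allowed species tags; "DOPC-SM" means shared by DOPC and SM.
SPECIES_TAGS = frozenset({"Chol", "DOPC", "SM", "DOPC-SM", "All"})

# Unicode dash variants that may appear in hand-edited catalogs.
_DASHES = str.maketrans({"−": "-", "–": "-", "—": "-"})


@dataclass(frozen=True)
class BandAssignment:
    """One assigned vibrational band."""

    position: float  # cm^-1
    vibration: str
    species: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError("band position must be positive")
        tag = self.species.translate(_DASHES)
        if tag not in SPECIES_TAGS:
            raise ValueError(
                f"unknown species tag {self.species!r}; expected one of {sorted(SPECIES_TAGS)}"
            )
        object.__setattr__(self, "species", tag)


@dataclass(frozen=True)
class BandCatalog:
    """Ordered band assignments, descending by position as conventionally printed."""

    entries: tuple[BandAssignment, ...]

    def __post_init__(self) -> None:
        positions = [e.position for e in self.entries]
        if len(set(positions)) != len(positions):
            raise ValueError("band positions must be unique within a catalog")
        object.__setattr__(
            self,
            "entries",
            tuple(sorted(self.entries, key=lambda e: -e.position)),
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[BandAssignment]:
        return iter(self.entries)

    @property
    def positions(self) -> list[float]:
        return [e.position for e in self.entries]

    def __getitem__(self, position: float) -> BandAssignment:
        for entry in self.entries:
            if entry.position == position:
                return entry
        raise KeyError(f"no band at {position} cm^-1")

    def for_species(self, *tags: str) -> list[BandAssignment]:
        wanted = {t.translate(_DASHES) for t in tags}
        return [e for e in self.entries if e.species in wanted]


def load_catalog(path: str | Path | None = None) -> BandCatalog:
    """Load a band catalog from CSV (default: the packaged assignment table)."""
    if path is None:
        source = resources.files("lipidspec.data").joinpath("band_catalog.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines())
    required = {"position_cm1", "vibration", "species"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(f"catalog CSV must have columns {sorted(required)}")
    entries = [
        BandAssignment(
            position=float(row["position_cm1"]),
            vibration=row["vibration"],
            species=row["species"],
        )
        for row in reader
    ]
    return BandCatalog(tuple(entries))


def partition_bands(
    catalog: BandCatalog, boundary: float = 2000.0
) -> tuple[list[float], list[float]]:
    """Split catalog positions into (C-H stretching, fingerprint) blocks.

    Positions strictly above ``boundary`` go to the first list.  A boundary
    placed inside either scanned block (rather than the gap between them)
    still partitions, but draws a warning.
    """
    positions = catalog.positions
    ch = [p for p in positions if p > boundary]
    fp = [p for p in positions if p <= boundary]
    if len(positions) >= 2:
        ascending = sorted(positions)
        gaps = [b - a for a, b in zip(ascending, ascending[1:])]
        widest = int(max(range(len(gaps)), key=gaps.__getitem__))
        gap_lo, gap_hi = ascending[widest], ascending[widest + 1]
        if not (gap_lo < boundary < gap_hi):
            warnings.warn(
                f"boundary {boundary} cm^-1 falls inside a spectral block "
                f"(the gap between blocks spans {gap_lo}-{gap_hi})",
                stacklevel=2,
            )
    return ch, fp


#: Fixed-member presets (scan windows are (high, low) ranges, not members).
_LDA6 = (1731.0, 1645.0, 1555.0, 1464.0, 1375.0, 1056.0)

SUBSET_PRESETS = ("all22", "ch7", "fp15", "lda6", "sm_window", "chol_window")


def select_subset(catalog: BandCatalog, preset: str) -> list[float]:
    """Return the wavenumbers of a named subset preset.

    ``all22``/``ch7``/``fp15`` derive from the catalog partition; ``lda6``
    is the fixed six-band fingerprint subset; ``sm_window`` and
    ``chol_window`` are the narrow scan ranges used for the cell
    experiments, returned as ``[high, low]`` bounds.
    """
    if preset == "all22":
        return catalog.positions
    if preset in ("ch7", "fp15"):
        ch, fp = partition_bands(catalog)
        return ch if preset == "ch7" else fp
    if preset == "lda6":
        return list(_LDA6)
    if preset == "sm_window":
        return [1600.0, 1400.0]
    if preset == "chol_window":
        return [1070.0, 900.0]
    raise ValueError(
        f"unknown subset preset {preset!r}; valid presets: {', '.join(SUBSET_PRESETS)}"
    )
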