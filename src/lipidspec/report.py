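"""End-to-end analysis runs on synthetic scenarios.

Each function composes the pipeline stages exactly as the CLI does and
returns plain dictionaries, so the ``report`` subcommand and downstream
scripts share one code path.
"""

from __future__ import annotations

import numpy as np

from .bands import load_catalog, select_subset
from .classify import extract_labeled_pixels, lda_cross_validate
from .core import HyperCube
from .preprocess import (
    ReferenceMask,
    l1_normalize_pixels,
    normalize_cube_by_reference,
    preprocess_cell_spectrum,
)
from .simulate import (
    GUV_PRESETS,
    ScenarioConfig,
    canonical_rois,
    generate_cell_series,
    generate_guv_spectra,
    generate_phantom_cube,
)
from .stats import band_auc, paired_ttest, percent_change
from .unmix import (
    EndmemberLibrary,
    canonical_profile,
    crosstalk_profile,
    nnls_unmix,
    ternary_composition,
    unmix_cube,
)

__all__ = [
    "preprocess_phantom",
    "phantom_library",
    "run_phantom_analysis",
    "run_guv_analysis",
    "run_cells_analysis",
    "build_report",
]


def preprocess_phantom(cube: HyperCube) -> HyperCube:
    """Reference-normalize (carbon tape from truth) then L1-normalize pixels."""
    mask = ReferenceMask.from_truth(cube, "carbon_tape")
    return l1_normalize_pixels(normalize_cube_by_reference(cube, mask))


def phantom_library(cube: HyperCube) -> EndmemberLibrary:
    """The generator's own endmembers on the cube grid (lipids + water + tape)."""
    if cube.truth is None:
        raise ValueError("phantom_library requires a cube with ground truth")
    species = cube.truth.names[1:] + ["carbon_tape"]  # lipids, water, tape
    return EndmemberLibrary.build(species, cube.grid)


def run_phantom_analysis(
    config: ScenarioConfig,
    subset: str = "fp15",
    folds: int = 5,
    roi_size: int = 50,
    classify: bool = True,
) -> dict:
    """Phantom pipeline: simulate, preprocess, unmix, crosstalk, LDA CV."""
    cube = generate_phantom_cube(config)
    pre = preprocess_phantom(cube)
    lib = phantom_library(pre)
    ab = unmix_cube(pre, lib)

    crosstalk = {}
    for lipid in lib.lipid_names:
        entry = crosstalk_profile(ab, canonical_profile(ab, lipid), lipid)
        crosstalk[lipid] = {
            "crosstalk_pct": entry.crosstalk_pct,
            "means": entry.means,
        }

    result = {
        "scenario": config.scenario,
        "seed": config.seed,
        "crosstalk": crosstalk,
    }
    if not classify:
        return result

    wavenumbers = select_subset(load_catalog(), subset)
    rois = canonical_rois(pre, roi_size=roi_size)
    pixels = extract_labeled_pixels(pre, rois, wavenumbers)
    cm = lda_cross_validate(pixels, folds=folds, seed=config.seed)
    result["classification"] = {
        "subset": subset,
        "folds": folds,
        "classes": cm.classes,
        "confusion": cm.counts.tolist(),
        "overall_accuracy": cm.overall_accuracy,
        "per_class_accuracy": cm.per_class_accuracy,
    }
    return result


def run_guv_analysis(seed: int = 0, n_samples: int = 10) -> dict:
    """Unmix synthetic vesicle spectra of all three presets into ternary points."""
    out: dict = {"seed": seed, "presets": {}}
    for preset, composition in GUV_PRESETS.items():
        config = ScenarioConfig.defaults(
            "guv", seed=seed, composition=dict(composition), n_samples=n_samples
        )
        samples = generate_guv_spectra(config)
        lib = EndmemberLibrary.build(
            ["DOPC", "SM", "Chol", "sucrose"], samples[0][0].grid
        )
        points, errors = [], []
        for spectrum, truth in samples:
            norm = np.abs(spectrum.intensity).sum()
            abundances, _ = nnls_unmix(spectrum.intensity / norm, lib)
            point = ternary_composition(abundances, lib)
            points.append(
                {"fractions": point.fractions, "x": point.x, "y": point.y}
            )
            errors.append(
                max(
                    abs(point.fractions[sp] - truth[sp])
                    for sp in ("DOPC", "SM", "Chol")
                )
            )
        out["presets"][preset] = {
            "nominal": composition,
            "points": points,
            "max_abs_fraction_error": float(max(errors)),
        }
    return out


def run_cells_analysis(scenario: str, seed: int = 0) -> dict:
    """Full enrichment pipeline: simulate, preprocess, AUC, percent change."""
    config = ScenarioConfig.defaults(scenario, seed=seed)
    series = generate_cell_series(config)
    window = series.truth["window"]
    labels = list(series.timepoints)
    first, last = labels[0], labels[-1]
    aucs = {
        label: [
            band_auc(
                preprocess_cell_spectrum(s, series.medium, s.grid).spectrum, window
            )
            for s in series.timepoints[label]
        ]
        for label in (first, last)
    }
    change = percent_change(aucs[last], aucs[first])
    ttest = paired_ttest(aucs[last], aucs[first])
    return {
        "scenario": scenario,
        "seed": seed,
        "n_cells": config.n_samples,
        "window": list(window),
        "injected_effect_percent": config.effect_percent,
        "recovered_percent_change": change,
        "paired_ttest": {"n": ttest.n, "t": ttest.t, "df": ttest.df, "p": ttest.p},
    }


def build_report(seed: int = 0) -> dict:
    """Bundle crosstalk, classification, ternary and enrichment outputs."""
    phantom = run_phantom_analysis(ScenarioConfig("phantom2d", seed=seed))
    return {
        "seed": seed,
        "crosstalk": phantom["crosstalk"],
        "classification": phantom["classification"],
        "ternary": run_guv_analysis(seed=seed),
        "enrichment": {
            scenario: run_cells_analysis(scenario, seed=seed)
            for scenario in ("cells_sm", "cells_control", "cells_chol")
        },
    }
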