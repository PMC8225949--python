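"""Remodeling-site classification and spatial validation metrics.

Comparing an aligned longitudinal image pair voxel by voxel, surface voxels
whose tissue mineral density increased are classified as bone apposition
sites and decreases as resorption sites; a background-to-bone transition on
the surface counts as apposition (the surface advanced) and bone-to-
background as resorption (it retreated).  Sites are tagged by the surface
they belong to (periosteal or endosteal).

Two overlap scores compare a predicted map against the experimental one for
a given state and surface:

* spatial match — correct voxels normalized by the **predicted** count,
* prediction accuracy — the same numerator normalized by the
  **experimental** count.

Undefined ratios (zero denominator) are reported as NaN, never as 0 or 1,
so averages are not silently inflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .image import GrayImage
from .imageproc import SurfaceClass, binarize, find_surfaces
from .morphometry import SectionPartition
from .remodeling import Calibration, gray_to_tmd

__all__ = [
    "RemodelingMap",
    "MatchScore",
    "classify_remodeling",
    "spatial_match",
    "prediction_accuracy",
    "scoreboard",
]

State = Literal["apposition", "resorption", "unchanged"]
Surface = Literal["periosteal", "endosteal"]

_STATE_CODE = {"unchanged": 0, "apposition": 1, "resorption": 2}


@dataclass(frozen=True)
class RemodelingMap:
    """Per-voxel remodeling state on the union surface of two time points.

    ``state`` holds 0 = unchanged, 1 = apposition, 2 = resorption (non-zero
    only on surface voxels); ``surface_class`` tags each surface voxel
    periosteal or endosteal (:class:`SurfaceClass` codes).
    """

    state: np.ndarray  # uint8
    surface_class: np.ndarray  # uint8
    spacing: float = 10.4

    def state_mask(self, state: State, surface: Surface | None = None) -> np.ndarray:
        m = self.state == _STATE_CODE[state]
        if surface is not None:
            code = SurfaceClass.PERIOSTEAL if surface == "periosteal" else SurfaceClass.ENDOSTEAL
            m = m & (self.surface_class == code)
        return m


def classify_remodeling(
    img_t0: GrayImage,
    img_t1: GrayImage,
    calib: Calibration,
    threshold: float,
    min_delta: float = 0.0,
) -> RemodelingMap:
    """Classify apposition/resorption sites between two aligned scans.

    Surface voxels (union of both time points' periosteal/endosteal voxels,
    plus voxels whose bone/background status changed) with a TMD change
    beyond ``min_delta`` (mgHA/cc) are classified by its sign; status
    transitions override: background→bone is apposition, bone→background
    resorption.  A voxel that is surface in only one time point is evaluated
    against this union set — by definition remodeling moves the surface.
    """
    if img_t0.shape != img_t1.shape:
        raise ValueError("images are on different grids; align them first")
    mask0 = binarize(img_t0, threshold)
    mask1 = binarize(img_t1, threshold)
    surf0 = find_surfaces(mask0)
    surf1 = find_surfaces(mask1)
    status_changed = mask0.values ^ mask1.values
    union = surf0.surface | surf1.surface | status_changed

    tmd0 = gray_to_tmd(img_t0, calib)
    tmd1 = gray_to_tmd(img_t1, calib)
    dtmd = tmd1 - tmd0

    state = np.zeros(img_t0.shape, dtype=np.uint8)
    appo = union & ((dtmd > min_delta) | (~mask0.values & mask1.values))
    reso = union & ((dtmd < -min_delta) | (mask0.values & ~mask1.values))
    state[appo] = _STATE_CODE["apposition"]
    state[reso] = _STATE_CODE["resorption"]

    # surface tag: the baseline's label where it has one, else the follow-up's
    sclass = np.zeros(img_t0.shape, dtype=np.uint8)
    for surf in (surf1, surf0):  # t0 written last -> wins ties
        peri, endo = surf.periosteal, surf.endosteal
        sclass[union & endo] = SurfaceClass.ENDOSTEAL
        sclass[union & peri] = SurfaceClass.PERIOSTEAL
    # status-changed voxels outside both label sets: tag by adjacency side of
    # the baseline partition (exterior -> periosteal, medullary -> endosteal)
    untagged = union & (sclass == 0)
    if untagged.any():
        sclass[untagged & (surf0.exterior | surf1.exterior)] = SurfaceClass.PERIOSTEAL
        sclass[untagged & (surf0.medullary & surf1.medullary)] = SurfaceClass.ENDOSTEAL
        sclass[untagged & (sclass == 0)] = SurfaceClass.PERIOSTEAL
    return RemodelingMap(state=state, surface_class=sclass, spacing=img_t0.spacing)


@dataclass(frozen=True)
class MatchScore:
    """An overlap ratio with its counts; ``value`` is NaN when undefined."""

    value: float
    n_match: int
    n_denominator: int


def _overlap(
    pred: RemodelingMap,
    exp: RemodelingMap,
    state: State,
    surface: Surface | None,
    denominator: Literal["pred", "exp"],
    region: slice | None = None,
) -> MatchScore:
    if pred.state.shape != exp.state.shape:
        raise ValueError("remodeling maps are on different grids")
    pm = pred.state_mask(state, surface)
    em = exp.state_mask(state, surface)
    if region is not None:
        pm, em = pm[region], em[region]
    n_match = int((pm & em).sum())
    n_den = int((pm if denominator == "pred" else em).sum())
    value = n_match / n_den if n_den > 0 else float("nan")
    return MatchScore(value=value, n_match=n_match, n_denominator=n_den)


def spatial_match(
    pred: RemodelingMap,
    exp: RemodelingMap,
    state: State,
    surface: Surface | None = None,
) -> MatchScore:
    """Fraction of predicted state voxels confirmed by the experiment
    (normalized by the predicted count)."""
    return _overlap(pred, exp, state, surface, "pred")


def prediction_accuracy(
    pred: RemodelingMap,
    exp: RemodelingMap,
    state: State,
    surface: Surface | None = None,
) -> MatchScore:
    """Fraction of experimental state voxels recovered by the prediction
    (normalized by the experimental count)."""
    return _overlap(pred, exp, state, surface, "exp")


def scoreboard(
    pred: RemodelingMap,
    exp: RemodelingMap,
    partition: SectionPartition | None = None,
) -> pd.DataFrame:
    """Full validation table: per region x state x surface class.

    Rows cover the whole bone and, if a partition is given, each of its
    sections; columns report both overlap scores with their numerator and
    denominators.  Section scores weighted by their denominators aggregate
    exactly to the whole-bone scores.
    """
    regions: list[tuple[str | int, slice | None]] = [("whole", None)]
    if partition is not None:
        regions += [(s, zs) for s, zs in partition]
    rows = []
    for name, zs in regions:
        for state in ("apposition", "resorption"):
            for surface in ("periosteal", "endosteal"):
                sm = _overlap(pred, exp, state, surface, "pred", zs)
                pa = _overlap(pred, exp, state, surface, "exp", zs)
                rows.append(
                    {
                        "region": name,
                        "state": state,
                        "surface": surface,
                        "spatial_match": sm.value,
                        "prediction_accuracy": pa.value,
                        "n_match": sm.n_match,
                        "n_pred": sm.n_denominator,
                        "n_exp": pa.n_denominator,
                    }
                )
    return pd.DataFrame(rows)
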