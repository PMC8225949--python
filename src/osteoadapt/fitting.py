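"""Inverse estimation of the three remodeling parameters.

The apposition rate, resorption rate and SED setpoint are estimated by
minimizing the discrepancy between experimental and predicted changes in
per-section volumetric second moments (medial-lateral and anterior-
posterior) over one scan interval: the forward mechanostat model evolves the
baseline image, the pseudo follow-up is binarized, and its per-section
moment changes are compared with the experimental ones.

Objective
---------
A per-section normalized squared error,

    J(theta) = sum_s sum_d w_{s,d} (dI_pred - dI_exp)^2,
    w_{s,d} = 1 / max(dI_exp^2, eps_floor),

with ``eps_floor = (median |dI_exp|)^2`` (raw squared error is used when
every experimental change is zero).  The normalization makes sections of
different size commensurate while the floor caps the weight any
near-zero-change section can carry: with a much smaller floor, sections
whose experimental moment change happens to be tiny dominate the objective
by orders of magnitude, and the voxel-flip staircase of those terms makes
the landscape practically un-optimizable.

Optimization
------------
Because the predicted moments derive from a *binarized* volume, the
objective is piecewise constant at the single-voxel scale and finite-
difference gradients vanish between voxel flips, which stalls gradient-based
SQP.  The fit therefore uses a deterministic multi-phase strategy: a seeded
Latin-hypercube presample of the bounded parameter box, restarted
Nelder-Mead simplex descents from the best presample points, and "zoom"
rounds that re-sample shrinking boxes around the best distinct local
solutions and descend again.

The search runs in *cutoff coordinates* (U_thr, log d_a, log d_r), where
d_a = m_a / tau_a and d_r = m_r / tau_r are the stimulus excesses at which
a surface voxel's density change crosses the segmentation margin (m_a, m_r:
the gray-value gaps, in TMD units, from the background and bone histogram
modes to the threshold).  A voxel's bone/background status flips when its
stimulus passes U_thr + d_a (apposition) or U_thr - d_r (resorption), so
these coordinates align the staircase structure of the objective with the
search axes; in the raw (rate, threshold) coordinates the minimum lies in a
narrow curved valley that defeats both simplex and gradient descent.

Within one fit the baseline image, load and material are fixed, so the
micro-FE stage of the forward model — the expensive part — is computed once
and its voxel stimulus map reused across all objective evaluations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .image import GrayImage
from .imageproc import BinaryMask, binarize, find_surfaces, select_global_threshold
from .microfe import LoadCase, Material, build_problem, element_sed, solve
from .morphometry import SectionPartition, make_partition, second_moments
from .remodeling import (
    Calibration,
    RemodelingParams,
    VoxelSEDMap,
    step,
    voxel_sed_map,
)

__all__ = ["FitData", "FitResult", "delta_moments", "objective", "fit"]

logger = logging.getLogger(__name__)

#: nominal parameter scaling (apposition, resorption, threshold) used for
#: finite-difference steps reported to users; the optimizer itself works in
#: box-normalized coordinates so that problems whose stimulus scale differs
#: by orders of magnitude stay equally well conditioned
PARAM_SCALE = np.array([1.0, 1.0, 10.0])

_PENALTY = 1e12


def delta_moments(
    mask_t0: BinaryMask,
    mask_t1: BinaryMask,
    partition: SectionPartition,
    allow_empty: bool = False,
) -> pd.DataFrame:
    """Per-section change in volumetric second moments, I(t1) - I(t0)."""
    if mask_t0.shape != mask_t1.shape:
        raise ValueError("masks are on different grids")
    return second_moments(mask_t1, partition, allow_empty) - second_moments(
        mask_t0, partition, allow_empty
    )


@dataclass
class FitData:
    """Everything the objective needs, with the FE stage precomputed.

    Build with :meth:`from_images`; the voxel stimulus map of the baseline is
    computed lazily on first use and cached (the baseline mask, load and
    material do not change during a fit).
    """

    baseline: GrayImage
    followup: GrayImage
    load: LoadCase
    calib: Calibration
    material: Material
    partition: SectionPartition
    threshold: float
    exp_delta: pd.DataFrame
    _sedmap: VoxelSEDMap | None = field(default=None, repr=False)
    _baseline_sed_values: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_images(
        cls,
        baseline: GrayImage,
        followup: GrayImage,
        load: LoadCase,
        calib: Calibration,
        material: Material | None = None,
        n_sections: int = 10,
        threshold: float | None = None,
    ) -> "FitData":
        if baseline.shape != followup.shape:
            raise ValueError("baseline and follow-up must share a grid; align first")
        material = material or Material()
        if threshold is None:
            threshold = select_global_threshold(baseline)
        partition = make_partition(baseline.n_slices, n_sections)
        m0 = binarize(baseline, threshold)
        m1 = binarize(followup, threshold)
        exp_delta = delta_moments(m0, m1, partition)
        return cls(
            baseline=baseline,
            followup=followup,
            load=load,
            calib=calib,
            material=material,
            partition=partition,
            threshold=threshold,
            exp_delta=exp_delta,
        )

    def sedmap(self) -> VoxelSEDMap:
        if self._sedmap is None:
            mask = binarize(self.baseline, self.threshold)
            surfaces = find_surfaces(mask)
            problem = build_problem(mask, self.material, self.load)
            solution = solve(problem)
            sed = element_sed(problem, solution)
            self._sedmap = voxel_sed_map(sed, surfaces)
            self._baseline_sed_values = sed.values
        return self._sedmap

    def baseline_sed_values(self) -> np.ndarray:
        """Per-element SED of the baseline (Pa), used for threshold bounds."""
        self.sedmap()
        assert self._baseline_sed_values is not None
        return self._baseline_sed_values

    def weights(self) -> pd.DataFrame:
        """Per-section, per-direction objective weights."""
        exp = self.exp_delta.to_numpy()
        med = float(np.median(np.abs(exp)))
        floor = med**2 if med > 0 else 1.0
        w = 1.0 / np.maximum(exp**2, floor)
        return pd.DataFrame(w, index=self.exp_delta.index, columns=self.exp_delta.columns)

    def flip_margins(self) -> tuple[float, float]:
        """(m_a, m_r): TMD margins a background/bone voxel must gain/lose to
        cross the segmentation threshold, estimated from the gray-value
        levels on either side of it."""
        gv = self.baseline.values
        a = abs(self.calib.slope)
        below = gv[gv < self.threshold]
        above = gv[gv >= self.threshold]
        bg = float(np.median(below)) if below.size else self.threshold - 1.0
        bone = float(np.median(above)) if above.size else self.threshold + 1.0
        m_a = max(a * (self.threshold - bg), 1e-9)
        m_r = max(a * (bone - self.threshold), 1e-9)
        return m_a, m_r


def predicted_delta(params: RemodelingParams, data: FitData) -> pd.DataFrame:
    """Per-section moment changes predicted by one forward step."""
    pseudo = step(
        data.baseline,
        params,
        data.load,
        data.calib,
        material=data.material,
        threshold=data.threshold,
        sedmap=data.sedmap(),
    )
    m0 = binarize(data.baseline, data.threshold)
    m1 = binarize(pseudo, data.threshold)
    return delta_moments(m0, m1, data.partition, allow_empty=True)


def objective(params: RemodelingParams, data: FitData) -> float:
    """Normalized squared error between predicted and experimental moment
    changes; a large finite penalty if the forward model fails."""
    try:
        pred = predicted_delta(params, data)
    except Exception as exc:
        logger.warning("forward model failed at %s: %s", params, exc)
        return _PENALTY
    diff = (pred - data.exp_delta).to_numpy()
    w = data.weights().to_numpy()
    return float(np.sum(w * diff**2))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start parameter fit."""

    params: RemodelingParams
    objective: float
    n_iterations: int
    converged: bool
    residuals: pd.DataFrame  # per-section predicted vs experimental dI
    start_objectives: tuple[float, ...]
    start_points: tuple[tuple[float, float, float], ...]
    bounds: tuple[tuple[float, float], ...]
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params.as_array(),
                "lower_bound": [b[0] for b in self.bounds],
                "upper_bound": [b[1] for b in self.bounds],
            },
            index=["apposition_rate", "resorption_rate", "sed_threshold"],
        )


def default_bounds(data: FitData) -> tuple[tuple[float, float], ...]:
    """Rates in [0, 100] mg/cc-Pa-2wk; threshold in [0, 99th percentile of
    the baseline SED]."""
    u99 = float(np.percentile(data.baseline_sed_values(), 99))
    return ((0.0, 100.0), (0.0, 100.0), (0.0, u99))


def fit(
    data: FitData,
    initial: RemodelingParams | None = None,
    bounds: tuple[tuple[float, float], ...] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    n_presample: int = 512,
    maxiter: int = 400,
    n_restarts: int = 3,
    zoom_widths: tuple[float, ...] = (0.1, 0.02),
) -> FitResult:
    """Multi-start bound-constrained fit of the remodeling parameters.

    A Latin-hypercube presample of ``n_presample`` points (seeded) maps the
    bounded box in cutoff coordinates; the ``n_starts`` best points (plus
    ``initial`` if given) each seed a restarted Nelder-Mead descent.  The
    incumbent is then refined by ``zoom`` rounds that re-sample a shrinking
    box around it (half-widths ``zoom_widths`` in normalized coordinates)
    and descend from the best local points.  Identical inputs give identical
    results.  Objective evaluations reuse the cached baseline stimulus map,
    so each costs a mechanostat update and a morphometry pass only.
    """
    if bounds is None:
        bounds = default_bounds(data)
    (ta_lo, ta_hi), (tr_lo, tr_hi), (thr_lo, thr_hi) = bounds
    if not (ta_hi > 0 and tr_hi > 0 and thr_hi > thr_lo >= 0):
        raise ValueError("bounds must allow positive rates and a threshold range")
    m_a, m_r = data.flip_margins()
    u_cap = 2.0 * thr_hi  # largest stimulus excess worth resolving
    d_bounds = []
    for m, t_hi2 in ((m_a, ta_hi), (m_r, tr_hi)):
        d_lo = m / t_hi2  # smallest excess (largest rate)
        d_hi = max(u_cap, 10 * d_lo)
        d_bounds.append((np.log(d_lo), np.log(d_hi)))

    def unpack(t: np.ndarray) -> RemodelingParams:
        t = np.clip(t, 0.0, 1.0)
        thr = thr_lo + t[0] * (thr_hi - thr_lo)
        d_a = np.exp(d_bounds[0][0] + t[1] * (d_bounds[0][1] - d_bounds[0][0]))
        d_r = np.exp(d_bounds[1][0] + t[2] * (d_bounds[1][1] - d_bounds[1][0]))
        tau_a = min(max(m_a / d_a, ta_lo), ta_hi)
        tau_r = min(max(m_r / d_r, tr_lo), tr_hi)
        return RemodelingParams(tau_a, tau_r, thr)

    def pack(p: RemodelingParams) -> np.ndarray:
        t0 = (p.sed_threshold - thr_lo) / (thr_hi - thr_lo)
        d_a = m_a / max(p.apposition_rate, m_a / np.exp(d_bounds[0][1]))
        d_r = m_r / max(p.resorption_rate, m_r / np.exp(d_bounds[1][1]))
        t1 = (np.log(d_a) - d_bounds[0][0]) / (d_bounds[0][1] - d_bounds[0][0])
        t2 = (np.log(d_r) - d_bounds[1][0]) / (d_bounds[1][1] - d_bounds[1][0])
        return np.clip([t0, t1, t2], 0.0, 1.0)

    def f(t: np.ndarray) -> float:
        return objective(unpack(t), data)

    sampler = qmc.LatinHypercube(d=3, seed=seed)
    presample = sampler.random(n_presample)
    pre_vals = np.array([f(t) for t in presample])
    order = np.argsort(pre_vals, kind="stable")
    starts = [presample[i] for i in order[:n_starts]]
    if initial is not None:
        starts.insert(0, pack(initial))

    solutions: list[tuple[float, np.ndarray]] = []
    start_objs: list[float] = []
    failures: list[str] = []
    best_nit, best_ok = 0, False
    for t0 in starts:
        try:
            x, fun = np.asarray(t0, dtype=float), np.inf
            for _ in range(n_restarts):
                res = minimize(
                    f,
                    x,
                    method="Nelder-Mead",
                    bounds=[(0.0, 1.0)] * 3,
                    options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-14},
                )
                x, fun = res.x, float(res.fun)
                best_nit += int(res.nit)
                best_ok = best_ok or bool(res.success)
            start_objs.append(fun)
            solutions.append((fun, np.clip(x, 0.0, 1.0)))
        except Exception as exc:  # keep other starts alive
            failures.append(f"start {t0}: {exc}")
            start_objs.append(np.inf)
    if not solutions:
        raise RuntimeError("all optimization starts failed:\n" + "\n".join(failures))

    # zoom phase: the near-zero basin is only a few voxel flips wide, so
    # re-sample shrinking boxes around the best distinct local solutions and
    # descend again in each
    solutions.sort(key=lambda s: s[0])
    incumbents: list[tuple[float, np.ndarray]] = []
    for fun, x in solutions:
        if all(np.max(np.abs(x - xi)) > 0.02 for _, xi in incumbents):
            incumbents.append((fun, x))
        if len(incumbents) == 3:
            break
    best_f, best_t = incumbents[0]
    for rank, (_, center) in enumerate(incumbents):
        local_best_t, local_best_f = center, f(center)
        for zoom, half_width in enumerate(zoom_widths):
            zoom_sampler = qmc.LatinHypercube(
                d=3, seed=seed + 7919 * (zoom + 1) + 104729 * rank
            )
            local = local_best_t + (
                zoom_sampler.random(max(n_presample // 4, 16)) - 0.5
            ) * 2 * half_width
            local = np.clip(local, 0.0, 1.0)
            local_vals = np.array([f(t) for t in local])
            top = np.argsort(local_vals, kind="stable")[:2]
            for t0 in [local_best_t] + [local[i] for i in top]:
                res = minimize(
                    f,
                    t0,
                    method="Nelder-Mead",
                    bounds=[(0.0, 1.0)] * 3,
                    options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-15},
                )
                best_nit += int(res.nit)
                if res.fun < local_best_f:
                    local_best_t = np.clip(res.x, 0.0, 1.0)
                    local_best_f = float(res.fun)
        if local_best_f < best_f:
            best_t, best_f = local_best_t, local_best_f

    params = unpack(best_t)
    pred = predicted_delta(params, data)
    residuals = pd.concat(
        {"predicted": pred, "experimental": data.exp_delta, "residual": pred - data.exp_delta},
        axis=1,
    )
    return FitResult(
        params=params,
        objective=best_f,
        n_iterations=best_nit,
        converged=best_ok,
        residuals=residuals,
        start_objectives=tuple(start_objs),
        start_points=tuple(tuple(unpack(s).as_array()) for s in starts),
        bounds=bounds,
        seed=seed,
    )
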