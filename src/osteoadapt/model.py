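"""Model/results interface to the bone-adaptation pipeline.

:class:`BoneAdaptationModel` bundles an aligned longitudinal image pair with
a loading condition and calibration; ``fit()`` estimates the three
mechanostat parameters (apposition rate, resorption rate, SED setpoint) and
returns a :class:`BoneAdaptationResults` carrying the estimates, approximate
uncertainties, per-section residuals, and validation utilities (pseudo-CT
prediction, densitometrics, spatial match / prediction accuracy tables).

Example
-------
>>> model = BoneAdaptationModel(baseline, followup, load=LoadCase("combined", bw=22.0),
...                             calib=Calibration())
>>> res = model.fit(seed=1)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitData, PARAM_SCALE, fit as _fit, predicted_delta
from .image import GrayImage
from .imageproc import binarize
from .metrics import RemodelingMap, classify_remodeling, scoreboard
from .microfe import LoadCase, Material
from .morphometry import densitometrics
from .remodeling import Calibration, RemodelingParams, step

__all__ = ["BoneAdaptationModel", "BoneAdaptationResults"]

_PARAM_NAMES = ["apposition_rate", "resorption_rate", "sed_threshold"]
_PARAM_UNITS = ["mg/cc-Pa-2wk", "mg/cc-Pa-2wk", "Pa"]


class BoneAdaptationModel:
    """Mechanostat bone-adaptation model for one scan interval.

    Parameters
    ----------
    baseline, followup : GrayImage
        Aligned gray-value volumes two weeks apart (slice 0 distal).
    load : LoadCase
        Loading condition over the interval.
    calib : Calibration
        Gray-value to TMD calibration.
    material : Material, optional
        Tissue elasticity (default E = 14.8 GPa, nu = 0.3).
    n_sections : int
        Number of longitudinal sections for the moment objective.
    threshold : float, optional
        Global segmentation threshold; derived from the baseline histogram
        when omitted.
    """

    def __init__(
        self,
        baseline: GrayImage,
        followup: GrayImage,
        load: LoadCase,
        calib: Calibration,
        material: Material | None = None,
        n_sections: int = 10,
        threshold: float | None = None,
    ) -> None:
        self.data = FitData.from_images(
            baseline, followup, load, calib,
            material=material, n_sections=n_sections, threshold=threshold,
        )

    @property
    def exog_names(self) -> list[str]:
        return list(_PARAM_NAMES)

    def simulate(self, params: RemodelingParams, steps: int = 1) -> GrayImage:
        """Forward-run the fitted pipeline from the baseline."""
        current = self.data.baseline
        for _ in range(steps):
            current = step(
                current, params, self.data.load, self.data.calib,
                material=self.data.material, threshold=self.data.threshold,
            )
        return current

    def fit(
        self,
        initial: RemodelingParams | None = None,
        bounds: tuple[tuple[float, float], ...] | None = None,
        n_starts: int = 8,
        seed: int = 0,
        **kwargs,
    ) -> "BoneAdaptationResults":
        result = _fit(
            self.data, initial=initial, bounds=bounds, n_starts=n_starts,
            seed=seed, **kwargs,
        )
        return BoneAdaptationResults(self, result)


@dataclass
class BoneAdaptationResults:
    """Fit results with uncertainties, diagnostics and validation tables."""

    model: BoneAdaptationModel
    fit_result: FitResult

    @property
    def params(self) -> RemodelingParams:
        return self.fit_result.params

    @property
    def objective(self) -> float:
        return self.fit_result.objective

    @property
    def residuals(self) -> pd.DataFrame:
        return self.fit_result.residuals

    def bse(self, rel_step: float = 0.05) -> np.ndarray:
        """Approximate standard errors from a Gauss-Newton linearization.

        The weighted residual Jacobian is finite-differenced at the optimum
        (step ``rel_step`` of each parameter scale); the covariance is
        s^2 (J'J)^-1 with s^2 the residual variance.  Because the moment
        objective derives from binarized volumes the surface is locally
        stepped, so these are order-of-magnitude uncertainties only.
        """
        data = self.model.data
        w = np.sqrt(data.weights().to_numpy()).ravel()

        def resid(p: np.ndarray) -> np.ndarray:
            pred = predicted_delta(RemodelingParams.from_array(p), data)
            return w * (pred - data.exp_delta).to_numpy().ravel()

        p0 = self.params.as_array()
        r0 = resid(p0)
        m = len(r0)
        jac = np.empty((m, 3))
        for j in range(3):
            dp = rel_step * max(abs(p0[j]), PARAM_SCALE[j])
            p = p0.copy()
            p[j] += dp
            jac[:, j] = (resid(p) - r0) / dp
        dof = max(m - 3, 1)
        s2 = float(r0 @ r0) / dof
        try:
            cov = s2 * np.linalg.pinv(jac.T @ jac)
            return np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return np.full(3, np.nan)

    def predict(self, steps: int = 1) -> GrayImage:
        """Pseudo micro-CT follow-up at the fitted parameters."""
        return self.model.simulate(self.params, steps=steps)

    def remodeling_maps(self) -> tuple[RemodelingMap, RemodelingMap]:
        """(predicted, experimental) remodeling maps vs the baseline."""
        data = self.model.data
        pred_img = self.predict()
        pred = classify_remodeling(data.baseline, pred_img, data.calib, data.threshold)
        exp = classify_remodeling(data.baseline, data.followup, data.calib, data.threshold)
        return pred, exp

    def scoreboard(self) -> pd.DataFrame:
        """Spatial match and prediction accuracy per section/state/surface."""
        pred, exp = self.remodeling_maps()
        return scoreboard(pred, exp, self.model.data.partition)

    def densitometrics(self) -> pd.DataFrame:
        """BV/TV/BMC/BMD of baseline, experimental and predicted follow-up."""
        data = self.model.data
        frames = {}
        for name, img in (
            ("baseline", data.baseline),
            ("experimental", data.followup),
            ("predicted", self.predict()),
        ):
            mask = binarize(img, data.threshold)
            frames[name] = densitometrics(img, mask, data.calib, data.partition)
        return pd.concat(frames, names=["dataset", "region"])

    def summary(self) -> str:
        """Human-readable fit summary (estimates, uncertainties, fit stats)."""
        se = self.bse()
        est = self.params.as_array()
        lines = [
            "Bone Adaptation Model Results",
            "=" * 64,
            f"{'parameter':<18}{'estimate':>12}{'approx. se':>12}  unit",
            "-" * 64,
        ]
        for name, unit, e, s in zip(_PARAM_NAMES, _PARAM_UNITS, est, se):
            lines.append(f"{name:<18}{e:>12.4g}{s:>12.2g}  {unit}")
        lines += [
            "-" * 64,
            f"objective (normalized SSE): {self.objective:.6g}",
            f"sections x directions:      {self.residuals.shape[0]} x 2",
            f"iterations:                 {self.fit_result.n_iterations}",
            f"converged:                  {self.fit_result.converged}",
            f"multi-start seed:           {self.fit_result.seed}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def plot_moment_fit(self, ax=None):
        """Per-section experimental vs predicted moment changes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        res = self.fit_result.residuals
        sections = res.index.to_numpy()
        for d, style in (("I_ML", "o-"), ("I_AP", "s--")):
            ax.plot(sections, res[("experimental", d)], style, label=f"exp d{d}")
            ax.plot(sections, res[("predicted", d)], style, alpha=0.5, label=f"pred d{d}")
        ax.set_xlabel("section (1 = distal)")
        ax.set_ylabel("change in second moment (mm$^5$)")
        ax.legend(fontsize="small")
        return ax
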