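"""Solid-of-revolution head volumetry and fresh-weight calibration.

The multi-view radial profiles of a plant are composed into a head volume by
revolving a per-row aggregate radius about the turntable axis:

    Vh = pi * sum_h rbar(h)^2 * row_height

with rbar(h) the mean (default), min, or max over views of the row-h radii.
Fresh weight is then predicted through a linear calibration FWh = a0 + a1*Vh,
fitted by ordinary least squares on a cohort of destructively weighed plants
and characterised by its root-mean-square error of calibration (RMSEC,
computed with denominator n as is conventional for calibration models).

The calibration is exposed statsmodels-style: :class:`VolumeCalibration` is
the model, ``fit()`` returns :class:`CalibrationResults` carrying estimates,
standard errors, confidence intervals and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import InvalidInputError, SingularFitError
from .silhouette import RadialProfile

__all__ = [
    "VolumeEstimate",
    "compose_volume",
    "VolumeCalibration",
    "CalibrationResults",
    "fit_calibration",
    "predict_fw",
    "validate_estimates",
]

_AGGREGATIONS = {"mean": np.mean, "min": np.min, "max": np.max}


@dataclass(frozen=True)
class VolumeEstimate:
    """Head volume (cm^3) from revolved, view-aggregated radial profiles."""

    head_volume: float
    aggregation: str
    aggregated_radii: np.ndarray  # per-row radius, cm
    n_views: int
    row_height: float
    plant_id: str = ""
    timepoint: float = 0.0


def compose_volume(profile: RadialProfile, aggregation: str = "mean") -> VolumeEstimate:
    """Compose multi-view radial profiles into a solid-of-revolution volume.

    Per image row the view radii are aggregated (mean approximates the
    average side silhouette; min approximates a revolved visual hull) and the
    aggregate profile revolved about the vertical axis with the midpoint
    rule. Rows where every view saw no foreground contribute zero.
    """
    if aggregation not in _AGGREGATIONS:
        raise InvalidInputError(f"unknown aggregation '{aggregation}'")
    radii = np.asarray(profile.radii, dtype=float)
    if radii.ndim != 2 or radii.shape[0] < 1:
        raise InvalidInputError("profile must be a [n_views, n_rows] matrix")
    rbar = _AGGREGATIONS[aggregation](radii, axis=0)
    rbar = np.where(radii.max(axis=0) == 0, 0.0, rbar)
    vh = float(np.pi * np.sum(rbar**2) * profile.row_height)
    return VolumeEstimate(
        head_volume=vh, aggregation=aggregation, aggregated_radii=rbar,
        n_views=radii.shape[0], row_height=profile.row_height,
        plant_id=profile.plant_id, timepoint=profile.timepoint,
    )


class Prediction(NamedTuple):
    fw: float
    extrapolated: bool


class VolumeCalibration:
    """Linear volume -> fresh weight calibration model, FWh = a0 + a1 * Vh.

    Parameters
    ----------
    fw : array-like
        Destructively measured fresh weights (g), the response.
    volume : array-like
        Computed head volumes (cm^3), the regressor.

    ``fit()`` returns a :class:`CalibrationResults`.
    """

    def __init__(self, fw, volume):
        fw = np.asarray(fw, dtype=float)
        volume = np.asarray(volume, dtype=float)
        if fw.shape != volume.shape or fw.ndim != 1:
            raise InvalidInputError("fw and volume must be 1D arrays of equal length")
        if fw.size < 2:
            raise InvalidInputError(f"calibration needs n >= 2 pairs, got {fw.size}")
        if np.ptp(volume) == 0:
            raise SingularFitError("all calibration volumes are equal")
        self.fw = fw
        self.volume = volume
        self.nobs = fw.size

    @classmethod
    def from_dataframe(cls, data, volume_col: str = "volume_cm3",
                       fw_col: str = "fw_g") -> "VolumeCalibration":
        return cls(data[fw_col].to_numpy(), data[volume_col].to_numpy())

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple]) -> "VolumeCalibration":
        """Build from an iterable of (volume cm^3, fresh weight g) pairs."""
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidInputError("pairs must be (volume, fw) tuples")
        return cls(arr[:, 1], arr[:, 0])

    def fit(self) -> "CalibrationResults":
        X = sm.add_constant(self.volume)
        ols = sm.OLS(self.fw, X).fit()
        resid = self.fw - ols.fittedvalues
        rmsec = float(np.sqrt(np.mean(resid**2)))
        return CalibrationResults(self, ols, rmsec)


class CalibrationResults:
    """Fitted volume -> fresh-weight calibration.

    Attributes
    ----------
    a0, a1 : float
        Intercept (g) and slope (g/cm^3).
    rmsec : float
        Root-mean-square error of calibration, denominator n.
    fw_range : (float, float)
        Observed fresh-weight range; predictions outside it are flagged as
        extrapolation.
    """

    def __init__(self, model: VolumeCalibration, ols_results, rmsec: float,
                 fw_range: tuple | None = None):
        self.model = model
        self._ols = ols_results
        self.a0 = float(ols_results.params[0])
        self.a1 = float(ols_results.params[1])
        self.rmsec = rmsec
        self.n = int(model.nobs) if model is not None else 0
        self.fw_range = fw_range if fw_range is not None else (
            float(model.fw.min()), float(model.fw.max()))

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a0, self.a1])

    @property
    def bse(self) -> np.ndarray:
        """OLS standard errors of (a0, a1)."""
        return np.asarray(self._ols.bse)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Two-sided (1 - alpha) confidence intervals for (a0, a1)."""
        return np.asarray(self._ols.conf_int(alpha))

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    def predict(self, vh) -> list:
        """Predicted fresh weight(s) with extrapolation flags."""
        vh = np.atleast_1d(np.asarray(vh, dtype=float))
        fw = self.a0 + self.a1 * vh
        lo, hi = self.fw_range
        return [Prediction(float(f), bool(f < lo or f > hi)) for f in fw]

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Volume -> fresh weight calibration (OLS)",
            "=" * 56,
            f"n                 {self.n:>10d}",
            f"a0 (g)            {self.a0:>10.4f}  SE {self.bse[0]:.4f}  "
            f"95% CI [{ci[0, 0]:.4f}, {ci[0, 1]:.4f}]",
            f"a1 (g/cm^3)       {self.a1:>10.6f}  SE {self.bse[1]:.6f}  "
            f"95% CI [{ci[1, 0]:.6f}, {ci[1, 1]:.6f}]",
            f"RMSEC (g)         {self.rmsec:>10.4f}",
            f"R^2               {self.rsquared:>10.4f}",
            f"FW range (g)      [{self.fw_range[0]:.2f}, {self.fw_range[1]:.2f}]",
            "=" * 56,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return dict(a0=self.a0, a1=self.a1, rmsec=self.rmsec, n=self.n,
                    fw_range=[float(self.fw_range[0]), float(self.fw_range[1])])

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationResults":
        obj = cls.__new__(cls)
        obj.model = None
        obj._ols = None
        obj.a0 = float(d["a0"])
        obj.a1 = float(d["a1"])
        obj.rmsec = float(d["rmsec"])
        obj.n = int(d["n"])
        obj.fw_range = tuple(float(x) for x in d["fw_range"])
        return obj

    @classmethod
    def from_yaml(cls, path) -> "CalibrationResults":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def plot_calibration(self, ax=None):
        """Scatter of calibration pairs with the fitted line."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.scatter(self.model.volume, self.model.fw, s=12, alpha=0.7,
                       label="calibration plants")
            vv = np.linspace(self.model.volume.min(), self.model.volume.max(), 50)
        else:
            vv = np.linspace(0, (self.fw_range[1] - self.a0) / self.a1, 50)
        ax.plot(vv, self.a0 + self.a1 * vv, "r-",
                label=f"FW = {self.a0:.2f} + {self.a1:.4f} V  (RMSEC {self.rmsec:.2f} g)")
        ax.set_xlabel("head volume Vh (cm$^3$)")
        ax.set_ylabel("fresh weight (g)")
        ax.legend()
        return ax


def fit_calibration(pairs: Sequence[tuple]) -> CalibrationResults:
    """OLS calibration from (volume cm^3, fresh weight g) pairs."""
    return VolumeCalibration.from_pairs(pairs).fit()


def predict_fw(results: CalibrationResults, vh: float) -> Prediction:
    """Predicted fresh weight for one head volume, with extrapolation flag."""
    return results.predict(vh)[0]


class ValidationMetrics(NamedTuple):
    r_squared: float
    bias_g: float
    rmse_g: float


def validate_estimates(estimated_fw, true_fw) -> ValidationMetrics:
    """Agreement of image-based estimates with destructive measurements.

    R^2 of the OLS regression of estimated on true weight, mean bias
    (estimated - true, g), and RMSE (g).
    """
    est = np.asarray(estimated_fw, dtype=float)
    true = np.asarray(true_fw, dtype=float)
    if est.shape != true.shape or est.ndim != 1 or est.size < 2:
        raise InvalidInputError("need equal-length 1D arrays with n >= 2")
    from scipy import stats
    res = stats.linregress(true, est)
    return ValidationMetrics(
        r_squared=float(res.rvalue**2),
        bias_g=float(np.mean(est - true)),
        rmse_g=float(np.sqrt(np.mean((est - true) ** 2))),
    )
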