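"""Absorbance-to-concentration calibration for nanoparticle eluates.

A standard curve of absorbance at 425 nm against known nanoparticle
concentration (default standards 0.1-1.0 nM in duplicate) is fit by
ordinary least squares; the unknown eluate concentration is recovered by
inverse prediction, c = (A - b)/m, with the classical inverse-regression
standard error

    SE(c) = (s / m) * sqrt(1/k + 1/n + (c - cbar)^2 / Sxx)

where s is the residual SD of the line, k the number of unknown-well
replicates averaged, n the number of standard points, cbar the mean standard
concentration and Sxx its centred sum of squares.  Concentrations are nM at
the interface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .chip import ChipLayout, MNPBatch


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted absorbance-vs-concentration line."""

    slope: float  # absorbance per nM
    intercept: float  # absorbance
    r_squared: float
    n_points: int
    residual_sd: float
    conc_mean: float = 0.0
    conc_sxx: float = 0.0
    conc_min: float = 0.0
    conc_max: float = 0.0

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = asdict(self)
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        payload = json.loads(Path(path).read_text())
        fields = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in payload.items() if k in fields})


class AbsorbanceCalibrator(BaseEstimator, RegressorMixin):
    """OLS calibration line with inverse prediction of concentration.

    scikit-learn estimator: ``fit(X, y)`` takes standard concentrations
    (nM, shape (n, 1) or (n,)) and absorbances; ``predict(X)`` returns
    absorbance at given concentrations; :meth:`inverse_predict` returns
    the concentration (and SE) for a measured absorbance.

    The intercept is estimated, not forced through zero: blank-buffer
    absorbance is nonzero in practice.  Replicates enter as individual
    points, preserving residual degrees of freedom.
    """

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).reshape(-1)
        a = np.asarray(y, dtype=float).reshape(-1)
        if c.shape != a.shape:
            raise CalibrationError("concentration and absorbance lengths differ")
        if np.any(c < 0):
            raise CalibrationError("negative standard concentration")
        if len(np.unique(c)) < 2:
            raise CalibrationError(
                "all standards at one concentration: calibration line is rank-deficient"
            )
        if len(c) < 3:
            raise CalibrationError("need >= 3 standard points")
        n = len(c)
        cbar = c.mean()
        sxx = float(np.sum((c - cbar) ** 2))
        slope = float(np.sum((c - cbar) * (a - a.mean())) / sxx)
        intercept = float(a.mean() - slope * cbar)
        resid = a - (slope * c + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((a - a.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        dof = n - 2
        s = float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0
        self.slope_ = slope
        self.intercept_ = intercept
        self.r_squared_ = r2
        self.residual_sd_ = s
        self.n_points_ = n
        self.conc_mean_ = float(cbar)
        self.conc_sxx_ = sxx
        self.conc_range_ = (float(c.min()), float(c.max()))
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        c = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * c + self.intercept_

    def inverse_predict(self, absorbance, n_replicates: int = 1):
        """Concentration (nM) and inverse-prediction SE for an absorbance.

        ``absorbance`` may be a scalar or the mean of ``n_replicates``
        unknown-well readings.  Negative predictions are returned as-is
        with a warning, never clipped.
        """
        check_is_fitted(self, "slope_")
        if self.slope_ == 0:
            raise CalibrationError("degenerate calibration curve: slope = 0")
        a = float(np.mean(np.asarray(absorbance, dtype=float)))
        c = (a - self.intercept_) / self.slope_
        se = abs(self.residual_sd_ / self.slope_) * np.sqrt(
            1.0 / n_replicates
            + 1.0 / self.n_points_
            + (c - self.conc_mean_) ** 2 / self.conc_sxx_
        )
        lo, hi = self.conc_range_
        if c < 0:
            warnings.warn(f"predicted concentration {c:.4g} nM is negative")
        elif not (lo <= c <= hi):
            warnings.warn(
                f"predicted concentration {c:.4g} nM outside the standard "
                f"range [{lo:.4g}, {hi:.4g}] nM (extrapolation)"
            )
        return c, float(se)

    @property
    def curve_(self) -> CalibrationCurve:
        check_is_fitted(self, "slope_")
        return CalibrationCurve(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            n_points=self.n_points_,
            residual_sd=self.residual_sd_,
            conc_mean=self.conc_mean_,
            conc_sxx=self.conc_sxx_,
            conc_min=self.conc_range_[0],
            conc_max=self.conc_range_[1],
        )


def fit_calibration(table: pd.DataFrame) -> CalibrationCurve:
    """Fit the calibration line from a plate table (calibration.csv dialect)."""
    std = table[table["role"] == "standard"]
    cal = AbsorbanceCalibrator().fit(
        std["concentration_nM"].to_numpy(float),
        std["absorbance_425nm"].to_numpy(float),
    )
    return cal.curve_


def predict_concentration(
    curve: CalibrationCurve, absorbance, n_replicates: int = 1
) -> tuple[float, float]:
    """Inverse-predict concentration (nM) with SE from a fitted curve."""
    cal = AbsorbanceCalibrator()
    cal.slope_ = curve.slope
    cal.intercept_ = curve.intercept
    cal.r_squared_ = curve.r_squared
    cal.residual_sd_ = curve.residual_sd
    cal.n_points_ = curve.n_points
    cal.conc_mean_ = curve.conc_mean
    cal.conc_sxx_ = curve.conc_sxx if curve.conc_sxx > 0 else np.inf
    cal.conc_range_ = (curve.conc_min, curve.conc_max)
    return cal.inverse_predict(absorbance, n_replicates=n_replicates)


def predict_unknown(table: pd.DataFrame, curve: CalibrationCurve | None = None):
    """Fit (if needed) and inverse-predict the unknown wells of a plate."""
    if curve is None:
        curve = fit_calibration(table)
    unk = table[table["role"] == "unknown"]["absorbance_425nm"].to_numpy(float)
    if len(unk) == 0:
        raise CalibrationError("plate contains no unknown wells")
    c, se = predict_concentration(curve, unk.mean(), n_replicates=len(unk))
    return c, se, curve


def channel_concentrations(eluted_nM: float, layout: ChipLayout, prey: str = "prey") -> MNPBatch:
    """Propagate the eluted concentration to per-channel molar values."""
    if eluted_nM < 0:
        raise ValueError("eluted concentration must be nonnegative")
    return MNPBatch.from_layout(prey, eluted_nM * 1e-9, layout)
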