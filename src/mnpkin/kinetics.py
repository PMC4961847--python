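"""Decoupling bivalent rate constants and converting to monovalent affinity.

Under pseudo-first-order Langmuir kinetics the observed rate is linear in
complex concentration,

    k_obs = k_on^bi * C + k_off^bi,

so pooling the (C, k_obs) points from all channels (and all experiments)
and fitting an ordinary least-squares line decouples the two rates: the
slope is k_on^bi, the y-intercept k_off^bi, and K_D^bi = k_off^bi/k_on^bi
with a delta-method standard error.  A negative intercept (off-rate below
the noise floor) is reported as-is with a warning, never clamped.

The bivalent (avidity) dissociation constant is converted to the
monovalent site constant through an effective-local-concentration model:
once one site of a bivalent particle is bound, its second site sees the
surface bait at an effective concentration c_eff, giving

    K_D^bi = (K_D^mono)^v / c_eff^(v-1)
    K_D^mono = (K_D^bi * c_eff^(v-1))^(1/v)

for valency v (geometric-mean form; v = 2 by default).  c_eff must be
supplied by the caller -- it depends on linker geometry and site density
and a silent default would fabricate affinities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class InsufficientDataError(ValueError):
    pass


@dataclass
class BivalentKinetics:
    """Pooled-regression output for one prey/bait interaction."""

    prey: str
    bait: str
    kon_bi: float  # M^-1 s^-1
    koff_bi: float  # s^-1
    kd_bi: float  # M
    se_kon: float
    se_koff: float
    se_kd: float
    n_points: int
    r_squared: float
    points: list = field(default_factory=list)  # (concentration_M, k_obs, experiment)
    negative_intercept: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MonovalentAffinity:
    """Monovalent site affinity derived from the bivalent constant."""

    kd_mono: float  # M
    valency: int
    c_eff: float  # M
    kd_bi: float  # M


class ObservedRateRegression(BaseEstimator, RegressorMixin):
    """OLS line of k_obs on concentration (unweighted).

    scikit-learn estimator: ``fit(X, y)`` with concentrations (M) and
    observed rates (1/s); fitted attributes ``kon_bi_`` (slope),
    ``koff_bi_`` (intercept), ``kd_bi_``, their SEs, ``r_squared_``.
    SE of K_D^bi = intercept/slope comes from the delta method with the
    full slope/intercept covariance.
    """

    def fit(self, X, y, sample_weight=None):
        """Fit the line; ``sample_weight`` enables inverse-variance weighting
        (e.g. 1/SD^2 of duplicate k_obs means), default unweighted."""
        c = np.asarray(X, dtype=float).reshape(-1)
        k = np.asarray(y, dtype=float).reshape(-1)
        if c.shape != k.shape:
            raise ValueError("concentration and k_obs lengths differ")
        if len(c) < 2:
            raise InsufficientDataError("need >= 2 (C, k_obs) points")
        if len(np.unique(c)) < 2:
            raise InsufficientDataError(
                "single distinct concentration: slope/intercept not identifiable"
            )
        n = len(c)
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float).reshape(-1)
            if w.shape != c.shape or np.any(w <= 0):
                raise ValueError("sample_weight must be positive, one per point")
        sw = w.sum()
        cbar = float(np.sum(w * c) / sw)
        kbar = float(np.sum(w * k) / sw)
        sxx = float(np.sum(w * (c - cbar) ** 2))
        slope = float(np.sum(w * (c - cbar) * (k - kbar)) / sxx)
        intercept = kbar - slope * cbar
        resid = k - (slope * c + intercept)
        ss_res = float(np.sum(w * resid**2))
        ss_tot = float(np.sum(w * (k - kbar) ** 2))
        self.r_squared_ = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        dof = n - 2
        if dof > 0:
            s2 = ss_res / dof
            var_slope = s2 / sxx
            var_int = s2 * (1.0 / sw + cbar**2 / sxx)
            cov_si = -s2 * cbar / sxx
            self.se_kon_ = float(np.sqrt(var_slope))
            self.se_koff_ = float(np.sqrt(var_int))
        else:
            var_slope = var_int = cov_si = np.nan
            self.se_kon_ = np.nan
            self.se_koff_ = np.nan
        self.kon_bi_ = slope
        self.koff_bi_ = intercept
        self.negative_intercept_ = intercept < 0
        if self.negative_intercept_:
            warnings.warn(
                f"fitted y-intercept (k_off^bi) is negative ({intercept:.3g} 1/s): "
                f"off-rate below the noise floor; reported unclamped"
            )
        if slope != 0:
            kd = intercept / slope
            self.kd_bi_ = float(kd)
            if dof > 0:
                # delta method for the ratio intercept/slope
                g = np.array([-intercept / slope**2, 1.0 / slope])
                cov = np.array([[var_slope, cov_si], [cov_si, var_int]])
                self.se_kd_ = float(np.sqrt(max(g @ cov @ g, 0.0)))
            else:
                self.se_kd_ = np.nan
        else:
            self.kd_bi_ = np.nan
            self.se_kd_ = np.nan
        self.n_points_ = n
        return self

    def predict(self, X):
        check_is_fitted(self, "kon_bi_")
        c = np.asarray(X, dtype=float).reshape(-1)
        return self.kon_bi_ * c + self.koff_bi_

    def confidence_interval_kon(self, level: float = 0.95) -> tuple[float, float]:
        """t-based CI for the association rate (slope)."""
        check_is_fitted(self, "kon_bi_")
        from scipy.stats import t as t_dist

        dof = self.n_points_ - 2
        if dof <= 0 or not np.isfinite(self.se_kon_):
            return (np.nan, np.nan)
        tq = t_dist.ppf(0.5 + level / 2, dof)
        return (self.kon_bi_ - tq * self.se_kon_, self.kon_bi_ + tq * self.se_kon_)


def pool_kobs(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    prey: str = "prey",
    bait: str = "bait",
    experiment_ids: Sequence | None = None,
    weights: Sequence[float] | None = None,
) -> BivalentKinetics:
    """Pool (concentration [M], k_obs [1/s]) points and regress.

    Accepts a sequence of pairs or a DataFrame with columns
    ``concentration_M`` and ``k_obs`` (optional ``experiment``).  Points
    from multiple experiments are concatenated; the regression is invariant
    to point order and experiment partitioning.  ``weights`` (optional,
    e.g. inverse duplicate variances) switch to weighted least squares;
    the default is unweighted.
    """
    if isinstance(points, pd.DataFrame):
        c = points["concentration_M"].to_numpy(float)
        k = points["k_obs"].to_numpy(float)
        exps = (
            points["experiment"].tolist()
            if "experiment" in points.columns
            else [0] * len(c)
        )
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (C, k_obs) pairs")
        c, k = arr[:, 0], arr[:, 1]
        exps = list(experiment_ids) if experiment_ids is not None else [0] * len(c)

    reg = ObservedRateRegression().fit(c, k, sample_weight=weights)
    return BivalentKinetics(
        prey=prey,
        bait=bait,
        kon_bi=reg.kon_bi_,
        koff_bi=reg.koff_bi_,
        kd_bi=reg.kd_bi_,
        se_kon=reg.se_kon_,
        se_koff=reg.se_koff_,
        se_kd=reg.se_kd_,
        n_points=reg.n_points_,
        r_squared=reg.r_squared_,
        points=[(float(ci), float(ki), e) for ci, ki, e in zip(c, k, exps)],
        negative_intercept=reg.negative_intercept_,
    )


# ---------------------------------------------------------------------------
# Avidity conversion

def kd_monovalent(
    kd_bi: float | BivalentKinetics, c_eff: float, valency: int = 2
) -> MonovalentAffinity:
    """Convert the bivalent K_D to the monovalent site K_D.

    kd_mono = (kd_bi * c_eff^(valency-1))^(1/valency); valency 1 returns
    kd_bi unchanged.  ``c_eff`` is the effective local concentration (M)
    seen by the particle's remaining site(s) once one site is bound.
    """
    kd = kd_bi.kd_bi if isinstance(kd_bi, BivalentKinetics) else float(kd_bi)
    if kd <= 0:
        raise ValueError("kd_bi must be positive for avidity conversion")
    if c_eff <= 0:
        raise ValueError("c_eff must be positive")
    if valency < 1:
        raise ValueError("valency must be >= 1")
    kd_mono = (kd * c_eff ** (valency - 1)) ** (1.0 / valency)
    return MonovalentAffinity(kd_mono=kd_mono, valency=valency, c_eff=c_eff, kd_bi=kd)


def kd_bivalent_from_mono(aff: MonovalentAffinity) -> float:
    """Inverse of :func:`kd_monovalent`: K_D^bi = kd_mono^v / c_eff^(v-1)."""
    return aff.kd_mono ** aff.valency / aff.c_eff ** (aff.valency - 1)


def valency_sensitivity(
    kd_bi: float | BivalentKinetics,
    c_eff: float,
    valencies: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """Monovalent K_D under alternative assumed valencies.

    Quantifies how strongly the inferred site affinity depends on the
    assumed binding mode; the max/min ratio over the valency range is the
    discrepancy metric (large whenever kd_bi << c_eff).
    """
    rows = []
    for v in valencies:
        aff = kd_monovalent(kd_bi, c_eff, valency=v)
        rows.append({"valency": v, "kd_mono_M": aff.kd_mono})
    df = pd.DataFrame(rows)
    vals = df["kd_mono_M"].to_numpy()
    df.attrs["spread_ratio"] = float(vals.max() / vals.min())
    return df


# ---------------------------------------------------------------------------
# Reporting

def report_interactions(
    kinetics: Sequence[BivalentKinetics],
    affinities: Sequence[MonovalentAffinity | None] | None = None,
) -> pd.DataFrame:
    """Interaction table in prey-(flowed) / bait-(immobilized) orientation.

    One row per interaction: monovalent K_D in uM when an avidity
    conversion is available, otherwise "N/A"; bivalent constants with SEs
    always.
    """
    if not kinetics:
        raise InsufficientDataError("no kinetics to report")
    if affinities is None:
        affinities = [None] * len(kinetics)
    rows = []
    for kin, aff in zip(kinetics, affinities):
        rows.append(
            {
                "prey_flowed": kin.prey,
                "bait_immobilized": kin.bait,
                "kd_mono_uM": (
                    f"{aff.kd_mono * 1e6:.1f}" if aff is not None else "N/A"
                ),
                "kon_bi_M-1s-1": kin.kon_bi,
                "se_kon": kin.se_kon,
                "koff_bi_s-1": kin.koff_bi,
                "se_koff": kin.se_koff,
                "kd_bi_M": kin.kd_bi,
                "se_kd_bi": kin.se_kd,
                "n": kin.n_points,
                "r_squared": kin.r_squared,
            }
        )
    return pd.DataFrame(rows)


def write_kinetics(
    kinetics: Sequence[BivalentKinetics], path: str | Path, fmt: str = "tsv"
) -> None:
    rows = [k.as_dict() for k in kinetics]
    if fmt == "json":
        Path(path).write_text(json.dumps(rows, indent=2, default=str))
    else:
        df = pd.DataFrame([{k: v for k, v in r.items() if k != "points"} for r in rows])
        df.to_csv(path, sep="\t", index=False)
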