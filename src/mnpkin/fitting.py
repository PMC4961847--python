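"""Per-trace exponential association fitting.

The observed binding signal after reference subtraction follows

    S(t) = A * (1 - exp(-k_obs * (t - t0))),   t >= t0,

with only two free parameters: the amplitude A and the observed rate
k_obs; the onset t0 is fixed by synchronization, not fitted.  Fitting uses
damped least squares with an analytic Jacobian over the first 80 samples
after the onset.  Reference subtraction removes any channel-common signal
(drift, baseline step) using the mean of the channel's control/reference
sensors, so fitted rates are invariant to common-mode perturbations.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .chip import (
    ROLE_NEGATIVE_CONTROL,
    ROLE_PROBE,
    ROLE_REFERENCE,
    BindingTrace,
    ChipLayout,
)

logger = logging.getLogger(__name__)

FIT_COLUMNS = (
    "bait", "channel", "sensor", "amplitude_A", "se_A", "k_obs", "se_kobs",
    "t0", "rmse", "n_points", "converged",
)


class FittingConfigError(ValueError):
    pass


class WindowingError(ValueError):
    pass


@dataclass
class ExponentialFit:
    """Per-trace estimates of amplitude and observed rate."""

    bait: str
    channel: int
    sensor: int
    amplitude_A: float
    k_obs: float
    t0: float
    se_A: float
    se_kobs: float
    rmse: float
    n_points: int
    converged: bool
    window_truncated: bool = False

    def as_row(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Reference subtraction

def subtract_reference(
    traces: Sequence[BindingTrace],
    layout: ChipLayout,
    reference_roles: tuple[str, ...] | None = None,
) -> list[BindingTrace]:
    """Subtract the channel-mean reference signal from every trace.

    Reference sensors are those with role ``reference`` when the layout
    declares any; otherwise the ``negative_control`` sensors stand in
    (their signals remain low and constant by design).  The per-time-point
    mean across the channel's reference sensors is subtracted from all
    traces in that channel; reference traces are retained, flagged
    ``consumed_as_reference``.
    """
    if reference_roles is None:
        has_dedicated = any(t.role == ROLE_REFERENCE for t in traces)
        reference_roles = (ROLE_REFERENCE,) if has_dedicated else (ROLE_NEGATIVE_CONTROL,)

    out: list[BindingTrace] = []
    channels = sorted({t.channel for t in traces})
    for ch in channels:
        ch_traces = [t for t in traces if t.channel == ch]
        refs = [t for t in ch_traces if t.role in reference_roles]
        if not refs:
            raise FittingConfigError(
                f"channel {ch} has no sensor with role in {reference_roles}; "
                f"reference subtraction impossible"
            )
        ref_mean = np.mean([t.signals for t in refs], axis=0)
        for t in ch_traces:
            out.append(
                t.with_signals(
                    t.signals - ref_mean,
                    reference_subtracted=True,
                    consumed_as_reference=(t.role in reference_roles),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Onset synchronization

def detect_onset(
    traces: Sequence[BindingTrace],
    channel: int,
    n_baseline: int | None = None,
    threshold_sd: float = 5.0,
) -> float | None:
    """Detect the binding onset of one channel from its mean probe signal.

    Rule: first time the channel-mean probe signal exceeds
    baseline mean + ``threshold_sd`` x baseline SD, rounded to the nearest
    sample; the baseline window is the first ``n_baseline`` samples
    (default: 10% of the trace, at least 5 samples).  Returns None when no
    crossing occurs (flat traces).
    """
    probes = [t for t in traces if t.channel == channel and t.role == ROLE_PROBE]
    if not probes:
        return None
    times = probes[0].times
    mean_sig = np.mean([t.signals for t in probes], axis=0)
    if n_baseline is None:
        n_baseline = max(5, len(times) // 10)
    base = mean_sig[:n_baseline]
    thresh = base.mean() + threshold_sd * max(base.std(ddof=1), 1e-12)
    above = np.nonzero(mean_sig > thresh)[0]
    above = above[above >= n_baseline] if len(above) else above
    if len(above) == 0:
        return None
    return float(times[above[0]])


def synchronize_onset(
    traces: Sequence[BindingTrace],
    layout: ChipLayout,
    onset_time: float | None = None,
    auto: bool = False,
) -> tuple[list[BindingTrace], float]:
    """Align all channels so the binding onset sits at ``onset_time``.

    With ``auto=True`` the onset of each channel is detected by threshold
    crossing and the time axes shifted channel-by-channel; channels whose
    onset is undetectable (all-flat controls) keep the configured onset
    with a warning.  Returns the synchronized traces and the common t0.
    """
    t0 = layout.onset_time if onset_time is None else onset_time
    spans = [(t.times[0], t.times[-1]) for t in traces]
    if any(not (lo <= t0 <= hi) for lo, hi in spans) and not auto:
        raise WindowingError(
            f"onset {t0} s outside the recorded span of at least one trace"
        )
    if not auto:
        return list(traces), t0

    out: list[BindingTrace] = []
    for ch in sorted({t.channel for t in traces}):
        detected = detect_onset(traces, ch)
        if detected is None:
            warnings.warn(
                f"channel {ch}: onset undetectable, keeping configured "
                f"onset {t0} s"
            )
            shift = 0.0
        else:
            shift = t0 - detected
        for t in traces:
            if t.channel == ch:
                out.append(t.with_times(t.times + shift))
    return out, t0


# ---------------------------------------------------------------------------
# Exponential association fit

class ExponentialAssociationFitter(BaseEstimator):
    """Least-squares fit of S(t) = A*(1 - exp(-k_obs*(t - t0))).

    scikit-learn estimator: ``fit(t, y)`` with times and (reference-
    subtracted) signals; fitted attributes ``amplitude_``, ``k_obs_``,
    ``se_amplitude_``, ``se_k_obs_``, ``rmse_``, ``n_points_``,
    ``converged_``.  ``t0`` is a hyperparameter fixed by onset
    synchronization; the fit covers the first ``window`` samples with
    t >= t0.  Initial values are deterministic: A0 = max windowed signal,
    k0 = ln 2 / (time to half of A0); both parameters bounded below by 0.
    Non-convergence sets ``converged_ = False`` instead of raising.
    """

    def __init__(self, t0: float = 60.0, window: int = 80):
        self.t0 = t0
        self.window = window

    def _window(self, t, y):
        sel = np.nonzero(t >= self.t0)[0]
        if len(sel) < 8:
            raise WindowingError(
                f"only {len(sel)} points at t >= t0 = {self.t0}; need >= 8"
            )
        truncated = len(sel) < self.window
        if truncated:
            warnings.warn(
                f"window of {self.window} points truncated to {len(sel)} available"
            )
        sel = sel[: self.window]
        return t[sel], y[sel], truncated

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        sig = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != sig.shape:
            raise ValueError("times and signals differ in length")
        if np.all(np.isnan(sig)):
            raise ValueError("all-NaN trace")
        tw, yw, truncated = self._window(t, sig)
        self.window_truncated_ = truncated
        self.n_points_ = len(tw)
        dt = tw - self.t0

        a0 = max(float(np.max(yw)), 1e-12)
        half = np.nonzero(yw >= a0 / 2)[0]
        t_half = dt[half[0]] if len(half) and dt[half[0]] > 0 else max(dt[-1] / 2, 1e-9)
        k0 = np.log(2) / t_half

        def resid(p):
            a, k = p
            return a * -np.expm1(-k * dt) - yw

        def jac(p):
            a, k = p
            e = np.exp(-k * dt)
            return np.column_stack([-np.expm1(-k * dt), a * dt * e])

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = least_squares(
                resid, x0=[a0, k0], jac=jac, bounds=([0.0, 0.0], [np.inf, np.inf]),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        self.converged_ = bool(sol.success)
        self.amplitude_, self.k_obs_ = (float(v) for v in sol.x)
        r = sol.fun
        self.rmse_ = float(np.sqrt(np.mean(r**2)))
        dof = max(len(tw) - 2, 1)
        s2 = float(np.sum(r**2)) / dof
        J = jac(sol.x)
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            self.se_amplitude_ = float(np.sqrt(max(cov[0, 0], 0.0)))
            self.se_k_obs_ = float(np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            self.se_amplitude_ = np.nan
            self.se_k_obs_ = np.nan
            self.converged_ = False
        return self

    def predict(self, X):
        check_is_fitted(self, "k_obs_")
        t = np.asarray(X, dtype=float).reshape(-1)
        out = self.amplitude_ * -np.expm1(-self.k_obs_ * (t - self.t0))
        return np.where(t < self.t0, 0.0, out)


def fit_binding_curve(
    trace: BindingTrace, t0: float, window: int = 80
) -> ExponentialFit:
    """Fit one reference-subtracted trace; see :class:`ExponentialAssociationFitter`."""
    est = ExponentialAssociationFitter(t0=t0, window=window)
    est.fit(trace.times, trace.signals)
    return ExponentialFit(
        bait=trace.bait,
        channel=trace.channel,
        sensor=trace.sensor,
        amplitude_A=est.amplitude_,
        k_obs=est.k_obs_,
        t0=t0,
        se_A=est.se_amplitude_,
        se_kobs=est.se_k_obs_,
        rmse=est.rmse_,
        n_points=est.n_points_,
        converged=est.converged_,
        window_truncated=est.window_truncated_,
    )


def fit_all_probes(
    traces: Sequence[BindingTrace], t0: float, window: int = 80
) -> list[ExponentialFit]:
    """Fit every probe trace, logging (not raising) per-trace failures."""
    fits = []
    for tr in traces:
        if tr.role != ROLE_PROBE:
            continue
        try:
            fits.append(fit_binding_curve(tr, t0, window))
        except WindowingError as e:
            logger.warning(
                "channel %d sensor %d (%s) excluded: %s",
                tr.channel, tr.sensor, tr.bait, e,
            )
    return fits


# ---------------------------------------------------------------------------
# Duplicate aggregation

def aggregate_duplicates(fits: Sequence[ExponentialFit]) -> pd.DataFrame:
    """Mean and SD of A and k_obs per (bait, channel) across duplicate sensors.

    Converged fits only.  A singleton "duplicate" reports SD as NaN
    (missing), never 0.
    """
    rows = [f.as_row() for f in fits if f.converged]
    if not rows:
        raise ValueError("no converged fits to aggregate")
    df = pd.DataFrame(rows)
    agg = df.groupby(["bait", "channel"], as_index=False).agg(
        k_obs_mean=("k_obs", "mean"),
        k_obs_sd=("k_obs", lambda v: v.std(ddof=1) if len(v) > 1 else np.nan),
        amplitude_mean=("amplitude_A", "mean"),
        amplitude_sd=("amplitude_A", lambda v: v.std(ddof=1) if len(v) > 1 else np.nan),
        n_sensors=("k_obs", "size"),
    )
    return agg


# ---------------------------------------------------------------------------
# fits.tsv I/O

def write_fits(fits: Sequence[ExponentialFit], path: str | Path) -> None:
    df = pd.DataFrame([f.as_row() for f in fits])
    df.to_csv(path, sep="\t", index=False)


def read_fits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fits file missing column(s): {', '.join(missing)}")
    return df


def dissociation_phase_fit(*args, **kwargs):
    """Dissociation-phase (buffer washout) fitting is unsupported.

    The bivalent off-rate is too slow to produce measurable signal decay
    within a practical acquisition window; off-rates come instead from the
    y-intercept of the k_obs-vs-concentration regression.
    """
    raise NotImplementedError(
        "dissociation-phase fitting is not supported; use the intercept of "
        "the observed-rate regression"
    )
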