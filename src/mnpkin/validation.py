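"""Seeded end-to-end validation studies.

Monte-Carlo checks of the full analysis chain against known simulation
ground truth: rate-constant recovery through simulate -> reference-subtract
-> fit -> pooled regression, transport-limitation sweeps against the
two-compartment oracle, and calibration inverse-prediction coverage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import fit_calibration, predict_unknown
from .chip import ChipLayout, MNPBatch, default_layout
from .fitting import (
    ExponentialAssociationFitter,
    aggregate_duplicates,
    fit_all_probes,
    subtract_reference,
    synchronize_onset,
)
from .kinetics import ObservedRateRegression
from .simulate import (
    DEFAULT_TRUTH,
    KineticTruth,
    NoiseModel,
    simulate_calibration_plate,
    simulate_dataset,
    two_compartment_theta,
)


def recover_kinetics_once(
    layout: ChipLayout,
    truth: KineticTruth,
    sigma_rel: float,
    amp_cv: float,
    seed: int,
    n_experiments: int = 3,
    bait: str = "PD-L1",
    eluted: float = 1e-9,
    duration: float = 520.0,
) -> ObservedRateRegression:
    """One full pipeline pass: pooled regression from simulated experiments."""
    batch = MNPBatch.from_layout("prey", eluted, layout)
    truth_map: dict[str, KineticTruth | None] = {b: None for b in layout.baits}
    truth_map[bait] = truth
    conc, kobs = [], []
    for exp in range(n_experiments):
        nm = NoiseModel(sigma_rel, amp_cv, seed=seed * 1009 + exp)
        traces = simulate_dataset(layout, batch, truth_map, nm, duration)
        traces = subtract_reference(traces, layout)
        traces, t0 = synchronize_onset(traces, layout)
        agg = aggregate_duplicates(fit_all_probes(traces, t0))
        sub = agg[agg.bait == bait]
        for _, row in sub.iterrows():
            conc.append(batch.channel_concentrations[int(row.channel)])
            kobs.append(float(row.k_obs_mean))
    return ObservedRateRegression().fit(conc, kobs)


def kobs_recovery_study(
    n_reps: int = 100,
    seed: int = 0,
    truth: KineticTruth = DEFAULT_TRUTH,
    sigma_rel: float = 0.02,
    amp_cv: float = 0.05,
    n_experiments: int = 3,
) -> dict:
    """Distribution of pooled-regression errors over seeded repetitions.

    Returns median relative errors of k_on^bi and K_D^bi and the empirical
    coverage of the regression 95% CI for k_on^bi.
    """
    layout = default_layout()
    err_kon, err_kd, covered = [], [], []
    for rep in range(n_reps):
        reg = recover_kinetics_once(
            layout, truth, sigma_rel, amp_cv, seed=seed + rep,
            n_experiments=n_experiments,
        )
        err_kon.append(abs(reg.kon_bi_ - truth.kon_bi) / truth.kon_bi)
        err_kd.append(abs(reg.kd_bi_ - truth.kd_bi) / truth.kd_bi)
        lo, hi = reg.confidence_interval_kon()
        covered.append(lo <= truth.kon_bi <= hi)
    return {
        "median_rel_err_kon": float(np.median(err_kon)),
        "median_rel_err_kd": float(np.median(err_kd)),
        "ci95_coverage_kon": float(np.mean(covered)),
        "n_reps": n_reps,
    }


def two_compartment_kobs_deviation(
    da_values=(0.01, 0.1, 1.0, 10.0),
    truth: KineticTruth = DEFAULT_TRUTH,
    concentration: float = 1e-9,
    onset: float = 60.0,
    duration: float = 520.0,
    interval: float = 5.5,
) -> pd.DataFrame:
    """Relative k_obs suppression of noiseless two-compartment traces.

    For each Damkoehler number, a noiseless trace is integrated, fitted
    with the reaction-limited exponential model, and the fitted rate
    compared with k_on*C + k_off.
    """
    t = np.arange(0, duration, interval)
    k_true = truth.k_obs(concentration)
    rows = []
    for da in da_values:
        th = two_compartment_theta(t, concentration, truth, da_local=da, t0=onset)
        est = ExponentialAssociationFitter(t0=onset).fit(t, th)
        rows.append({
            "damkohler": da,
            "k_obs_fit": est.k_obs_,
            "k_obs_reaction_limited": k_true,
            "rel_deviation": abs(est.k_obs_ - k_true) / k_true,
        })
    return pd.DataFrame(rows)


def calibration_recovery_study(
    n_runs: int = 1000,
    seed: int = 0,
    slope: float = 0.5,
    intercept: float = 0.05,
    unknown_nm: float = 0.55,
    noise_frac: float = 0.01,
) -> dict:
    """Inverse-prediction coverage over seeded calibration plates.

    Noise SD is ``noise_frac`` of the maximum standard absorbance.  Counts
    runs where R^2 > 0.99 and the recovered unknown lies within 3
    inverse-prediction SEs of truth.
    """
    import warnings

    noise_sd = noise_frac * (slope * 1.0 + intercept)
    ok = 0
    r2s = []
    for i in range(n_runs):
        plate = simulate_calibration_plate(
            slope, intercept, unknown_nm=unknown_nm, noise_sd=noise_sd,
            seed=seed + i,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c_hat, se, curve = predict_unknown(plate)
        r2s.append(curve.r_squared)
        if curve.r_squared > 0.99 and abs(c_hat - unknown_nm) < 3 * se:
            ok += 1
    return {
        "fraction_ok": ok / n_runs,
        "median_r_squared": float(np.median(r2s)),
        "n_runs": n_runs,
    }
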