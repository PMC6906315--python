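"""Behavioral analyses for both tasks.

Old/new judgment task: the proportion of "old" responses is modeled as a
cumulative Weibull function of the probe's orientation similarity to the
ensemble mean, sim(θ) = 1 − |θ|/(π/2), fitted by maximum likelihood under
a per-similarity-level binomial model.  The threshold α — where the curve
reaches 63.2% of its amplitude between the asymptotes — indexes how
narrowly responses concentrate around the mean (the "ensemble tendency").

Continuous estimation task: signed response errors are summarized by their
circular mean per target offset, sign-flipped so positive = toward the
mean; precision is the reciprocal circular standard deviation; and trials
are split at the circular median of the toward-mean errors into mean-like
and target-like response trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .circular import (circ_mean_orientation, circ_median_orientation,
                       circ_std_orientation, wrap_orientation)

__all__ = [
    "orientation_similarity",
    "weibull_cdf",
    "WeibullFit",
    "fit_weibull_mle",
    "weibull_nll",
    "oldnew_tuning_curve",
    "EnsembleTendency",
    "estimation_bias",
    "estimation_precision",
    "median_split",
]

_EPS = 1e-9
_BOUNDS = [(1e-4, 1.0), (1e-4, 100.0), (1e-4, 1.0 - 1e-6), (1e-4, 1.0 - 1e-6)]


def orientation_similarity(theta_rad):
    """Similarity of a probe offset (radians) to the mean: 1 − |θ|/(π/2)."""
    theta = np.asarray(theta_rad, dtype=float)
    if np.any(np.abs(theta) > np.pi / 2 + 1e-12):
        raise ValueError("theta must lie in [-pi/2, pi/2] after wrapping")
    return 1.0 - np.abs(theta) / (np.pi / 2.0)


def weibull_cdf(sim, alpha, beta, gamma, delta):
    """Cumulative Weibull psychometric function γ − (γ − δ)·e^−(sim/α)^β."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    sim = np.asarray(sim, dtype=float)
    # evaluate (sim/alpha)^beta in log space; large exponents saturate to 0/1
    with np.errstate(divide="ignore"):
        log_ratio = np.log(sim) - np.log(alpha)
    exponent = np.exp(np.clip(beta * log_ratio, -700.0, 700.0))
    return gamma - (gamma - delta) * np.exp(-exponent)


@dataclass
class WeibullFit:
    """Fitted psychometric parameters with the minimized negative log-likelihood."""

    alpha: float
    beta: float
    gamma: float
    delta: float
    nll: float
    n_restarts_used: int
    boundary_flag: bool = False
    inverted_flag: bool = False  # γ < δ (not enforced, only reported)

    def predict(self, sim):
        return weibull_cdf(sim, self.alpha, self.beta, self.gamma, self.delta)


def _level_counts(table: pd.DataFrame):
    """Per-similarity trial and "old" counts from an old/new response table."""
    if len(table) == 0:
        raise ValueError("empty behavioral table")
    theta = np.deg2rad(wrap_orientation(table["probe_offset_deg"].to_numpy()))
    theta = np.where(theta < -np.pi / 2 + 1e-12, theta + np.pi, theta)  # -90 ≡ +90
    sim = orientation_similarity(theta)
    old = (table["response"].to_numpy() == "old").astype(int)
    df = pd.DataFrame({"sim": np.round(sim, 12), "old": old})
    grouped = df.groupby("sim", sort=True)["old"].agg(["count", "sum"])
    return (grouped.index.to_numpy(),
            grouped["count"].to_numpy(float),
            grouped["sum"].to_numpy(float))


def weibull_nll(params, sim, n, k):
    """Binomial negative log-likelihood (constant combinatorial terms dropped)."""
    w = np.clip(weibull_cdf(sim, *params), _EPS, 1.0 - _EPS)
    return float(-(k * np.log(w) + (n - k) * np.log(1.0 - w)).sum())


def fit_weibull_mle(table: pd.DataFrame, n_restarts: int = 30, seed: int = 0) -> WeibullFit:
    """Bounded MLE of the cumulative Weibull with random restarts.

    Restart initial values are drawn uniformly in α (0,1), β (0,10),
    γ (0,1), δ (0,1); the restart with the minimum negative log-likelihood
    wins.  The likelihood drops constant log-binomial terms, which shifts
    the reported NLL by a data-dependent constant without moving the argmin.
    """
    sim, n, k = _level_counts(table)
    if len(sim) < 2:
        raise ValueError("need at least 2 distinct similarity levels")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        x0 = np.array([rng.uniform(0.05, 0.95), rng.uniform(0.1, 10.0),
                       rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95)])
        res = minimize(weibull_nll, x0, args=(sim, n, k), method="L-BFGS-B",
                       bounds=_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
    a, b, g, d = best.x
    at_bound = any(
        np.isclose(v, lo, atol=1e-6) or np.isclose(v, hi, atol=1e-6)
        for v, (lo, hi) in zip(best.x, _BOUNDS)
    )
    degenerate = k.sum() == 0 or k.sum() == n.sum()
    return WeibullFit(alpha=float(a), beta=float(b), gamma=float(g), delta=float(d),
                      nll=float(best.fun), n_restarts_used=n_restarts,
                      boundary_flag=bool(at_bound or degenerate),
                      inverted_flag=bool(g < d))


def oldnew_tuning_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Proportion of "old" responses per probe offset (mean-relative axis).

    Offsets absent from the table are simply absent from the result (never
    reported as zero).
    """
    if len(table) == 0:
        raise ValueError("empty behavioral table")
    df = table.assign(old=(table["response"] == "old").astype(int))
    out = (df.groupby("probe_offset_deg", sort=True)["old"]
             .agg(n_trials="count", n_old="sum"))
    out["proportion_old"] = out["n_old"] / out["n_trials"]
    return out.reset_index()


@dataclass
class EnsembleTendency:
    """Scalar behavioral index of reliance on the ensemble mean."""

    experiment: int
    value: float  # Exp 1: Weibull threshold α; Exp 2: mean toward-mean bias (deg)


def toward_mean_errors(table: pd.DataFrame) -> np.ndarray:
    """Response errors re-coded so positive = displaced toward the mean."""
    err = table["response_error_deg"].to_numpy(float)
    off = table["target_offset_deg"].to_numpy(float)
    return -np.sign(off) * err


def estimation_bias(table: pd.DataFrame):
    """Per-target toward-mean bias and the collapsed ensemble tendency.

    The bias at each target offset is the circular mean of the response
    errors, sign-flipped so positive values point toward the ensemble mean;
    the tendency averages the four per-target biases.
    """
    offsets = np.sort(table["target_offset_deg"].unique())
    if len(offsets) < 1:
        raise ValueError("empty estimation table")
    rows = []
    for off in offsets:
        sub = table[table["target_offset_deg"] == off]
        if len(sub) == 0:
            raise ValueError(f"no trials at target offset {off}")
        raw = circ_mean_orientation(sub["response_error_deg"].to_numpy())
        rows.append({"target_offset_deg": off,
                     "bias_toward_mean_deg": -np.sign(off) * raw,
                     "n_trials": len(sub)})
    per_target = pd.DataFrame(rows)
    tendency = EnsembleTendency(experiment=2,
                                value=float(per_target["bias_toward_mean_deg"].mean()))
    return per_target, tendency


def estimation_precision(table: pd.DataFrame) -> float:
    """Reciprocal circular SD of response errors, in deg⁻¹.

    Returns ``inf`` for zero-dispersion samples (flagged infinite precision).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 trials")
    sd = circ_std_orientation(table["response_error_deg"].to_numpy())
    if sd == 0.0:
        return float("inf")
    return 1.0 / sd


def median_split(table: pd.DataFrame) -> pd.DataFrame:
    """Label VO trials "mean" or "target" at the circular median of errors.

    Errors are first re-coded so positive = toward the mean; trials above
    the circular median are labelled "mean", those below "target", and
    exact ties go to "mean" (deterministic, order-independent).
    """
    if len(table) < 4:
        raise ValueError("need at least 4 trials for a median split")
    toward = toward_mean_errors(table)
    if np.allclose(toward, toward[0]):
        raise ValueError("degenerate split: all re-coded errors identical")
    med = circ_median_orientation(toward)
    delta = wrap_orientation(toward - med)
    out = table.copy()
    out["split_label"] = np.where(delta >= 0.0, "mean", "target")
    return out
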