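"""Group-level inference for decoding sensitivities.

Significance of the group-mean sensitivity is assessed with one-sample
t statistics referred to a label-shuffling permutation null: orientation
labels are shuffled within subject (jointly across conditions when both
are supplied), the IEM is refit, and the one-tailed p-value uses the
add-one rule p = (1 + #{null ≥ observed}) / (1 + n_permutations).
Standard errors come from bootstrap resampling of participants.
Brain–behavior association is an OLS R² with its regression p plus a
Spearman rank correlation, relating each subject's window-averaged TG
sensitivity to their behavioral ensemble tendency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .encoding import TGMatrix, _cv_sensitivity

__all__ = [
    "group_tstat",
    "PermutationNull",
    "permutation_null",
    "bootstrap_se",
    "window_average_sensitivity",
    "BrainBehaviorResult",
    "brain_behavior_correlation",
]


def group_tstat(values) -> float:
    """One-sample t statistic of per-subject values against zero."""
    x = np.asarray(values, float)
    if x.ndim == 1:
        if len(x) < 2:
            raise ValueError("need at least 2 subjects")
        sd = x.std(ddof=1)
        if sd == 0.0:
            raise ValueError("degenerate zero-variance sample")
        return float(x.mean() / (sd / np.sqrt(len(x))))
    # vectorized over trailing axes; zero-variance entries become nan
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return x.mean(axis=0) / (sd / np.sqrt(x.shape[0]))


@dataclass
class PermutationNull:
    """Observed group t, label-shuffled null t's, and one-tailed p-values."""

    times: np.ndarray
    observed_t: np.ndarray
    null_t: np.ndarray      # (n_permutations, n_times)
    p_values: np.ndarray    # add-one rule, in (0, 1]
    n_permutations: int
    seed: int
    meta: dict = field(default_factory=dict)


def permutation_null(so_epochs_list, vo_epochs_list=None, time_indices=None,
                     n_permutations: int = 1000, n_folds: int = 3,
                     n_iterations: int = 10, seed: int = 0) -> PermutationNull:
    """Label-shuffling permutation null for the group sensitivity t statistic.

    For each permutation, every subject's orientation labels are shuffled —
    jointly across the SO and VO conditions when ``vo_epochs_list`` is given
    (the statistic is then the SO→VO cross-condition sensitivity) — the IEM
    is refit at the selected time indices, and the group t is recomputed.
    ``n_iterations`` defaults to 10 (a fidelity/runtime knob for the
    per-permutation refits).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    subjects = list(so_epochs_list)
    S = len(subjects)
    vo_list = list(vo_epochs_list) if vo_epochs_list is not None else [None] * S
    times = subjects[0].times
    if time_indices is None:
        time_sel = np.arange(len(times))
    else:
        time_sel = np.atleast_1d(np.asarray(time_indices, int))
    out_times = times[time_sel]

    so_bins = [e.orientation_bins0() for e in subjects]
    vo_bins = [v.orientation_bins0() if v is not None else None for v in vo_list]

    obs = np.stack([
        _cv_slopes_with_bins(subjects[s], vo_list[s], so_bins[s], vo_bins[s],
                             time_sel, n_folds, n_iterations,
                             _derive_seed(seed, 0, s))
        for s in range(S)
    ])
    t_obs = np.atleast_1d(group_tstat(obs))

    null_t = np.empty((n_permutations, len(time_sel)))
    for p in range(1, n_permutations + 1):
        slopes = np.empty((S, len(time_sel)))
        for s in range(S):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(p, s)))
            nb_so = len(so_bins[s])
            if vo_list[s] is None:
                shuffled = rng.permutation(so_bins[s])
                sb, vb = shuffled, None
            else:
                joint = np.concatenate([so_bins[s], vo_bins[s]])
                shuffled = rng.permutation(joint)
                sb, vb = shuffled[:nb_so], shuffled[nb_so:]
            slopes[s] = _cv_slopes_with_bins(subjects[s], vo_list[s], sb, vb,
                                             time_sel, n_folds, n_iterations,
                                             _derive_seed(seed, p, s))
        null_t[p - 1] = np.atleast_1d(group_tstat(slopes))

    p_vals = (1.0 + (null_t >= t_obs[None, :]).sum(axis=0)) / (1.0 + n_permutations)
    return PermutationNull(times=out_times, observed_t=t_obs, null_t=null_t,
                           p_values=p_vals, n_permutations=n_permutations,
                           seed=seed,
                           meta={"n_folds": n_folds, "n_iterations": n_iterations,
                                 "cross_condition": vo_epochs_list is not None})


def _cv_slopes_with_bins(so, vo, so_bins, vo_bins, time_sel, n_folds,
                         n_iterations, seed):
    if vo is None:
        return _cv_sensitivity(so.data[:, :, time_sel], so_bins, n_folds,
                               n_iterations, seed)
    return _cv_sensitivity(so.data[:, :, time_sel], so_bins, n_folds, n_iterations,
                           seed, test_data=vo.data[:, :, time_sel],
                           test_bins0=vo_bins, average_test=True)


def _derive_seed(seed, perm, subject):
    return int(np.random.SeedSequence(seed, spawn_key=(perm, subject))
               .generate_state(1)[0] % (2**31 - 1))


def bootstrap_se(values, n_boot: int = 10000, seed: int = 0):
    """Bootstrap standard error: SD of means over participant resamples."""
    x = np.asarray(values, float)
    if x.shape[0] == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.shape[0], size=(n_boot, x.shape[0]))
    means = x[idx].mean(axis=1)
    return means.std(axis=0, ddof=1)


def window_average_sensitivity(tg: TGMatrix, window=(0.2, 1.0)) -> float:
    """Mean TG sensitivity over a closed train × test time window."""
    lo, hi = window
    t = tg.times
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"window {window} lies outside the epoch [{t[0]}, {t[-1]}]")
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not sel.any():
        raise ValueError("empty window")
    return float(tg.matrix[np.ix_(sel, sel)].mean())


@dataclass
class BrainBehaviorResult:
    """Across-participant association of neural sensitivity with behavior."""

    r_squared: float
    p_value: float
    slope: float
    intercept: float
    spearman_rho: float
    spearman_p: float
    n_subjects: int


def brain_behavior_correlation(sensitivities, tendencies) -> BrainBehaviorResult:
    """OLS R² (with regression p) plus Spearman ρ of paired subject scalars."""
    x = np.asarray(tendencies, float)
    y = np.asarray(sensitivities, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need paired, equal-length 1-d inputs")
    if len(x) < 3:
        raise ValueError("need at least 3 subjects")
    if np.allclose(x, x[0]):
        raise ValueError("constant behavioral predictor")
    fit = sps.linregress(x, y)
    rho, rho_p = sps.spearmanr(x, y)
    return BrainBehaviorResult(r_squared=float(fit.rvalue**2), p_value=float(fit.pvalue),
                               slope=float(fit.slope), intercept=float(fit.intercept),
                               spearman_rho=float(rho), spearman_p=float(rho_p),
                               n_subjects=len(x))
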