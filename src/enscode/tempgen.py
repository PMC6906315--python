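"""Temporal generalization (TG) and the stable/dynamic coding index.

A decoder trained at time t₁ is tested at every time t₂, giving a train ×
test matrix of orientation sensitivities per subject.  Off-diagonal cells
are classified at the group level by three one-sided hypotheses:

    H1(t₁,t₂): TG(t₁,t₂) < TG(t₁,t₁)
    H2(t₁,t₂): TG(t₁,t₂) < TG(t₂,t₂)
    H3(t₁,t₂): TG(t₁,t₂) > 0

    dynamic(t₁,t₂) = H1 ∧ H2          (below both diagonals)
    stable(t₁,t₂)  = ¬H1 ∧ ¬H2 ∧ H3   (above zero, not below the diagonals)

The time-resolved stable (dynamic) index at t is the proportion of stable
(dynamic) cells within a square window centered on (t, t), excluding a
guard band around the diagonal that absorbs the temporal smearing of the
moving-average filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .encoding import TGMatrix, _check_counts, _cv_sensitivity

__all__ = [
    "tg_matrix",
    "cross_condition_tg",
    "SignificanceMaps",
    "SDIndexSeries",
    "classify_cells",
    "classify_from_maps",
    "stable_dynamic_index",
    "plot_tg_heatmap",
]


def tg_matrix(epochs, n_folds: int = 3, n_iterations: int = 100, seed: int = 0) -> TGMatrix:
    """Within-condition TG matrix for one subject.

    Partitions and iterations are shared across the whole matrix, so the
    diagonal reproduces the per-timepoint cross-validated sensitivity
    obtained under the same seed.
    """
    bins0 = epochs.orientation_bins0()
    _check_counts(bins0, n_folds)
    mat = _cv_sensitivity(epochs.data, bins0, n_folds, n_iterations, seed, tg=True)
    return TGMatrix(times=epochs.times.copy(), matrix=mat,
                    meta={"n_folds": n_folds, "n_iterations": n_iterations,
                          "seed": seed, "mode": "within"})


def cross_condition_tg(so_epochs, vo_epochs, n_folds: int = 3, n_iterations: int = 100,
                       seed: int = 0, average_test: bool = True,
                       trial_indices=None) -> TGMatrix:
    """TG matrix of the SO-trained decoder generalized to VO test trials."""
    if list(so_epochs.electrode_labels) != list(vo_epochs.electrode_labels):
        raise ValueError("SO and VO epochs must share the same electrodes")
    if not np.allclose(so_epochs.times, vo_epochs.times):
        raise ValueError("SO and VO epochs must share the same time axis")
    so_bins = so_epochs.orientation_bins0()
    _check_counts(so_bins, n_folds)
    vo_bins = vo_epochs.orientation_bins0()
    vo_data = vo_epochs.data
    if trial_indices is not None:
        trial_indices = np.asarray(trial_indices, int)
        vo_data, vo_bins = vo_data[trial_indices], vo_bins[trial_indices]
    if len(vo_bins) == 0:
        raise ValueError("empty VO test set")
    mat = _cv_sensitivity(so_epochs.data, so_bins, n_folds, n_iterations, seed,
                          tg=True, test_data=vo_data, test_bins0=vo_bins,
                          average_test=average_test)
    return TGMatrix(times=so_epochs.times.copy(), matrix=mat,
                    meta={"n_folds": n_folds, "n_iterations": n_iterations,
                          "seed": seed, "mode": "cross"})


@dataclass
class SignificanceMaps:
    """Boolean off-diagonal decision maps for the three cell hypotheses."""

    times: np.ndarray
    h1: np.ndarray  # TG(t1,t2) significantly below TG(t1,t1)
    h2: np.ndarray  # TG(t1,t2) significantly below TG(t2,t2)
    h3: np.ndarray  # TG(t1,t2) significantly above 0
    alpha: float = 0.05
    method: str = "parametric"
    n_degenerate: int = 0
    meta: dict = field(default_factory=dict)


@dataclass
class SDIndexSeries:
    """Stable and dynamic index time courses, each bounded in [0, 1]."""

    times: np.ndarray
    stable: np.ndarray
    dynamic: np.ndarray
    window_ms: float = 310.0
    guard_ms: float = 50.0


def _offdiag_mask(T: int) -> np.ndarray:
    return ~np.eye(T, dtype=bool)


def _signflip_pvalues(x, tail, n_permutations, rng):
    """One-sided sign-flip randomization p-values for mean(x) per cell.

    ``x`` is (subjects, cells).  The t statistic under sign flips is a
    monotone function of the flipped mean (the sum of squares is flip
    invariant), so the test is carried out on means.  Add-one rule.
    """
    S, C = x.shape
    obs = x.mean(axis=0)
    exceed = np.zeros(C)
    chunk = max(1, int(4e6 // max(C, 1)))
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, S))
    for a in range(0, n_permutations, chunk):
        null = signs[a:a + chunk] @ x / S  # (chunk, C)
        if tail == "less":
            exceed += (null <= obs[None, :]).sum(axis=0)
        else:
            exceed += (null >= obs[None, :]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + n_permutations)


def classify_cells(tg_matrices, alpha: float = 0.05, method: str = "parametric",
                   n_permutations: int = 2000, seed: int = 0):
    """Group-level cell classification of a stack of subject TG matrices.

    Returns ``(maps, classes)`` where ``classes`` maps "stable"/"dynamic"
    to boolean off-diagonal masks (mutually exclusive by construction).
    ``method`` is "parametric" (one-sided paired/one-sample t-tests) or
    "permutation" (sign-flip randomization of the same statistics).
    """
    if isinstance(tg_matrices[0], TGMatrix):
        times = tg_matrices[0].times
        stack = np.stack([m.matrix for m in tg_matrices])
    else:
        stack = np.asarray(tg_matrices, float)
        times = np.arange(stack.shape[1], dtype=float)
    S, T, _ = stack.shape
    if S < 2:
        raise ValueError("need at least 2 subjects")
    if method not in ("parametric", "permutation"):
        raise ValueError(f"unknown method {method!r}")

    diag = stack[:, np.arange(T), np.arange(T)]  # (S, T)
    d1 = stack - diag[:, :, None]  # vs TG(t1,t1)
    d2 = stack - diag[:, None, :]  # vs TG(t2,t2)
    tests = [(d1, "less"), (d2, "less"), (stack, "greater")]

    n_degenerate = 0
    rejections = []
    for x, tail in tests:
        flat = x.reshape(S, T * T)
        sd = flat.std(axis=0, ddof=1)
        degen = sd == 0.0
        n_degenerate += int(degen.sum())
        if method == "parametric":
            with np.errstate(divide="ignore", invalid="ignore"):
                t = flat.mean(axis=0) / (sd / np.sqrt(S))
            p = sps.t.cdf(t, S - 1) if tail == "less" else sps.t.sf(t, S - 1)
            # zero-variance cells: decide by the (degenerate) mean sign
            mean = flat.mean(axis=0)
            p = np.where(degen, np.where((mean < 0) if tail == "less" else (mean > 0), 0.0, 1.0), p)
        else:
            rng = np.random.default_rng(seed)
            p = _signflip_pvalues(flat, tail, n_permutations, rng)
        rejections.append((p < alpha).reshape(T, T))

    off = _offdiag_mask(T)
    h1, h2, h3 = (r & off for r in rejections)
    maps = SignificanceMaps(times=np.asarray(times, float), h1=h1, h2=h2, h3=h3,
                            alpha=alpha, method=method, n_degenerate=n_degenerate,
                            meta={"n_subjects": S, "n_permutations": n_permutations})
    return maps, classify_from_maps(maps)


def classify_from_maps(maps: SignificanceMaps) -> dict:
    """Apply the Boolean stable/dynamic formulas to decision maps."""
    off = _offdiag_mask(len(maps.times))
    dynamic = maps.h1 & maps.h2 & off
    stable = ~maps.h1 & ~maps.h2 & maps.h3 & off
    return {"stable": stable, "dynamic": dynamic}


def stable_dynamic_index(maps_or_classes, times=None, window_ms: float = 310.0,
                         guard_ms: float = 50.0) -> SDIndexSeries:
    """Proportion of stable/dynamic cells in a sliding square window.

    The window (default 310 ms) is centered on (t, t) and truncated at the
    epoch boundaries; cells within ±``guard_ms`` of the diagonal
    (inclusive) are excluded, and the denominator is the number of
    remaining eligible cells.
    """
    if isinstance(maps_or_classes, SignificanceMaps):
        classes = classify_from_maps(maps_or_classes)
        times = maps_or_classes.times if times is None else times
    else:
        classes = maps_or_classes
        if times is None:
            raise ValueError("times must be given when passing raw class maps")
    times = np.asarray(times, float)
    T = len(times)
    fs = 1.0 / np.median(np.diff(times))
    n_win = int(round(window_ms / 1000.0 * fs))
    if n_win % 2 == 0:
        n_win += 1
    half = n_win // 2
    guard = int(np.floor(guard_ms / 1000.0 * fs + 1e-9))
    if half <= guard:
        raise ValueError("window must extend beyond the diagonal guard")

    ii, jj = np.meshgrid(np.arange(T), np.arange(T), indexing="ij")
    eligible_full = np.abs(ii - jj) > guard
    stable = np.zeros(T)
    dynamic = np.zeros(T)
    for t in range(T):
        lo, hi = max(0, t - half), min(T, t + half + 1)
        win = (slice(lo, hi), slice(lo, hi))
        denom = eligible_full[win].sum()
        if denom == 0:
            stable[t] = dynamic[t] = np.nan
            continue
        stable[t] = (classes["stable"][win] & eligible_full[win]).sum() / denom
        dynamic[t] = (classes["dynamic"][win] & eligible_full[win]).sum() / denom
    return SDIndexSeries(times=times.copy(), stable=stable, dynamic=dynamic,
                         window_ms=window_ms, guard_ms=guard_ms)


def plot_tg_heatmap(tg_matrices, classes=None, ax=None, cmap="RdBu_r"):
    """Group-mean TG heatmap with an optional significant-cell contour mask."""
    import matplotlib.pyplot as plt

    if isinstance(tg_matrices[0], TGMatrix):
        times = tg_matrices[0].times
        mean = np.mean([m.matrix for m in tg_matrices], axis=0)
    else:
        mean = np.mean(tg_matrices, axis=0)
        times = np.arange(mean.shape[0])
    if ax is None:
        _, ax = plt.subplots()
    extent = [times[0], times[-1], times[0], times[-1]]
    vmax = np.abs(mean).max() or 1.0
    im = ax.imshow(mean, origin="lower", extent=extent, cmap=cmap,
                   vmin=-vmax, vmax=vmax, aspect="auto")
    if classes is not None:
        mask = classes["stable"] | classes["dynamic"]
        ax.contour(times, times, mask.astype(float), levels=[0.5], colors="k",
                   linewidths=0.8)
    ax.set_xlabel("test time (s)")
    ax.set_ylabel("train time (s)")
    return im
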