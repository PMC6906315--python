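"""Inverted encoding model (IEM) for orientation.

The model treats each electrode's signal as a weighted sum of eight
hypothetical orientation channels with cos⁷ tuning: B = W C, with
B (electrodes × observations), W (electrodes × channels) and
C (channels × observations).  Training solves the least-squares problem
Ŵ = B₁C₁ᵀ(C₁C₁ᵀ)⁻¹; testing inverts the estimated weights,
Ĉ₂ = (ŴᵀŴ)⁻¹ŴᵀB₂.  Reconstructed channel profiles are baseline-corrected,
circularly aligned to a common center, averaged, and summarized by the
slope of the profile over the sign-folded offset axis ("orientation
sensitivity"): zero for flat profiles, positive for center-peaked tuning.

Channel centers sit at the eight stimulus orientations (−78.75° … 78.75°,
spaced 22.5°); the aligned offset axis runs −90° … 67.5°.  Orientation
differences are wrapped to [−90°, 90°) before the cosine, which makes the
tuning function |cos Δ|⁷ on the 180°-periodic orientation circle and keeps
the 8 × 8 design full rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circular import wrap_orientation

__all__ = [
    "STIMULUS_ORIENTATIONS_DEG",
    "ALIGNED_OFFSETS_DEG",
    "BasisSet",
    "basis_responses",
    "design_matrix",
    "estimate_weights",
    "invert_to_ctf",
    "baseline_correct",
    "align_profiles",
    "align_and_average",
    "ctf_slope",
    "ideal_basis_profile",
    "SensitivitySeries",
    "TGMatrix",
    "run_iem",
    "cross_condition_iem",
]

#: The eight stimulus orientations (degrees), also the channel centers.
STIMULUS_ORIENTATIONS_DEG = np.arange(8) * 22.5 - 78.75

#: Offset axis of an aligned channel profile (degrees from the stimulus).
ALIGNED_OFFSETS_DEG = np.arange(8) * 22.5 - 90.0

# Sign-folded regression axis: positive offsets mirrored to negative, so a
# center-peaked profile regresses with positive slope.
_FOLDED_AXIS = -np.abs(ALIGNED_OFFSETS_DEG)
_xc = _FOLDED_AXIS - _FOLDED_AXIS.mean()
#: Linear functional giving the OLS slope (with intercept) of an 8-profile.
SLOPE_COEF = _xc / (_xc @ _xc)

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class BasisSet:
    """Eight cos^exponent orientation channels centered on the stimulus grid."""

    centers_deg: tuple = tuple(STIMULUS_ORIENTATIONS_DEG)
    exponent: int = 7


def basis_responses(theta_deg, basis: BasisSet | None = None) -> np.ndarray:
    """Channel responses to orientation(s) ``theta_deg``.

    Returns shape (8,) for a scalar input or (n, 8) for a vector; responses
    are cos^7 of the wrapped center offset — 1 at zero offset, 0 at ±90°.
    """
    basis = basis or BasisSet()
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    delta = wrap_orientation(theta[:, None] - np.asarray(basis.centers_deg)[None, :])
    resp = np.cos(np.deg2rad(delta)) ** basis.exponent
    return resp[0] if np.isscalar(theta_deg) or np.ndim(theta_deg) == 0 else resp


def design_matrix(orientations_deg, basis: BasisSet | None = None) -> np.ndarray:
    """Channel × observation design matrix C for the given orientations."""
    resp = np.atleast_2d(basis_responses(np.atleast_1d(orientations_deg), basis))
    return resp.T  # (8, n)


def _bin_design(n_reps: int) -> np.ndarray:
    """Design for observations that cycle through the 8 bins n_reps times."""
    R = basis_responses(STIMULUS_ORIENTATIONS_DEG)  # (8 orientations, 8 channels)
    return np.tile(R.T, (1, n_reps))  # (8, 8*n_reps)


def estimate_weights(B1: np.ndarray, C1: np.ndarray) -> np.ndarray:
    """Least-squares weight estimate Ŵ = B₁C₁ᵀ(C₁C₁ᵀ)⁻¹.

    Raises if the design is rank deficient (fewer than 8 distinct
    orientations represented), naming the unexcited channels.
    """
    B1 = np.asarray(B1, float)
    C1 = np.asarray(C1, float)
    gram = C1 @ C1.T
    rank = np.linalg.matrix_rank(gram, tol=_RANK_RTOL * np.linalg.norm(gram, 2))
    if rank < C1.shape[0]:
        peak = np.argmax(C1, axis=0)
        missing = sorted(set(range(C1.shape[0])) - set(peak[C1.max(axis=0) > 0]))
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {C1.shape[0]}); "
            f"channels without a peaking observation: {missing}"
        )
    return np.linalg.solve(gram, C1 @ B1.T).T


def invert_to_ctf(W: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Reconstruct channel responses Ĉ₂ = (ŴᵀŴ)⁻¹ŴᵀB₂ for test observations."""
    W = np.asarray(W, float)
    B2 = np.asarray(B2, float)
    m, k = W.shape
    if m < k:
        raise np.linalg.LinAlgError(f"need at least {k} electrodes, got {m}")
    if np.linalg.matrix_rank(W, tol=_RANK_RTOL * max(1.0, np.linalg.norm(W, 2))) < k:
        raise np.linalg.LinAlgError("rank-deficient weight matrix")
    return np.linalg.solve(W.T @ W, W.T @ B2)


def baseline_correct(ctf: np.ndarray, channel_axis: int = 0) -> np.ndarray:
    """Remove the across-channel mean from each observation (idempotent)."""
    ctf = np.asarray(ctf, float)
    return ctf - ctf.mean(axis=channel_axis, keepdims=True)


# circular-shift gather: _ALIGN_IDX[bin, i] = channel landing at aligned slot i
_ALIGN_IDX = (np.arange(8)[:, None] + np.arange(8)[None, :] - 4) % 8


def align_profiles(ctf: np.ndarray, bins0: np.ndarray) -> np.ndarray:
    """Circularly shift per-observation profiles to a common center.

    ``ctf`` has channels on the second-to-last axis and observations on the
    last; ``bins0`` gives each observation's 0-based orientation bin.  In the
    output (..., 8 offsets, n_obs), slot 4 (offset 0°) holds the response of
    the observation's own channel.
    """
    ctf = np.asarray(ctf, float)
    bins0 = np.asarray(bins0, int)
    ch = _ALIGN_IDX[bins0].T  # (8 slots, n_obs)
    return ctf[..., ch, np.arange(len(bins0))[None, :]]


def align_and_average(ctf: np.ndarray, bins0: np.ndarray) -> np.ndarray:
    """Aligned, observation-averaged channel profile (last axis length 8)."""
    aligned = align_profiles(ctf, bins0)
    return aligned.mean(axis=-1)


def ctf_slope(profile: np.ndarray) -> np.ndarray:
    """OLS slope (with intercept) of aligned profile(s) on the folded axis."""
    return np.asarray(profile, float) @ SLOPE_COEF


def ideal_basis_profile() -> np.ndarray:
    """The noiseless aligned profile: the basis function on the offset axis."""
    return np.cos(np.deg2rad(wrap_orientation(ALIGNED_OFFSETS_DEG))) ** 7


@dataclass
class SensitivitySeries:
    """Orientation sensitivity (CTF slope) per time point for one subject."""

    times: np.ndarray
    slopes: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "slope": self.slopes})


@dataclass
class TGMatrix:
    """Temporal-generalization matrix of CTF slopes (train time × test time)."""

    times: np.ndarray
    matrix: np.ndarray  # (n_train_times, n_test_times)
    meta: dict = field(default_factory=dict)

    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.matrix).copy()

    def to_frame(self):
        import pandas as pd

        t1, t2 = np.meshgrid(self.times, self.times, indexing="ij")
        return pd.DataFrame(
            {"train_time": t1.ravel(), "test_time": t2.ravel(), "slope": self.matrix.ravel()}
        )


def _partition_means(data, bins0, n_folds, rng):
    """Equalized random partition with per-fold, per-orientation averaging.

    Returns (fold_avg (n_folds, 8, m, T), n_discarded).  Raises when an
    orientation bin holds fewer than ``n_folds`` trials.
    """
    n, m, T = data.shape
    fold_avg = np.empty((n_folds, 8, m, T))
    discarded = 0
    for j in range(8):
        idx = np.flatnonzero(bins0 == j)
        n_per = len(idx) // n_folds
        if n_per == 0:
            raise ValueError(
                f"orientation bin {j + 1} has {len(idx)} trials; need at least {n_folds}"
            )
        perm = rng.permutation(idx)
        used = perm[: n_per * n_folds].reshape(n_folds, n_per)
        discarded += len(idx) - n_per * n_folds
        fold_avg[:, j] = data[used].mean(axis=1)
    return fold_avg, discarded


def _iter_rng(seed: int, iteration: int) -> np.random.Generator:
    """Reproducible per-iteration RNG substream."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration,)))


def _slope_from_ctf(C, bins0):
    """Baseline-correct, align, average and regress reconstructed profiles.

    ``C`` has shape (..., 8 channels, n_obs).
    """
    C = C - C.mean(axis=-2, keepdims=True)
    aligned = align_profiles(C, bins0)  # (..., 8, n_obs)
    return aligned.mean(axis=-1) @ SLOPE_COEF


def _cv_sensitivity(data, bins0, n_folds, n_iterations, seed, tg=False,
                    test_data=None, test_bins0=None, average_test=True,
                    _t1_block=64):
    """Cross-validated per-time (or train × test time) CTF slopes.

    Within-condition mode (``test_data is None``): the held-out fold's
    per-orientation averages form the test set.  Cross-condition mode:
    weights come from the training folds while every test observation (all
    of ``test_data``) is evaluated each fold, averaged per orientation bin
    beforehand when ``average_test``.

    Inversion uses an SVD pseudoinverse so that identically zero training
    data (e.g. noiseless pre-onset samples) yields zero reconstructions
    rather than an error.
    """
    data = np.asarray(data, float)
    n, m, T = data.shape
    if m < 8:
        raise ValueError("need at least 8 electrodes")
    n_train = n_folds - 1
    C1 = _bin_design(n_train)  # (8, 8*n_train)
    P = np.linalg.solve(C1 @ C1.T, C1).T  # (8*n_train, 8): Ŵ = B₁ @ P

    if test_data is not None:
        test_data = np.asarray(test_data, float)
        if test_data.shape[1:] != (m, T):
            raise ValueError("training and test sets must share electrodes and times")
        if average_test:
            present = np.unique(test_bins0)
            B2_fixed = np.stack([test_data[test_bins0 == j].mean(axis=0) for j in present])
            tb_fixed = present
        else:
            B2_fixed, tb_fixed = test_data, np.asarray(test_bins0, int)

    acc = np.zeros((T, T)) if tg else np.zeros(T)
    train_sel = [np.array([g for g in range(n_folds) if g != f]) for f in range(n_folds)]
    for it in range(n_iterations):
        rng = _iter_rng(seed, it)
        fold_avg, _ = _partition_means(data, bins0, n_folds, rng)
        for f in range(n_folds):
            train = fold_avg[train_sel[f]].reshape(n_train * 8, m, T)
            W = np.einsum("omt,ok->tmk", train, P)  # (T, m, 8)
            pinvW = np.linalg.pinv(W)  # (T, 8, m)
            if test_data is None:
                B2, tb = fold_avg[f], np.arange(8)
            else:
                B2, tb = B2_fixed, tb_fixed
            if tg:
                for a in range(0, T, _t1_block):
                    blk = slice(a, min(a + _t1_block, T))
                    C = np.einsum("akm,omb->abko", pinvW[blk], B2)
                    acc[blk] += _slope_from_ctf(C, tb)
            else:
                C = np.einsum("tkm,omt->tko", pinvW, B2)
                acc += _slope_from_ctf(C, tb)
    return acc / (n_folds * n_iterations)


def _check_counts(bins0, n_folds):
    counts = np.bincount(bins0, minlength=8)
    if (counts < n_folds).any():
        low = [int(j + 1) for j in np.flatnonzero(counts < n_folds)]
        raise ValueError(f"orientation bins {low} have fewer than {n_folds} trials")


def run_iem(epochs, n_folds: int = 3, n_iterations: int = 100, seed: int = 0) -> SensitivitySeries:
    """Within-condition cross-validated IEM: sensitivity per time point.

    Per iteration, trials are randomly partitioned into ``n_folds`` subsets
    with equalized per-orientation counts, averaged per orientation within
    each subset; each fold in turn serves as the test set.  Results average
    over folds and iterations.
    """
    bins0 = epochs.orientation_bins0()
    _check_counts(bins0, n_folds)
    slopes = _cv_sensitivity(epochs.data, bins0, n_folds, n_iterations, seed)
    return SensitivitySeries(
        times=epochs.times.copy(),
        slopes=slopes,
        meta={"n_folds": n_folds, "n_iterations": n_iterations, "seed": seed,
              "mode": "within"},
    )


def cross_condition_iem(so_epochs, vo_epochs, n_folds: int = 3, n_iterations: int = 100,
                        seed: int = 0, average_test: bool = True,
                        trial_indices=None) -> SensitivitySeries:
    """Generalize the SO-trained decoder to VO trials labelled by their mean.

    Weights are fit on SO folds only; every VO trial is tested in each fold.
    ``average_test`` averages VO trials per mean-orientation bin before
    inversion (mirroring the within-condition averaging); the per-trial path
    is retained for trial-subset analyses.  ``trial_indices`` optionally
    restricts the VO test set.
    """
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
        vo_data = vo_data[trial_indices]
        vo_bins = vo_bins[trial_indices]
    if len(vo_bins) == 0:
        raise ValueError("empty VO test set")
    slopes = _cv_sensitivity(so_epochs.data, so_bins, n_folds, n_iterations, seed,
                             test_data=vo_data, test_bins0=vo_bins,
                             average_test=average_test)
    return SensitivitySeries(
        times=so_epochs.times.copy(),
        slopes=slopes,
        meta={"n_folds": n_folds, "n_iterations": n_iterations, "seed": seed,
              "mode": "cross", "average_test": average_test},
    )
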