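"""Temporal smoothing, downsampling, and electrode-subset selection.

Decoding operates on epochs smoothed with a 51-point (100 ms at 500 Hz)
centered moving average and decimated to 100 Hz.  Edge samples use
truncated (shrinking) windows so the output length equals the input
length; decimation keeps sample 0 and every native/target-th sample after
it.  Region-of-interest (ROI) subsets split the 28-electrode montage into
14 frontocentral and 14 occipitoparietal channels per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .synthdata import EpochSet, _ROIS
from .encoding import _partition_means, _check_counts  # re-exported for pipeline use

__all__ = ["ROISpec", "roi_spec", "moving_average", "downsample",
           "select_electrodes", "equalize_and_partition"]

ROI_NAMES = ("all", "frontocentral", "occipitoparietal")


@dataclass(frozen=True)
class ROISpec:
    """Named electrode subset for one experiment's montage."""

    name: str
    experiment: int
    electrode_labels: tuple

    def __post_init__(self):
        if self.name not in ROI_NAMES:
            raise ValueError(f"unknown ROI {self.name!r}; choose from {ROI_NAMES}")


def roi_spec(name: str, experiment: int) -> ROISpec:
    """Look up the packaged per-experiment ROI electrode list."""
    if name not in ROI_NAMES:
        raise ValueError(f"unknown ROI {name!r}; choose from {ROI_NAMES}")
    if name == "all":
        labels = tuple(_ROIS["montage"][str(experiment)])
    else:
        labels = tuple(_ROIS[name][str(experiment)])
    return ROISpec(name=name, experiment=experiment, electrode_labels=labels)


def _copy_with(epochs: EpochSet, **kw) -> EpochSet:
    fields = dict(data=epochs.data, times=epochs.times,
                  sampling_rate=epochs.sampling_rate,
                  electrode_labels=list(epochs.electrode_labels),
                  trial_table=epochs.trial_table.copy())
    fields.update(kw)
    return EpochSet(**fields)


def moving_average(epochs: EpochSet, window_samples: int = 51) -> EpochSet:
    """Centered boxcar smoothing with truncated windows at the epoch edges."""
    T = epochs.data.shape[2]
    if window_samples % 2 == 0:
        raise ValueError("window_samples must be odd")
    if window_samples > T:
        raise ValueError(f"window of {window_samples} samples exceeds epoch length {T}")
    half = window_samples // 2
    summed = uniform_filter1d(epochs.data, size=window_samples, axis=2,
                              mode="constant", cval=0.0) * window_samples
    idx = np.arange(T)
    counts = np.minimum(idx + half, T - 1) - np.maximum(idx - half, 0) + 1
    return _copy_with(epochs, data=summed / counts)


def downsample(epochs: EpochSet, target_rate: float = 100.0) -> EpochSet:
    """Keep every (native/target)-th sample, starting at the first sample."""
    ratio = epochs.sampling_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"native rate {epochs.sampling_rate} Hz is not an integer multiple of "
            f"{target_rate} Hz"
        )
    step = int(round(ratio))
    return _copy_with(epochs, data=epochs.data[:, :, ::step],
                      times=epochs.times[::step], sampling_rate=target_rate)


def select_electrodes(epochs: EpochSet, roi: ROISpec | str,
                      experiment: int | None = None) -> EpochSet:
    """Restrict the epochs to an ROI's electrodes, in ROI order."""
    if isinstance(roi, str):
        if experiment is None:
            experiment = int(epochs.trial_table["experiment"].iloc[0])
        roi = roi_spec(roi, experiment)
    if roi.name == "all" and set(roi.electrode_labels) != set(epochs.electrode_labels):
        return _copy_with(epochs)  # "all" on a non-montage set: identity
    missing = [lab for lab in roi.electrode_labels if lab not in epochs.electrode_labels]
    if missing:
        raise ValueError(f"electrodes missing from the epochs: {missing}")
    order = [epochs.electrode_labels.index(lab) for lab in roi.electrode_labels]
    return _copy_with(epochs, data=epochs.data[:, order],
                      electrode_labels=list(roi.electrode_labels))


def equalize_and_partition(epochs: EpochSet, n_folds: int = 3, seed: int = 0):
    """Random equalized partition with per-fold, per-orientation averaging.

    Returns ``(fold_avg, n_discarded)`` where ``fold_avg`` has shape
    (n_folds, 8 orientations, electrodes, samples).  Trials beyond the
    equalized per-bin count are discarded uniformly at random under the
    seed.
    """
    bins0 = epochs.orientation_bins0()
    _check_counts(bins0, n_folds)
    rng = np.random.default_rng(seed)
    return _partition_means(epochs.data, bins0, n_folds, rng)
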