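"""Synthetic stimuli, forward-model EEG epochs, and behavioral responses.

The generator emulates the statistical structure assumed by the inverted
encoding model: the signal of each electrode is a weighted sum of eight
orientation-channel responses plus Gaussian noise.  Two display conditions
are produced — same-orientation (SO) displays in which all 20 bars share one
orientation, and varied-orientation (VO) displays in which four offsets are
arranged around a never-shown ensemble mean.  Weight matrices can be held
constant over time (stable coding), redrawn per time segment (dynamic
coding), or mixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import wrap_orientation
from .encoding import STIMULUS_ORIENTATIONS_DEG, BasisSet, basis_responses

__all__ = [
    "STIMULUS_ORIENTATIONS_DEG",
    "VO_OFFSETS_DEG",
    "PROBE_OFFSETS_VO_DEG",
    "PROBE_OFFSETS_SO_NEW_DEG",
    "StimulusSet",
    "SimConfig",
    "EpochSet",
    "generate_stimuli",
    "simulate_epochs",
    "simulate_oldnew_behavior",
    "simulate_estimation_behavior",
    "simulate_subject",
    "subject_rng",
    "montage_labels",
]

#: Item offsets from the ensemble mean in the varied-orientation condition.
VO_OFFSETS_DEG = {1: (-30.0, -10.0, 10.0, 30.0), 2: (-22.5, -7.5, 7.5, 22.5)}

#: Old/new probe offsets from the mean orientation, VO condition (equal probability).
PROBE_OFFSETS_VO_DEG = (0.0, 10.0, -10.0, 20.0, -20.0, 30.0, -30.0, 40.0, -40.0,
                        50.0, -50.0, 60.0, -60.0, 70.0, -70.0, 80.0, -80.0, -90.0)

#: Old/new probe offsets from the item orientation for "new" SO trials.
PROBE_OFFSETS_SO_NEW_DEG = (4.0, -4.0, 8.0, -8.0, 12.0, -12.0, 16.0, -16.0,
                            20.0, -20.0, 24.0, -24.0, 28.0, -28.0, 32.0, -32.0)

_N_ITEMS = 20
_N_REPS_PER_OFFSET = 5


def _load_rois() -> dict:
    with resources.files("enscode.data").joinpath("rois.json").open() as fh:
        return json.load(fh)


_ROIS = _load_rois()


def montage_labels(experiment: int) -> list[str]:
    """The 28 scalp electrode labels used in the given experiment."""
    return list(_ROIS["montage"][str(experiment)])


@dataclass(frozen=True)
class StimulusSet:
    """One trial's display: 20 oriented bars around a (possibly unshown) mean."""

    mean_orientation: float
    condition: str            # "SO" or "VO"
    experiment: int           # 1 or 2
    item_orientations: tuple  # 20 orientations in degrees, wrapped to [-90, 90)

    def __post_init__(self):
        if self.condition not in ("SO", "VO"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.experiment not in (1, 2):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if len(self.item_orientations) != _N_ITEMS:
            raise ValueError("a display holds exactly 20 items")

    @property
    def orientation_bin(self) -> int:
        """1-based index of the mean orientation in the 8-orientation set."""
        diffs = np.abs(wrap_orientation(STIMULUS_ORIENTATIONS_DEG - self.mean_orientation))
        return int(np.argmin(diffs)) + 1


@dataclass
class SimConfig:
    """Forward-model generator settings.

    Defaults follow the old/new judgment study protocol: 1024 SO / 288 VO
    trials, 28 electrodes, 500 Hz sampling, epochs from -200 to 1600 ms
    around stimulus onset.  ``signal_scale`` sets the amplitude of the tuned
    component (0 gives pure-noise null data).  ``coding_regime`` chooses a
    single weight matrix ("stable"), independent redraws every
    ``segment_len_s`` seconds after onset ("dynamic"), or an equal mixture
    ("mixed").
    """

    n_trials_so: int = 1024
    n_trials_vo: int = 288
    n_electrodes: int = 28
    sampling_rate: float = 500.0
    epoch_window: tuple = (-0.2, 1.6)
    noise_sd: float = 1.0
    signal_scale: float = 1.0
    coding_regime: str = "stable"
    segment_len_s: float = 0.1
    ensemble_weight: float = 0.5   # λ: weight of the mean-orientation channel input in VO trials
    behavior_bias: float = 0.3     # w: pull of responses toward the ensemble mean
    response_noise_kappa: float = 8.0  # von Mises concentration on the doubled circle
    ar1_rho: float = 0.0           # temporal autocorrelation of the noise; 0 = white
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ensemble_weight <= 1.0:
            raise ValueError("ensemble_weight must lie in [0, 1]")
        if not 0.0 <= self.behavior_bias <= 1.0:
            raise ValueError("behavior_bias must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.coding_regime not in ("stable", "dynamic", "mixed"):
            raise ValueError(f"unknown coding_regime {self.coding_regime!r}")
        if not (self.epoch_window[0] <= 0.0 < self.epoch_window[1]):
            raise ValueError("epoch window must cover stimulus onset at t=0")
        if self.n_electrodes < 8:
            raise ValueError("need at least 8 electrodes for an invertible model")
        if self.segment_len_s <= 0:
            raise ValueError("segment_len_s must be positive")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in (-1, 1)")

    @classmethod
    def for_experiment(cls, experiment: int, **overrides) -> "SimConfig":
        """Preset trial counts and epoch windows of the two study protocols."""
        if experiment == 1:
            base = dict(n_trials_so=1024, n_trials_vo=288, epoch_window=(-0.2, 1.6))
        elif experiment == 2:
            base = dict(n_trials_so=512, n_trials_vo=512, epoch_window=(-0.2, 1.0))
        else:
            raise ValueError(f"unknown experiment {experiment!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class EpochSet:
    """Epoched multichannel data: trials × electrodes × samples plus labels."""

    data: np.ndarray            # (n_trials, n_electrodes, n_samples)
    times: np.ndarray           # seconds relative to stimulus onset
    sampling_rate: float
    electrode_labels: list
    trial_table: pd.DataFrame   # one row per trial

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be trials × electrodes × samples")
        if len(self.trial_table) != self.data.shape[0]:
            raise ValueError("trial_table length must equal the number of trials")
        if len(self.electrode_labels) != self.data.shape[1]:
            raise ValueError("one label per electrode required")
        if len(set(self.electrode_labels)) != len(self.electrode_labels):
            raise ValueError("electrode labels must be unique")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("times length must equal the number of samples")
        dt = np.diff(self.times)
        if self.times.size > 1 and not (np.all(dt > 0) and np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6)):
            raise ValueError("times must increase uniformly at sampling_rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def orientation_bins0(self) -> np.ndarray:
        """0-based orientation bin per trial."""
        return self.trial_table["orientation_bin"].to_numpy() - 1

    def save(self, directory) -> None:
        """Persist as metadata JSON + trial CSV + flat little-endian float64 binary."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "sampling_rate": self.sampling_rate,
            "times": self.times.tolist(),
            "electrode_labels": list(self.electrode_labels),
            "shape": list(self.data.shape),
            "dtype": "<f8",
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=1))
        self.trial_table.to_csv(directory / "trials.csv", index=False)
        self.data.astype("<f8").tofile(directory / "data.bin")

    @classmethod
    def load(cls, directory) -> "EpochSet":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        data = np.fromfile(directory / "data.bin", dtype="<f8").reshape(meta["shape"])
        table = pd.read_csv(directory / "trials.csv")
        return cls(
            data=data,
            times=np.asarray(meta["times"], dtype=float),
            sampling_rate=float(meta["sampling_rate"]),
            electrode_labels=list(meta["electrode_labels"]),
            trial_table=table,
        )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def subject_rng(master_seed: int, subject_id: int) -> np.random.Generator:
    """Independent per-subject RNG substream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(subject_id,)))


def generate_stimuli(n_trials: int, condition: str, experiment: int, seed=0,
                     balanced: bool = False) -> list:
    """Draw trial displays with uniformly sampled mean orientations.

    SO displays repeat the mean orientation 20 times; VO displays contain
    five repetitions of each of the four experiment-specific offsets around
    the mean, never the mean itself.  With ``balanced``, the mean
    orientations cycle through the 8-orientation set in shuffled order so
    every orientation bin receives an (almost) equal trial count — handy
    for decoding analyses that equalize per-bin counts anyway.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if condition not in ("SO", "VO"):
        raise ValueError(f"unknown condition {condition!r}")
    if experiment not in (1, 2):
        raise ValueError(f"unknown experiment {experiment!r}")
    rng = _rng(seed)
    if balanced:
        reps = int(np.ceil(n_trials / 8))
        means = rng.permutation(np.tile(STIMULUS_ORIENTATIONS_DEG, reps))[:n_trials]
    else:
        means = rng.choice(STIMULUS_ORIENTATIONS_DEG, size=n_trials)
    out = []
    for mu in means:
        if condition == "SO":
            items = tuple(float(mu) for _ in range(_N_ITEMS))
        else:
            items = tuple(
                float(wrap_orientation(mu + off))
                for off in VO_OFFSETS_DEG[experiment]
                for _ in range(_N_REPS_PER_OFFSET)
            )
        out.append(StimulusSet(float(mu), condition, experiment, items))
    return out


def _channel_input(stim: StimulusSet, lam: float, basis: BasisSet) -> np.ndarray:
    """Channel-response vector driving the electrodes for one trial."""
    if stim.condition == "SO":
        return basis_responses(stim.mean_orientation, basis)
    mean_part = basis_responses(stim.mean_orientation, basis)
    offsets = VO_OFFSETS_DEG[stim.experiment]
    item_part = np.mean(
        [basis_responses(wrap_orientation(stim.mean_orientation + o), basis) for o in offsets],
        axis=0,
    )
    return lam * mean_part + (1.0 - lam) * item_part


def epoch_times(cfg: SimConfig) -> np.ndarray:
    """Sample times (s, relative to onset) implied by the epoch window and rate."""
    t0, t1 = cfg.epoch_window
    n_samp = int(round((t1 - t0) * cfg.sampling_rate))
    return t0 + np.arange(n_samp) / cfg.sampling_rate


def n_segments(cfg: SimConfig) -> int:
    """Number of post-onset weight segments in the dynamic/mixed regimes."""
    post = epoch_times(cfg)[epoch_times(cfg) >= 0.0]
    return len(np.unique(np.floor(post / cfg.segment_len_s).astype(int)))


def draw_weights(cfg: SimConfig, rng):
    """Draw the true electrode × channel weights for one subject.

    Returns an (m, 8) matrix in the stable regime, an (n_segments, m, 8)
    stack in the dynamic regime, and a (stable, stack) tuple in the mixed
    regime.  Entries are i.i.d. standard normal.
    """
    rng = _rng(rng)
    m = cfg.n_electrodes
    if cfg.coding_regime == "stable":
        return rng.standard_normal((m, 8))
    segs = rng.standard_normal((n_segments(cfg), m, 8))
    if cfg.coding_regime == "mixed":
        return rng.standard_normal((m, 8)), segs
    return segs


def simulate_epochs(stimuli: list, cfg: SimConfig, rng=None, subject_id: int = 0,
                    weights=None, return_weights: bool = False):
    """Forward-model epochs: electrode signal = W(t) · c(trial) + noise.

    Tuned signal starts at stimulus onset (t = 0); earlier samples contain
    noise only.  In the dynamic regime, W is redrawn independently for each
    post-onset segment of ``segment_len_s`` seconds.  Pass ``weights`` (from
    :func:`draw_weights`) to share the generating weights across condition
    calls for the same subject.
    """
    if not stimuli:
        raise ValueError("stimuli must be non-empty")
    rng = _rng(cfg.seed if rng is None else rng)
    basis = BasisSet()
    m = cfg.n_electrodes
    fs = cfg.sampling_rate
    times = epoch_times(cfg)
    n_samp = len(times)
    post = times >= 0.0

    C = np.stack([_channel_input(s, cfg.ensemble_weight, basis) for s in stimuli])  # (n, 8)
    n = len(stimuli)

    if weights is None:
        weights = draw_weights(cfg, rng)
    if cfg.coding_regime in ("dynamic", "mixed"):
        seg_of_sample = np.floor(times[post] / cfg.segment_len_s).astype(int)
        seg_ids, seg_inverse = np.unique(seg_of_sample, return_inverse=True)
        W_segs = weights[1] if cfg.coding_regime == "mixed" else weights
        if W_segs.shape[0] != len(seg_ids):
            raise ValueError("weight stack does not match the number of segments")

    signal = np.zeros((n, m, n_samp))
    if cfg.signal_scale != 0.0 and post.any():
        if cfg.coding_regime == "stable":
            sig = C @ weights.T  # (n, m)
            signal[:, :, post] = sig[:, :, None]
        else:
            # (n, m) per segment, broadcast to that segment's samples
            per_seg = np.einsum("nk,smk->snm", C, W_segs)
            if cfg.coding_regime == "mixed":
                stable_part = C @ weights[0].T
                per_seg = (per_seg + stable_part[None]) / np.sqrt(2.0)
            signal[:, :, post] = np.moveaxis(per_seg[seg_inverse], 0, 2)
        signal *= cfg.signal_scale

    noise = rng.standard_normal((n, m, n_samp))
    if cfg.ar1_rho != 0.0:
        rho = cfg.ar1_rho
        for t in range(1, n_samp):
            noise[:, :, t] = rho * noise[:, :, t - 1] + np.sqrt(1 - rho**2) * noise[:, :, t]
    data = signal + cfg.noise_sd * noise

    labels = montage_labels(stimuli[0].experiment) if m == 28 else [f"E{i+1:02d}" for i in range(m)]
    table = pd.DataFrame(
        {
            "subject_id": subject_id,
            "condition": [s.condition for s in stimuli],
            "experiment": [s.experiment for s in stimuli],
            "mean_orientation": [s.mean_orientation for s in stimuli],
            "orientation_bin": [s.orientation_bin for s in stimuli],
            "stimulus_index": np.arange(n),
        }
    )
    epochs = EpochSet(data=data, times=times, sampling_rate=fs,
                      electrode_labels=labels, trial_table=table)
    if return_weights:
        return epochs, weights
    return epochs


def _orientation_noise(rng, kappa, size=()):
    """Zero-mean circular noise in orientation degrees (von Mises on 2θ)."""
    if kappa is None or np.isinf(kappa):
        return np.zeros(size if size is not None else ())
    return np.rad2deg(rng.vonmises(0.0, kappa, size)) / 2.0


def simulate_oldnew_behavior(stimuli: list, w: float, kappa: float, seed=0,
                             criterion_deg: float = 20.0) -> pd.DataFrame:
    """Old/new responses under a noisy blended-memory observer.

    The remembered orientation is (1-w)·item + w·mean plus circular noise;
    the observer answers "old" when the probe lies within ``criterion_deg``
    of that memory.  Probe offsets follow the task design: VO probes sit at
    {0, ±10, …, ±80, −90}° from the mean with equal probability; SO probes
    are "old" on half the trials and offset by ±4…±32° otherwise.
    """
    if not stimuli:
        raise ValueError("stimuli must be non-empty")
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    rng = _rng(seed)
    rows = []
    for stim in stimuli:
        if stim.condition == "VO":
            probe_off = float(rng.choice(PROBE_OFFSETS_VO_DEG))
            item_off = float(rng.choice(VO_OFFSETS_DEG[stim.experiment]))
        else:
            if rng.random() < 0.5:
                probe_off = 0.0
            else:
                probe_off = float(rng.choice(PROBE_OFFSETS_SO_NEW_DEG))
            item_off = 0.0
        memory_off = (1.0 - w) * item_off + float(_orientation_noise(rng, kappa, None))
        old = abs(float(wrap_orientation(probe_off - memory_off))) < criterion_deg
        rows.append((stim.condition, probe_off, "old" if old else "new"))
    return pd.DataFrame(rows, columns=["condition", "probe_offset_deg", "response"])


def simulate_estimation_behavior(stimuli: list, w: float, kappa: float, seed=0) -> pd.DataFrame:
    """Continuous-report errors with a tunable pull toward the ensemble mean.

    The response to a cued target is target + w·(mean − target) + noise, so
    the expected signed error equals −w·(target offset).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    if not stimuli:
        raise ValueError("stimuli must be non-empty")
    for stim in stimuli:
        if stim.condition != "VO":
            raise ValueError("estimation behavior is defined for VO displays only")
    rng = _rng(seed)
    rows = []
    for stim in stimuli:
        target_off = float(rng.choice(VO_OFFSETS_DEG[stim.experiment]))
        err = -w * target_off + float(_orientation_noise(rng, kappa, None))
        rows.append((stim.condition, target_off, float(wrap_orientation(err)), "unassigned"))
    return pd.DataFrame(
        rows, columns=["condition", "target_offset_deg", "response_error_deg", "split_label"]
    )


def simulate_subject(cfg: SimConfig, experiment: int, subject_id: int,
                     master_seed: int | None = None, balanced: bool = True):
    """Generate one synthetic subject's SO and VO epoch sets.

    Uses an independent RNG substream per subject so that multi-subject
    groups are reproducible and mutually independent.  ``balanced`` keeps
    per-orientation trial counts equal (recommended at small trial counts
    so the equalized cross-validation partition discards nothing).
    """
    seed = cfg.seed if master_seed is None else master_seed
    rng = subject_rng(seed, subject_id)
    stim_seed = int(rng.integers(2**31 - 1))
    so_stim = generate_stimuli(cfg.n_trials_so, "SO", experiment, stim_seed,
                               balanced=balanced)
    vo_stim = generate_stimuli(cfg.n_trials_vo, "VO", experiment, stim_seed + 1,
                               balanced=balanced)
    weights = draw_weights(cfg, rng)  # shared so the SO decoder generalizes to VO
    so = simulate_epochs(so_stim, cfg, rng=rng, subject_id=subject_id, weights=weights)
    vo = simulate_epochs(vo_stim, cfg, rng=rng, subject_id=subject_id, weights=weights)
    return so, vo
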