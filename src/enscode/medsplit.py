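"""Trial-wise median-split decoding.

Varied-orientation (VO) trials are divided at the circular median of the
toward-mean response errors into "mean" response trials and "target"
response trials; the SO-trained decoder is then generalized to each split
separately.  If the reconstruction is stronger from the mean-like trials,
the decoded content reflects the ensemble mean rather than the cued item.

Within splits, inversion operates on single trials (splits generally leave
unequal per-orientation counts); reconstructed profiles are aligned per
trial and averaged before the slope regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import median_split
from .encoding import TGMatrix
from .tempgen import classify_cells, cross_condition_tg, stable_dynamic_index

__all__ = ["SplitDecodingResult", "split_decode", "split_group_indices"]

SPLIT_LABELS = ("mean", "target")


@dataclass
class SplitDecodingResult:
    """Per-split TG matrices (and, at group level, stable/dynamic indices)."""

    tg: dict                 # split label -> TGMatrix
    counts: dict             # split label -> number of trials
    indices: dict = field(default_factory=dict)  # split label -> SDIndexSeries


def split_decode(so_epochs, vo_epochs, est_table, n_folds: int = 3,
                 n_iterations: int = 100, seed: int = 0,
                 tg: bool = True) -> SplitDecodingResult:
    """Decode the "mean" and "target" VO trial subsets for one subject.

    ``est_table`` must align one-to-one with the VO trials; rows without
    split labels are labelled here via :func:`enscode.behavior.median_split`.
    """
    if len(est_table) != vo_epochs.n_trials:
        raise ValueError(
            f"estimation table ({len(est_table)} rows) does not match "
            f"VO epochs ({vo_epochs.n_trials} trials)"
        )
    if not set(est_table["split_label"]) <= set(SPLIT_LABELS):
        est_table = median_split(est_table)
    tgs, counts = {}, {}
    for label in SPLIT_LABELS:
        idx = np.flatnonzero(est_table["split_label"].to_numpy() == label)
        if len(idx) == 0:
            raise ValueError(f"empty {label!r} split")
        counts[label] = int(len(idx))
        result = cross_condition_tg(so_epochs, vo_epochs, n_folds=n_folds,
                                    n_iterations=n_iterations, seed=seed,
                                    average_test=False, trial_indices=idx)
        if not tg:
            diag = result.diagonal()
            result = TGMatrix(times=result.times, matrix=np.diag(diag),
                              meta=result.meta)
        tgs[label] = result
    return SplitDecodingResult(tg=tgs, counts=counts)


def split_group_indices(results, alpha: float = 0.05, method: str = "parametric",
                        n_permutations: int = 2000, seed: int = 0,
                        window_ms: float = 310.0, guard_ms: float = 50.0) -> dict:
    """Group stable/dynamic index time courses per split label.

    ``results`` is a list of per-subject :class:`SplitDecodingResult`; the
    returned dict maps each split label to (maps, classes, SDIndexSeries).
    """
    out = {}
    for label in SPLIT_LABELS:
        tgs = [r.tg[label] for r in results]
        maps, classes = classify_cells(tgs, alpha=alpha, method=method,
                                       n_permutations=n_permutations, seed=seed)
        series = stable_dynamic_index(maps, window_ms=window_ms, guard_ms=guard_ms)
        out[label] = (maps, classes, series)
    return out
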