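"""Epoching and single-trial normalization of band-amplitude series.

Trials are cut around stimulation onsets on the 100 Hz amplitude timebase,
z-scored per trial using the pre-trial baseline mean and the full-epoch
standard deviation ("single-trial full-epoch length correction" -- robust
when single trials are noisy), averaged by condition, and summarized over
target windows.  All time windows are half-open [start, end) in seconds;
sample index = round((t - t0) * rate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import AmplitudeSeries, BandSpec

logger = logging.getLogger(__name__)

#: canonical order of the 2 x 2 conditions: (frequency_level, amplitude_level)
CONDITION_ORDER = (("low", "low"), ("low", "high"), ("high", "low"), ("high", "high"))

#: default epoch/baseline windows by modality (s relative to onset)
EPOCH_WINDOWS = {
    "iVNS": (-4.0, 11.0),
    "taVNS-matched": (-4.0, 11.0),
    "taVNS-short": (-2.0, 2.5),
}
BASELINE_WINDOWS = {
    "iVNS": (-4.0, -0.5),
    "taVNS-matched": (-4.0, -0.5),
    "taVNS-short": (-2.0, -0.5),
}
TARGET_WINDOWS = {
    "iVNS": (2.0, 9.0),
    "taVNS-matched": (2.0, 9.0),
    "taVNS-short": (0.0, 2.5),
}


@dataclass
class TrialTensor:
    """z-scored band amplitude, electrodes x time x trials."""

    z: np.ndarray
    time_axis: np.ndarray  # s relative to stimulation onset
    condition: pd.DataFrame  # per-trial frequency_level / amplitude_level
    band: BandSpec
    modality: str
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 3:
            raise ValueError("z must be electrodes x time x trials")
        if len(self.time_axis) != self.z.shape[1]:
            raise ValueError("time_axis length mismatch")
        if len(self.condition) != self.z.shape[2]:
            raise ValueError("condition table must have one row per trial")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.z.shape[0])]

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_axis)))

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask of samples in half-open [start, end)."""
        lo, hi = window
        return (self.time_axis >= lo - 1e-9) & (self.time_axis < hi - 1e-9)

    def condition_trials(self, frequency_level: str, amplitude_level: str) -> np.ndarray:
        return np.flatnonzero(
            (self.condition.frequency_level == frequency_level).to_numpy()
            & (self.condition.amplitude_level == amplitude_level).to_numpy()
        )


@dataclass
class ConditionMatrix:
    """Electrode x (time x condition) concatenation of condition means."""

    data: np.ndarray  # electrodes x (n_times * n_conditions)
    layout: list[tuple[str, str]]  # condition blocks in concatenation order
    n_times: int
    time_axis: np.ndarray
    channel_ids: list[str]

    def block(self, frequency_level: str, amplitude_level: str) -> np.ndarray:
        i = self.layout.index((frequency_level, amplitude_level))
        return self.data[:, i * self.n_times : (i + 1) * self.n_times]


@dataclass
class WindowStat:
    """Mean z inside a target window, per electrode/cluster x trial."""

    values: np.ndarray  # units x trials
    window: tuple[float, float]
    condition: pd.DataFrame
    unit_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for u, uid in enumerate(self.unit_ids):
            for t in range(self.values.shape[1]):
                rows.append(
                    {
                        "unit": uid,
                        "trial": t,
                        "frequency_level": self.condition.frequency_level.iloc[t],
                        "amplitude_level": self.condition.amplitude_level.iloc[t],
                        "mean_z": self.values[u, t],
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def epoch(
    amp: AmplitudeSeries | np.ndarray,
    onsets: np.ndarray,
    window: tuple[float, float],
    sampling_rate: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut trials around onsets (sample indices on the amplitude timebase).

    Returns (electrodes x time x trials array, kept onset indices).  Onsets
    whose half-open window [start, end) would run past an edge are dropped
    with a log entry.
    """
    if isinstance(amp, AmplitudeSeries):
        values, rate = amp.values, amp.sampling_rate
    else:
        values = np.asarray(amp, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for bare arrays")
        rate = sampling_rate
    lo, hi = window
    n_t = int(round((hi - lo) * rate))
    off = int(round(lo * rate))
    n_samples = values.shape[-1]
    trials, kept = [], []
    for i, onset in enumerate(np.asarray(onsets, dtype=int)):
        a = onset + off
        b = a + n_t
        if a < 0 or b > n_samples:
            continue
        trials.append(values[..., a:b])
        kept.append(i)
    n_dropped = len(onsets) - len(kept)
    if n_dropped:
        logger.info("dropped %d trial(s) too near a recording edge", n_dropped)
    if not trials:
        return np.empty(values.shape[:-1] + (n_t, 0)), np.array(kept, dtype=int)
    return np.stack(trials, axis=-1), np.array(kept, dtype=int)


def normalize_single_trial(
    trials: np.ndarray,
    time_axis: np.ndarray,
    baseline_window: tuple[float, float] = (-4.0, -0.5),
) -> np.ndarray:
    """Single-trial full-epoch z-normalization.

    z(t) = (x(t) - mean(x over baseline)) / SD(x over the full epoch), per
    electrode x trial, NaN-aware (NaN samples are excluded from the mean/SD
    and preserved in the output).  The SD uses the sample (n-1) convention.
    Constant trials (zero SD) are set to NaN with a warning.
    """
    trials = np.asarray(trials, dtype=float)
    time_axis = np.asarray(time_axis)
    lo, hi = baseline_window
    bmask = (time_axis >= lo - 1e-9) & (time_axis < hi - 1e-9)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = np.nanmean(trials[..., bmask, :], axis=-2, keepdims=True)
        sd = np.nanstd(trials, axis=-2, keepdims=True, ddof=1)
    degenerate = ~(sd > 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant electrode x trial epoch(s) set to NaN"
        )
        sd = np.where(degenerate, np.nan, sd)
    return (trials - base) / sd


def condition_average_concat(tensor: TrialTensor) -> ConditionMatrix:
    """NaN-aware per-condition trial means, concatenated along time.

    Condition blocks follow the fixed canonical order (low-frequency/low,
    low/high, high/low, high/high); conditions with zero trials are omitted
    and the remaining layout is recorded.
    """
    blocks, layout = [], []
    for f_lvl, a_lvl in CONDITION_ORDER:
        idx = tensor.condition_trials(f_lvl, a_lvl)
        if idx.size == 0:
            logger.info("condition (%s, %s) has no trials; omitted", f_lvl, a_lvl)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            blocks.append(np.nanmean(tensor.z[:, :, idx], axis=2))
        layout.append((f_lvl, a_lvl))
    if not blocks:
        raise ValueError("no condition has any trials")
    return ConditionMatrix(
        data=np.concatenate(blocks, axis=1),
        layout=layout,
        n_times=tensor.z.shape[1],
        time_axis=tensor.time_axis,
        channel_ids=list(tensor.channel_ids),
    )


def window_average(
    tensor_or_values: TrialTensor | np.ndarray,
    window: tuple[float, float],
    time_axis: np.ndarray | None = None,
    condition: pd.DataFrame | None = None,
    unit_ids: list[str] | None = None,
) -> WindowStat:
    """NaN-aware mean z over the window, per unit (electrode/cluster) x trial."""
    if isinstance(tensor_or_values, TrialTensor):
        values = tensor_or_values.z
        time_axis = tensor_or_values.time_axis
        condition = tensor_or_values.condition
        unit_ids = unit_ids or list(tensor_or_values.channel_ids)
    else:
        values = np.asarray(tensor_or_values, dtype=float)
        if time_axis is None or condition is None:
            raise ValueError("time_axis and condition required for bare arrays")
        unit_ids = unit_ids or [f"u{i}" for i in range(values.shape[0])]
    lo, hi = window
    mask = (np.asarray(time_axis) >= lo - 1e-9) & (np.asarray(time_axis) < hi - 1e-9)
    if not mask.any():
        raise ValueError("window contains no samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmean(values[:, mask, :], axis=1)
    return WindowStat(values=vals, window=window, condition=condition.copy(),
                      unit_ids=unit_ids)


def sliding_window_proportions(
    tensor: TrialTensor,
    width: float = 2.0,
    step: float = 1.0,
    alpha: float = 0.01,
    baseline_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-window fraction of electrodes with significant amplitude change.

    Within each condition and each sliding window (anchored at epoch start),
    the per-trial window means are compared to the same trials' baseline
    means with a two-sided independent rank-sum test per electrode; the
    proportions of electrodes with p < alpha are reported split by effect
    direction.  No multiple-comparison correction is applied.
    """
    t = tensor.time_axis
    if baseline_window is None:
        baseline_window = BASELINE_WINDOWS.get(tensor.modality, (t[0], -0.5))
    epoch_len = t[-1] - t[0] + 1.0 / tensor.rate
    if epoch_len + 1e-9 < width:
        raise ValueError("epoch shorter than the sliding-window width")
    n_windows = int(np.floor((epoch_len - width) / step + 1e-9)) + 1
    starts = t[0] + step * np.arange(n_windows)

    bmask = tensor.window_mask(baseline_window)
    base = np.nanmean(tensor.z[:, bmask, :], axis=1)  # electrodes x trials
    rows = []
    n_e = tensor.z.shape[0]
    for f_lvl, a_lvl in CONDITION_ORDER:
        idx = tensor.condition_trials(f_lvl, a_lvl)
        if idx.size == 0:
            continue
        if idx.size < 5:
            raise ValueError(
                f"condition ({f_lvl}, {a_lvl}) has {idx.size} trials; "
                "need >= 5 for the rank-sum test"
            )
        for s in starts:
            wmask = tensor.window_mask((s, s + width))
            wm = np.nanmean(tensor.z[:, wmask, :][:, :, idx], axis=1)
            bm = base[:, idx]
            stat, p = stats.ranksums(wm, bm, axis=1)
            sig = p < alpha
            rows.append(
                {
                    "window_start": float(s),
                    "window_end": float(s + width),
                    "frequency_level": f_lvl,
                    "amplitude_level": a_lvl,
                    "prop_increase": float(np.sum(sig & (stat > 0)) / n_e),
                    "prop_decrease": float(np.sum(sig & (stat < 0)) / n_e),
                }
            )
    return pd.DataFrame(rows)
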