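"""Spike-data containers, binning, PSTHs, and preprocessing rules.

Spike tables are plain delimited text with columns
``neuron_id, area, condition_id, trial_id, time_ms`` (times in ms relative
to stimulus onset).  Analysis is restricted to a fixed window [0, T]
(default 500 ms after onset); a spike at exactly T is excluded, bins are
half-open [t, t + dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

COLUMNS = ["neuron_id", "area", "condition_id", "trial_id", "time_ms"]


@dataclass
class BinnedTrain:
    """Spike counts on a regular half-open bin grid."""

    counts: np.ndarray
    bin_width: float

    @property
    def n_bins(self) -> int:
        return self.counts.shape[-1]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def bin_spikes(times, window, bin_width) -> BinnedTrain:
    """Bin spike times into half-open bins [k*dt, (k+1)*dt) over ``window``.

    A spike at exactly the right edge of the window is dropped.  Times
    outside the window are rejected.
    """
    lo, hi = float(window[0]), float(window[1])
    n_bins = int(round((hi - lo) / bin_width))
    if not np.isclose(n_bins * bin_width, hi - lo):
        raise ValueError("bin_width must divide the window length")
    t = np.asarray(times, dtype=float)
    if t.size and (t.min() < lo or t.max() > hi):
        raise ValueError("spike times outside the analysis window")
    idx = np.floor((t - lo) / bin_width).astype(int)
    idx = idx[idx < n_bins]  # spike at exactly T is excluded
    counts = np.bincount(idx, minlength=n_bins)
    return BinnedTrain(counts=counts, bin_width=float(bin_width))


@dataclass
class SpikeDataset:
    """Spike times indexed by (neuron, area, condition, trial).

    ``trial_id`` refers to the same physical trial across areas
    (simultaneous recording), so every (condition, trial) pair present in
    one area must be present in all areas.
    """

    spikes: pd.DataFrame
    window: tuple = (0.0, 500.0)
    neuron_area: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.spikes
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"spike table missing columns: {sorted(missing)}")
        lo, hi = self.window
        if len(df) and ((df["time_ms"] < lo).any() or (df["time_ms"] > hi).any()):
            raise ValueError("spike times outside the analysis window")
        if not self.neuron_area:
            self.neuron_area = dict(
                df.drop_duplicates("neuron_id")[["neuron_id", "area"]].itertuples(
                    index=False, name=None
                )
            )
        amb = df.groupby("neuron_id")["area"].nunique()
        if len(amb) and (amb > 1).any():
            raise ValueError("a neuron may belong to exactly one area")

    # --- index properties -------------------------------------------------
    @property
    def areas(self) -> list:
        return sorted(set(self.neuron_area.values()))

    @property
    def conditions(self) -> list:
        return sorted(self.spikes["condition_id"].unique())

    def trials(self, condition) -> list:
        sub = self.spikes[self.spikes["condition_id"] == condition]
        return sorted(sub["trial_id"].unique())

    def neurons(self, area=None) -> list:
        if area is None:
            return sorted(self.neuron_area)
        return sorted(n for n, a in self.neuron_area.items() if a == area)

    @property
    def T(self) -> float:
        return float(self.window[1])

    # --- IO ----------------------------------------------------------------
    @classmethod
    def from_table(cls, path, window=(0.0, 500.0), sep="\t") -> "SpikeDataset":
        df = pd.read_csv(path, sep=sep)
        return cls(spikes=df[COLUMNS], window=window)

    def to_table(self, path, sep="\t") -> None:
        self.spikes[COLUMNS].to_csv(path, sep=sep, index=False)

    # --- accessors ---------------------------------------------------------
    def spike_times(self, neuron_ids, condition, trial) -> np.ndarray:
        ids = np.atleast_1d(neuron_ids)
        df = self.spikes
        m = (
            df["neuron_id"].isin(ids)
            & (df["condition_id"] == condition)
            & (df["trial_id"] == trial)
        )
        return np.sort(df.loc[m, "time_ms"].to_numpy())

    def total_counts(self) -> pd.Series:
        """In-window spike count per neuron, merged across conditions/trials."""
        counts = self.spikes.groupby("neuron_id").size()
        return counts.reindex(sorted(self.neuron_area), fill_value=0)


def population_train(dataset, member_ids, condition, trial, bin_width=2.0) -> BinnedTrain:
    """Merged (population) spike train of ``member_ids`` on one trial.

    Merging spike times then binning equals the elementwise sum of the
    members' binned trains; the population count is conserved.
    """
    ids = list(member_ids)
    if not ids:
        raise ValueError("empty member set: degenerate population")
    areas = {dataset.neuron_area[n] for n in ids}
    if len(areas) != 1:
        raise ValueError("population members must come from a single area")
    times = dataset.spike_times(ids, condition, trial)
    return bin_spikes(times, dataset.window, bin_width)


def psth(dataset, member_ids, condition, bin_width=2.0) -> np.ndarray:
    """Trial-averaged population rate in spikes/s per neuron, per bin."""
    trials = dataset.trials(condition)
    if not trials:
        raise ValueError("no trials for this condition")
    ids = list(member_ids)
    acc = np.zeros(int(round((dataset.window[1] - dataset.window[0]) / bin_width)))
    for r in trials:
        acc += population_train(dataset, ids, condition, r, bin_width).counts
    dt_s = bin_width / 1000.0
    return acc / (len(trials) * len(ids) * dt_s)


def select_active_neurons(dataset, fraction=0.5) -> list:
    """The ceil(fraction * N) most active neurons per area.

    Activity is the total in-window spike count merged across conditions and
    trials; ties go to the smaller neuron id.  Selection is per area so that
    every area keeps its own most active half.
    """
    counts = dataset.total_counts()
    keep: list = []
    for area in dataset.areas:
        ids = dataset.neurons(area)
        sub = counts.loc[ids]
        order = sorted(ids, key=lambda n: (-sub[n], n))
        k = int(np.ceil(fraction * len(ids)))
        keep.extend(order[:k])
    return sorted(keep)


def gaussian_smooth(values, sd_bins) -> np.ndarray:
    """Truncated-Gaussian smoothing (+-4 SD) with edge renormalization."""
    if sd_bins <= 0:
        return np.asarray(values, dtype=float)
    half = int(np.ceil(4 * sd_bins))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sd_bins) ** 2)
    k /= k.sum()
    v = np.asarray(values, dtype=float)
    num = convolve1d(v, k, mode="constant", cval=0.0)
    den = convolve1d(np.ones_like(v), k, mode="constant", cval=0.0)
    return num / den


def total_variation(values) -> float:
    """Sum of absolute successive differences of a discrete curve."""
    v = np.asarray(values, dtype=float)
    return float(np.abs(np.diff(v)).sum())


def rank_conditions_by_tv(dataset, areas=None, kernel_sd=10.0, member_ids=None,
                          bin_width=2.0) -> pd.DataFrame:
    """Rank conditions by summed total variation of smoothed group PSTHs.

    For each (area, condition), the group PSTH is smoothed with a Gaussian
    kernel (SD ``kernel_sd`` ms) and its total variation computed; the
    condition score is the sum over areas.  Conditions with strongly
    fluctuating (two-peak) responses score highest.
    """
    areas = list(areas) if areas is not None else dataset.areas
    sd_bins = kernel_sd / bin_width
    rows = []
    for c in dataset.conditions:
        score = 0.0
        for a in areas:
            ids = (
                [n for n in member_ids if dataset.neuron_area[n] == a]
                if member_ids is not None
                else dataset.neurons(a)
            )
            curve = gaussian_smooth(psth(dataset, ids, c, bin_width), sd_bins)
            score += total_variation(curve)
        rows.append((c, score))
    out = pd.DataFrame(rows, columns=["condition_id", "tv_score"])
    return out.sort_values("tv_score", ascending=False, ignore_index=True)
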