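"""Burst segmentation at a fixed ISI threshold and per-burst properties.

A burst is a maximal run of consecutive spikes whose internal ISIs are all
strictly below the threshold θ, with at least ``min_spikes`` (default 4)
spikes.  Four properties are measured: burst duration (first to last spike),
spikes per burst, intraburst firing rate ((n−1)/duration, the rate of
intervals), and the interburst interval (last spike of one burst to first
spike of the next, ignoring any non-burst spikes between them).

For group comparisons each neuron contributes at most ``n`` (default 100)
randomly selected bursts, so high-burst cells cannot dominate pooled
distributions; neurons with fewer bursts contribute all of them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeTrain, compute_isis

__all__ = [
    "Burst",
    "BurstSet",
    "segment_bursts",
    "collect_burst_properties",
    "subsample_bursts",
    "neuron_rng",
]

BURST_PROPERTIES = ("duration", "spikes_per_burst", "intraburst_rate", "interburst_interval")


@dataclass(frozen=True)
class Burst:
    first_spike_t: float
    last_spike_t: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.n_spikes < 2:
            raise ValueError("a burst needs at least two spikes")
        if self.last_spike_t <= self.first_spike_t:
            raise ValueError("burst duration must be positive")

    @property
    def duration_s(self) -> float:
        return self.last_spike_t - self.first_spike_t

    @property
    def intraburst_rate_hz(self) -> float:
        return (self.n_spikes - 1) / self.duration_s


@dataclass(frozen=True)
class BurstSet:
    """Time-ordered bursts of one neuron at one threshold."""

    neuron_id: str
    threshold_s: float
    bursts: tuple[Burst, ...]

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def interburst_intervals_s(self) -> np.ndarray:
        if self.n_bursts < 2:
            return np.empty(0)
        firsts = np.array([b.first_spike_t for b in self.bursts[1:]])
        lasts = np.array([b.last_spike_t for b in self.bursts[:-1]])
        return firsts - lasts


def segment_bursts(
    train: SpikeTrain, threshold_s: float, min_spikes: int = 4
) -> BurstSet:
    """Split a train into bursts: maximal runs of ISIs < θ with ≥ min_spikes spikes."""
    if threshold_s <= 0:
        raise ValueError("threshold_s must be > 0")
    if min_spikes < 2:
        raise ValueError("min_spikes must be ≥ 2")
    times = train.spike_times
    bursts: list[Burst] = []
    if times.size >= 2:
        isis = compute_isis(train)
        # boundaries where a run of short ISIs starts/ends
        joined = isis < threshold_s
        i = 0
        n = times.size
        while i < n:
            j = i
            while j < n - 1 and joined[j]:
                j += 1
            run_len = j - i + 1
            if run_len >= min_spikes:
                bursts.append(Burst(float(times[i]), float(times[j]), run_len))
            i = j + 1
    return BurstSet(train.neuron_id, float(threshold_s), tuple(bursts))


def collect_burst_properties(bs: BurstSet) -> dict[str, np.ndarray]:
    """Aligned property vectors: durations, spike counts, intraburst rates,
    plus the (one shorter) interburst-interval vector."""
    return {
        "duration": np.array([b.duration_s for b in bs.bursts]),
        "spikes_per_burst": np.array([b.n_spikes for b in bs.bursts], dtype=float),
        "intraburst_rate": np.array([b.intraburst_rate_hz for b in bs.bursts]),
        "interburst_interval": bs.interburst_intervals_s,
    }


def neuron_rng(seed: int, neuron_id: str) -> np.random.Generator:
    """Per-neuron RNG stream derived from (global seed, neuron id).

    Cohort composition therefore cannot perturb any one neuron's draws.
    """
    tag = zlib.crc32(neuron_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def subsample_bursts(bs: BurstSet, n: int = 100, seed: int = 0) -> BurstSet:
    """Randomly keep at most *n* bursts (without replacement, seeded).

    Sets with ≤ n bursts are returned unchanged, so sparse cells contribute
    everything they have.  Selected bursts keep their time order, so
    interburst intervals of a subsampled set remain well defined (between
    the retained bursts).
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if bs.n_bursts <= n:
        return bs
    rng = neuron_rng(seed, bs.neuron_id)
    idx = np.sort(rng.choice(bs.n_bursts, size=n, replace=False))
    return BurstSet(bs.neuron_id, bs.threshold_s, tuple(bs.bursts[i] for i in idx))


def burst_table(burst_sets: list[BurstSet]) -> pd.DataFrame:
    """Long-format burst table across neurons."""
    rows = []
    for bs in burst_sets:
        for k, b in enumerate(bs.bursts):
            rows.append(
                {
                    "neuron_id": bs.neuron_id,
                    "burst_index": k,
                    "first_spike_s": b.first_spike_t,
                    "last_spike_s": b.last_spike_t,
                    "n_spikes": b.n_spikes,
                    "duration_s": b.duration_s,
                    "intraburst_rate_hz": b.intraburst_rate_hz,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "neuron_id",
            "burst_index",
            "first_spike_s",
            "last_spike_s",
            "n_spikes",
            "duration_s",
            "intraburst_rate_hz",
        ],
    )


def interval_table(burst_sets: list[BurstSet]) -> pd.DataFrame:
    rows = []
    for bs in burst_sets:
        for k, iv in enumerate(bs.interburst_intervals_s):
            rows.append(
                {
                    "neuron_id": bs.neuron_id,
                    "interval_index": k,
                    "interburst_interval_s": iv,
                }
            )
    return pd.DataFrame(
        rows, columns=["neuron_id", "interval_index", "interburst_interval_s"]
    )
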