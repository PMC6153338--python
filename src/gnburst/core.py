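"""Domain model for extracellular spike-train recordings.

A :class:`SpikeTrain` holds the spike times of one loose-patch recorded
neuron (seconds from recording onset) together with its recording metadata:
treatment group, estrous cycle stage and soma location.  The elementary
quantities every downstream stage builds on — interspike intervals (ISIs),
the log-log ISI return-map pairs, and the mean firing rate — live here.

Times are in seconds throughout; logarithms are base 10.  Duplicate spike
times are rejected at construction because a zero ISI has no logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Treatment",
    "CycleStage",
    "Location",
    "SpikeTrain",
    "ISIPairSet",
    "ValidationError",
    "compute_isis",
    "compute_isi_pairs",
    "mean_firing_rate",
]


class ValidationError(ValueError):
    """Raised when input data violate a domain invariant."""


class Treatment(str, Enum):
    SALINE = "saline"
    KA_LONG = "ka_long"
    KA_REGULAR = "ka_regular"
    KA_MALE_SALINE = "ka_male_saline"
    KA_MALE = "ka_male"


class CycleStage(str, Enum):
    DIESTRUS = "diestrus"
    ESTRUS = "estrus"
    NONE = "none"


class Location(str, Enum):
    MS = "MS"
    POA = "POA"
    AHA = "AHA"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SpikeTrain:
    """One neuron's spike record.

    Parameters
    ----------
    neuron_id
        Unique identifier within a cohort.
    spike_times
        Strictly increasing spike times in seconds, all within
        ``[0, duration)``.
    duration
        Recording length in seconds; must be positive.
    treatment, cycle_stage, location
        Grouping metadata; defaults mark them unspecified.
    """

    neuron_id: str
    spike_times: np.ndarray
    duration: float
    treatment: Treatment = Treatment.SALINE
    cycle_stage: CycleStage = CycleStage.NONE
    location: Location = Location.UNKNOWN

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.ndim != 1:
            raise ValidationError(f"{self.neuron_id}: spike_times must be 1-D")
        if self.duration <= 0:
            raise ValidationError(f"{self.neuron_id}: duration must be > 0")
        if times.size:
            diffs = np.diff(times)
            if np.any(diffs <= 0):
                raise ValidationError(
                    f"{self.neuron_id}: spike times must be strictly increasing "
                    "(duplicates produce a zero ISI, whose log is undefined)"
                )
            if times[0] < 0 or times[-1] > self.duration:
                raise ValidationError(
                    f"{self.neuron_id}: spike times must lie in [0, duration]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class ISIPairSet:
    """Return-map coordinates of a spike train.

    For each interior spike the pair is ``(log10 ISI before, log10 ISI
    after)``; a train of *n* spikes yields ``max(n - 2, 0)`` pairs, in
    spike order.
    """

    log_before: np.ndarray
    log_after: np.ndarray
    n_spikes_source: int = 0

    def __post_init__(self) -> None:
        lb = np.asarray(self.log_before, dtype=float)
        la = np.asarray(self.log_after, dtype=float)
        if lb.shape != la.shape:
            raise ValidationError("log_before and log_after must align")
        object.__setattr__(self, "log_before", lb)
        object.__setattr__(self, "log_after", la)

    def __len__(self) -> int:
        return int(self.log_before.size)

    @property
    def pairs(self) -> np.ndarray:
        """(n, 2) array of (x, y) return-map points."""
        return np.column_stack([self.log_before, self.log_after])

    def all_log_isis(self) -> np.ndarray:
        """Every distinct ISI (log10 s) represented in the pair set.

        The x coordinates cover ISI_1 .. ISI_{n-2} and the final y
        coordinate adds ISI_{n-1}, so together they recover the full ISI
        sequence of the source train.
        """
        if len(self) == 0:
            return np.empty(0)
        return np.concatenate([self.log_before, self.log_after[-1:]])


def compute_isis(train: SpikeTrain) -> np.ndarray:
    """Successive interspike intervals in seconds (length ``n_spikes - 1``)."""
    return np.diff(train.spike_times)


def compute_isi_pairs(train: SpikeTrain) -> ISIPairSet:
    """Return-map pairs ``(log10 ISI_{i-1}, log10 ISI_i)`` per interior spike."""
    isis = compute_isis(train)
    if isis.size < 2:
        return ISIPairSet(np.empty(0), np.empty(0), n_spikes_source=train.n_spikes)
    log_isis = np.log10(isis)
    return ISIPairSet(log_isis[:-1], log_isis[1:], n_spikes_source=train.n_spikes)


def mean_firing_rate(train: SpikeTrain) -> float:
    """Mean firing rate in Hz: spike count over recording duration."""
    return train.n_spikes / train.duration
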