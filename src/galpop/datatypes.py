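"""Core in-memory containers shared across the pipeline.

Conventions used throughout:

* time is in seconds, voltages in mV, currents in pA, fluorescence either in
  raw arbitrary units or Z-score units (``TraceMatrix.zscored`` flags which);
* a "bout" is a labeled interval ``[onset_s, offset_s)`` of behavior or of
  stimulus presentation, held in an :class:`EventTable`;
* transition probabilities are bout-level: consecutive identical labels are
  merged before counting, so self-transitions are impossible by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraceMatrix",
    "EventTable",
    "PatchRecord",
    "EphysFeatures",
    "PscEventSet",
    "AlignedResponse",
    "ClusterOrdering",
    "TuningRecord",
    "SelectivityRecord",
    "BoutFeatureMatrix",
    "SeparabilityResult",
    "TransitionMatrix",
    "BehaviorSummary",
]

EVENT_COLUMNS = ("onset_s", "offset_s", "label", "actor")


@dataclass
class TraceMatrix:
    """Neuron x time fluorescence matrix with session metadata.

    ``traces`` holds one row per neuron.  When ``zscored`` is True the values
    are in Z units relative to a baseline period and ``constant_flags`` marks
    neurons whose baseline standard deviation was zero (their Z trace is 0).
    """

    traces: np.ndarray
    sampling_rate: float
    neuron_ids: np.ndarray | None = None
    animal_id: str = ""
    state_label: str = ""
    zscored: bool = False
    constant_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D (neuron x time) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces contain non-finite values")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.traces.shape[0])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if self.neuron_ids.shape[0] != self.traces.shape[0]:
                raise ValueError("neuron_ids length must match neuron count")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class EventTable:
    """Timestamped labeled bouts (onset_s, offset_s, label, actor).

    ``meta`` carries assay metadata (animal_id, timepoint, assay_duration_s,
    nest-zone definition, ...).  ``ground_truth`` is populated by the
    synthetic generators with every planted quantity downstream stages
    estimate.
    """

    df: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        for col in EVENT_COLUMNS:
            if col not in df.columns:
                if col == "actor":
                    df["actor"] = "subject"
                else:
                    raise ValueError(f"event table missing column {col!r}")
        if len(df) and not (df["onset_s"] < df["offset_s"]).all():
            raise ValueError("every bout must satisfy onset_s < offset_s")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> list[str]:
        return list(pd.unique(self.df["label"]))

    def of_label(self, label: str) -> pd.DataFrame:
        return self.df[self.df["label"] == label]

    def onsets(self, label: str) -> np.ndarray:
        return self.of_label(label)["onset_s"].to_numpy(dtype=float)

    @property
    def assay_duration_s(self) -> float | None:
        return self.meta.get("assay_duration_s")


@dataclass
class PatchRecord:
    """Intracellular voltage (current clamp) and/or current (voltage clamp)
    traces with the current-step stimulation protocol."""

    voltage: np.ndarray | None
    sampling_rate: float
    current: np.ndarray | None = None
    step_protocol: list[tuple[float, float, float]] = field(default_factory=list)
    cell_id: str = ""
    group_label: str = ""
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voltage is not None:
            self.voltage = np.asarray(self.voltage, dtype=float)
        if self.current is not None:
            self.current = np.asarray(self.current, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration
        prev_end = None
        for amp, start, end in sorted(self.step_protocol, key=lambda s: s[1]):
            if not (0 <= start < end):
                raise ValueError("step windows must satisfy 0 <= start < end")
            if dur is not None and end > dur + 1e-9:
                raise ValueError("step window extends beyond the record")
            if prev_end is not None and start < prev_end - 1e-9:
                raise ValueError("step windows must not overlap")
            prev_end = end

    @property
    def duration(self) -> float | None:
        for series in (self.voltage, self.current):
            if series is not None:
                return len(series) / self.sampling_rate
        return None

    def time(self) -> np.ndarray:
        series = self.voltage if self.voltage is not None else self.current
        if series is None:
            return np.empty(0)
        return np.arange(len(series)) / self.sampling_rate


@dataclass
class EphysFeatures:
    """Per-cell intracellular feature set (baseline firing, resting
    potential, silent flag, depolarization block, AP half-width)."""

    cell_id: str = ""
    group_label: str = ""
    baseline_firing_hz: float = np.nan
    resting_potential_mv: float = np.nan
    is_silent: bool | None = None
    depol_block: bool | None = None
    depol_block_current: float | None = None
    depol_block_status: str = "ok"
    ap_half_width_ms: float = np.nan
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class PscEventSet:
    """Detected spontaneous postsynaptic currents and their per-kind rates."""

    event_times: np.ndarray
    amplitudes: np.ndarray
    kinds: np.ndarray  # "EPSC" / "IPSC" per event
    duration_s: float
    sign_convention: str = "negative deflection = EPSC"

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if not (len(self.event_times) == len(self.amplitudes) == len(self.kinds)):
            raise ValueError("event arrays must have equal length")

    @property
    def frequency_hz(self) -> float:
        return len(self.event_times) / self.duration_s

    @property
    def epsc_frequency_hz(self) -> float:
        return float(np.sum(self.kinds == "EPSC")) / self.duration_s

    @property
    def ipsc_frequency_hz(self) -> float:
        return float(np.sum(self.kinds == "IPSC")) / self.duration_s


@dataclass
class AlignedResponse:
    """One neuron's event-aligned responses for one bout label.

    ``aligned`` is events x window in Z units, sampled at ``sampling_rate``;
    the window spans ``[-pre_s, post_s)`` around bout onset.
    ``evoked_amplitude`` is mean Z over the response window minus mean Z over
    the pre-onset baseline window.
    """

    neuron_id: Any
    event_label: str
    aligned: np.ndarray
    sampling_rate: float
    pre_s: float
    post_s: float
    response_s: float
    mean_trace: np.ndarray = field(default=None)  # type: ignore[assignment]
    evoked_amplitude: float = np.nan
    activated: bool | None = None
    activation_p: float = np.nan
    onset_latency_s: float | None = None
    n_dropped_events: int = 0

    def __post_init__(self) -> None:
        self.aligned = np.atleast_2d(np.asarray(self.aligned, dtype=float))
        if self.mean_trace is None:
            self.mean_trace = self.aligned.mean(axis=0) if self.aligned.size else np.empty(0)
        if np.isnan(self.evoked_amplitude) and self.aligned.size:
            base, resp = self.event_means()
            self.evoked_amplitude = float(resp.mean() - base.mean())

    @property
    def n_events(self) -> int:
        return 0 if self.aligned.size == 0 else self.aligned.shape[0]

    def window_time(self) -> np.ndarray:
        n = self.aligned.shape[1] if self.aligned.size else 0
        return np.arange(n) / self.sampling_rate - self.pre_s

    def event_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-event mean Z over the baseline and response windows."""
        t = self.window_time()
        base = (t >= -self.pre_s) & (t < 0)
        resp = (t >= 0) & (t < self.response_s)
        return self.aligned[:, base].mean(axis=1), self.aligned[:, resp].mean(axis=1)


@dataclass
class ClusterOrdering:
    """Partition of neurons plus the onset-sorted display order."""

    labels: np.ndarray  # cluster id per neuron, relabeled by ascending mean onset
    order: np.ndarray  # permutation of neuron indices
    cluster_onsets: np.ndarray  # mean onset (s) per cluster id
    neuron_ids: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_onsets)


@dataclass
class TuningRecord:
    neuron_id: Any
    stimulus: str
    tuning_index: float
    tuning_index_normalized: float = np.nan
    baseline_activity: float = np.nan  # transients / min
    baseline_activity_normalized: float = np.nan


@dataclass
class SelectivityRecord:
    neuron_id: Any
    stim_a: str
    stim_b: str
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("selectivity score must lie in [0, 1]")


@dataclass
class BoutFeatureMatrix:
    """Samples x features matrix for stimulus separability.

    Default sample definition: one row per (neuron, bout); features are the
    mean Z per temporal bin over the bout-aligned window.
    """

    X: np.ndarray
    labels: np.ndarray  # stimulus per sample
    bin_width_s: float
    window: tuple[float, float]
    neuron_of_sample: np.ndarray
    bout_of_sample: np.ndarray
    n_dropped_bouts: int = 0
    sample_mode: str = "neuron_bouts"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label per sample required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class SeparabilityResult:
    stimulus_set: list[str]
    embedding: np.ndarray  # samples x (C-1)
    labels: np.ndarray
    cluster_labels: np.ndarray
    ellipsoids: dict[str, tuple[np.ndarray, np.ndarray, float]]
    rand_index: float
    n_samples: int
    config: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rand_index <= 1.0):
            raise ValueError("rand_index must lie in [0, 1]")


@dataclass
class TransitionMatrix:
    """Bout-level behavioral transition probabilities for one animal/assay."""

    behaviors: list[str]
    counts: np.ndarray
    P: np.ndarray
    animal_id: str = ""
    timepoint: str = ""
    zero_rows: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.behaviors)
        if self.counts.shape != (k, k) or self.P.shape != (k, k):
            raise ValueError("matrix shapes must match the behavior list")
        out = self.counts.sum(axis=1)
        if self.zero_rows is None:
            self.zero_rows = out == 0
        rowsum = self.P.sum(axis=1)
        if not np.allclose(rowsum[~self.zero_rows], 1.0, atol=1e-9):
            raise ValueError("rows with outgoing transitions must sum to 1")

    def prob(self, src: str, dst: str) -> float:
        i, j = self.behaviors.index(src), self.behaviors.index(dst)
        return float(self.P[i, j])


@dataclass
class BehaviorSummary:
    """Per-assay parental-behavior metrics."""

    animal_id: str = ""
    timepoint: str = ""
    assay_duration_s: float = np.nan
    retrieval_latency_s: float = np.nan
    retrieval_censored: bool = True
    crouch_fraction: float = np.nan
    nest_time_fraction: float = np.nan
    contact_latency_s: float = np.nan
    contact_censored: bool = True


def as_event_dataframe(rows: Sequence[tuple[float, float, str]] | pd.DataFrame,
                       actor: str = "subject") -> pd.DataFrame:
    """Build a canonical event DataFrame from (onset, offset, label) rows."""
    if isinstance(rows, pd.DataFrame):
        return rows
    df = pd.DataFrame(rows, columns=["onset_s", "offset_s", "label"])
    df["actor"] = actor
    return df
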