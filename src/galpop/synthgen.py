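"""Synthetic sessions with known ground truth.

Three generators emulate the study's recording structure:

* :func:`generate_population_session` — a miniscope-style neuron x time
  fluorescence matrix plus the stimulus/behavior bout table that drove it.
  Calcium transients are instantaneous rises with single-exponential decay;
  a seeded shuffle assigns a ``silent_fraction`` of neurons that emit noise
  only; active neurons emit spontaneous transients at a Poisson rate and
  stimulus-evoked transients whose amplitude is lognormal around the
  neuron x stimulus ``tuning_matrix`` entry and whose onset lags the bout by
  a truncated-normal latency draw.
* :func:`generate_ethogram` — a Markovian bout sequence with exponential
  dwell times drawn from a known row-stochastic transition matrix.
* :func:`generate_patch_record` — an intracellular voltage trace with
  stereotyped triangular spikes at Poisson times, current-step responses
  with optional depolarization block, and a voltage-clamp current trace with
  spontaneous postsynaptic currents.

Every planted quantity a downstream stage estimates (silent flags, evoked
amplitudes and latencies, spontaneous event times, transition counts, spike
and PSC times) is recorded in the output's ``ground_truth`` so recovery can
be tested without external data.  Identical config (including seed) yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .datatypes import EventTable, PatchRecord, TraceMatrix

__all__ = [
    "PopulationConfig",
    "EthogramConfig",
    "PatchConfig",
    "generate_population_session",
    "generate_ethogram",
    "generate_patch_record",
    "uniform_tuning_matrix",
    "vir_like_population",
    "d18_like_population",
    "vir_like_ethogram",
    "d18_like_ethogram",
]

# coefficient of variation of evoked transient amplitudes around the
# tuning_matrix mean (lognormal draw)
EVOKED_AMPLITUDE_CV = 0.3
# SD of the onset-latency draw, as a fraction of the mean latency
LATENCY_SD_FRACTION = 0.2


@dataclass
class PopulationConfig:
    """Parameters of one synthetic calcium-imaging session."""

    n_neurons: int = 60
    duration: float = 600.0  # s
    sampling_rate: float = 20.0  # Hz
    silent_fraction: float = 0.2
    spontaneous_rate: float = 2.0  # transients / min per active neuron
    spontaneous_amplitude: float = 1.0  # fluorescence units (lognormal mean)
    calcium_decay_tau: float = 1.5  # s
    noise_sd: float = 0.1
    stimulus_set: list[str] = field(default_factory=lambda: ["pup", "intruder", "object"])
    tuning_matrix: np.ndarray | None = None  # n_neurons x n_stimuli mean amplitudes
    response_latency_mean: float = 0.8  # s
    state_label: str = "Vir"
    n_bouts_per_stimulus: int = 8
    bout_duration: float = 2.0  # s
    inter_bout_gap: tuple[float, float] = (6.0, 10.0)  # uniform draw, s
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.silent_fraction <= 1.0:
            raise ValueError("silent_fraction must lie in [0, 1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_neurons < 0 or self.duration < 0:
            raise ValueError("n_neurons and duration must be nonnegative")
        if self.tuning_matrix is not None:
            tm = np.asarray(self.tuning_matrix, dtype=float)
            if tm.shape != (self.n_neurons, len(self.stimulus_set)):
                raise ValueError(
                    "tuning_matrix must be n_neurons x n_stimuli "
                    f"({self.n_neurons} x {len(self.stimulus_set)}), got {tm.shape}"
                )
            if np.any(tm < 0):
                raise ValueError("tuning amplitudes must be nonnegative")


@dataclass
class EthogramConfig:
    """Parameters of one synthetic behavioral bout sequence."""

    behavior_labels: list[str] = field(
        default_factory=lambda: ["sniff", "retrieve", "crouch", "groom", "nest_enter", "nest_build"]
    )
    transition_matrix_true: np.ndarray | None = None  # row-stochastic
    dwell_mean: float | Sequence[float] = 5.0  # s, scalar or per behavior
    n_bouts: int = 100
    start_time: float = 0.0
    seed: int = 0

    def validate(self) -> np.ndarray:
        if self.transition_matrix_true is None:
            raise ValueError("transition_matrix_true is required")
        P = np.asarray(self.transition_matrix_true, dtype=float)
        k = len(self.behavior_labels)
        if P.shape != (k, k):
            raise ValueError("transition matrix must be square over behavior_labels")
        rowsum = P.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-9) or np.any(P < 0):
            raise ValueError("each transition-matrix row must be a probability vector summing to 1")
        dwell = np.broadcast_to(np.asarray(self.dwell_mean, dtype=float), (k,))
        if np.any(dwell <= 0):
            raise ValueError("dwell_mean must be positive")
        return P


@dataclass
class PatchConfig:
    """Parameters of one synthetic whole-cell recording."""

    duration: float = 60.0  # s of baseline recording
    sampling_rate: float = 20_000.0  # Hz
    resting_potential_true: float = -60.0  # mV
    spike_rate_true: float = 2.0  # Hz at baseline
    silent: bool = False
    spike_peak_mv: float = 20.0
    spike_threshold_offset_mv: float = 20.0  # threshold = resting + offset
    ap_half_width_true_ms: float = 1.0
    depol_block_current: float | None = None  # pA
    current_steps: list[float] = field(default_factory=list)  # pA
    step_duration: float = 1.0  # s
    step_gap: float = 0.5  # s between steps
    step_rate_per_pa: float = 0.1  # evoked spikes/s per pA of injected current
    step_depolarization_mv_per_pa: float = 0.05  # subthreshold depolarization
    block_plateau_mv: float = -25.0  # plateau voltage during depolarization block
    psc_rate_true: float = 0.0  # Hz
    psc_amplitude_mean: float = 20.0  # pA
    psc_decay_tau: float = 5.0  # ms
    epsc_fraction: float = 1.0
    noise_sd_mv: float = 0.5
    noise_sd_pa: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.epsc_fraction <= 1.0:
            raise ValueError("epsc_fraction must lie in [0, 1]")
        if self.sampling_rate <= 0 or self.duration < 0:
            raise ValueError("sampling_rate must be positive and duration nonnegative")
        if sorted(self.current_steps) != list(self.current_steps):
            raise ValueError("current_steps must be increasing")


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float,
                      size: int | None = None) -> np.ndarray | float:
    """Lognormal draw with the given arithmetic mean and CV."""
    if mean <= 0:
        return np.zeros(size) if size else 0.0
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _dead_time_poisson(rng: np.random.Generator, rate: float, duration: float,
                       dead: float) -> np.ndarray:
    """Renewal process with a refractory dead time: gaps = dead + Exp(mean
    1/rate - dead), so the mean event rate equals ``rate`` exactly while no
    two events fall closer than ``dead`` seconds."""
    if rate <= 0 or duration <= 0:
        return np.empty(0)
    mean_gap = 1.0 / rate
    if dead >= mean_gap:
        raise ValueError("dead time incompatible with the requested rate")
    times = []
    t = float(rng.exponential(mean_gap))
    while t < duration:
        times.append(t)
        t += dead + float(rng.exponential(mean_gap - dead))
    return np.asarray(times)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero (resampled; mean >= 0 required)."""
    if mean <= 0:
        return 0.0
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0


def _add_transient(trace: np.ndarray, onset_idx: int, amplitude: float,
                   decay_samples: float) -> None:
    """Instantaneous rise at onset_idx followed by exponential decay."""
    n = len(trace)
    if onset_idx >= n or amplitude <= 0:
        return
    # truncate the kernel where it falls below 1e-3 of the amplitude
    length = min(n - onset_idx, int(np.ceil(decay_samples * np.log(1e3))) + 1)
    k = amplitude * np.exp(-np.arange(length) / decay_samples)
    trace[onset_idx:onset_idx + length] += k


def _place_bouts(cfg: PopulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out non-overlapping stimulus bouts over the session."""
    labels = []
    for s in cfg.stimulus_set:
        labels.extend([s] * cfg.n_bouts_per_stimulus)
    rng.shuffle(labels)
    lo, hi = cfg.inter_bout_gap
    rows = []
    cursor = float(rng.uniform(lo, hi))
    for lab in labels:
        onset = cursor
        offset = onset + cfg.bout_duration
        if offset > cfg.duration:
            raise ValueError(
                "duration too short to place the requested bouts "
                f"(needed > {offset:.1f} s, have {cfg.duration:.1f} s)"
            )
        rows.append((onset, offset, lab))
        cursor = offset + float(rng.uniform(lo, hi))
    df = pd.DataFrame(rows, columns=["onset_s", "offset_s", "label"])
    df["actor"] = "subject"
    return df


def generate_population_session(config: PopulationConfig) -> tuple[TraceMatrix, EventTable]:
    """Simulate one calcium-imaging session.

    Returns the trace matrix and the bout table actually used; the bout
    table's ``ground_truth`` records silent flags, the tuning matrix, every
    evoked transient (neuron, bout, amplitude, onset) and all spontaneous
    transient times.
    """
    config.validate()
    rng = _rng(config.seed)
    n_samples = int(round(config.duration * config.sampling_rate))
    traces = rng.normal(0.0, config.noise_sd, size=(config.n_neurons, n_samples))

    # silent assignment by seeded shuffle (not first-k raw indices)
    order = rng.permutation(config.n_neurons)
    n_silent = int(np.floor(config.silent_fraction * config.n_neurons))
    silent = np.zeros(config.n_neurons, dtype=bool)
    silent[order[:n_silent]] = True

    if config.tuning_matrix is None:
        tuning = np.zeros((config.n_neurons, len(config.stimulus_set)))
    else:
        tuning = np.asarray(config.tuning_matrix, dtype=float)

    if config.n_neurons > 0 and len(config.stimulus_set) > 0:
        events_df = _place_bouts(config, rng)
    else:
        events_df = pd.DataFrame(columns=["onset_s", "offset_s", "label", "actor"])

    decay_samples = config.calcium_decay_tau * config.sampling_rate
    lat_sd = LATENCY_SD_FRACTION * config.response_latency_mean

    spont_times: list[list[float]] = []
    evoked_log: list[dict[str, Any]] = []
    stim_index = {s: j for j, s in enumerate(config.stimulus_set)}

    for i in range(config.n_neurons):
        if silent[i]:
            spont_times.append([])
            continue
        # spontaneous transients at spontaneous_rate/min; a 4 s dead time
        # keeps planted transients individually resolvable at the default
        # decay tau without biasing the mean rate
        times = _dead_time_poisson(rng, config.spontaneous_rate / 60.0,
                                   config.duration, dead=4.0)
        amps = _lognormal_around(rng, config.spontaneous_amplitude,
                                 EVOKED_AMPLITUDE_CV, size=len(times))
        for t, a in zip(times, np.atleast_1d(amps)):
            _add_transient(traces[i], int(round(t * config.sampling_rate)), float(a),
                           decay_samples)
        spont_times.append([float(t) for t in times])
        # evoked transients at each matching bout
        for b, row in events_df.iterrows():
            mean_amp = tuning[i, stim_index[row["label"]]]
            if mean_amp <= 0:
                continue
            amp = float(_lognormal_around(rng, mean_amp, EVOKED_AMPLITUDE_CV))
            latency = _truncated_normal(rng, config.response_latency_mean, lat_sd)
            onset = row["onset_s"] + latency
            _add_transient(traces[i], int(round(onset * config.sampling_rate)), amp,
                           decay_samples)
            evoked_log.append({"neuron": i, "bout": int(b), "label": row["label"],
                               "amplitude": amp, "latency_s": latency,
                               "onset_s": float(onset)})

    tm = TraceMatrix(traces=traces, sampling_rate=config.sampling_rate,
                     state_label=config.state_label)
    gt = {
        "silent": silent,
        "tuning_matrix": tuning,
        "spontaneous_times": spont_times,
        "evoked": evoked_log,
        "config": _config_dict(config),
    }
    table = EventTable(df=events_df,
                       meta={"assay_duration_s": config.duration,
                             "timepoint": config.state_label,
                             "sampling_rate": config.sampling_rate},
                       ground_truth=gt)
    return tm, table


def _config_dict(cfg: Any) -> dict[str, Any]:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d


def generate_ethogram(config: EthogramConfig) -> EventTable:
    """Simulate a bout-level ethogram from a known Markov chain.

    Successive labels are drawn from ``transition_matrix_true``; consecutive
    identical labels are merged into one bout, so the output has exactly
    ``n_bouts`` bouts with no self-transitions.  Dwell times are exponential
    with per-behavior means; bouts abut (offset_i == onset_{i+1}).
    """
    P = config.validate()
    rng = _rng(config.seed)
    k = len(config.behavior_labels)
    dwell = np.broadcast_to(np.asarray(config.dwell_mean, dtype=float), (k,))

    states: list[int] = []
    s = int(rng.integers(k))
    states.append(s)
    # sample raw chain, merging self-transitions, until n_bouts bouts exist
    guard = 0
    while len(states) < config.n_bouts:
        s = int(rng.choice(k, p=P[s]))
        if s != states[-1]:
            states.append(s)
        guard += 1
        if guard > 1000 * max(config.n_bouts, 1):
            raise ValueError("chain failed to leave a state; check transition matrix")

    rows = []
    t = config.start_time
    for s in states:
        d = float(rng.exponential(dwell[s]))
        rows.append((t, t + d, config.behavior_labels[s]))
        t += d
    df = pd.DataFrame(rows, columns=["onset_s", "offset_s", "label"])
    df["actor"] = "subject"
    return EventTable(
        df=df,
        meta={"assay_duration_s": float(t), "timepoint": ""},
        ground_truth={"transition_matrix_true": P,
                      "state_sequence": states,
                      "config": _config_dict(config)},
    )


def _add_spike(voltage: np.ndarray, idx: int, threshold_mv: float, peak_mv: float,
               half_width_samples: float) -> None:
    """Triangular spike: linear rise threshold -> peak over half the base,
    then symmetric fall.  Width at half amplitude equals half the base, i.e.
    exactly ``half_width_samples``."""
    base = int(round(2 * half_width_samples))
    half = max(base // 2, 1)
    n = len(voltage)
    for j in range(-half, half + 1):
        p = idx + j
        if 0 <= p < n:
            frac = 1.0 - abs(j) / half
            v = threshold_mv + frac * (peak_mv - threshold_mv)
            voltage[p] = max(voltage[p], v)


def generate_patch_record(config: PatchConfig) -> PatchRecord:
    """Simulate one whole-cell recording.

    The voltage trace holds a baseline period at ``resting_potential_true``
    with Poisson spiking (none if ``silent``) followed by the current-step
    protocol; steps at or above ``depol_block_current`` produce a spike-free
    depolarized plateau.  A separate current trace carries PSC events
    (instant rise, exponential decay; negative deflection = EPSC).
    """
    config.validate()
    rng = _rng(config.seed)
    fs = config.sampling_rate
    threshold = config.resting_potential_true + config.spike_threshold_offset_mv
    hw_samples = config.ap_half_width_true_ms * 1e-3 * fs

    step_protocol: list[tuple[float, float, float]] = []
    t_cursor = config.duration
    for amp in config.current_steps:
        start = t_cursor + config.step_gap
        step_protocol.append((float(amp), start, start + config.step_duration))
        t_cursor = start + config.step_duration
    total_dur = t_cursor + (config.step_gap if config.current_steps else 0.0)
    n_total = int(round(total_dur * fs))

    voltage = rng.normal(config.resting_potential_true, config.noise_sd_mv, size=n_total)

    # baseline spiking
    if config.silent or config.spike_rate_true <= 0:
        spike_times = np.empty(0)
    else:
        # 5 ms dead time keeps planted spikes resolvable at the default
        # refractory setting without biasing the mean rate
        spike_times = _dead_time_poisson(rng, config.spike_rate_true,
                                         config.duration, dead=5e-3)
    for t in spike_times:
        _add_spike(voltage, int(round(t * fs)), threshold, config.spike_peak_mv, hw_samples)

    # current steps
    step_spike_times: dict[float, list[float]] = {}
    blocked = False
    if (config.depol_block_current is not None and config.current_steps
            and config.depol_block_current <= min(config.current_steps)):
        import warnings
        warnings.warn("depol_block_current at or below the smallest step; "
                      "no spiking step will precede the block", stacklevel=2)
    for amp, start, end in step_protocol:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        if config.depol_block_current is not None and amp >= config.depol_block_current:
            voltage[i0:i1] = rng.normal(config.block_plateau_mv, config.noise_sd_mv,
                                        size=i1 - i0)
            step_spike_times[amp] = []
            blocked = True
            continue
        depol = config.step_depolarization_mv_per_pa * amp
        voltage[i0:i1] += depol
        rate = config.step_rate_per_pa * amp
        n_step_spk = max(int(round(rate * (end - start))), 0)
        if n_step_spk > 0:
            # regularly spaced evoked spikes: deterministic count per step
            ts = start + (np.arange(n_step_spk) + 0.5) * (end - start) / n_step_spk
            for t in ts:
                _add_spike(voltage, int(round(t * fs)), threshold + depol,
                           config.spike_peak_mv, hw_samples)
            step_spike_times[amp] = [float(t) for t in ts]
        else:
            step_spike_times[amp] = []

    # voltage-clamp current trace with PSCs (baseline period length only)
    n_base = int(round(config.duration * fs))
    current = rng.normal(0.0, config.noise_sd_pa, size=n_base)
    psc_times = np.empty(0)
    psc_signs: np.ndarray = np.empty(0)
    psc_amps: np.ndarray = np.empty(0)
    if config.psc_rate_true > 0:
        # dead time of 6 decay constants keeps planted PSCs resolvable
        psc_times = _dead_time_poisson(rng, config.psc_rate_true, config.duration,
                                       dead=6 * config.psc_decay_tau * 1e-3)
        n_psc = len(psc_times)
        psc_amps = np.atleast_1d(_lognormal_around(rng, config.psc_amplitude_mean,
                                                   0.2, size=n_psc))
        psc_signs = np.where(rng.uniform(size=n_psc) < config.epsc_fraction, -1.0, 1.0)
        tau_samples = config.psc_decay_tau * 1e-3 * fs
        for t, a, sgn in zip(psc_times, psc_amps, psc_signs):
            _add_transient(current, int(round(t * fs)), a, tau_samples)
            if sgn < 0:
                # _add_transient adds a positive kernel; flip the added part
                i0 = int(round(t * fs))
                length = min(n_base - i0, int(np.ceil(tau_samples * np.log(1e3))) + 1)
                current[i0:i0 + length] -= 2 * a * np.exp(-np.arange(length) / tau_samples)

    gt = {
        "spike_times": spike_times,
        "step_spike_times": step_spike_times,
        "depol_block": blocked,
        "psc_times": psc_times,
        "psc_amplitudes": psc_amps,
        "psc_signs": psc_signs,
        "resting_potential_true": config.resting_potential_true,
        "spike_rate_true": config.spike_rate_true,
        "psc_rate_true": config.psc_rate_true,
        "ap_half_width_true_ms": config.ap_half_width_true_ms,
        "spike_threshold_true_mv": threshold,
        "config": _config_dict(config),
    }
    return PatchRecord(voltage=voltage, current=current, sampling_rate=fs,
                       step_protocol=step_protocol, ground_truth=gt)


# ---------------------------------------------------------------------------
# tuning-matrix helpers and state presets
# ---------------------------------------------------------------------------

def uniform_tuning_matrix(n_neurons: int, stimulus_set: Sequence[str],
                          amplitudes: dict[str, float],
                          responsive_fraction: dict[str, float],
                          rng: np.random.Generator) -> np.ndarray:
    """Mean-amplitude matrix where a seeded random subset of neurons responds
    to each stimulus with the given mean amplitude, others with 0."""
    tm = np.zeros((n_neurons, len(stimulus_set)))
    for j, s in enumerate(stimulus_set):
        frac = responsive_fraction.get(s, 0.0)
        n_resp = int(round(frac * n_neurons))
        idx = rng.permutation(n_neurons)[:n_resp]
        tm[idx, j] = amplitudes.get(s, 0.0)
    return tm


_PRESET_STIMULI = ["retrieval", "pup", "intruder", "object"]


def vir_like_population(seed: int, n_neurons: int = 60,
                        duration: float = 600.0) -> PopulationConfig:
    """Virgin-like session: few silent neurons, broad weak tuning with
    little pup preference, slower evoked responses."""
    rng = _rng(seed + 10_000)
    tuning = uniform_tuning_matrix(
        n_neurons, _PRESET_STIMULI,
        amplitudes={"retrieval": 2.0, "pup": 1.5, "intruder": 1.4, "object": 1.4},
        responsive_fraction={"retrieval": 0.7, "pup": 0.7, "intruder": 0.6, "object": 0.6},
        rng=rng,
    )
    return PopulationConfig(
        n_neurons=n_neurons, duration=duration, silent_fraction=0.2,
        spontaneous_rate=2.0, stimulus_set=list(_PRESET_STIMULI),
        tuning_matrix=tuning, response_latency_mean=1.0, state_label="Vir",
        seed=seed,
    )


def d18_like_population(seed: int, n_neurons: int = 60,
                        duration: float = 600.0) -> PopulationConfig:
    """Late-pregnancy-like session: sparsened population (more silent
    neurons, fewer retrieval-activated ones), stronger and more selective
    pup tuning, shorter evoked latency."""
    rng = _rng(seed + 20_000)
    tuning = uniform_tuning_matrix(
        n_neurons, _PRESET_STIMULI,
        amplitudes={"retrieval": 2.0, "pup": 3.0, "intruder": 0.7, "object": 0.7},
        responsive_fraction={"retrieval": 0.3, "pup": 0.7, "intruder": 0.5, "object": 0.5},
        rng=rng,
    )
    return PopulationConfig(
        n_neurons=n_neurons, duration=duration, silent_fraction=0.55,
        spontaneous_rate=1.0, stimulus_set=list(_PRESET_STIMULI),
        tuning_matrix=tuning, response_latency_mean=0.4, state_label="D18",
        seed=seed,
    )


def vir_like_ethogram(seed: int, n_bouts: int = 60) -> EthogramConfig:
    """Virgin-like bout sequence: mass on sniff -> groom -> nest_enter cycles."""
    labels = ["sniff", "retrieve", "crouch", "groom", "nest_enter", "nest_build"]
    P = np.array([
        #  sniff retr  crouch groom nest_e nest_b
        [0.00, 0.05, 0.05, 0.60, 0.25, 0.05],   # sniff
        [0.40, 0.00, 0.20, 0.20, 0.10, 0.10],   # retrieve
        [0.40, 0.10, 0.00, 0.30, 0.10, 0.10],   # crouch
        [0.30, 0.05, 0.05, 0.00, 0.55, 0.05],   # groom
        [0.60, 0.05, 0.05, 0.25, 0.00, 0.05],   # nest_enter
        [0.40, 0.10, 0.10, 0.20, 0.20, 0.00],   # nest_build
    ])
    return EthogramConfig(behavior_labels=labels, transition_matrix_true=P,
                          dwell_mean=5.0, n_bouts=n_bouts, seed=seed)


def d18_like_ethogram(seed: int, n_bouts: int = 60) -> EthogramConfig:
    """Late-pregnancy-like bout sequence: mass on retrieve -> crouch ->
    nest_build chains."""
    labels = ["sniff", "retrieve", "crouch", "groom", "nest_enter", "nest_build"]
    P = np.array([
        [0.00, 0.60, 0.10, 0.10, 0.10, 0.10],   # sniff
        [0.05, 0.00, 0.60, 0.10, 0.05, 0.20],   # retrieve
        [0.05, 0.15, 0.00, 0.15, 0.05, 0.60],   # crouch
        [0.20, 0.30, 0.20, 0.00, 0.15, 0.15],   # groom
        [0.25, 0.30, 0.20, 0.10, 0.00, 0.15],   # nest_enter
        [0.10, 0.30, 0.40, 0.10, 0.10, 0.00],   # nest_build
    ])
    return EthogramConfig(behavior_labels=labels, transition_matrix_true=P,
                          dwell_mean=5.0, n_bouts=n_bouts, seed=seed)
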