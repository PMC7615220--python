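"""Intracellular feature extraction from whole-cell recordings.

Extracts the slice-physiology feature set used to characterize the
population: spike times, baseline firing frequency, resting membrane
potential, silent-neuron classification, depolarization block across a
current-step protocol, action-potential half-width, and spontaneous
postsynaptic current (sPSC/EPSC/IPSC) events from voltage-clamp traces.

Thresholds that the underlying experimental literature leaves implicit are
explicit configuration here:

* a cell is *silent* when its baseline firing is below ``SILENT_THRESHOLD_HZ``
  (0.05 Hz, i.e. no spike in a 20 s window);
* the spike threshold defaults to the baseline voltage mode + 20 mV, which
  makes detection invariant to resting-potential differences between groups;
* *depolarization block* is declared at the first current step whose spike
  count falls below 50% of the maximum across lower steps while the step's
  mean voltage sits >= 5 mV above the mean of the spiking steps.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import EphysFeatures, PatchRecord, PscEventSet

__all__ = [
    "SILENT_THRESHOLD_HZ",
    "detect_spikes",
    "baseline_features",
    "detect_depolarization_block",
    "ap_half_width",
    "detect_pscs",
    "extract_features",
]

SILENT_THRESHOLD_HZ = 0.05
BLOCK_COUNT_DROP = 0.5   # spike count below this fraction of the running max
BLOCK_PLATEAU_MV = 5.0   # mean step voltage this far above spiking steps


def _voltage_mode(v: np.ndarray, bin_mv: float = 0.5) -> float:
    """Mode of the voltage distribution (histogram peak); robust estimate of
    the resting level in the presence of spikes."""
    lo, hi = np.min(v), np.max(v)
    if hi - lo < bin_mv:
        return float(np.median(v))
    edges = np.arange(lo, hi + bin_mv, bin_mv)
    hist, edges = np.histogram(v, bins=edges)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def detect_spikes(record: PatchRecord, threshold_mv: float | None = None,
                  refractory_ms: float = 2.0,
                  window: tuple[float, float] | None = None) -> np.ndarray:
    """Times (s) of upward threshold crossings separated by >= refractory_ms.

    ``threshold_mv`` is absolute; when None it is set to the baseline voltage
    mode + 20 mV, which makes detection invariant to a DC offset.  ``window``
    restricts detection to a time interval.
    """
    if record.voltage is None:
        raise ValueError("record has no voltage trace")
    v = record.voltage
    fs = record.sampling_rate
    if len(v) == 0:
        return np.empty(0)
    if window is not None:
        i0, i1 = (max(int(round(t * fs)), 0) for t in window)
        i1 = min(i1, len(v))
        v = v[i0:i1]
        offset = i0
    else:
        offset = 0
    if len(v) == 0:
        return np.empty(0)
    if threshold_mv is None:
        threshold_mv = _voltage_mode(v) + 20.0
    refractory = refractory_ms * 1e-3
    if fs < 2.0 / refractory:
        warnings.warn("sampling rate too low to resolve the refractory period",
                      stacklevel=2)
    above = v >= threshold_mv
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    if len(crossings) == 0:
        return np.empty(0)
    times = (crossings + offset) / fs
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def baseline_features(record: PatchRecord,
                      baseline_window: tuple[float, float] | None = None,
                      threshold_mv: float | None = None,
                      silent_threshold_hz: float = SILENT_THRESHOLD_HZ,
                      spike_mask_ms: float = 5.0) -> EphysFeatures:
    """Baseline firing frequency, resting potential, and silent flag.

    Firing = spike count / window length.  Resting potential = median
    voltage over inter-spike samples (spikes masked +/- ``spike_mask_ms``).
    The baseline window must precede any current step.
    """
    if record.voltage is None:
        raise ValueError("record has no voltage trace")
    fs = record.sampling_rate
    if baseline_window is None:
        first_step = min((s[1] for s in record.step_protocol), default=record.duration)
        baseline_window = (0.0, float(first_step))
    t0, t1 = baseline_window
    for _, start, _ in record.step_protocol:
        if t1 > start + 1e-9:
            raise ValueError("baseline window must precede any current step")
    if t1 - t0 < 1.0:
        warnings.warn("baseline window shorter than 1 s; rate estimate imprecise",
                      stacklevel=2)
    spikes = detect_spikes(record, threshold_mv=threshold_mv, window=(t0, t1))
    firing = len(spikes) / (t1 - t0)

    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    v = record.voltage[i0:i1]
    mask = np.ones(len(v), dtype=bool)
    half = int(round(spike_mask_ms * 1e-3 * fs))
    for t in spikes:
        c = int(round(t * fs)) - i0
        mask[max(c - half, 0):c + half + 1] = False
    resting = float(np.median(v[mask])) if mask.any() else np.nan

    return EphysFeatures(
        cell_id=record.cell_id, group_label=record.group_label,
        baseline_firing_hz=firing, resting_potential_mv=resting,
        is_silent=firing < silent_threshold_hz, spike_times=spikes,
    )


def detect_depolarization_block(record: PatchRecord,
                                threshold_mv: float | None = None,
                                count_drop: float = BLOCK_COUNT_DROP,
                                plateau_mv: float = BLOCK_PLATEAU_MV,
                                ) -> tuple[bool, float | None, str]:
    """Scan the current-step protocol for depolarization block.

    Returns ``(flag, block_current_pa, status)``.  Block is declared at the
    first step whose spike count falls below ``count_drop`` of the maximum
    across lower steps while the step's mean voltage exceeds the spiking
    steps' mean by >= ``plateau_mv``.  Status is "insufficient spiking" when
    no step elicits >= 2 spikes.
    """
    steps = sorted(record.step_protocol, key=lambda s: s[0])
    if len(steps) < 3:
        raise ValueError("step protocol needs >= 3 increasing steps")
    fs = record.sampling_rate
    counts, mean_v = [], []
    for amp, start, end in steps:
        spikes = detect_spikes(record, threshold_mv=threshold_mv, window=(start, end))
        counts.append(len(spikes))
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        mean_v.append(float(np.mean(record.voltage[i0:i1])))
    counts_arr = np.asarray(counts)
    if counts_arr.max(initial=0) < 2:
        return False, None, "insufficient spiking"
    for k in range(1, len(steps)):
        prior = counts_arr[:k]
        if prior.max() < 2:
            continue
        spiking_mean_v = float(np.mean([mv for c, mv in zip(counts_arr[:k], mean_v[:k])
                                        if c >= 2]))
        if (counts_arr[k] < count_drop * prior.max()
                and mean_v[k] - spiking_mean_v >= plateau_mv):
            return True, float(steps[k][0]), "ok"
    return False, None, "ok"


def ap_half_width(record: PatchRecord, spike_times: np.ndarray,
                  threshold_mv: float | None = None,
                  window_ms: float = 5.0) -> float:
    """Median action-potential half-width (ms) across spikes.

    Per spike: amplitude = peak voltage - threshold voltage; half-width =
    duration for which the waveform stays above the half-amplitude level,
    measured with linear interpolation at the edges.  Spikes clipped at the
    trace maximum for more than 2 samples are excluded with a warning.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) == 0:
        raise ValueError("at least one spike is required")
    v = record.voltage
    fs = record.sampling_rate
    if threshold_mv is None:
        threshold_mv = _voltage_mode(v) + 20.0
    half_win = int(round(window_ms * 1e-3 * fs))
    trace_max = np.max(v)
    widths = []
    n_clipped = 0
    for t in spike_times:
        c = int(round(t * fs))
        seg = v[max(c - half_win, 0):c + half_win + 1]
        if len(seg) < 3:
            continue
        peak = float(np.max(seg))
        if np.sum(seg >= trace_max) > 2:
            n_clipped += 1
            continue
        half_level = threshold_mv + 0.5 * (peak - threshold_mv)
        above = seg >= half_level
        if not above.any():
            continue
        idx = np.flatnonzero(above)
        first, last = idx[0], idx[-1]
        # linear interpolation for the sub-sample edge positions
        left = float(first)
        if first > 0 and seg[first] != seg[first - 1]:
            left = first - (seg[first] - half_level) / (seg[first] - seg[first - 1])
        right = float(last)
        if last < len(seg) - 1 and seg[last] != seg[last + 1]:
            right = last + (seg[last] - half_level) / (seg[last] - seg[last + 1])
        widths.append((right - left) / fs * 1e3)
    if n_clipped:
        warnings.warn(f"{n_clipped} clipped spike(s) excluded from half-width",
                      stacklevel=2)
    if not widths:
        raise ValueError("no usable spike waveform for half-width")
    return float(np.median(widths))


def detect_pscs(record: PatchRecord, amplitude_threshold_pa: float = 5.0,
                decay_fit_window_ms: float = 20.0,
                min_separation_ms: float | None = None,
                min_duration_ms: float = 0.3,
                tau_bounds_ms: tuple[float, float] = (0.2, 100.0),
                fit_decay: bool = False) -> PscEventSet:
    """Detect spontaneous postsynaptic currents in a voltage-clamp trace.

    Events are deflections exceeding ``amplitude_threshold_pa`` over the
    local baseline (trace median) for at least ``min_duration_ms`` (rejects
    single-sample noise excursions); surviving regions closer than
    ``min_separation_ms`` are merged into one event at the larger peak.
    Sign assigns the kind (negative deflection = EPSC at the configured
    holding potential).  With ``fit_decay`` the post-peak decay is fit by a
    log-linear regression and events whose time constant falls outside
    ``tau_bounds_ms`` are discarded.
    """
    if record.current is None:
        raise ValueError("record has no current trace")
    x = record.current
    fs = record.sampling_rate
    duration = len(x) / fs
    if len(x) == 0 or duration == 0:
        return PscEventSet(np.empty(0), np.empty(0), np.empty(0), duration_s=max(duration, 1e-12))
    if min_separation_ms is None:
        min_separation_ms = decay_fit_window_ms / 2.0
    d = x - np.median(x)
    above = np.abs(d) > amplitude_threshold_pa
    if not above.any():
        return PscEventSet(np.empty(0), np.empty(0), np.empty(0), duration_s=duration)
    # contiguous supra-threshold regions lasting >= min_duration
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
    min_len = max(int(round(min_duration_ms * 1e-3 * fs)), 1)
    keep = (ends - starts + 1) >= min_len
    starts, ends = starts[keep], ends[keep]
    if len(starts) == 0:
        return PscEventSet(np.empty(0), np.empty(0), np.empty(0), duration_s=duration)
    # merge surviving regions closer than the separation gap
    gap = int(round(min_separation_ms * 1e-3 * fs))
    runs = [(int(starts[0]), int(ends[0]))]
    for s, e in zip(starts[1:], ends[1:]):
        if s - runs[-1][1] <= gap:
            runs[-1] = (runs[-1][0], int(e))
        else:
            runs.append((int(s), int(e)))

    times, amps, kinds = [], [], []
    fit_win = int(round(decay_fit_window_ms * 1e-3 * fs))
    for i0, i1 in runs:
        seg = d[i0:i1 + 1]
        k = int(np.argmax(np.abs(seg)))
        peak_idx = i0 + k
        amp = float(seg[k])
        if fit_decay:
            tail = np.abs(d[peak_idx:peak_idx + fit_win])
            tail = tail[tail > 0.05 * abs(amp)]
            if len(tail) >= 4:
                slope = np.polyfit(np.arange(len(tail)) / fs, np.log(tail), 1)[0]
                if slope >= 0:
                    continue
                tau_ms = -1e3 / slope
                if not (tau_bounds_ms[0] <= tau_ms <= tau_bounds_ms[1]):
                    continue
        times.append(peak_idx / fs)
        amps.append(amp)
        kinds.append("EPSC" if amp < 0 else "IPSC")
    return PscEventSet(np.asarray(times), np.asarray(amps),
                       np.asarray(kinds, dtype=object), duration_s=duration)


def extract_features(record: PatchRecord,
                     threshold_mv: float | None = None) -> EphysFeatures:
    """Full per-cell feature extraction (baseline + depolarization block +
    half-width when spikes exist)."""
    feats = baseline_features(record, threshold_mv=threshold_mv)
    if len(record.step_protocol) >= 3:
        flag, cur, status = detect_depolarization_block(record, threshold_mv=threshold_mv)
        feats.depol_block, feats.depol_block_current, feats.depol_block_status = flag, cur, status
    if len(feats.spike_times):
        try:
            feats.ap_half_width_ms = ap_half_width(record, feats.spike_times,
                                                   threshold_mv=threshold_mv)
        except ValueError:
            pass
    return feats
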