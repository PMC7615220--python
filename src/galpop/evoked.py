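"""Event-aligned population analysis of calcium trace matrices.

The stages mirror the standard peri-event workflow for miniscope data:
Z-score each neuron against an event-free baseline, count detected
(non-silent) neurons, align traces to bout onsets, test each neuron for a
positive evoked response with a paired sign-permutation test, measure
response-onset latency, and order activated neurons by hierarchical
clustering sorted by mean cluster onset.

Defaults (all configurable): alignment window -2..+5 s around onset with a
0..3 s response window; activation requires permutation p < 0.05 AND a mean
effect >= 0.5 Z over >= 3 bouts; onset latency is the first time the mean
trace holds >= 1 Z for 0.25 s; transient detection asks for >= 0.2 s above
3 baseline SD.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .datatypes import AlignedResponse, ClusterOrdering, EventTable, TraceMatrix

__all__ = [
    "baseline_mask_from_events",
    "zscore",
    "detect_transient_onsets",
    "detected_mask",
    "count_detected",
    "select_detected",
    "align",
    "classify_activated",
    "onset_latency",
    "cluster_and_order",
    "activated_fraction",
]

DEFAULT_PRE_S = 2.0
DEFAULT_POST_S = 5.0
DEFAULT_RESPONSE_S = 3.0
EVENT_PAD_S = 2.0  # padding around events excluded from the baseline mask


def baseline_mask_from_events(n_samples: int, sampling_rate: float,
                              events: EventTable | None,
                              pad_s: float = EVENT_PAD_S) -> np.ndarray:
    """Boolean sample mask: True outside any event window +/- pad_s."""
    mask = np.ones(n_samples, dtype=bool)
    if events is None or len(events) == 0:
        return mask
    for _, row in events.df.iterrows():
        i0 = max(int(np.floor((row["onset_s"] - pad_s) * sampling_rate)), 0)
        i1 = min(int(np.ceil((row["offset_s"] + pad_s) * sampling_rate)), n_samples)
        mask[i0:i1] = False
    return mask


def zscore(traces: TraceMatrix, baseline_mask: np.ndarray | None = None,
           events: EventTable | None = None) -> TraceMatrix:
    """Per-neuron Z-scoring against the baseline samples.

    ``baseline_mask`` may be a shared 1-D sample mask or a per-neuron 2-D
    mask; when omitted it is built from ``events`` (all samples outside any
    event window +/- 2 s).  Neurons with zero baseline SD are flagged
    constant and their Z trace set to 0.  Idempotent within float tolerance
    on already-Z-scored input.
    """
    if baseline_mask is None:
        baseline_mask = baseline_mask_from_events(traces.n_samples,
                                                  traces.sampling_rate, events)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if baseline_mask.ndim == 1:
        baseline_mask = np.broadcast_to(baseline_mask, traces.traces.shape)
    if not baseline_mask.any(axis=1).all():
        raise ValueError("baseline mask empty for at least one neuron")
    out = np.empty_like(traces.traces)
    constant = np.zeros(traces.n_neurons, dtype=bool)
    for i in range(traces.n_neurons):
        base = traces.traces[i, baseline_mask[i]]
        mu, sd = base.mean(), base.std()
        if sd == 0:
            constant[i] = True
            out[i] = 0.0
        else:
            out[i] = (traces.traces[i] - mu) / sd
    return TraceMatrix(traces=out, sampling_rate=traces.sampling_rate,
                       neuron_ids=traces.neuron_ids, animal_id=traces.animal_id,
                       state_label=traces.state_label, zscored=True,
                       constant_flags=constant)


def _baseline_stats(trace: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Robust baseline center/scale (median, MAD*1.4826) so transients do
    not inflate the noise estimate on raw traces."""
    base = trace[mask]
    med = np.median(base)
    mad = np.median(np.abs(base - med)) * 1.4826
    return float(med), float(mad)


def detect_transient_onsets(trace: np.ndarray, sampling_rate: float,
                            k: float = 3.0, min_duration_s: float = 0.2,
                            baseline_mask: np.ndarray | None = None,
                            zscored: bool = False,
                            merge_gap_s: float = 1.0) -> np.ndarray:
    """Onset sample indices of calcium transients: contiguous runs above
    mu + k*sigma lasting >= min_duration_s.  Runs separated by less than
    ``merge_gap_s`` are merged, so noise dips near the threshold crossing of
    a decaying transient do not split it into two events."""
    if not np.isfinite(k):
        return np.empty(0, dtype=int)
    if zscored:
        mu, sd = 0.0, 1.0
    else:
        if baseline_mask is None:
            baseline_mask = np.ones(len(trace), dtype=bool)
        mu, sd = _baseline_stats(trace, baseline_mask)
        if sd == 0:
            return np.empty(0, dtype=int)
    above = trace > mu + k * sd
    if not above.any():
        return np.empty(0, dtype=int)
    min_len = max(int(round(min_duration_s * sampling_rate)), 1)
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    # stage 1: bridge 1-2 sample noise dips inside a transient (micro-merge)
    # and apply the duration criterion to the supra-threshold samples
    micro_gap = max(int(round(0.1 * sampling_rate)), 1)
    events: list[tuple[int, int, int]] = []  # (start, end, n_above)
    for s, e in zip(starts, ends):
        if events and s - events[-1][1] <= micro_gap:
            ps, _, pn = events[-1]
            events[-1] = (ps, int(e), pn + int(e - s))
        else:
            events.append((int(s), int(e), int(e - s)))
    # stage 2: absorb re-crossings during a transient's slow decay
    gap = max(int(round(merge_gap_s * sampling_rate)), 0)
    onsets: list[int] = []
    last_end = -10 * gap - 10
    for s, e, n_above in events:
        if n_above < min_len:
            continue
        if s - last_end > gap:
            onsets.append(s)
        last_end = e
    return np.asarray(onsets, dtype=int)


def detected_mask(traces: TraceMatrix, k: float = 3.0, min_duration_s: float = 0.2,
                  baseline_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-neuron flag: has >= 1 detected calcium transient."""
    out = np.zeros(traces.n_neurons, dtype=bool)
    for i in range(traces.n_neurons):
        onsets = detect_transient_onsets(traces.traces[i], traces.sampling_rate,
                                         k=k, min_duration_s=min_duration_s,
                                         baseline_mask=baseline_mask,
                                         zscored=traces.zscored)
        out[i] = len(onsets) > 0
    return out


def count_detected(traces: TraceMatrix, k: float = 3.0,
                   min_duration_s: float = 0.2,
                   baseline_mask: np.ndarray | None = None) -> int:
    """Number of detected (non-silent) neurons in the session."""
    return int(detected_mask(traces, k=k, min_duration_s=min_duration_s,
                             baseline_mask=baseline_mask).sum())


def select_detected(traces: TraceMatrix, events: EventTable | None = None,
                    k: float = 3.0, min_duration_s: float = 0.2) -> TraceMatrix:
    """Subset of the session containing only detected (non-silent) neurons;
    the usual substrate for population-level separability analyses."""
    mask = baseline_mask_from_events(traces.n_samples, traces.sampling_rate, events)
    det = detected_mask(traces, k=k, min_duration_s=min_duration_s,
                        baseline_mask=mask)
    return TraceMatrix(traces=traces.traces[det],
                       sampling_rate=traces.sampling_rate,
                       neuron_ids=np.asarray(traces.neuron_ids)[det],
                       animal_id=traces.animal_id, state_label=traces.state_label,
                       zscored=traces.zscored,
                       constant_flags=None if traces.constant_flags is None
                       else traces.constant_flags[det])


def align(traces: TraceMatrix, events: EventTable, label: str,
          pre_s: float = DEFAULT_PRE_S, post_s: float = DEFAULT_POST_S,
          response_s: float = DEFAULT_RESPONSE_S) -> list[AlignedResponse]:
    """Align every neuron's Z trace to the onsets of ``label`` bouts.

    Input is Z-scored automatically (baseline = event-free samples) when the
    matrix is raw.  Events whose window [-pre_s, +post_s) is not fully
    inside the recording are dropped and counted.  Returns one
    :class:`AlignedResponse` per neuron; an empty list when no usable event
    remains.
    """
    if not traces.zscored:
        traces = zscore(traces, events=events)
    fs = traces.sampling_rate
    n_pre, n_post = int(round(pre_s * fs)), int(round(post_s * fs))
    onsets = events.onsets(label)
    windows, dropped = [], 0
    for t in onsets:
        c = int(round(t * fs))
        if c - n_pre < 0 or c + n_post > traces.n_samples:
            dropped += 1
            continue
        windows.append((c - n_pre, c + n_post))
    if not windows:
        return []
    out = []
    for i in range(traces.n_neurons):
        aligned = np.stack([traces.traces[i, a:b] for a, b in windows])
        resp = AlignedResponse(
            neuron_id=traces.neuron_ids[i], event_label=label, aligned=aligned,
            sampling_rate=fs, pre_s=pre_s, post_s=post_s,
            response_s=min(response_s, post_s), n_dropped_events=dropped,
        )
        base, rw = resp.event_means()
        resp.evoked_amplitude = float(rw.mean() - base.mean())
        out.append(resp)
    return out


def classify_activated(resp: AlignedResponse, alpha: float = 0.05,
                       min_effect: float = 0.5, n_permutations: int = 10_000,
                       seed: int = 0) -> bool | None:
    """One-sided paired sign-permutation test for a positive evoked response.

    Per-event differences d_i = (response-window mean) - (baseline-window
    mean) are sign-flipped; p = fraction of permuted means >= the observed
    mean.  All 2^n sign patterns are enumerated when n <= 14, otherwise
    ``n_permutations`` random patterns (seeded).  Activated requires
    p < alpha AND mean(d) >= min_effect.  Returns None (indeterminate) for
    fewer than 3 events; the decision is stored on ``resp``.
    """
    if resp.n_events < 3:
        resp.activated = None
        return None
    base, rw = resp.event_means()
    d = rw - base
    obs = d.mean()
    n = len(d)
    if n <= 14:
        codes = np.arange(2 ** n, dtype=np.int64)[:, None] >> np.arange(n)
        signs = (codes & 1) * 2.0 - 1.0
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_permutations, n))
    perm_means = (signs * d).mean(axis=1)
    p = float(np.mean(perm_means >= obs - 1e-12))
    resp.activation_p = p
    resp.activated = bool(p < alpha and obs >= min_effect)
    return resp.activated


def onset_latency(resp: AlignedResponse, threshold_z: float = 1.0,
                  sustain_s: float = 0.25) -> float | None:
    """First post-onset time (s) where the mean trace holds >= threshold_z
    for >= sustain_s contiguously; None if never.  Stored on ``resp``."""
    t = resp.window_time()
    post = t >= 0
    trace = resp.mean_trace[post]
    times = t[post]
    need = max(int(round(sustain_s * resp.sampling_rate)), 1)
    above = trace >= threshold_z
    run = 0
    for j, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            lat = float(times[j - need + 1])
            resp.onset_latency_s = lat
            return lat
    resp.onset_latency_s = None
    return None


def _neuron_onset(resp: AlignedResponse) -> float:
    """Onset for ordering: measured latency, else time of the mean-trace
    peak (keeps never-crossing neurons sortable)."""
    lat = onset_latency(resp) if resp.onset_latency_s is None else resp.onset_latency_s
    if lat is not None:
        return lat
    t = resp.window_time()
    post = t >= 0
    return float(t[post][np.argmax(resp.mean_trace[post])])


def cluster_and_order(responses: list[AlignedResponse],
                      n_clusters: int | None = None) -> ClusterOrdering:
    """Agglomerative clustering of unit-normalized mean traces (correlation
    distance, average linkage); cluster count by largest silhouette over
    2..min(8, n-1) when not given; clusters relabeled and ordered by
    ascending mean onset, neurons within a cluster by onset then neuron_id.
    """
    if len(responses) < 2:
        raise ValueError("need >= 2 activated neurons to cluster")
    M = np.stack([r.mean_trace for r in responses])
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = M / norms
    # correlation distance degenerates on constant rows; nudge them
    sd = U.std(axis=1)
    if np.any(sd == 0):
        U = U + 1e-12 * np.random.default_rng(0).normal(size=U.shape)
    D = pdist(U, metric="correlation")
    if np.allclose(D, 0):
        labels = np.zeros(len(responses), dtype=int)
    else:
        Z = linkage(D, method="average")
        if n_clusters is None:
            best_k, best_s = 2, -np.inf
            for k in range(2, min(8, len(responses) - 1) + 1):
                lab = fcluster(Z, t=k, criterion="maxclust")
                if len(np.unique(lab)) < 2:
                    continue
                s = silhouette_score(U, lab, metric="correlation")
                if s > best_s:
                    best_k, best_s = k, s
            n_clusters = best_k
        labels = fcluster(Z, t=min(n_clusters, len(responses)),
                          criterion="maxclust") - 1

    onsets = np.array([_neuron_onset(r) for r in responses])
    ids = np.array([r.neuron_id for r in responses])
    uniq = np.unique(labels)
    cluster_mean_onset = np.array([onsets[labels == c].mean() for c in uniq])
    # relabel clusters by ascending mean onset (ties by smallest member id)
    order_of_clusters = np.lexsort(
        (np.array([ids[labels == c].min() for c in uniq]), cluster_mean_onset))
    relabel = {int(uniq[oc]): rank for rank, oc in enumerate(order_of_clusters)}
    new_labels = np.array([relabel[int(c)] for c in labels])
    cluster_onsets = cluster_mean_onset[order_of_clusters]

    order = np.lexsort((ids, onsets, new_labels))
    return ClusterOrdering(labels=new_labels, order=order,
                           cluster_onsets=cluster_onsets, neuron_ids=ids)


def activated_fraction(traces: TraceMatrix, events: EventTable, label: str,
                       pre_s: float = DEFAULT_PRE_S, post_s: float = DEFAULT_POST_S,
                       response_s: float = DEFAULT_RESPONSE_S,
                       alpha: float = 0.05, min_effect: float = 0.5,
                       seed: int = 0, detection_k: float = 3.0,
                       ) -> tuple[float, int, int]:
    """Fraction of detected (non-silent) neurons activated during ``label``.

    Returns (fraction, n_activated, n_detected); fraction is NaN when the
    detected-neuron denominator is zero or no usable event exists.
    """
    base_mask = baseline_mask_from_events(traces.n_samples, traces.sampling_rate,
                                          events)
    det = detected_mask(traces, k=detection_k, baseline_mask=base_mask)
    n_det = int(det.sum())
    responses = align(traces, events, label, pre_s=pre_s, post_s=post_s,
                      response_s=response_s)
    if n_det == 0 or not responses:
        return float("nan"), 0, n_det
    n_act = 0
    for i, resp in enumerate(responses):
        if not det[i]:
            continue
        if classify_activated(resp, alpha=alpha, min_effect=min_effect, seed=seed):
            n_act += 1
    return n_act / n_det, n_act, n_det
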