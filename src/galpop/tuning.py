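"""Per-neuron tuning and selectivity statistics.

* :func:`baseline_activity` — spontaneous transient rate (transients/min)
  over event-free time.
* :func:`tuning_index` — bounded contrast between rectified response- and
  baseline-window activity, TI = (mu_resp - mu_base)/(mu_resp + mu_base + eps)
  in [-1, 1]; the *normalized* variant is a min-max rescaling over the
  session's neurons.
* :func:`selectivity_score` — S = A_a / (A_a + A_b) on rectified evoked
  amplitudes; anchors: 1 = activated only by the reference stimulus, 0 =
  only by the other, 0.5 = equal/non-selective (both-zero convention).
* :func:`baseline_tuning_regression` — OLS of normalized tuning on
  normalized baseline activity (slope, r^2, two-sided p).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import AlignedResponse, SelectivityRecord, TraceMatrix, TuningRecord
from .evoked import baseline_mask_from_events, detect_transient_onsets

__all__ = [
    "baseline_activity",
    "minmax_normalize",
    "tuning_index",
    "selectivity_score",
    "selectivity_from_amplitudes",
    "score_session",
    "baseline_tuning_regression",
]

TI_EPS = 1e-9
MIN_EVENT_FREE_S = 60.0


def baseline_activity(trace: np.ndarray, sampling_rate: float,
                      event_free_mask: np.ndarray, k: float = 3.0,
                      min_duration_s: float = 0.2,
                      zscored: bool = False) -> float:
    """Detected transients per event-free minute; NaN when less than 60 s of
    event-free time is available."""
    event_free_mask = np.asarray(event_free_mask, dtype=bool)
    free_s = event_free_mask.sum() / sampling_rate
    if free_s < MIN_EVENT_FREE_S:
        return float("nan")
    onsets = detect_transient_onsets(trace, sampling_rate, k=k,
                                     min_duration_s=min_duration_s,
                                     baseline_mask=event_free_mask,
                                     zscored=zscored)
    n = int(np.sum(event_free_mask[onsets])) if len(onsets) else 0
    return n / (free_s / 60.0)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max rescaling to [0, 1] over finite entries; rank-preserving.
    Constant input maps to 0.5; NaNs propagate."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    out = np.full_like(v, np.nan)
    if not finite.any():
        return out
    lo, hi = v[finite].min(), v[finite].max()
    if hi == lo:
        out[finite] = 0.5
    else:
        out[finite] = (v[finite] - lo) / (hi - lo)
    return out


def tuning_index(resp: AlignedResponse) -> float:
    """Rectified response/baseline contrast in [-1, 1]; NaN for < 3 bouts."""
    if resp.n_events < 3:
        return float("nan")
    t = resp.window_time()
    base_w = (t >= -resp.pre_s) & (t < 0)
    resp_w = (t >= 0) & (t < resp.response_s)
    mu_resp = float(np.maximum(resp.aligned[:, resp_w], 0.0).mean())
    mu_base = float(np.maximum(resp.aligned[:, base_w], 0.0).mean())
    return (mu_resp - mu_base) / (abs(mu_resp) + abs(mu_base) + TI_EPS)


def selectivity_from_amplitudes(amp_a: float, amp_b: float) -> float:
    """S = A_a / (A_a + A_b) with A = max(0, amplitude); 0.5 when both are
    zero (non-selective by convention)."""
    a, b = max(0.0, float(amp_a)), max(0.0, float(amp_b))
    if a + b == 0.0:
        return 0.5
    return a / (a + b)


def selectivity_score(resp_a: AlignedResponse, resp_b: AlignedResponse) -> SelectivityRecord:
    """Pairwise selectivity of one neuron for stimulus a over stimulus b,
    from rectified evoked amplitudes.  Requires >= 3 bouts of each."""
    if resp_a.n_events < 3 or resp_b.n_events < 3:
        raise ValueError("selectivity requires >= 3 bouts of each stimulus")
    if resp_a.neuron_id != resp_b.neuron_id:
        raise ValueError("aligned responses belong to different neurons")
    s = selectivity_from_amplitudes(resp_a.evoked_amplitude, resp_b.evoked_amplitude)
    return SelectivityRecord(neuron_id=resp_a.neuron_id,
                             stim_a=resp_a.event_label, stim_b=resp_b.event_label,
                             score=s)


def score_session(traces: TraceMatrix, events, stimulus: str,
                  pairs: list[tuple[str, str]] | None = None,
                  pre_s: float = 2.0, post_s: float = 5.0,
                  response_s: float = 3.0,
                  ) -> tuple[list[TuningRecord], list[SelectivityRecord]]:
    """Session-level tuning and selectivity table.

    Computes per-neuron baseline activity (event-free transient rate), the
    tuning index for ``stimulus``, min-max-normalized variants across the
    session's neurons, and — for each (stim_a, stim_b) pair — the pairwise
    selectivity score.
    """
    from .evoked import align, zscore

    if not traces.zscored:
        traces = zscore(traces, events=events)
    free = baseline_mask_from_events(traces.n_samples, traces.sampling_rate, events)
    resp_by_label: dict[str, list[AlignedResponse]] = {}

    def responses(label: str) -> list[AlignedResponse]:
        if label not in resp_by_label:
            resp_by_label[label] = align(traces, events, label, pre_s=pre_s,
                                         post_s=post_s, response_s=response_s)
        return resp_by_label[label]

    ti = np.array([tuning_index(r) for r in responses(stimulus)]) \
        if responses(stimulus) else np.full(traces.n_neurons, np.nan)
    ba = np.array([baseline_activity(traces.traces[i], traces.sampling_rate, free,
                                     zscored=traces.zscored)
                   for i in range(traces.n_neurons)])
    ti_n, ba_n = minmax_normalize(ti), minmax_normalize(ba)
    records = [
        TuningRecord(neuron_id=traces.neuron_ids[i], stimulus=stimulus,
                     tuning_index=float(ti[i]), tuning_index_normalized=float(ti_n[i]),
                     baseline_activity=float(ba[i]),
                     baseline_activity_normalized=float(ba_n[i]))
        for i in range(traces.n_neurons)
    ]
    sel: list[SelectivityRecord] = []
    for a, b in pairs or []:
        ra, rb = responses(a), responses(b)
        if not ra or not rb:
            continue
        for i in range(traces.n_neurons):
            try:
                sel.append(selectivity_score(ra[i], rb[i]))
            except ValueError:
                continue
    return records, sel


def baseline_tuning_regression(records: list[TuningRecord]
                               ) -> tuple[float, float, float]:
    """OLS of normalized tuning index on normalized baseline activity.

    Returns (slope, r_squared, p_value); requires >= 3 neurons with both
    quantities defined and non-degenerate predictor variance.
    """
    x = np.array([r.baseline_activity_normalized for r in records])
    y = np.array([r.tuning_index_normalized for r in records])
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 neurons with defined values")
    if np.std(x[ok]) == 0:
        raise ValueError("zero variance in the predictor")
    res = stats.linregress(x[ok], y[ok])
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
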