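"""Behavioral-sequence analytics: per-assay bout metrics, bout-level
transition matrices with between-group edge tests, and retrieval-latency
survival analysis.

Transition matrices are bout-level: consecutive identical labels are merged
first, so self-transitions are impossible and every row with at least one
outgoing transition is a probability vector.  Group comparisons use a
two-sided Mann-Whitney U test per edge on per-animal transition
probabilities (exact null for n <= 8 per group), flagged at raw p < alpha
by default with an optional Benjamini-Hochberg switch.  Latency analysis is
Kaplan-Meier with right-censoring at assay end and a log-rank test across
groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BehaviorSummary, EventTable, TransitionMatrix

__all__ = [
    "merge_bouts",
    "summarize_assay",
    "transition_matrix",
    "mean_transition_matrix",
    "compare_transition_groups",
    "km_survival",
]

PUP_CONTACT_LABELS = ("sniff", "retrieve", "groom", "crouch")
EXACT_U_MAX_N = 8


def merge_bouts(events: EventTable) -> EventTable:
    """Merge runs of consecutive identical labels (per actor order as
    given) into single bouts spanning first onset to last offset."""
    df = events.df
    if len(df) < 2:
        return events
    rows = []
    cur = df.iloc[0].copy()
    for _, row in df.iloc[1:].iterrows():
        if row["label"] == cur["label"] and row["actor"] == cur["actor"]:
            cur["offset_s"] = row["offset_s"]
        else:
            rows.append(cur)
            cur = row.copy()
    rows.append(cur)
    return EventTable(df=pd.DataFrame(rows), meta=dict(events.meta),
                      ground_truth=dict(events.ground_truth))


def summarize_assay(events: EventTable,
                    retrieval_label: str = "retrieve",
                    crouch_label: str = "crouch",
                    nest_labels: tuple[str, ...] = ("nest_enter", "nest_build"),
                    contact_labels: tuple[str, ...] = PUP_CONTACT_LABELS,
                    ) -> BehaviorSummary:
    """Per-assay parental-behavior metrics.

    Retrieval latency = onset of the first retrieval bout, right-censored
    at assay end when absent; crouch and nest-time fractions are total bout
    time over assay duration; contact latency = first pup-directed bout
    onset.
    """
    dur = events.assay_duration_s
    if dur is None:
        dur = float(events.df["offset_s"].max()) if len(events) else 0.0
    if dur <= 0:
        raise ValueError("zero-duration assay")
    df = events.df

    def first_onset(labels: tuple[str, ...]) -> tuple[float, bool]:
        sel = df[df["label"].isin(labels)]
        if len(sel) == 0:
            return float(dur), True
        return float(sel["onset_s"].min()), False

    lat, lat_cens = first_onset((retrieval_label,))
    contact, contact_cens = first_onset(contact_labels)

    def time_fraction(labels: tuple[str, ...]) -> float:
        sel = df[df["label"].isin(labels)]
        return float((sel["offset_s"] - sel["onset_s"]).sum() / dur)

    return BehaviorSummary(
        animal_id=str(events.meta.get("animal_id", "")),
        timepoint=str(events.meta.get("timepoint", "")),
        assay_duration_s=float(dur),
        retrieval_latency_s=lat, retrieval_censored=lat_cens,
        crouch_fraction=time_fraction((crouch_label,)),
        nest_time_fraction=time_fraction(nest_labels),
        contact_latency_s=contact, contact_censored=contact_cens,
    )


def transition_matrix(events: EventTable,
                      behaviors: list[str] | None = None,
                      min_count: int = 0) -> TransitionMatrix:
    """Bout-level transition counts and row-normalized probabilities.

    Consecutive identical labels are merged first.  ``behaviors`` fixes the
    matrix universe (default: labels observed in this table, in order of
    first appearance); ``min_count`` drops behaviors with fewer total bouts.
    Rows with no outgoing transition are left all-zero and flagged.
    """
    merged = merge_bouts(events)
    seq = list(merged.df["label"])
    if len(seq) < 2:
        raise ValueError("need >= 2 bouts for a transition matrix")
    if behaviors is None:
        behaviors = list(dict.fromkeys(seq))
    if min_count > 0:
        keep = {b for b in behaviors if seq.count(b) >= min_count}
        behaviors = [b for b in behaviors if b in keep]
        seq = [s for s in seq if s in keep]
        # re-merge after filtering may create identical neighbors; collapse
        seq = [s for i, s in enumerate(seq) if i == 0 or s != seq[i - 1]]
    index = {b: i for i, b in enumerate(behaviors)}
    k = len(behaviors)
    counts = np.zeros((k, k))
    for a, b in zip(seq[:-1], seq[1:]):
        if a in index and b in index:
            counts[index[a], index[b]] += 1
    out = counts.sum(axis=1)
    P = np.zeros_like(counts)
    nz = out > 0
    P[nz] = counts[nz] / out[nz, None]
    return TransitionMatrix(behaviors=list(behaviors), counts=counts, P=P,
                            animal_id=str(events.meta.get("animal_id", "")),
                            timepoint=str(events.meta.get("timepoint", "")),
                            zero_rows=~nz)


def mean_transition_matrix(mats: list[TransitionMatrix],
                           behaviors: list[str]) -> np.ndarray:
    """Average per-animal P over a group on a common behavior universe;
    missing behaviors contribute zero probability."""
    acc = np.zeros((len(behaviors), len(behaviors)))
    for m in mats:
        P = _expand(m, behaviors)
        acc += P
    return acc / max(len(mats), 1)


def _expand(m: TransitionMatrix, behaviors: list[str]) -> np.ndarray:
    P = np.zeros((len(behaviors), len(behaviors)))
    for i, a in enumerate(m.behaviors):
        if a not in behaviors:
            continue
        for j, b in enumerate(m.behaviors):
            if b in behaviors:
                P[behaviors.index(a), behaviors.index(b)] = m.P[i, j]
    return P


def compare_transition_groups(group_a: list[TransitionMatrix],
                              group_b: list[TransitionMatrix],
                              alpha: float = 0.05,
                              bh_correct: bool = False) -> pd.DataFrame:
    """Per-edge two-sided Mann-Whitney U comparison of per-animal transition
    probabilities between two groups.

    Uses the exact U null when both groups have n <= 8 animals, the
    tie-corrected normal approximation otherwise.  Edges absent (zero
    probability) in every animal of both groups are skipped and listed with
    status "absent".  Returns a DataFrame with columns src, dst, U, p,
    flagged, status; ``bh_correct`` applies Benjamini-Hochberg across tested
    edges before flagging (off by default).
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("need >= 3 animals per group")
    behaviors = list(dict.fromkeys(
        [b for m in list(group_a) + list(group_b) for b in m.behaviors]))
    Pa = np.stack([_expand(m, behaviors) for m in group_a])
    Pb = np.stack([_expand(m, behaviors) for m in group_b])
    method = "exact" if max(len(group_a), len(group_b)) <= EXACT_U_MAX_N else "asymptotic"
    rows = []
    for i, src in enumerate(behaviors):
        for j, dst in enumerate(behaviors):
            if i == j:
                continue
            xa, xb = Pa[:, i, j], Pb[:, i, j]
            if np.all(xa == 0) and np.all(xb == 0):
                rows.append({"src": src, "dst": dst, "U": np.nan, "p": np.nan,
                             "flagged": False, "status": "absent"})
                continue
            # exact method is undefined under ties; fall back per edge
            m = method
            if m == "exact" and (len(np.unique(np.concatenate([xa, xb])))
                                 < len(xa) + len(xb)):
                m = "asymptotic"
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=m)
            rows.append({"src": src, "dst": dst, "U": float(res.statistic),
                         "p": float(res.pvalue), "flagged": False,
                         "status": "ok"})
    df = pd.DataFrame(rows)
    tested = df["status"] == "ok"
    pvals = df.loc[tested, "p"].to_numpy()
    if bh_correct and len(pvals):
        order = np.argsort(pvals)
        ranked = np.empty_like(pvals)
        n = len(pvals)
        adj = pvals[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        ranked[order] = np.minimum(adj, 1.0)
        df.loc[tested, "p_adjusted"] = ranked
        df.loc[tested, "flagged"] = ranked < alpha
    else:
        df.loc[tested, "flagged"] = pvals < alpha
    return df


def km_survival(durations, observed, groups=None):
    """Kaplan-Meier survival curves with a log-rank test across groups.

    ``durations`` are latencies (s), ``observed`` marks uncensored
    observations (False = right-censored at assay end), ``groups`` an
    optional per-observation group label.  Returns
    ``(curves, statistic, p)`` with ``curves`` a dict mapping group label to
    a DataFrame with columns ``time`` and ``survival``.  With every
    observation censored in every group the statistic is NaN but curves are
    still returned; with a single group no test is run.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if groups is None:
        groups = np.zeros(len(durations), dtype=int)
    groups = np.asarray(groups)
    if len(durations) == 0:
        raise ValueError("no observations")

    curves = {}
    for g in pd.unique(groups):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(durations[sel], event_observed=observed[sel])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                                  "survival": sf.iloc[:, 0].to_numpy()})
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        return curves, float("nan"), float("nan")
    if not observed.any():
        return curves, float("nan"), float("nan")
    if len(uniq) == 2:
        a, b = (groups == uniq[0], groups == uniq[1])
        res = logrank_test(durations[a], durations[b],
                           event_observed_A=observed[a],
                           event_observed_B=observed[b])
    else:
        res = multivariate_logrank_test(durations, groups, observed)
    return curves, float(res.test_statistic), float(res.p_value)
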