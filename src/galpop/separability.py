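"""Stimulus separability of population activity in LDA space.

Pipeline: bout-aligned temporal-bin features -> shrinkage LDA projection to
C-1 dimensions -> k-means partition (k = number of stimuli, 50 restarts,
fixed seed) -> Rand index between the bout-stimulus labels and the cluster
labels.  Per-stimulus 95% confidence ellipsoids are chi-square quantile
contours of the Gaussian fitted to each class in the embedding.

Sample definition (default ``sample_mode="neuron_bouts"``): one sample per
(neuron, bout), features = that neuron's mean Z per temporal bin over the
bout-aligned window.  ``sample_mode="population_bins"`` instead treats each
(bout, bin) population vector as a sample with one feature per neuron.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .datatypes import BoutFeatureMatrix, EventTable, SeparabilityResult, TraceMatrix

__all__ = [
    "build_features",
    "fit_lda",
    "confidence_ellipsoid",
    "points_inside_ellipsoid",
    "rand_index",
    "rand_index_bruteforce",
    "separability",
    "separability_vs_sparseness",
]


def build_features(traces: TraceMatrix, events: EventTable, stimuli: list[str],
                   window_s: float = 4.0, bin_width_s: float = 0.5,
                   sample_mode: str = "neuron_bouts") -> BoutFeatureMatrix:
    """Temporal-bin feature matrix over the bout-aligned window [0, window_s).

    Requires >= 2 stimuli with >= 3 usable bouts each.  Bouts whose window
    extends past the recording are dropped and counted.
    """
    if len(stimuli) < 2:
        raise ValueError("need >= 2 stimuli")
    from .evoked import zscore
    if not traces.zscored:
        traces = zscore(traces, events=events)
    fs = traces.sampling_rate
    n_bins = int(round(window_s / bin_width_s))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    bin_len = int(round(bin_width_s * fs))
    dropped = 0
    bout_slices: list[tuple[str, int, int]] = []  # (label, bout_id, start idx)
    bout_id = 0
    for s in stimuli:
        for t in events.onsets(s):
            i0 = int(round(t * fs))
            if i0 < 0 or i0 + n_bins * bin_len > traces.n_samples:
                dropped += 1
                continue
            bout_slices.append((s, bout_id, i0))
            bout_id += 1
    labels_per_bout = [s for s, _, _ in bout_slices]
    for s in stimuli:
        if labels_per_bout.count(s) < 3:
            raise ValueError(f"stimulus {s!r} has fewer than 3 usable bouts")

    # per-bout neuron x bin mean-Z tensor
    binned = np.empty((len(bout_slices), traces.n_neurons, n_bins))
    for b, (_, _, i0) in enumerate(bout_slices):
        seg = traces.traces[:, i0:i0 + n_bins * bin_len]
        binned[b] = seg.reshape(traces.n_neurons, n_bins, bin_len).mean(axis=2)

    if sample_mode == "neuron_bouts":
        X = binned.transpose(1, 0, 2).reshape(traces.n_neurons * len(bout_slices), n_bins)
        labels = np.tile(labels_per_bout, traces.n_neurons)
        neuron_of = np.repeat(traces.neuron_ids, len(bout_slices))
        bout_of = np.tile([b for _, b, _ in bout_slices], traces.n_neurons)
    elif sample_mode == "population_bins":
        # one sample per (bout, bin); features = neurons
        X = binned.transpose(0, 2, 1).reshape(len(bout_slices) * n_bins,
                                              traces.n_neurons)
        labels = np.repeat(labels_per_bout, n_bins)
        neuron_of = np.full(X.shape[0], -1)
        bout_of = np.repeat([b for _, b, _ in bout_slices], n_bins)
    else:
        raise ValueError(f"unknown sample_mode {sample_mode!r}")
    return BoutFeatureMatrix(X=X, labels=labels, bin_width_s=bin_width_s,
                             window=(0.0, window_s), neuron_of_sample=neuron_of,
                             bout_of_sample=bout_of, n_dropped_bouts=dropped,
                             sample_mode=sample_mode)


def fit_lda(features: BoutFeatureMatrix, shrinkage: float | str = "auto",
            ) -> tuple[np.ndarray, LinearDiscriminantAnalysis]:
    """Shrinkage LDA projection to C-1 dimensions.

    Within-class scatter is shrunk toward its diagonal (Ledoit-Wolf when
    ``shrinkage="auto"``), keeping the fit well-posed when samples are
    scarce relative to features.  Deterministic; each axis's sign is fixed
    so that its largest-magnitude loading is positive.
    """
    classes = features.classes
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    for c in classes:
        if np.sum(features.labels == c) < 2:
            raise ValueError("every class needs >= 2 samples")
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)
    lda.fit(features.X, features.labels)
    emb = lda.transform(features.X)[:, : len(classes) - 1]
    scal = lda.scalings_[:, : emb.shape[1]]
    for j in range(emb.shape[1]):
        k = int(np.argmax(np.abs(scal[:, j])))
        if scal[k, j] < 0:
            emb[:, j] = -emb[:, j]
    return emb, lda


def confidence_ellipsoid(points: np.ndarray, level: float = 0.95,
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian confidence ellipsoid of a point cloud.

    Returns (center, covariance, radius) with the ellipsoid
    {x : (x-mu)' Sigma^-1 (x-mu) <= radius}, radius the chi-square quantile
    at ``level`` with dim degrees of freedom.  A singular covariance gets a
    small ridge.  Requires >= dim+1 points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = pts.shape
    if n < d + 1:
        raise ValueError("need at least dim+1 points")
    center = pts.mean(axis=0)
    cov = np.atleast_2d(np.cov(pts, rowvar=False))
    if np.linalg.matrix_rank(cov) < d:
        cov = cov + 1e-9 * max(np.trace(cov), 1.0) / d * np.eye(d)
    radius = float(stats.chi2.ppf(level, df=d)) if level > 0 else 0.0
    return center, cov, radius


def points_inside_ellipsoid(points: np.ndarray, center: np.ndarray,
                            cov: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of points with squared Mahalanobis distance <= radius."""
    pts = np.atleast_2d(points) - center
    sol = np.linalg.solve(np.atleast_2d(cov), pts.T)
    return np.einsum("ij,ji->i", pts, sol) <= radius


def rand_index(labels_true, labels_pred) -> float:
    """Rand index: fraction of sample pairs on which two partitions agree
    (grouped together in both, or apart in both).  Invariant to label
    renaming; defined for n >= 2."""
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("rand index requires n >= 2")
    # pair counts from the contingency table
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)
    sum_ij = sum(comb(int(x), 2) for x in cont.ravel())
    sum_a = sum(comb(int(x), 2) for x in cont.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in cont.sum(axis=0))
    total = comb(n, 2)
    together = sum_ij
    apart = total + sum_ij - sum_a - sum_b
    return (together + apart) / total


def rand_index_bruteforce(labels_true, labels_pred) -> float:
    """Direct O(n^2) pair enumeration; independent oracle for rand_index."""
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    n = len(a)
    if n < 2:
        raise ValueError("rand index requires n >= 2")
    agree = 0
    for i, j in combinations(range(n), 2):
        if (a[i] == a[j]) == (b[i] == b[j]):
            agree += 1
    return agree / comb(n, 2)


def separability(traces: TraceMatrix, events: EventTable, stimuli: list[str],
                 window_s: float = 4.0, bin_width_s: float = 0.5,
                 sample_mode: str = "neuron_bouts",
                 shrinkage: float | str = "auto", level: float = 0.95,
                 n_restarts: int = 50, seed: int = 0) -> SeparabilityResult:
    """Full separability pipeline for one stimulus set.

    build_features -> fit_lda -> k-means (k = #stimuli, ``n_restarts``
    restarts, fixed seed) -> Rand index of the k-means partition against
    the bout-stimulus labels, plus per-stimulus confidence ellipsoids.
    """
    feats = build_features(traces, events, stimuli, window_s=window_s,
                           bin_width_s=bin_width_s, sample_mode=sample_mode)
    emb, _ = fit_lda(feats, shrinkage=shrinkage)
    km = KMeans(n_clusters=len(feats.classes), n_init=n_restarts,
                random_state=seed)
    pred = km.fit_predict(emb)
    ri = rand_index(feats.labels, pred)
    ellipsoids = {}
    for s in feats.classes:
        pts = emb[feats.labels == s]
        if len(pts) >= emb.shape[1] + 1:
            ellipsoids[str(s)] = confidence_ellipsoid(pts, level=level)
    return SeparabilityResult(
        stimulus_set=list(stimuli), embedding=emb, labels=feats.labels,
        cluster_labels=pred, ellipsoids=ellipsoids, rand_index=float(ri),
        n_samples=feats.n_samples,
        config={"window_s": window_s, "bin_width_s": bin_width_s,
                "sample_mode": sample_mode, "shrinkage": shrinkage,
                "level": level, "n_restarts": n_restarts, "seed": seed},
    )


def separability_vs_sparseness(rand_indices, activated_fractions,
                               ) -> tuple[float, float, float]:
    """Least-squares regression of Rand index on activated fraction across
    sessions; returns (slope, r_squared, p)."""
    x = np.asarray(activated_fractions, dtype=float)
    y = np.asarray(rand_indices, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 sessions with both quantities")
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        raise ValueError("degenerate variance")
    res = stats.linregress(x[ok], y[ok])
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
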