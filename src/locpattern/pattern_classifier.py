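"""Bootstrap + k-medoids classification of localization-response patterns.

The idea: a listener's localization pattern is summarized as a 38-value
feature vector (19 per-angle response means followed by 19 per-angle SDs,
degrees). The listener is then clustered *jointly* with 1000 simulated
subjects — 50 bootstrap draws from each of the 20 pattern categories, each
with the same 15 repetitions per angle as the experiment — using
partitioning around medoids (PAM) with k = 20 on Euclidean distances. The
listener inherits the modal ground-truth category of the simulated subjects
sharing their cluster. Because a single run depends on one random reference
cohort, the whole procedure is repeated (50 runs by default) with freshly
simulated cohorts; the histogram of run assignments measures reliability and
its mode is the final category.

PAM here is the classical deterministic BUILD + SWAP algorithm on the full
distance matrix: BUILD greedily seeds k medoids, SWAP repeatedly applies the
single (medoid, non-medoid) exchange that most reduces the total
point-to-medoid distance until no exchange improves it. All swap deltas of
one pass are evaluated in O(n^2) with vectorized bookkeeping of each point's
nearest and second-nearest medoid, which is exactly the classical steepest
descent, just fast enough to rerun hundreds of times.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_model import ListenerSummary
from .synthetic_data import CategorySpec, simulate_reference_features, stock_categories

#: Label returned when a listener lands in a cluster with no simulated members.
UNCLASSIFIABLE = "unclassifiable-singleton"


@dataclass
class PamResult:
    """Medoid indices, point-to-medoid assignment, and total cost."""

    medoids: np.ndarray          # (k,) indices into the input points
    labels: np.ndarray           # (n,) index into ``medoids`` for each point
    cost: float                  # sum of distances to assigned medoids
    n_swaps: int
    cost_trace: list[float]      # cost after BUILD and after each swap


def _build(D: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD phase: each new medoid maximally reduces total distance.

    Gain ties go to the highest-index candidate, matching the reference
    implementation's scan order (R's cluster::pam).
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        m = n - 1 - int(np.argmax(gain[::-1]))
        medoids.append(m)
        d_near = np.minimum(d_near, D[m])
    return np.asarray(medoids)


def _nearest_two(D: np.ndarray, medoids: np.ndarray):
    """Each point's nearest and second-nearest medoid (index-into-medoids)."""
    sub = D[medoids]                       # (k, n)
    order = np.argsort(sub, axis=0, kind="stable")
    i1 = order[0]                          # nearest medoid, per point
    d1 = sub[i1, np.arange(D.shape[0])]
    if len(medoids) > 1:
        i2 = order[1]
        d2 = sub[i2, np.arange(D.shape[0])]
    else:
        d2 = np.full(D.shape[0], np.inf)
    return i1, d1, d2


def pam(
    points: np.ndarray,
    k: int,
    *,
    precomputed: bool = False,
    max_swaps: int = 10_000,
) -> PamResult:
    """Classical PAM (BUILD + steepest-descent SWAP) on Euclidean distances.

    ``points`` is an (n, p) feature array, or an (n, n) distance matrix when
    ``precomputed=True``. Deterministic given input order; ties in BUILD and
    SWAP break toward the lowest index. The returned configuration is a local
    minimum under single-medoid exchanges, and the recorded ``cost_trace`` is
    strictly decreasing.
    """
    X = np.asarray(points, dtype=float)
    D = X if precomputed else cdist(X, X)
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds number of points n = {n}")
    if k < 1:
        raise ValueError("k must be >= 1")

    medoids = _build(D, k)
    i1, d1, d2 = _nearest_two(D, medoids)
    cost = float(d1.sum())
    trace = [cost]
    n_swaps = 0

    onehot = np.zeros((n, k))
    while n_swaps < max_swaps and k < n:
        non = np.setdiff1d(np.arange(n), medoids, assume_unique=False)
        # Delta in total cost for swapping medoid i with candidate o, for all
        # (o, i) at once. "shared" is the gain every point j would get from o
        # regardless of which medoid leaves; the correction term handles
        # points currently assigned to the leaving medoid.
        shared = np.minimum(D[non] - d1[None, :], 0.0)        # (m, n)
        correction = np.minimum(D[non], d2[None, :]) - d1[None, :] - shared
        onehot[:] = 0.0
        onehot[np.arange(n), i1] = 1.0
        delta = shared.sum(axis=1)[:, None] + correction @ onehot  # (m, k)

        o_idx, i_idx = np.unravel_index(np.argmin(delta), delta.shape)
        best_delta = delta[o_idx, i_idx]
        if best_delta >= -1e-12:
            break
        medoids = medoids.copy()
        medoids[i_idx] = non[o_idx]
        i1, d1, d2 = _nearest_two(D, medoids)
        new_cost = float(d1.sum())
        assert new_cost <= cost + 1e-9, "SWAP must never increase cost"
        cost = new_cost
        trace.append(cost)
        n_swaps += 1

    return PamResult(medoids, i1, cost, n_swaps, trace)


# ---------------------------------------------------------------------------
# Bootstrap classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    """Category assignments of one listener over repeated bootstrap runs."""

    subject_code: str
    run_assignments: list[str]
    reliability: Counter        # category label -> number of runs
    final_category: str
    n_runs: int


def _modal_category(
    labels_in_cluster: list[str], dists_in_cluster: np.ndarray
) -> str:
    """Mode of the simulated labels; ties go to the tied category whose
    members sit closest (smallest mean distance) to the listener."""
    counts = Counter(labels_in_cluster)
    top = max(counts.values())
    tied = sorted(lab for lab, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    arr = np.asarray(labels_in_cluster)
    mean_dist = {
        lab: float(dists_in_cluster[arr == lab].mean()) for lab in tied
    }
    return min(tied, key=lambda lab: (mean_dist[lab], lab))


def classify_once(
    listener: ListenerSummary,
    reference_features: np.ndarray,
    reference_labels: Sequence[str],
    k: int = 20,
    *,
    standardize: bool = False,
) -> str:
    """One bootstrap classification run against a labeled reference cohort.

    The listener's feature vector is appended to the reference cohort's
    (n_ref, 38) feature matrix, the n_ref + 1 points are clustered with
    ``pam(..., k)``, and the modal ground-truth label of the simulated
    subjects in the listener's cluster is returned. ``standardize`` optionally
    z-scores each feature across the joint matrix before clustering (off by
    default: means and SDs already share degree units).
    """
    feats = np.vstack([reference_features, listener.feature_vector()])
    if standardize:
        sd = feats.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        feats = (feats - feats.mean(axis=0)) / sd
    result = pam(feats, k)
    me = feats.shape[0] - 1
    members = np.flatnonzero(result.labels == result.labels[me])
    members = members[members != me]
    if members.size == 0:
        warnings.warn(
            f"listener {listener.subject_code} formed a singleton cluster",
            stacklevel=2,
        )
        return UNCLASSIFIABLE
    labels = [reference_labels[m] for m in members]
    dists = np.linalg.norm(feats[members] - feats[me], axis=1)
    return _modal_category(labels, dists)


def classify(
    listener: ListenerSummary,
    n_runs: int = 50,
    *,
    n_per_category: int = 50,
    reps: int = 15,
    k: int = 20,
    categories: Sequence[CategorySpec] | None = None,
    rng: np.random.Generator | int | None = None,
    standardize: bool = False,
) -> ClassificationResult:
    """Full bootstrap classification with a reliability histogram.

    Runs :func:`classify_once` ``n_runs`` times, each against a freshly
    simulated reference cohort whose seed is drawn from the master ``rng``;
    the final category is the mode of the run assignments. A tie in the mode
    is resolved by the assignment of the highest-numbered run among the tied
    categories, then lexicographically — deterministic either way.
    """
    cats = list(categories) if categories is not None else stock_categories()
    master = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    assignments = []
    for _ in range(n_runs):
        child = np.random.default_rng(master.integers(0, 2**63))
        feats, labels = simulate_reference_features(
            n_per_category, reps, child, cats, angle_grid=listener.angle_grid
        )
        assignments.append(
            classify_once(listener, feats, labels, k, standardize=standardize)
        )
    reliability = Counter(assignments)
    top = max(reliability.values())
    tied = sorted(lab for lab, c in reliability.items() if c == top)
    if len(tied) == 1:
        final = tied[0]
    else:
        last_tied = max(i for i, a in enumerate(assignments) if a in tied)
        final = assignments[last_tied]
    return ClassificationResult(
        listener.subject_code, assignments, reliability, final, n_runs
    )


def classify_dataset(
    summaries: Sequence[ListenerSummary],
    n_runs: int = 50,
    rng: np.random.Generator | int | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify many listeners; returns (categories, reliability) tables.

    ``categories`` has one row per listener (subject, final mean/SD shape);
    ``reliability`` is the long-format histogram (subject, mean_shape,
    sd_shape, count).
    """
    master = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    cat_rows, rel_rows = [], []
    for summary in summaries:
        res = classify(summary, n_runs, rng=master, **kwargs)
        mean_shape, sd_shape = _split_label(res.final_category)
        cat_rows.append(
            {
                "subject": res.subject_code,
                "final_category": res.final_category,
                "mean_shape": mean_shape,
                "sd_shape": sd_shape,
                "n_runs": res.n_runs,
            }
        )
        for lab, count in sorted(res.reliability.items()):
            m, s = _split_label(lab)
            rel_rows.append(
                {"subject": res.subject_code, "mean_shape": m, "sd_shape": s,
                 "count": count}
            )
    return pd.DataFrame(cat_rows), pd.DataFrame(rel_rows)


def _split_label(label: str) -> tuple[str, str]:
    if label == UNCLASSIFIABLE:
        return UNCLASSIFIABLE, UNCLASSIFIABLE
    mean_shape, sd_shape = label.split(",")
    return mean_shape, sd_shape


def group_contingency(
    categories: pd.DataFrame,
    factors: pd.DataFrame,
    margin: str = "sd_ideal_vs_other",
) -> np.ndarray:
    """2x2 counts of ideal-vs-other category membership by onset group.

    Rows are onset groups ordered (late, early); columns are (ideal, other)
    on the chosen margin: ``sd_ideal_vs_other`` collapses the 20 categories
    by whether the SD shape is Ideal (any mean shape), ``mean_ideal_vs_other``
    symmetrically for the mean shape. Listeners with the unclassifiable label
    are excluded (their count is warned about).
    """
    if margin == "sd_ideal_vs_other":
        col = "sd_shape"
    elif margin == "mean_ideal_vs_other":
        col = "mean_shape"
    else:
        raise ValueError(f"unknown margin {margin!r}")
    merged = categories.merge(
        factors[["subject", "onset_group"]], on="subject", how="left"
    )
    n_unclass = int((merged["final_category"] == UNCLASSIFIABLE).sum())
    if n_unclass:
        warnings.warn(f"excluding {n_unclass} unclassifiable listener(s)",
                      stacklevel=2)
        merged = merged[merged["final_category"] != UNCLASSIFIABLE]
    if merged["onset_group"].isna().any():
        missing = merged.loc[merged["onset_group"].isna(), "subject"].tolist()
        raise ValueError(f"no onset group for subject(s) {missing}")
    table = np.zeros((2, 2), dtype=int)
    for i, group in enumerate(("late", "early")):
        sub = merged[merged["onset_group"] == group]
        ideal = int((sub[col] == "Ideal").sum())
        table[i] = (ideal, len(sub) - ideal)
    return table
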