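"""Localization error metrics: RMS error and the localization sensitivity index.

RMS error is the workhorse of the localization literature — the root mean
squared deviation of response from target angle, reported overall and per
target angle (the per-angle values, natural-log transformed, feed the
mixed-effects regression). The localization sensitivity index (LSI)
summarizes how well *separated* the response distributions at different
target angles are: for every unordered pair of target angles a Kruskal-Wallis
rank statistic compares the two response samples, its p-value is converted to
a z-score, and the LSI is the mean z over all C(19,2) = 171 pairs. An LSI
near zero means responses overlap regardless of where the sound came from;
large values mean well-separated (discriminable) responses, akin to an
average d-prime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import LocalizationDataset

#: Per-angle RMS of exactly zero is replaced by this value (degrees) before
#: the log transform; real response data never achieves zero error.
LOG_RMS_EPSILON = 1e-3


@dataclass
class RmsResult:
    """Overall and per-angle RMS error (degrees) plus the log-transformed values."""

    overall_rms: float
    per_angle_rms: np.ndarray
    log_per_angle_rms: np.ndarray
    angle_grid: np.ndarray


@dataclass
class LsiResult:
    """Localization sensitivity index and its per-pair z-scores."""

    lsi: float
    pairwise_z: np.ndarray  # upper triangle over angle pairs, grid order
    angle_pairs: list[tuple[float, float]]


def rms_error(trials: pd.DataFrame, angle_grid: np.ndarray | None = None) -> RmsResult:
    """RMS error for one subject's trial table.

    ``per_angle_rms[i]`` is the RMS of (response - target) over the
    repetitions at grid angle ``i``; ``overall_rms`` pools all trials. With
    equal repetitions per angle the identity
    ``overall_rms**2 == mean(per_angle_rms**2)`` holds exactly. When
    ``angle_grid`` is omitted the angles present in the trials are used.
    """
    if angle_grid is None:
        angle_grid = np.sort(trials["target_deg"].unique())
    grid = np.asarray(angle_grid, dtype=float)
    per_angle = np.empty(len(grid))
    for i, angle in enumerate(grid):
        resp = trials.loc[trials["target_deg"] == angle, "response_deg"].to_numpy()
        if resp.size == 0:
            raise ValueError(f"no trials at angle {angle:g}")
        per_angle[i] = np.sqrt(np.mean((resp - angle) ** 2))
    err = trials["response_deg"].to_numpy() - trials["target_deg"].to_numpy()
    overall = float(np.sqrt(np.mean(err**2)))
    safe = per_angle.copy()
    if np.any(safe == 0.0):
        warnings.warn(
            "per-angle RMS of 0 encountered; log transform uses "
            f"ln({LOG_RMS_EPSILON}) for those angles",
            stacklevel=2,
        )
        safe[safe == 0.0] = LOG_RMS_EPSILON
    return RmsResult(overall, per_angle, np.log(safe), grid)


def _pair_z(
    x: np.ndarray,
    y: np.ndarray,
    convention: str,
    p_method: str = "asymptotic",
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Kruskal-Wallis z for one angle pair under the chosen p-to-z convention."""
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 0.0  # H = 0, p = 1 by convention; scipy would raise
    h, p = stats.kruskal(x, y)
    if p_method == "permutation":
        # Monte-Carlo permutation reference for H; useful at small n where
        # the chi-square(1) approximation is coarse.
        gen = rng if rng is not None else np.random.default_rng(0)
        pooled = np.concatenate([x, y])
        count = 1
        for _ in range(n_perm):
            perm = gen.permutation(pooled)
            hp, _ = stats.kruskal(perm[: x.size], perm[x.size:])
            count += hp >= h - 1e-12
        p = count / (n_perm + 1)
    elif p_method != "asymptotic":
        raise ValueError(f"unknown p method {p_method!r}")
    if convention == "positive":
        return float(max(0.0, stats.norm.isf(p)))
    if convention == "two_sided":
        return float(stats.norm.isf(p / 2.0))
    raise ValueError(f"unknown p-to-z convention {convention!r}")


def lsi(
    trials: pd.DataFrame,
    angle_grid: np.ndarray,
    *,
    convention: str = "positive",
    p_method: str = "asymptotic",
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
) -> LsiResult:
    """Localization sensitivity index for one subject.

    For each of the C(n_angles, 2) unordered target-angle pairs, the two
    response samples are compared with the tie-corrected Kruskal-Wallis
    statistic (chi-square(1) reference distribution); the p-value is mapped
    to a z-score and the LSI is the mean z over pairs.

    ``convention`` selects the p-to-z mapping: ``"positive"`` (default) takes
    the one-sided survival quantile ``z = Phi^{-1}(1 - p)`` floored at 0, so
    every pair contributes non-negatively and a null pair contributes ~0.4 on
    average; ``"two_sided"`` maps ``p`` to ``Phi^{-1}(1 - p/2)`` (always
    positive, larger under the null). The choice shifts the absolute scale of
    the index, not its ordering of listeners.
    """
    grid = np.asarray(angle_grid, dtype=float)
    groups = {
        a: trials.loc[trials["target_deg"] == a, "response_deg"].to_numpy()
        for a in grid
    }
    for a, resp in groups.items():
        if resp.size < 2:
            raise ValueError(f"need >=2 trials per angle (angle {a:g})")
    zs, pairs = [], []
    for a, b in combinations(grid, 2):
        zs.append(_pair_z(groups[a], groups[b], convention, p_method, n_perm, rng))
        pairs.append((a, b))
    z = np.asarray(zs)
    return LsiResult(float(z.mean()), z, pairs)


def metric_battery(
    dataset: LocalizationDataset, *, convention: str = "positive"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both metrics for every subject in a dataset.

    Returns ``(summary, long)``: one summary row per subject with
    ``overall_rms`` and ``lsi``, and a long table with one row per subject x
    angle carrying ``per_angle_rms``, ``log_rms`` and ``sta`` (squared target
    angle) ready for the mixed model. Per-subject failures are recorded in the
    summary's ``error`` column instead of aborting the batch.
    """
    summary_rows, long_frames = [], []
    for code in dataset.subjects:
        sub = dataset.for_subject(code)
        try:
            rms = rms_error(sub, dataset.angle_grid)
            sens = lsi(sub, dataset.angle_grid, convention=convention)
        except Exception as exc:  # propagate per-subject, keep the batch
            summary_rows.append(
                {"subject": code, "overall_rms": np.nan, "lsi": np.nan,
                 "error": str(exc)}
            )
            continue
        summary_rows.append(
            {"subject": code, "overall_rms": rms.overall_rms, "lsi": sens.lsi,
             "error": ""}
        )
        long_frames.append(
            pd.DataFrame(
                {
                    "subject": code,
                    "target_deg": rms.angle_grid,
                    "sta": rms.angle_grid**2,
                    "per_angle_rms": rms.per_angle_rms,
                    "log_rms": rms.log_per_angle_rms,
                }
            )
        )
    summary = pd.DataFrame(summary_rows)
    long = (
        pd.concat(long_frames, ignore_index=True)
        if long_frames
        else pd.DataFrame(
            columns=["subject", "target_deg", "sta", "per_angle_rms", "log_rms"]
        )
    )
    return summary, long
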