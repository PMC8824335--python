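"""Generative models of localization-response patterns.

The pattern classifier works by comparing a real listener against subjects
*simulated* from a taxonomy of 20 response-pattern categories: 5 shapes of the
per-angle response mean (Ideal, Flat, Compressed, BiasedLeft, BiasedRight)
crossed with 4 shapes of the per-angle response SD (Ideal, LargerLateral,
LargerLeft, LargerRight). The mean shape captures bias in where sounds are
heard; the SD shape captures how reliable the percept is from trial to trial.

A simulated trial at target angle ``a`` is drawn ``Normal(mean_fn(a),
sd_fn(a))`` and clipped to [-90, 90] degrees, mirroring the touchscreen's
response range. The parametric forms below are this package's defaults (all
overridable): the Ideal mean is the identity, Flat is constant 0, Compressed
is a logistic saturating at +/-40 deg, and the Biased means are the
full-range logistic shifted laterally by 35 deg; the Ideal SD is a constant
8 deg and the Larger* SDs grow linearly with (one-sided) eccentricity at
0.30 deg per degree. The sigmoid mean shapes use a slope parameter of -30,
which brings the Compressed curve to ~90% of its asymptote by the edge of
the grid — the shape visibly flattens laterally, and the asymptotes remain
identifiable when the same 4PL model is fit back to simulated trials.

This module also builds the two kinds of synthetic cohorts the test suite
leans on: labeled reference cohorts for the classifier (by default 50
simulated subjects per category, 15 repetitions per angle — 1000 subjects)
and regression cohorts with a known mixed-effects structure for
parameter-recovery checks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ANGLE_GRID, BICI_REPS, LocalizationDataset, ListenerSummary

MEAN_SHAPES = ("Ideal", "Flat", "Compressed", "BiasedLeft", "BiasedRight")
SD_SHAPES = ("Ideal", "LargerLateral", "LargerLeft", "LargerRight")

#: Default shape parameters, degrees unless noted.
DEFAULT_SHAPE_PARAMS: Mapping[str, float] = {
    "logistic_sigma": -30.0,   # slope parameter of the sigmoid mean shapes
    "compressed_asymptote": 40.0,  # |asymptote| of the Compressed mean
    "bias_shift": 35.0,        # lateral shift of the Biased means
    "ideal_sd": 8.0,           # constant SD of the Ideal SD shape
    "sd_slope": 0.30,          # deg of extra SD per deg of eccentricity
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logistic_mean(a, alpha: float, beta: float, mu: float, sigma: float):
    """Four-parameter logistic, increasing left-to-right for sigma < 0."""
    a = np.asarray(a, dtype=float)
    return beta + (alpha - beta) * _sigmoid((mu - a) / sigma)


@dataclass(frozen=True)
class CategorySpec:
    """One of the 20 pattern categories: a mean shape crossed with an SD shape."""

    mean_shape: str
    sd_shape: str
    mean_fn: Callable[[np.ndarray], np.ndarray]
    sd_fn: Callable[[np.ndarray], np.ndarray]

    @property
    def label(self) -> str:
        return f"{self.mean_shape},{self.sd_shape}"

    def __repr__(self) -> str:  # noqa: D105
        return f"CategorySpec({self.label})"


def make_category(
    mean_shape: str,
    sd_shape: str,
    params: Mapping[str, float] | None = None,
) -> CategorySpec:
    """Build a :class:`CategorySpec` from shape names and optional overrides."""
    if mean_shape not in MEAN_SHAPES:
        raise ValueError(
            f"unknown mean shape {mean_shape!r}; valid: {list(MEAN_SHAPES)}"
        )
    if sd_shape not in SD_SHAPES:
        raise ValueError(f"unknown SD shape {sd_shape!r}; valid: {list(SD_SHAPES)}")
    p = dict(DEFAULT_SHAPE_PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown shape parameter(s) {sorted(unknown)}")
        p.update(params)

    sig, comp, shift = p["logistic_sigma"], p["compressed_asymptote"], p["bias_shift"]

    if mean_shape == "Ideal":
        mean_fn = lambda a: np.asarray(a, dtype=float)
    elif mean_shape == "Flat":
        mean_fn = lambda a: np.zeros_like(np.asarray(a, dtype=float))
    elif mean_shape == "Compressed":
        mean_fn = lambda a: _logistic_mean(a, comp, -comp, 0.0, sig)
    elif mean_shape == "BiasedRight":
        mean_fn = lambda a: np.clip(
            _logistic_mean(a, 90.0, -90.0, 0.0, sig) + shift, -90.0, 90.0
        )
    else:  # BiasedLeft
        mean_fn = lambda a: np.clip(
            _logistic_mean(a, 90.0, -90.0, 0.0, sig) - shift, -90.0, 90.0
        )

    base, slope = p["ideal_sd"], p["sd_slope"]
    if sd_shape == "Ideal":
        sd_fn = lambda a: np.full_like(np.asarray(a, dtype=float), base)
    elif sd_shape == "LargerLateral":
        sd_fn = lambda a: base + slope * np.abs(np.asarray(a, dtype=float))
    elif sd_shape == "LargerLeft":
        sd_fn = lambda a: base + slope * np.maximum(0.0, -np.asarray(a, dtype=float))
    else:  # LargerRight
        sd_fn = lambda a: base + slope * np.maximum(0.0, np.asarray(a, dtype=float))

    return CategorySpec(mean_shape, sd_shape, mean_fn, sd_fn)


def stock_categories(
    params: Mapping[str, float] | None = None,
) -> list[CategorySpec]:
    """All 20 default categories, in fixed (mean-major) registration order."""
    return [
        make_category(m, s, params) for m in MEAN_SHAPES for s in SD_SHAPES
    ]


@dataclass
class SimulatedSubject:
    """A simulated listener with known ground-truth category."""

    category_label: str
    dataset: LocalizationDataset
    rng_seed: int
    subject_code: str = "SIM"


def _draw_responses(
    category: CategorySpec,
    reps: int,
    rng: np.random.Generator,
    angle_grid: np.ndarray,
) -> np.ndarray:
    """(reps, n_angles) clipped-Gaussian response draws."""
    mu = category.mean_fn(angle_grid)
    sd = category.sd_fn(angle_grid)
    raw = rng.normal(loc=mu, scale=sd, size=(reps, len(angle_grid)))
    return np.clip(raw, -90.0, 90.0)


def simulate_subject(
    category: CategorySpec,
    reps: int = BICI_REPS,
    rng: np.random.Generator | int | None = None,
    subject_code: str = "SIM",
    angle_grid: np.ndarray = ANGLE_GRID,
) -> SimulatedSubject:
    """Simulate one subject: ``reps`` clipped-Gaussian trials per grid angle."""
    if reps < 2:
        raise ValueError("need reps >= 2 (per-angle SD must be defined)")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    grid = np.asarray(angle_grid, dtype=float)
    resp = _draw_responses(category, reps, gen, grid)
    trials = pd.DataFrame(
        {
            "subject": subject_code,
            "target_deg": np.tile(grid, reps),
            "response_deg": resp.ravel(),
            "rep": np.repeat(np.arange(1, reps + 1), len(grid)),
        }
    )
    return SimulatedSubject(
        category.label, LocalizationDataset(trials, grid), seed if seed is not None else -1,
        subject_code,
    )


def simulate_reference_cohort(
    n_per_category: int = 50,
    reps: int = BICI_REPS,
    rng: np.random.Generator | int | None = None,
    categories: Sequence[CategorySpec] | None = None,
    angle_grid: np.ndarray = ANGLE_GRID,
) -> list[SimulatedSubject]:
    """Labeled reference cohort: ``n_per_category`` subjects per category.

    A single base seed is drawn from the master ``rng`` and each category's
    subjects are seeded from (base seed, hash of category label), so a fixed
    master seed reproduces the cohort bit-identically and permuting the
    category registration order changes nothing but subject ordering.
    """
    cats = list(categories) if categories is not None else stock_categories()
    master = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    base = int(master.integers(0, 2**63))
    subjects = []
    for cat in cats:
        children = _category_seed(base, cat.label).spawn(n_per_category)
        for i, child_ss in enumerate(children):
            subjects.append(
                simulate_subject(
                    cat, reps, np.random.default_rng(child_ss),
                    subject_code=f"{cat.label}#{i}", angle_grid=angle_grid,
                )
            )
    return subjects


def _category_seed(base: int, label: str) -> np.random.SeedSequence:
    """Deterministic per-category seed, independent of registration order."""
    return np.random.SeedSequence([base, zlib.crc32(label.encode())])


def simulate_reference_features(
    n_per_category: int = 50,
    reps: int = BICI_REPS,
    rng: np.random.Generator | int | None = None,
    categories: Sequence[CategorySpec] | None = None,
    angle_grid: np.ndarray = ANGLE_GRID,
) -> tuple[np.ndarray, list[str]]:
    """Reference cohort reduced to classifier features, without trial tables.

    Simulates the same clipped-Gaussian trials as :func:`simulate_subject`
    (``reps`` per angle) and summarizes each subject to its 38-value feature
    vector (19 per-angle means then 19 per-angle sample SDs). Vectorized over
    subjects; this is the hot path of the bootstrap classifier.
    """
    cats = list(categories) if categories is not None else stock_categories()
    master = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    base = int(master.integers(0, 2**63))
    grid = np.asarray(angle_grid, dtype=float)
    blocks, labels = [], []
    for cat in cats:
        gen = np.random.default_rng(_category_seed(base, cat.label))
        mu = cat.mean_fn(grid)
        sd = cat.sd_fn(grid)
        raw = gen.normal(loc=mu, scale=sd, size=(n_per_category, reps, len(grid)))
        resp = np.clip(raw, -90.0, 90.0)
        feats = np.concatenate(
            [resp.mean(axis=1), resp.std(axis=1, ddof=1)], axis=1
        )
        blocks.append(feats)
        labels.extend([cat.label] * n_per_category)
    return np.vstack(blocks), labels


def subject_summary(subject: SimulatedSubject) -> ListenerSummary:
    """Per-angle means/SDs of a simulated subject (same path as real data)."""
    from .data_model import summarize

    return summarize(subject.dataset, subject.subject_code)


# ---------------------------------------------------------------------------
# Regression cohorts with known structure
# ---------------------------------------------------------------------------

#: Fixed-effect point estimates of the published random-intercept model of
#: log per-angle RMS error: intercept, onset-group (0 = early, 1 = late),
#: squared target angle (deg^2), and their interaction.
PUBLISHED_COEFFICIENTS: Mapping[str, float] = {
    "intercept": 3.339,
    "od_effect": -0.401,
    "sta_effect": 3.626e-5,
    "interaction": 3.668e-5,
}

#: Default variance components for regression cohorts, log-RMS units. These
#: are back-derived from the published coefficient standard errors of the
#: 48-listener study (see docs/methods.md).
DEFAULT_SIGMA_BETWEEN = 0.31
DEFAULT_SIGMA_WITHIN = 0.43


def simulate_regression_cohort(
    n_subjects: int = 48,
    coefficients: Mapping[str, float] = PUBLISHED_COEFFICIENTS,
    sigma_between: float = DEFAULT_SIGMA_BETWEEN,
    sigma_within: float = DEFAULT_SIGMA_WITHIN,
    rng: np.random.Generator | int | None = None,
    angle_grid: np.ndarray = ANGLE_GRID,
    early_fraction: float = 1.0 / 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-angle log-RMS table plus patient factors with known ground truth.

    The generative model is the random-intercept regression
    ``log_rms = b0 + b1*OD + b2*STA + b3*OD*STA + u_subject + e`` with
    ``u ~ N(0, sigma_between^2)`` and ``e ~ N(0, sigma_within^2)``; OD is the
    onset-group indicator (0 = early, 1 = late) and STA the squared target
    angle. One third of subjects are early-onset by default, matching the
    16:32 split of the study cohort.

    Returns ``(long, factors)``: the long table has one row per subject x
    angle with columns ``subject, target_deg, sta, od, log_rms``; the factors
    table carries synthetic onset/testing ages consistent with the group
    labels.
    """
    if n_subjects < 10:
        raise ValueError("need at least 10 subjects for a meaningful cohort")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    grid = np.asarray(angle_grid, dtype=float)
    n_early = max(1, round(n_subjects * early_fraction))
    od = np.array([0] * n_early + [1] * (n_subjects - n_early))
    codes = [f"S{i:03d}" for i in range(n_subjects)]

    b0 = coefficients["intercept"]
    b1 = coefficients["od_effect"]
    b2 = coefficients["sta_effect"]
    b3 = coefficients["interaction"]
    sta = grid**2

    intercepts = gen.normal(0.0, sigma_between, size=n_subjects)
    rows = []
    for j in range(n_subjects):
        noise = gen.normal(0.0, sigma_within, size=len(grid))
        y = b0 + b1 * od[j] + (b2 + b3 * od[j]) * sta + intercepts[j] + noise
        rows.append(
            pd.DataFrame(
                {
                    "subject": codes[j],
                    "target_deg": grid,
                    "sta": sta,
                    "od": od[j],
                    "log_rms": y,
                }
            )
        )
    long = pd.concat(rows, ignore_index=True)

    onset_age = np.where(
        od == 0, gen.uniform(0.0, 5.0, n_subjects), gen.uniform(6.0, 60.0, n_subjects)
    )
    testing_age = np.maximum(onset_age + 1.0, gen.uniform(18.0, 85.0, n_subjects))
    factors = pd.DataFrame(
        {
            "subject": codes,
            "onset_age": onset_age,
            "testing_age": testing_age,
            "onset_group": np.where(od == 0, "early", "late"),
        }
    )
    return long, factors
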