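"""Domain types and I/O for sound-source localization trial data.

The experimental substrate is a free-field localization task: on each trial a
noise burst is played from one of 19 loudspeakers spanning -90 deg (listener's
left) to +90 deg (right) in 10-degree steps, and the listener reports the
perceived azimuth on a touchscreen restricted to the same +/-90 deg span.
Negative angles are to the listener's left, positive to the right; the grid is
stored ascending.

This module holds the trial-level containers, delimited-text readers/writers,
per-listener summaries (per-angle response means and SDs), and the
patient-dependent factors derived from demographic ages (onset of deafness,
implantation, testing).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The 19 loudspeaker azimuths, degrees, ascending left-to-right.
ANGLE_GRID: np.ndarray = np.arange(-90, 91, 10)

#: Repetitions per loudspeaker in the implant-listener protocol.
BICI_REPS = 15
#: Repetitions per loudspeaker in the normal-hearing protocol.
NH_REPS = 10

#: Onset-of-deafness age (years) at or below which a listener counts as
#: "early" onset.
EARLY_ONSET_MAX_YEARS = 5.0

#: Absolute Pearson correlation above which two patient factors are treated as
#: collinear and barred from entering the same stepwise selection.
COLLINEARITY_THRESHOLD = 0.75

DEFAULT_TRIAL_COLUMNS: Mapping[str, str] = {
    "subject": "subject",
    "target": "target_deg",
    "response": "response_deg",
    "rep": "rep",
    "block": "block",
}


class FormatError(ValueError):
    """A file is structurally unreadable (missing columns, bad delimiter)."""


class ValidationError(ValueError):
    """Rows parsed but violated a domain invariant; offending rows listed."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


@dataclass(frozen=True)
class TrialRecord:
    """One localization trial: where the sound came from and where it was heard."""

    subject_code: str
    target_angle: float
    response_angle: float
    repetition_index: int
    block_index: int | None = None


@dataclass
class LocalizationDataset:
    """Trial table for one or more listeners over the fixed angle grid.

    ``trials`` is a DataFrame with columns ``subject, target_deg, response_deg,
    rep`` (and optionally ``block``). Every subject must cover every grid angle
    with an equal number of repetitions per angle, which makes the overall RMS
    error reconstructible from per-angle RMS values.
    """

    trials: pd.DataFrame
    angle_grid: np.ndarray = field(default_factory=lambda: ANGLE_GRID.copy())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.trials["subject"].unique())

    def for_subject(self, subject_code: str) -> pd.DataFrame:
        sub = self.trials[self.trials["subject"] == subject_code]
        if sub.empty:
            raise KeyError(f"unknown subject {subject_code!r}")
        return sub

    def validate(self) -> None:
        """Check grid coverage and balanced repetitions for every subject."""
        grid = set(np.asarray(self.angle_grid, dtype=float))
        for code, sub in self.trials.groupby("subject"):
            counts = sub.groupby("target_deg").size()
            missing = grid - set(counts.index.astype(float))
            if missing:
                raise ValidationError(
                    f"subject {code}: no trials at angle(s) {sorted(missing)}"
                )
            if counts.nunique() != 1:
                raise ValidationError(
                    f"subject {code}: unequal repetition counts per angle "
                    f"({counts.min()}..{counts.max()})"
                )


@dataclass
class ListenerSummary:
    """Per-angle response means and sample SDs for one listener.

    This 19+19 summary is the feature representation consumed by the pattern
    classifier: the means capture response bias, the SDs capture trial-to-trial
    reliability.
    """

    subject_code: str
    means: np.ndarray
    sds: np.ndarray
    angle_grid: np.ndarray = field(default_factory=lambda: ANGLE_GRID.copy())

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        n = len(self.angle_grid)
        if self.means.shape != (n,) or self.sds.shape != (n,):
            raise ValueError("means/sds length must match the angle grid")
        if np.any(self.sds < 0):
            raise ValueError("SDs must be non-negative")

    def feature_vector(self) -> np.ndarray:
        """Concatenate means then SDs, each ascending by angle (38 values)."""
        return np.concatenate([self.means, self.sds])


# ---------------------------------------------------------------------------
# Trial file I/O
# ---------------------------------------------------------------------------

def load_trials(
    path,
    *,
    delimiter: str = ",",
    columns: Mapping[str, str] | None = None,
    angle_grid: np.ndarray = ANGLE_GRID,
    max_reps: int = BICI_REPS,
) -> LocalizationDataset:
    """Read a delimited trial file into a validated :class:`LocalizationDataset`.

    Parameters
    ----------
    path
        Delimited text file with (configurable) columns for subject, target
        angle and response angle. A repetition column is optional; when absent
        repetitions are numbered by order of appearance within each
        subject x angle cell.
    max_reps
        Cap on the repetition index (15 for implant-protocol data, 10 for the
        normal-hearing protocol).

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If any row has an off-grid target, a response outside [-90, 90], or a
        repetition index above ``max_reps``; the error lists 1-based data row
        numbers.
    """
    cols = dict(DEFAULT_TRIAL_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=delimiter)
    required = [cols["subject"], cols["target"], cols["response"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} in {path}")

    out = pd.DataFrame(
        {
            "subject": df[cols["subject"]].astype(str),
            "target_deg": pd.to_numeric(df[cols["target"]], errors="coerce"),
            "response_deg": pd.to_numeric(df[cols["response"]], errors="coerce"),
        }
    )
    if cols["rep"] in df.columns:
        out["rep"] = pd.to_numeric(df[cols["rep"]], errors="coerce").astype("Int64")
    else:
        out["rep"] = (
            out.groupby(["subject", "target_deg"]).cumcount() + 1
        ).astype("Int64")
    if cols["block"] in df.columns:
        out["block"] = pd.to_numeric(df[cols["block"]], errors="coerce").astype("Int64")

    grid = set(np.asarray(angle_grid, dtype=float))
    problems: list[str] = []
    bad_rows: list[int] = []
    for idx, row in out.iterrows():
        line = idx + 1  # 1-based data row (header excluded)
        if not np.isfinite(row["target_deg"]) or row["target_deg"] not in grid:
            problems.append(f"row {line}: target angle {row['target_deg']} off grid")
            bad_rows.append(line)
        elif not np.isfinite(row["response_deg"]) or not (
            -90.0 <= row["response_deg"] <= 90.0
        ):
            problems.append(
                f"row {line}: response angle {row['response_deg']} outside [-90, 90]"
            )
            bad_rows.append(line)
        elif pd.isna(row["rep"]) or row["rep"] < 1 or row["rep"] > max_reps:
            problems.append(f"row {line}: repetition index {row['rep']} outside 1..{max_reps}")
            bad_rows.append(line)
    if problems:
        raise ValidationError(
            "invalid trial rows:\n" + "\n".join(problems), rows=bad_rows
        )
    out["rep"] = out["rep"].astype(int)
    return LocalizationDataset(out, np.asarray(angle_grid, dtype=float))


def write_trials(dataset: LocalizationDataset, path, *, delimiter: str = ",") -> None:
    """Write trials in the same dialect ``load_trials`` reads (round-trips)."""
    df = dataset.trials.rename(
        columns={
            "subject": DEFAULT_TRIAL_COLUMNS["subject"],
            "target_deg": DEFAULT_TRIAL_COLUMNS["target"],
            "response_deg": DEFAULT_TRIAL_COLUMNS["response"],
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def dataset_from_records(records: Iterable[TrialRecord]) -> LocalizationDataset:
    rows = [
        {
            "subject": r.subject_code,
            "target_deg": float(r.target_angle),
            "response_deg": float(r.response_angle),
            "rep": int(r.repetition_index),
        }
        for r in records
    ]
    return LocalizationDataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Per-listener summaries
# ---------------------------------------------------------------------------

def summarize(dataset: LocalizationDataset, subject_code: str) -> ListenerSummary:
    """Per-angle mean and sample SD (n-1 denominator) of response angles.

    Raises ``ValidationError`` naming the angle if any grid angle has fewer
    than two repetitions (the SD is undefined there).
    """
    sub = dataset.for_subject(subject_code)
    means = np.empty(len(dataset.angle_grid))
    sds = np.empty(len(dataset.angle_grid))
    for i, angle in enumerate(dataset.angle_grid):
        resp = sub.loc[sub["target_deg"] == angle, "response_deg"].to_numpy()
        if resp.size < 2:
            raise ValidationError(
                f"subject {subject_code}: {resp.size} repetition(s) at angle "
                f"{angle:g}; SD undefined"
            )
        means[i] = resp.mean()
        sds[i] = resp.std(ddof=1)
    return ListenerSummary(subject_code, means, sds, np.asarray(dataset.angle_grid))


# ---------------------------------------------------------------------------
# Patient-dependent factors
# ---------------------------------------------------------------------------

DERIVED_FACTOR_COLUMNS = [
    "duration_bilateral_impairment",
    "acoustic_exposure",
    "inter_implant_delay",
    "years_bilateral_ci",
    "years_any_ci",
]


def derive_factors(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive deprivation/experience durations from demographic ages.

    Input columns: ``subject, onset_age, testing_age`` and optionally
    ``first_ci_age, second_ci_age`` (years). Derived, in years:

    - ``duration_bilateral_impairment`` = second_ci_age - onset_age
    - ``acoustic_exposure``             = second_ci_age (birth to second implant)
    - ``inter_implant_delay``           = second_ci_age - first_ci_age
    - ``years_bilateral_ci``            = testing_age - second_ci_age
    - ``years_any_ci``                  = testing_age - first_ci_age
    - ``onset_group``                   = "early" if onset_age <= 5 else "late"

    Derived fields stay missing (NaN) when an input age is absent; nothing is
    imputed.
    """
    for col in ("subject", "onset_age", "testing_age"):
        if col not in raw.columns:
            raise FormatError(f"demographics table missing column {col!r}")
    df = raw.copy()
    for col in ("first_ci_age", "second_ci_age"):
        if col not in df.columns:
            df[col] = np.nan

    bad = df["onset_age"] > df["testing_age"]
    if bad.any():
        raise ValidationError(
            "onset_age exceeds testing_age for subject(s) "
            f"{df.loc[bad, 'subject'].tolist()}",
            rows=list(np.flatnonzero(bad.to_numpy()) + 1),
        )
    order = df[["first_ci_age", "second_ci_age", "testing_age"]].to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad_order = (order[:, 0] > order[:, 1]) | (order[:, 1] > order[:, 2])
    if np.any(bad_order):
        raise ValidationError(
            "implantation ages out of order (need first <= second <= testing) for "
            f"subject(s) {df.loc[bad_order, 'subject'].tolist()}",
            rows=list(np.flatnonzero(bad_order) + 1),
        )

    df["duration_bilateral_impairment"] = df["second_ci_age"] - df["onset_age"]
    df["acoustic_exposure"] = df["second_ci_age"]
    df["inter_implant_delay"] = df["second_ci_age"] - df["first_ci_age"]
    df["years_bilateral_ci"] = df["testing_age"] - df["second_ci_age"]
    df["years_any_ci"] = df["testing_age"] - df["first_ci_age"]
    df["onset_group"] = np.where(
        df["onset_age"] <= EARLY_ONSET_MAX_YEARS, "early", "late"
    )
    return df


def factor_correlations(
    factors: pd.DataFrame,
    *,
    threshold: float = COLLINEARITY_THRESHOLD,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Pairwise-complete Pearson correlations between numeric patient factors.

    Returns the symmetric correlation matrix (unit diagonal; NaN where a
    column is constant or fewer than ``min_pairs`` complete pairs exist) and
    the list of factor pairs with ``|r| > threshold`` — the collinearity
    screen feeding stepwise model selection.
    """
    numeric = factors.select_dtypes(include=[np.number])
    corr = numeric.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    flagged = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((a, b))
    return corr, flagged


def load_demographics(path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read a demographics table and derive the patient factors."""
    return derive_factors(pd.read_csv(path, sep=delimiter))


def table1_demographics() -> pd.DataFrame:
    """The 48-listener demographic table shipped with the package.

    Columns ``subject, onset_age, testing_age`` (years), with derived factors.
    Implantation ages are not part of this fixture; the corresponding derived
    durations are missing.
    """
    ref = importlib.resources.files("locpattern.data") / "table1_demographics.csv"
    with importlib.resources.as_file(ref) as p:
        return load_demographics(p)
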