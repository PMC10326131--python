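"""Data model and I/O for angular elastic-wave arrival-time measurements.

The measurement protocol records the arrival time of a Rayleigh surface wave
between two transducers at a series of probe orientations: 36 angles at 10°
increments around the full circle (360° coincides with 0°, so the grid is
0°, 10°, ..., 350°), repeated three times per subject in each of two skin
configurations (natural and stretched).  Arrival times are in the device's
arbitrary RRT units (Resonance Running Time).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_GRID_STEP = 10.0
FULL_PROTOCOL_ANGLES = 36


class Configuration(str, enum.Enum):
    """Skin state during measurement: untouched, or manually stretched
    along the identified Langer line."""

    NATURAL = "natural"
    STRETCHED = "stretched"


class Gender(str, enum.Enum):
    FEMALE = "F"
    MALE = "M"


class SchemaError(ValueError):
    """A required column is missing or mistyped in an input table."""


class ProfileValidationError(ValueError):
    """Readings violate the angular-grid protocol."""


@dataclass(frozen=True)
class AngularProfile:
    """One subject/configuration set of (angle, arrival-time) readings.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    configuration : Configuration
        Natural or stretched skin.
    angles_deg : ndarray
        Strictly increasing angles in [0, 360), each on the grid.
    rrt : ndarray
        Arrival times in RRT units, strictly positive, one per angle.
    repeat_index : int or None
        1-based repeat number; ``None`` marks a repeat-averaged profile.
    """

    subject_id: str
    configuration: Configuration
    angles_deg: np.ndarray
    rrt: np.ndarray
    repeat_index: int | None = None
    grid_step: float = DEFAULT_GRID_STEP

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles_deg, dtype=float)
        rrt = np.asarray(self.rrt, dtype=float)
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "rrt", rrt)
        if angles.ndim != 1 or rrt.shape != angles.shape:
            raise ProfileValidationError("angles and rrt must be 1-d and equal length")
        if angles.size == 0:
            raise ProfileValidationError("profile has no readings")
        if np.any(angles < 0) or np.any(angles >= 360):
            raise ProfileValidationError("angles must lie in [0, 360)")
        if np.any(np.diff(angles) <= 0):
            raise ProfileValidationError("angles must be strictly increasing")
        resid = np.abs(angles / self.grid_step - np.round(angles / self.grid_step))
        if np.any(resid > 1e-9):
            bad = angles[resid > 1e-9]
            raise ProfileValidationError(
                f"angles not on the {self.grid_step}° grid: {bad.tolist()}"
            )
        if np.any(~np.isfinite(rrt)) or np.any(rrt <= 0):
            raise ProfileValidationError("every arrival time must be finite and > 0")

    @property
    def n_readings(self) -> int:
        return int(self.angles_deg.size)

    def is_full_protocol(self) -> bool:
        return self.n_readings == FULL_PROTOCOL_ANGLES and self.grid_step == 10.0


@dataclass
class SubjectRecord:
    """A subject's covariates and angular profiles across configurations."""

    subject_id: str
    age_years: float
    gender: Gender
    profiles: list[AngularProfile] = field(default_factory=list)

    MAX_PLAUSIBLE_AGE = 120.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.age_years <= self.MAX_PLAUSIBLE_AGE):
            raise ValueError(
                f"age {self.age_years} outside plausible range "
                f"[0, {self.MAX_PLAUSIBLE_AGE}]"
            )

    def profiles_for(self, configuration: Configuration) -> list[AngularProfile]:
        return [p for p in self.profiles if p.configuration is configuration]


REQUIRED_COLUMNS = (
    "subject_id",
    "age_years",
    "gender",
    "configuration",
    "repeat",
    "angle_deg",
    "rrt",
)


def read_cohort(path, grid_step: float = DEFAULT_GRID_STEP) -> list[SubjectRecord]:
    """Read a long-format cohort CSV into validated :class:`SubjectRecord`\\ s.

    One row per reading: ``subject_id, age_years, gender, configuration,
    repeat, angle_deg, rrt``.  Row order is irrelevant; readings are grouped
    by (subject, configuration, repeat) and sorted by angle.  A ``repeat``
    value of ``"avg"`` marks an already-averaged profile.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "repeat": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return []
    for col in ("angle_deg", "rrt", "age_years"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric value in column '{col}' at row {int(bad[0]) + 2}"
            )
        df[col] = coerced
    dup = df.duplicated(subset=["subject_id", "configuration", "repeat", "angle_deg"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ProfileValidationError(
            "duplicate reading for subject "
            f"{row['subject_id']} {row['configuration']} repeat {row['repeat']} "
            f"angle {row['angle_deg']}"
        )

    records: list[SubjectRecord] = []
    for subject_id, sub in df.groupby("subject_id", sort=True):
        ages = sub["age_years"].unique()
        genders = sub["gender"].unique()
        if len(ages) != 1 or len(genders) != 1:
            raise ProfileValidationError(
                f"subject {subject_id} has inconsistent age/gender rows"
            )
        record = SubjectRecord(
            subject_id=str(subject_id),
            age_years=float(ages[0]),
            gender=Gender(str(genders[0])),
        )
        for (config, rep), grp in sub.groupby(["configuration", "repeat"], sort=True):
            grp = grp.sort_values("angle_deg")
            record.profiles.append(
                AngularProfile(
                    subject_id=str(subject_id),
                    configuration=Configuration(str(config)),
                    angles_deg=grp["angle_deg"].to_numpy(),
                    rrt=grp["rrt"].to_numpy(),
                    repeat_index=None if str(rep) == "avg" else int(rep),
                    grid_step=grid_step,
                )
            )
        records.append(record)
    return records


def write_cohort(records: list[SubjectRecord], path) -> None:
    """Write records back to the long CSV schema (inverse of read_cohort)."""
    rows = []
    ages = {r.subject_id: (r.age_years, r.gender.value) for r in records}
    for rec in records:
        for prof in rec.profiles:
            rep = "avg" if prof.repeat_index is None else str(prof.repeat_index)
            for ang, rrt in zip(prof.angles_deg, prof.rrt):
                rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "age_years": ages[rec.subject_id][0],
                        "gender": ages[rec.subject_id][1],
                        "configuration": prof.configuration.value,
                        "repeat": rep,
                        "angle_deg": ang,
                        "rrt": rrt,
                    }
                )
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def average_repeats(profiles: list[AngularProfile]) -> AngularProfile:
    """Per-angle arithmetic mean over repeated profiles.

    All inputs must share subject, configuration and angle grid.  The output
    has no ``repeat_index``, marking it as an averaged profile.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if p.subject_id != first.subject_id or p.configuration is not first.configuration:
            raise ValueError("profiles mix subjects or configurations")
        if p.angles_deg.shape != first.angles_deg.shape or np.any(
            p.angles_deg != first.angles_deg
        ):
            offending = np.setxor1d(p.angles_deg, first.angles_deg)
            raise ProfileValidationError(
                f"mismatched angle grids; offending angles: {offending.tolist()}"
            )
    mean_rrt = np.mean([p.rrt for p in profiles], axis=0)
    return replace(first, rrt=mean_rrt, repeat_index=None)


def langer_direction_raw(profile: AngularProfile) -> float:
    """Langer-line direction from raw readings, in degrees in [0, 180).

    The protocol identifies the Langer line as the direction of the shortest
    arrival time (the fastest wave), reduced modulo 180° since direction is
    axial.  Ties break toward the smallest angle.
    """
    idx = int(np.argmin(profile.rrt))  # argmin takes the first minimum
    return float(profile.angles_deg[idx] % 180.0)
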