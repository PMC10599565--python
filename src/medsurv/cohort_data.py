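"""Cohort data model, I/O, eligibility filtering and case ascertainment.

The analyses operate on a one-row-per-subject table describing an
occupational cohort observed at two questionnaire waves (T1, T2) and then
followed in administrative claims data for incident physician-diagnosed
depression.  :class:`CohortTable` couples the raw table with a
variable-role map so downstream code addresses columns by *role*
(exposure, mediator, confounders, ...) rather than by name.

Case ascertainment follows the validated claims-based definition of
depression: ICD-9 codes 296.x (any 296 prefix), 300.4 and 311.  A subject
with a matching claim in the year before the T2 interview is a prevalent
case; the first matching claim within the three-year window after T2 is an
incident event; death before the first depression claim is a competing
risk, and everyone else is administratively censored at three years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: depression ICD-9 codes: any 296 prefix, plus 300.4 and 311 exactly
DEPRESSION_PREFIXES = ("296",)
DEPRESSION_EXACT = ("3004", "311")

#: calendar conventions: whole days; 1 year = 365 d, 3 years = 1095 d
PREVALENCE_WINDOW_DAYS = 365
DEFAULT_FOLLOWUP_DAYS_PER_YEAR = 365

#: exclusion reasons in their canonical order of precedence
EXCLUSION_REASONS = (
    "death_before_t2",
    "prevalent_depression",
    "not_working_t2",
    "no_linkage",
    "no_t2_participation",
)

EVENT_LEVELS = ("depression", "death", "admin_censor")


class SchemaError(ValueError):
    """A column required by the variable-role map is missing."""


class ValidationError(ValueError):
    """A value violates its declared level set or another invariant."""


@dataclass(frozen=True)
class VariableRoles:
    """Maps semantic variable roles to column names and level sets."""

    subject_id: str = "subject_id"
    exposure: str = "ses"
    exposure_levels: tuple = ("high", "medium", "low")
    exposure_reference: object = "high"
    mediator: str = "mediator_t2"
    mediator_levels: tuple = (0, 1)
    followup_time: str = "followup_time"
    event_status: str = "event_status"
    event_levels: tuple = EVENT_LEVELS
    sex: Optional[str] = None
    age: Optional[str] = None
    jobstrain_t1: Optional[str] = None
    censored_pre_t2: Optional[str] = None
    confounders_t1: tuple = ()
    confounders_t2: tuple = ()
    #: optional extra per-column level sets, e.g. {"smoking_t1": [0, 1, 2]}
    levels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.exposure_reference not in self.exposure_levels:
            raise ValidationError(
                f"exposure reference {self.exposure_reference!r} is not one of "
                f"the declared levels {self.exposure_levels}"
            )

    @property
    def mandatory(self):
        return {
            "subject_id": self.subject_id,
            "exposure": self.exposure,
            "mediator": self.mediator,
            "followup_time": self.followup_time,
            "event_status": self.event_status,
        }

    def level_map(self):
        """All declared categorical (column, levels) pairs."""
        out = {
            self.exposure: tuple(self.exposure_levels),
            self.mediator: tuple(self.mediator_levels),
            self.event_status: tuple(self.event_levels),
        }
        for col, lv in self.levels.items():
            out[col] = tuple(lv)
        return out

    def to_dict(self):
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d):
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path):
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d.get("roles", d))


def _coerce_levels(series: pd.Series, levels: Sequence, column: str) -> pd.Series:
    """Coerce values to the declared level objects, matching on string form."""
    lookup = {str(lv): lv for lv in levels}
    out = series.copy()
    mask = series.notna()
    for idx, val in series[mask].items():
        key = str(val)
        # integers read back as floats ("1.0") still match declared int levels
        if key.endswith(".0") and key[:-2] in lookup:
            key = key[:-2]
        if key not in lookup:
            raise ValidationError(
                f"value {val!r} in column {column!r} at row {idx} is outside "
                f"the declared level set {tuple(levels)}"
            )
        out.at[idx] = lookup[key]
    return out.infer_objects(copy=False)


@dataclass
class CohortTable:
    """One-row-per-subject cohort table plus its variable-role map."""

    df: pd.DataFrame
    roles: VariableRoles
    validate: bool = True

    def __post_init__(self):
        if self.validate:
            self._validate()

    def _validate(self):
        for role, col in self.roles.mandatory.items():
            if col not in self.df.columns:
                raise SchemaError(f"missing column {col!r} for mandatory role {role!r}")
        for col in (
            (self.roles.sex, self.roles.age, self.roles.jobstrain_t1,
             self.roles.censored_pre_t2)
            + tuple(self.roles.confounders_t1) + tuple(self.roles.confounders_t2)
        ):
            if col is not None and col != "" and col not in self.df.columns:
                raise SchemaError(f"column {col!r} named in the role map is missing")
        ids = self.df[self.roles.subject_id]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        t = pd.to_numeric(self.df[self.roles.followup_time], errors="coerce")
        bad = self.df.index[(t <= 0) & t.notna()]
        if len(bad):
            raise ValidationError(f"non-positive followup_time at row {bad[0]}")
        for col, levels in self.roles.level_map().items():
            if col not in self.df.columns:
                continue
            s = self.df[col]
            ok = s.isna() | s.isin(levels)
            if not ok.all():
                row = self.df.index[~ok][0]
                raise ValidationError(
                    f"value {s[row]!r} in column {col!r} at row {row} is outside "
                    f"the declared level set {levels}"
                )

    # -- convenience accessors -------------------------------------------------
    def __len__(self):
        return len(self.df)

    @property
    def subject_ids(self) -> pd.Series:
        return self.df[self.roles.subject_id]

    def col(self, role_or_column: str) -> pd.Series:
        """Resolve a role name (preferred) or a raw column name to a Series."""
        r = self.roles
        if hasattr(r, role_or_column):
            col = getattr(r, role_or_column)
            if isinstance(col, str) and col in self.df.columns:
                return self.df[col]
        if role_or_column in self.df.columns:
            return self.df[role_or_column]
        raise SchemaError(f"unknown role or column {role_or_column!r}")

    def subset(self, mask_or_ids) -> "CohortTable":
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and getattr(
            mask_or_ids, "dtype", None
        ) == bool:
            df = self.df[mask_or_ids]
        else:
            keep = self.subject_ids.isin(list(mask_or_ids))
            df = self.df[keep]
        return CohortTable(df.reset_index(drop=True), self.roles, validate=False)


def _sep_for(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def read_cohort(path, roles: VariableRoles) -> CohortTable:
    """Read a delimited cohort file (CSV/TSV by extension) and validate it.

    Missing values may be encoded as the empty string or "NA"; they are kept
    as explicit missing markers (NaN).  Categorical columns with declared
    level sets are coerced to the declared level objects.
    """
    df = pd.read_csv(
        path, sep=_sep_for(path), na_values=["", "NA"], keep_default_na=False
    )
    for role, col in roles.mandatory.items():
        if col not in df.columns:
            raise SchemaError(f"file {path} lacks column {col!r} for role {role!r}")
    for col, levels in roles.level_map().items():
        if col in df.columns:
            df[col] = _coerce_levels(df[col], levels, col)
    return CohortTable(df, roles)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort as delimited text; NaN becomes "NA"."""
    cohort.df.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")


@dataclass
class ClaimsTable:
    """Claims-style event records: subject id, service date, ICD-9 code."""

    df: pd.DataFrame

    def __post_init__(self):
        required = {"subject_id", "service_date", "icd9_code"}
        missing = required - set(self.df.columns)
        if missing:
            raise SchemaError(f"claims table lacks columns: {sorted(missing)}")
        dates = pd.to_datetime(self.df["service_date"], errors="coerce")
        if dates.isna().any():
            row = self.df.index[dates.isna()][0]
            raise ValidationError(f"unparseable service_date at row {row}")
        codes = self.df["icd9_code"].astype(str).str.strip()
        if (codes == "").any() or self.df["icd9_code"].isna().any():
            raise ValidationError("empty icd9_code in claims table")
        self.df = self.df.assign(service_date=dates, icd9_code=codes)


def is_depression_code(code) -> bool:
    """ICD-9 depression codes: 296.x prefix, 300.4 or 311 (string match, dots stripped)."""
    c = str(code).strip().replace(".", "")
    return c.startswith(DEPRESSION_PREFIXES) or c in DEPRESSION_EXACT


@dataclass
class EligibilityReport:
    retained_ids: list
    excluded: list  # (subject_id, reason) in input order
    counts: dict

    def __post_init__(self):
        self.counts = dict(self.counts)


def apply_eligibility(cohort: CohortTable, flags: pd.DataFrame) -> EligibilityReport:
    """Apply the five exclusion criteria in order of precedence.

    ``flags`` must carry one boolean column per reason in
    :data:`EXCLUSION_REASONS`, indexed by subject id (or with a subject_id
    column).  A subject failing several criteria is excluded once, with the
    first matching reason.
    """
    if "subject_id" in flags.columns:
        flags = flags.set_index("subject_id")
    ids = cohort.subject_ids
    unknown = flags.index.difference(ids)
    if len(unknown):
        raise ValidationError(f"flags refer to unknown subject {unknown[0]!r}")
    missing_cols = [r for r in EXCLUSION_REASONS if r not in flags.columns]
    if missing_cols:
        raise SchemaError(f"flags lack status columns: {missing_cols}")
    missing_subj = ids[~ids.isin(flags.index)]
    if len(missing_subj):
        raise ValidationError(f"no status flags for subject {missing_subj.iloc[0]!r}")

    aligned = flags.loc[ids, list(EXCLUSION_REASONS)].to_numpy(dtype=bool)
    retained, excluded = [], []
    counts = {r: 0 for r in EXCLUSION_REASONS}
    for sid, row in zip(ids, aligned):
        hit = np.flatnonzero(row)
        if len(hit):
            reason = EXCLUSION_REASONS[hit[0]]
            excluded.append((sid, reason))
            counts[reason] += 1
        else:
            retained.append(sid)
    logger.info(
        "eligibility: retained %d of %d subjects; exclusions: %s",
        len(retained), len(ids), counts,
    )
    return EligibilityReport(retained, excluded, counts)


def ascertain_depression(
    claims,
    t2_date: pd.Series,
    death_date: Optional[pd.Series] = None,
    followup_years: int = 3,
) -> pd.DataFrame:
    """Derive prevalence, follow-up time and event status from claims.

    Parameters
    ----------
    claims : ClaimsTable or DataFrame with subject_id/service_date/icd9_code.
    t2_date : Series of T2 interview dates indexed by subject id.
    death_date : optional Series of death dates indexed by subject id.
    followup_years : administrative follow-up horizon (3 years = 1095 days).

    Returns a DataFrame indexed by subject id with columns ``prevalent``
    (bool), ``followup_time`` (days from T2) and ``event_status``.  The
    prevalence window is the half-open year before T2, inclusive at T2:
    (T2 - 365 d, T2].  A depression claim and a death on the same day count
    as depression.
    """
    if isinstance(claims, pd.DataFrame):
        claims = ClaimsTable(claims)
    t2 = pd.to_datetime(t2_date)
    if t2.isna().any():
        raise ValidationError(
            f"missing T2 date for subject {t2.index[t2.isna()][0]!r}"
        )
    horizon = followup_years * DEFAULT_FOLLOWUP_DAYS_PER_YEAR
    death = None if death_date is None else pd.to_datetime(death_date)

    cdf = claims.df
    dep = cdf[cdf["icd9_code"].map(is_depression_code).astype(bool)]
    dep = dep[dep["subject_id"].isin(t2.index)]
    # suspect records: claims dated more than 10 years before the subject's T2
    old = dep["service_date"] < (t2.reindex(dep["subject_id"]).to_numpy()
                                 - pd.Timedelta(days=3650))
    if old.any():
        warnings.warn(
            f"{int(old.sum())} depression claim(s) dated more than 10 years "
            "before T2; check record quality", stacklevel=2,
        )
    by_subject = {sid: g["service_date"].sort_values() for sid, g in
                  dep.groupby("subject_id")}

    rows = []
    for sid, t2_i in t2.items():
        dates = by_subject.get(sid)
        prevalent = False
        first_incident = None
        if dates is not None:
            delta = (dates - t2_i).dt.days
            prevalent = bool(((delta > -PREVALENCE_WINDOW_DAYS) & (delta <= 0)).any())
            inc = delta[(delta > 0) & (delta <= horizon)]
            if len(inc):
                first_incident = int(inc.iloc[0])
        d_i = None
        if death is not None and sid in death.index and pd.notna(death.get(sid)):
            dd = (death[sid] - t2_i).days
            if 0 < dd <= horizon:
                d_i = int(dd)
        if first_incident is not None and (d_i is None or first_incident <= d_i):
            rows.append((sid, prevalent, float(first_incident), "depression"))
        elif d_i is not None:
            rows.append((sid, prevalent, float(d_i), "death"))
        else:
            rows.append((sid, prevalent, float(horizon), "admin_censor"))
    out = pd.DataFrame(
        rows, columns=["subject_id", "prevalent", "followup_time", "event_status"]
    ).set_index("subject_id")
    return out
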