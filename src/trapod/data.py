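"""Domain types and raw-table handling for perioperative cohorts.

Tables are plain pandas DataFrames in long or wide form:

* events: ``surgery_id, patient_id, feature_name, t_offset_min, value`` —
  one row per observation, times in minutes from anesthesia begin (T_begin = 0).
* statics: ``surgery_id, patient_id, <one column per static feature>``.
* nudesc: ``surgery_id, assess_time_min, c1..c5`` — Nu-DESC category points,
  each 0-2, assessed in the recovery room after anesthesia end.
* feature specs: one row per feature with clinical domain, valid range,
  missingness-indicator and cumulative flags, and composite membership.

The POD label of a surgery is 1 if any of its Nu-DESC assessments has a total
score of at least 1, and 0 if every assessment scores 0.  Surgeries without
any assessment cannot be labeled and are excluded (with a logged record)
rather than treated as negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["surgery_id", "patient_id", "feature_name", "t_offset_min", "value"]
NUDESC_CATEGORIES = ["c1", "c2", "c3", "c4", "c5"]


# ---------------------------------------------------------------------------
# Feature specifications


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one clinical feature.

    ``valid_range`` bounds are inclusive on both sides; values outside are
    physiologically impossible and cleaned to missing.  ``missing_indicator``
    marks features whose absence is itself informative and encoded as a
    binary channel.  ``cumulative`` marks medications whose administered
    amounts are additionally accumulated over time.  ``composite_of`` lists
    member features whose event streams are pooled into this feature.
    """

    name: str
    domain: str = "other"
    time_variance: str = "dynamic"  # {static, dynamic}
    dtype: str = "numeric"  # {numeric, binary}
    valid_range: tuple[float, float] | None = None
    missing_indicator: bool = False
    cumulative: bool = False
    composite_of: tuple[str, ...] = ()

    def __post_init__(self):
        if self.time_variance not in ("static", "dynamic"):
            raise ValueError(f"{self.name}: bad time_variance {self.time_variance!r}")
        if self.valid_range is not None and not self.valid_range[0] < self.valid_range[1]:
            raise ValueError(f"{self.name}: valid_range low must be < high")
        if self.cumulative and self.time_variance != "dynamic":
            raise ValueError(f"{self.name}: cumulative implies dynamic")

    @property
    def is_dynamic(self) -> bool:
        return self.time_variance == "dynamic"


def validate_specs(specs: list[FeatureSpec]) -> dict[str, FeatureSpec]:
    """Index specs by name and check composite membership declarations."""
    by_name = {s.name: s for s in specs}
    if len(by_name) != len(specs):
        raise ValueError("duplicate feature names in specs")
    for s in specs:
        for member in s.composite_of:
            if member not in by_name:
                raise ValueError(f"composite {s.name}: unknown member {member!r}")
            if not by_name[member].is_dynamic:
                raise ValueError(f"composite {s.name}: member {member!r} is not dynamic")
    return by_name


def read_feature_specs(path) -> list[FeatureSpec]:
    df = pd.read_csv(path)
    specs = []
    for row in df.itertuples(index=False):
        low, high = getattr(row, "range_low", np.nan), getattr(row, "range_high", np.nan)
        rng = None if pd.isna(low) or pd.isna(high) else (float(low), float(high))
        comp = getattr(row, "composite_of", "")
        members = tuple(str(comp).split(";")) if isinstance(comp, str) and comp else ()
        specs.append(
            FeatureSpec(
                name=row.name,
                domain=row.domain,
                time_variance=row.time_variance,
                dtype=row.dtype,
                valid_range=rng,
                missing_indicator=bool(row.missing_indicator),
                cumulative=bool(row.cumulative),
                composite_of=members,
            )
        )
    validate_specs(specs)
    return specs


def write_feature_specs(specs: list[FeatureSpec], path) -> None:
    rows = []
    for s in specs:
        rows.append(
            {
                "name": s.name,
                "domain": s.domain,
                "time_variance": s.time_variance,
                "dtype": s.dtype,
                "range_low": s.valid_range[0] if s.valid_range else np.nan,
                "range_high": s.valid_range[1] if s.valid_range else np.nan,
                "missing_indicator": s.missing_indicator,
                "cumulative": s.cumulative,
                "composite_of": ";".join(s.composite_of),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Table I/O


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns {sorted(missing)}")
    return df[EVENT_COLUMNS].copy()


def read_statics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "surgery_id" not in df.columns or "patient_id" not in df.columns:
        raise ValueError("statics table needs surgery_id and patient_id columns")
    return df


def read_nudesc(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"surgery_id", "assess_time_min", *NUDESC_CATEGORIES} - set(df.columns)
    if missing:
        raise ValueError(f"nudesc table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Labels


@dataclass(frozen=True)
class SurgeryLabel:
    surgery_id: object
    patient_id: object
    y: int
    n_assessments: int


def label_pod(
    nudesc: pd.DataFrame, surgery_patients: dict | pd.Series
) -> tuple[list[SurgeryLabel], list[object]]:
    """Derive the binary POD label per surgery from Nu-DESC assessments.

    A surgery is positive iff at least one assessment has a total category
    score >= 1 and negative iff every assessment scores 0.  Surgeries in
    ``surgery_patients`` with no assessment are returned as exclusions.

    Returns ``(labels, excluded_surgery_ids)``.
    """
    cats = nudesc[NUDESC_CATEGORIES].to_numpy()
    if cats.size and (not np.isin(cats, [0, 1, 2]).all()):
        raise ValueError("Nu-DESC category points must be in {0, 1, 2}")
    if isinstance(surgery_patients, pd.Series):
        surgery_patients = surgery_patients.to_dict()
    totals = nudesc.assign(total=cats.sum(axis=1)) if cats.size else nudesc.assign(total=[])
    by_surgery = totals.groupby("surgery_id")["total"]
    positive = by_surgery.max() >= 1
    counts = by_surgery.size()
    labels: list[SurgeryLabel] = []
    excluded: list[object] = []
    for sid, pid in surgery_patients.items():
        if sid in counts.index:
            labels.append(
                SurgeryLabel(sid, pid, int(positive.loc[sid]), int(counts.loc[sid]))
            )
        else:
            excluded.append(sid)
    if excluded:
        logger.info("excluded %d surgeries without Nu-DESC assessment", len(excluded))
    return labels, excluded


def labels_frame(labels: list[SurgeryLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "surgery_id": [l.surgery_id for l in labels],
            "patient_id": [l.patient_id for l in labels],
            "y": [l.y for l in labels],
            "n_assessments": [l.n_assessments for l in labels],
        }
    )


# ---------------------------------------------------------------------------
# Cleaning and availability


def clean_valid_ranges(
    events: pd.DataFrame, specs: list[FeatureSpec], inclusive: bool = True
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Replace physiologically impossible values by NaN.

    Bounds are inclusive by default: a value exactly at a range bound is
    retained.  Row count is never changed.  Returns the cleaned table and
    per-feature removal counts.
    """
    by_name = validate_specs(specs)
    unknown = set(events["feature_name"].unique()) - set(by_name)
    if unknown:
        raise ValueError(f"events reference undeclared features: {sorted(unknown)}")
    out = events.copy()
    removed: dict[str, int] = {}
    for name, spec in by_name.items():
        if spec.valid_range is None:
            continue
        low, high = spec.valid_range
        sel = out["feature_name"] == name
        vals = out.loc[sel, "value"]
        if inclusive:
            bad = (vals < low) | (vals > high)
        else:
            bad = (vals <= low) | (vals >= high)
        n_bad = int(bad.sum())
        if n_bad:
            out.loc[sel & bad.reindex(out.index, fill_value=False), "value"] = np.nan
        removed[name] = n_bad
    return out, removed


def filter_by_availability(
    events: pd.DataFrame,
    statics: pd.DataFrame,
    patient_ids,
    threshold: float = 0.01,
) -> list[str]:
    """Feature names observed for at least ``threshold`` of patients (inclusive)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    patient_ids = list(patient_ids)
    if not patient_ids:
        raise ValueError("empty patient set")
    n = len(set(patient_ids))
    pat_set = set(patient_ids)
    retained = []
    ev = events[events["patient_id"].isin(pat_set) & events["value"].notna()]
    per_feature = ev.groupby("feature_name")["patient_id"].nunique()
    for name, count in per_feature.items():
        if count / n >= threshold:
            retained.append(name)
    # static features: one column per feature, observed where non-null
    static_cols = [c for c in statics.columns if c not in ("surgery_id", "patient_id")]
    st = statics[statics["patient_id"].isin(pat_set)]
    for col in static_cols:
        n_obs = st.loc[st[col].notna(), "patient_id"].nunique()
        if n_obs / n >= threshold:
            retained.append(col)
    return retained


# ---------------------------------------------------------------------------
# Patient-level splitting


@dataclass(frozen=True)
class CohortSplit:
    """Patient-disjoint train/test partition; all surgeries of a patient fall
    on one side."""

    train_patient_ids: frozenset = field(default_factory=frozenset)
    test_patient_ids: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def side(self, patient_id) -> str:
        if patient_id in self.train_patient_ids:
            return "train"
        if patient_id in self.test_patient_ids:
            return "test"
        raise KeyError(patient_id)


def split_by_patient(
    labels: list[SurgeryLabel], test_fraction: float, seed: int
) -> CohortSplit:
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    patients = sorted({l.patient_id for l in labels}, key=str)
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_test = int(round(test_fraction * len(patients)))
    n_test = min(max(n_test, 1), len(patients) - 1)
    test = frozenset(patients[i] for i in order[:n_test])
    train = frozenset(patients[i] for i in order[n_test:])
    return CohortSplit(train, test, seed)
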