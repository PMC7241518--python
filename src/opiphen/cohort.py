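"""Study-eligibility algorithm, index date, observation window, and outcome.

Eligibility for the long-term ER/LA cohort requires, for each patient:

* age >= 18 years by the study start date;
* an index date — the first ER/LA dispensing ``d`` such that total ER/LA
  days' supply dispensed during the closed 90-day window ``[d, d+89]``
  reaches 60 days (both lengths configurable; buprenorphine products are
  never ER/LA-class in the drug catalog, so they cannot qualify);
* continuous enrollment covering 6 months before through 18 months after the
  index date (24 months total), with an optional gap-bridging tolerance;
* encounters in at least eight distinct calendar quarters of the study
  period; and
* no nursing-home/hospice-style care flag.

The observation window is 36 months: 12 months before through 24 months
after the index date (calendar-month arithmetic with end-of-month clamping;
the window ends the day before the +24-month anniversary).  The reference
outcome is positive when the documented onset falls on or before the window
end — onsets before the window also count as positive — and negative when
there is no onset or the onset falls after the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .synthetic import ClaimsDataset

__all__ = [
    "EligibilityConfig",
    "find_index_date",
    "check_continuous_enrollment",
    "count_encounter_quarters",
    "evaluate_eligibility",
    "build_cohort",
]

ELIGIBILITY_FLAGS = ("flag_age", "flag_index", "flag_enrollment",
                     "flag_quarters", "flag_not_excluded")


@dataclass(frozen=True)
class EligibilityConfig:
    min_days_supply: int = 60
    window_len: int = 90
    pre_index_enrollment: int = 6     # months
    post_index_enrollment: int = 18   # months
    total_enrollment: int = 24        # months
    min_encounter_quarters: int = 8
    enrollment_gap_tolerance: int = 0  # days
    obs_pre: int = 12                  # months
    obs_post: int = 24                 # months

    def validate(self) -> None:
        for name in ("min_days_supply", "window_len", "pre_index_enrollment",
                     "post_index_enrollment", "total_enrollment",
                     "min_encounter_quarters", "obs_pre", "obs_post"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.enrollment_gap_tolerance < 0:
            raise ConfigError("enrollment_gap_tolerance must be >= 0")
        if self.pre_index_enrollment + self.post_index_enrollment > self.total_enrollment:
            raise ConfigError("pre + post enrollment months exceed total_enrollment")


def find_index_date(dispensings: pd.DataFrame,
                    config: EligibilityConfig | None = None) -> pd.Timestamp | None:
    """First ER/LA fill opening a window that accumulates the supply minimum.

    Candidate windows are anchored at ER/LA dispense dates (the index is by
    definition a dispensing date); days' supply counts toward a window by
    dispense date.  Returns ``None`` when no window qualifies.
    """
    config = config or EligibilityConfig()
    if len(dispensings) == 0:
        return None
    if (dispensings["days_supply"] < 0).any():
        bad = dispensings.loc[dispensings["days_supply"] < 0, "patient_id"].unique()
        raise DataError(f"negative days_supply for patients: {list(bad)}")
    erla = dispensings[dispensings["drug_class"] == "ERLA_opioid"]
    if len(erla) == 0:
        return None
    erla = erla.sort_values("dispense_date")
    dates = erla["dispense_date"].to_numpy()
    supply = erla["days_supply"].to_numpy(dtype=float)
    horizon = np.timedelta64(config.window_len - 1, "D")
    for i in range(len(dates)):
        in_window = (dates >= dates[i]) & (dates <= dates[i] + horizon)
        if supply[in_window].sum() >= config.min_days_supply:
            return pd.Timestamp(dates[i])
    return None


def _merge_spans(spans: pd.DataFrame, gap_tolerance: int) -> list[tuple]:
    ordered = spans.sort_values("start_date")
    merged: list[list] = []
    for start, end in zip(ordered["start_date"], ordered["end_date"]):
        if start > end:
            raise DataError("enrollment span with start after end")
        if merged and (start - merged[-1][1]).days - 1 <= gap_tolerance:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(m) for m in merged]


def check_continuous_enrollment(spans: pd.DataFrame, index_date: pd.Timestamp,
                                config: EligibilityConfig | None = None) -> bool:
    """True iff one (gap-bridged) span covers index -6 months .. +18 months."""
    config = config or EligibilityConfig()
    if len(spans) == 0:
        return False
    need_start = index_date - pd.DateOffset(months=config.pre_index_enrollment)
    need_end = index_date + pd.DateOffset(months=config.post_index_enrollment)
    for start, end in _merge_spans(spans, config.enrollment_gap_tolerance):
        if start <= need_start and end >= need_end:
            return True
    return False


def count_encounter_quarters(encounters: pd.DataFrame) -> int:
    """Number of distinct calendar quarters containing at least one encounter."""
    if len(encounters) == 0:
        return 0
    return encounters["date"].dt.to_period("Q").nunique()


def observation_window(index_date: pd.Timestamp,
                       config: EligibilityConfig | None = None
                       ) -> tuple[pd.Timestamp, pd.Timestamp]:
    config = config or EligibilityConfig()
    start = index_date - pd.DateOffset(months=config.obs_pre)
    end = index_date + pd.DateOffset(months=config.obs_post) - pd.Timedelta(days=1)
    return start, end


def evaluate_eligibility(dataset: ClaimsDataset,
                         config: EligibilityConfig | None = None) -> pd.DataFrame:
    """One audit row per patient: all eligibility flags plus derived fields.

    Columns: patient_id, the five flags, eligible, index_date,
    observation_start, observation_end, outcome_36m, age_at_index.
    """
    config = config or EligibilityConfig()
    config.validate()
    demo = dataset.demographics
    study_start = dataset.study_start
    disp_by_pid = dict(iter(dataset.dispensings.groupby("patient_id", sort=False))) \
        if len(dataset.dispensings) else {}
    span_by_pid = dict(iter(dataset.enrollment.groupby("patient_id", sort=False))) \
        if len(dataset.enrollment) else {}
    enc_by_pid = dict(iter(dataset.encounters.groupby("patient_id", sort=False))) \
        if len(dataset.encounters) else {}
    labels = dataset.labels.set_index("patient_id") if len(dataset.labels) else None

    rows = []
    missing_labels = []
    for rec in demo.itertuples(index=False):
        pid = rec.patient_id
        age_at_start = (study_start - rec.birth_date).days / 365.25
        flag_age = age_at_start >= 18.0
        flag_not_excluded = not bool(rec.excluded_care)

        disp = disp_by_pid.get(pid)
        index_date = find_index_date(disp, config) if disp is not None else None
        flag_index = index_date is not None

        flag_enrollment = False
        if flag_index:
            spans = span_by_pid.get(pid)
            flag_enrollment = spans is not None and \
                check_continuous_enrollment(spans, index_date, config)
        enc = enc_by_pid.get(pid)
        n_quarters = count_encounter_quarters(enc) if enc is not None else 0
        flag_quarters = n_quarters >= config.min_encounter_quarters

        eligible = all((flag_age, flag_index, flag_enrollment, flag_quarters,
                        flag_not_excluded))
        obs_start = obs_end = pd.NaT
        outcome = pd.NA
        age_at_index = np.nan
        if flag_index:
            obs_start, obs_end = observation_window(index_date, config)
            age_at_index = (index_date - rec.birth_date).days / 365.25
        if eligible:
            if labels is None or pid not in labels.index:
                missing_labels.append(pid)
            else:
                onset = labels.loc[pid, "onset_date"]
                has_onset = bool(labels.loc[pid, "problem_use"]) and pd.notna(onset)
                outcome = bool(has_onset and onset <= obs_end)
        rows.append((pid, flag_age, flag_index, flag_enrollment, flag_quarters,
                     flag_not_excluded, eligible, index_date, obs_start, obs_end,
                     outcome, age_at_index))
    if missing_labels:
        raise DataError("missing reference label for eligible patients: "
                        f"{missing_labels[:20]}")
    return pd.DataFrame(rows, columns=[
        "patient_id", *ELIGIBILITY_FLAGS, "eligible", "index_date",
        "observation_start", "observation_end", "outcome_36m", "age_at_index"])


def build_cohort(dataset: ClaimsDataset,
                 config: EligibilityConfig | None = None) -> pd.DataFrame:
    """Eligible cohort members with index date, window, and outcome.

    A row per patient passing every eligibility criterion; ``outcome_36m`` is
    a plain boolean.  Raises :class:`DataError` when an eligible patient has
    no reference label.
    """
    audit = evaluate_eligibility(dataset, config)
    cohort = audit[audit["eligible"]].drop(columns=["eligible"]).reset_index(drop=True)
    cohort["outcome_36m"] = cohort["outcome_36m"].astype(bool)
    return cohort
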