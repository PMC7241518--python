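"""Predictor operationalization over each patient's 36-month observation window.

Candidate predictors are instances of :class:`PredictorSpec`, a named builder
family plus parameters.  The shipped catalog (:func:`default_spec_library`)
is a curated set of ~115 specs spanning every predictor category of the
claims codebook: diagnosis flags/counts/percent-of-quarters, days'-supply
aggregates, morphine-equivalent (MEQ) dose summaries, overlapping-fill
("early refill") patterns, concomitant opioid/psychoactive use, emergency
room encounters during opioid exposure, urine-drug-screen proximity,
OUD-treatment medications, a simplified Charlson index, demographics, and
age-group interaction terms.

Coverage arithmetic: a fill of ``s`` days dispensed on day ``d`` covers the
closed interval ``[d, d+s-1]``.  Daily MEQ on a covered day is
``quantity * mg_per_unit * meq_factor / days_supply`` summed over all fills
covering that day.  Month and quarter grains use calendar boundaries clipped
to the observation window; partial first/last quarters count as quarters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import (CHARLSON_WEIGHTS, DIAGNOSIS_GROUPS, OPIOID_CLASSES,
                    CodeGroup, charlson_index)
from .errors import ConfigError, DataError
from .synthetic import ClaimsDataset

__all__ = [
    "PredictorSpec",
    "PredictorMatrix",
    "daily_meq_series",
    "detect_overlap_events",
    "build_predictor",
    "build_matrix",
    "default_spec_library",
    "risk_ratio_screen",
]

_EPOCH = np.datetime64("1970-01-01", "D")
_DOW_NAMES = {"Mon": 0, "Tue": 1, "Wed": 2, "Thu": 3, "Fri": 4, "Sat": 5, "Sun": 6}
WEEKEND_DOW = ("Sat", "Sun", "Mon")

FAMILIES = ("diagnosis_flag", "diagnosis_count", "pct_quarters", "pain_site_count",
            "days_supply_agg", "fill_count", "meq_measure", "overlap_fills",
            "concomitant_use", "er_during_exposure", "enc_count",
            "procedure_proximity", "oud_treatment_med", "charlson",
            "demographic", "interaction")


@dataclass(frozen=True)
class PredictorSpec:
    """A named, parameterized predictor builder."""

    name: str
    family: str
    params: dict = field(default_factory=dict)
    output_type: str = "binary"  # binary | count | proportion | continuous

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown builder family {self.family!r} "
                              f"for predictor {self.name!r}")


def _days(dates) -> np.ndarray:
    return (np.asarray(dates, dtype="datetime64[D]") - _EPOCH).astype(np.int64)


def _month_quarter(days: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    di = pd.DatetimeIndex(np.asarray(days, dtype="datetime64[D]"))
    month = di.year.to_numpy() * 12 + (di.month.to_numpy() - 1)
    quarter = di.year.to_numpy() * 4 + (di.quarter.to_numpy() - 1)
    return month.astype(np.int64), quarter.astype(np.int64)


@dataclass
class _Window:
    start: int
    end: int
    start_month: int
    end_month: int
    start_q: int
    end_q: int

    @property
    def n_days(self) -> int:
        return self.end - self.start + 1

    @property
    def n_months(self) -> int:
        return self.end_month - self.start_month + 1

    @property
    def n_quarters(self) -> int:
        return self.end_q - self.start_q + 1

    @classmethod
    def from_dates(cls, start_date, end_date) -> "_Window":
        d = _days([start_date, end_date])
        m, q = _month_quarter(d)
        return cls(int(d[0]), int(d[1]), int(m[0]), int(m[1]), int(q[0]), int(q[1]))


@dataclass
class _PatientEvents:
    """One patient's records as sorted numpy arrays (days since 1970-01-01)."""

    disp_day: np.ndarray
    disp_class: np.ndarray
    disp_supply: np.ndarray
    disp_quantity: np.ndarray
    disp_mg: np.ndarray
    disp_meq: np.ndarray
    disp_dow: np.ndarray
    dx_day: np.ndarray
    dx_code: np.ndarray
    dx_month: np.ndarray
    dx_quarter: np.ndarray
    enc_day: np.ndarray
    enc_is_er: np.ndarray
    proc_day: np.ndarray
    proc_cat: np.ndarray
    age_at_index: float = np.nan
    sex: str = ""

    _group_masks: dict = field(default_factory=dict, repr=False)

    def group_mask(self, group: CodeGroup) -> np.ndarray:
        key = group.name
        if key not in self._group_masks:
            uniq = {c: group.matches(c) for c in set(self.dx_code.tolist())}
            self._group_masks[key] = np.array(
                [uniq[c] for c in self.dx_code], dtype=bool) \
                if len(self.dx_code) else np.zeros(0, dtype=bool)
        return self._group_masks[key]


_EMPTY_F = np.empty(0, dtype=float)
_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_O = np.empty(0, dtype=object)


def _events_from_frames(disp, dx, enc, proc, age_at_index, sex) -> _PatientEvents:
    if disp is not None and len(disp):
        disp = disp.sort_values("dispense_date")
        d_day = _days(disp["dispense_date"].to_numpy())
        ev_disp = (d_day, disp["drug_class"].to_numpy(dtype=object),
                   disp["days_supply"].to_numpy(dtype=np.int64),
                   disp["quantity"].to_numpy(dtype=float),
                   disp["mg_per_unit"].to_numpy(dtype=float),
                   disp["meq_factor"].to_numpy(dtype=float),
                   (d_day + 3) % 7)
    else:
        ev_disp = (_EMPTY_I, _EMPTY_O, _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F,
                   _EMPTY_I)
    if dx is not None and len(dx):
        dx = dx.sort_values("date")
        x_day = _days(dx["date"].to_numpy())
        m, q = _month_quarter(x_day)
        ev_dx = (x_day, dx["code"].to_numpy(dtype=object), m, q)
    else:
        ev_dx = (_EMPTY_I, _EMPTY_O, _EMPTY_I, _EMPTY_I)
    if enc is not None and len(enc):
        enc = enc.sort_values("date")
        ev_enc = (_days(enc["date"].to_numpy()),
                  (enc["setting"] == "ER").to_numpy())
    else:
        ev_enc = (_EMPTY_I, np.zeros(0, dtype=bool))
    if proc is not None and len(proc):
        proc = proc.sort_values("date")
        ev_proc = (_days(proc["date"].to_numpy()),
                   proc["category"].to_numpy(dtype=object))
    else:
        ev_proc = (_EMPTY_I, _EMPTY_O)
    return _PatientEvents(*ev_disp, *ev_dx, *ev_enc, *ev_proc,
                          age_at_index=age_at_index, sex=sex)


# ---------------------------------------------------------------------------
# core dose / overlap primitives
# ---------------------------------------------------------------------------

def _meq_series(ev: _PatientEvents, w: _Window) -> np.ndarray:
    series = np.zeros(w.n_days)
    is_opioid = np.isin(ev.disp_class, OPIOID_CLASSES)
    for i in np.flatnonzero(is_opioid):
        s = int(ev.disp_supply[i])
        if s <= 0:
            raise DataError("zero or negative days_supply in opioid dispensing")
        daily = ev.disp_quantity[i] * ev.disp_mg[i] * ev.disp_meq[i] / s
        lo = max(ev.disp_day[i], w.start)
        hi = min(ev.disp_day[i] + s - 1, w.end)
        if lo <= hi:
            series[lo - w.start: hi - w.start + 1] += daily
    return series


def daily_meq_series(dispensings: pd.DataFrame, window) -> np.ndarray:
    """Per-day morphine-equivalent dose over ``window = (start, end)`` dates.

    Each opioid fill contributes ``quantity * mg_per_unit * meq_factor /
    days_supply`` on every day of its coverage interval, summed across
    overlapping fills; days outside any coverage are 0.
    """
    w = _Window.from_dates(window[0], window[1])
    ev = _events_from_frames(dispensings, None, None, None, np.nan, "")
    return _meq_series(ev, w)


def _coverage_mask(ev: _PatientEvents, w: _Window, classes,
                   min_active: int = 1) -> np.ndarray:
    """Days of the window covered by >= ``min_active`` simultaneous fills."""
    count = np.zeros(w.n_days, dtype=np.int32)
    sel = np.isin(ev.disp_class, tuple(classes))
    for i in np.flatnonzero(sel):
        lo = max(ev.disp_day[i], w.start)
        hi = min(ev.disp_day[i] + int(ev.disp_supply[i]) - 1, w.end)
        if lo <= hi:
            count[lo - w.start: hi - w.start + 1] += 1
    return count >= min_active


def _overlap_chain_count(days: np.ndarray, supply: np.ndarray,
                         span_days: int, min_fills: int = 3) -> int:
    """Number of overlap chains containing >= min_fills fills in a rolling span.

    Fills are chained when each fill's dispense date falls on or before the
    running coverage end of the chain (partial overlap); a chain qualifies
    when some ``min_fills`` of its members fall within ``span_days`` days.
    """
    if len(days) < min_fills:
        return 0
    order = np.argsort(days, kind="stable")
    days, supply = days[order], supply[order]
    n_events = 0
    comp_start = 0
    run_end = days[0] + supply[0] - 1
    for i in range(1, len(days) + 1):
        if i == len(days) or days[i] > run_end:
            comp_days = days[comp_start:i]
            if len(comp_days) >= min_fills:
                hits = comp_days[min_fills - 1:] - comp_days[:1 - min_fills] \
                    <= span_days - 1
                n_events += int(hits.any())
            if i < len(days):
                comp_start = i
                run_end = days[i] + supply[i] - 1
        else:
            run_end = max(run_end, days[i] + supply[i] - 1)
    return n_events


def _overlap_events(ev: _PatientEvents, w: _Window, classes, max_days_supply,
                    dow_set, window_len_months: int, min_fills: int = 3) -> int:
    sel = np.isin(ev.disp_class, tuple(classes))
    sel &= (ev.disp_day >= w.start) & (ev.disp_day <= w.end)
    if max_days_supply is not None:
        sel &= ev.disp_supply <= max_days_supply
    if dow_set is not None:
        dows = [_DOW_NAMES[d] if isinstance(d, str) else int(d) for d in dow_set]
        sel &= np.isin(ev.disp_dow, dows)
    span_days = int(round(30.4375 * window_len_months))
    return _overlap_chain_count(ev.disp_day[sel], ev.disp_supply[sel], span_days,
                                min_fills)


def detect_overlap_events(dispensings: pd.DataFrame, class_filter=("IR_opioid",),
                          max_days_supply: int | None = 14,
                          dow_set=WEEKEND_DOW,
                          window_len_months: int = 3,
                          min_fills: int = 3,
                          window=None, count: bool = False):
    """Early-refill pattern: >= ``min_fills`` partially overlapping fills.

    A fill partially overlaps a prior fill when its dispense date is on or
    before the prior fill's coverage end.  Each fill must pass the
    days'-supply and day-of-week filters; the chained fills must fall within
    a rolling window of ``window_len_months`` (~30.44-day months).  Returns a
    boolean flag, or the number of qualifying chains when ``count=True``.
    """
    if len(dispensings) == 0:
        return 0 if count else False
    if window is None:
        dmin = dispensings["dispense_date"].min()
        dmax = dispensings["dispense_date"].max() + pd.Timedelta(days=400)
        window = (dmin, dmax)
    w = _Window.from_dates(window[0], window[1])
    ev = _events_from_frames(dispensings, None, None, None, np.nan, "")
    n = _overlap_events(ev, w, class_filter, max_days_supply, dow_set,
                        window_len_months, min_fills)
    return n if count else n > 0


# ---------------------------------------------------------------------------
# builder families
# ---------------------------------------------------------------------------

def _resolve_group(params) -> CodeGroup:
    g = params["code_group"]
    if isinstance(g, CodeGroup):
        return g
    try:
        return DIAGNOSIS_GROUPS[g]
    except KeyError:
        raise ConfigError(f"unknown diagnosis code group {g!r}") from None


def _dx_in_window(ev: _PatientEvents, w: _Window, group: CodeGroup) -> np.ndarray:
    in_w = (ev.dx_day >= w.start) & (ev.dx_day <= w.end)
    return in_w & ev.group_mask(group)


def _grain_counts(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return np.bincount(values - lo, minlength=hi - lo + 1)


def _pct_quarters(ev, w, mask) -> float:
    qs = np.unique(ev.dx_quarter[mask])
    return len(qs) / w.n_quarters


_PAIN_GROUPS = ("back_pain", "neck_disorder", "headache_migraine",
                "neuropathic_pain", "fibromyalgia", "arthritis")


def _exposure_mask(ev: _PatientEvents, w: _Window, exposure: str,
                   threshold: float | None) -> np.ndarray:
    if exposure == "opioid_coverage":
        return _coverage_mask(ev, w, OPIOID_CLASSES)
    if exposure == "overlap_coverage":
        return _coverage_mask(ev, w, OPIOID_CLASSES, min_active=2)
    if exposure == "high_meq":
        return _meq_series(ev, w) >= (threshold or 90.0)
    if exposure == "same_day_dispense":
        mask = np.zeros(w.n_days, dtype=bool)
        sel = np.isin(ev.disp_class, OPIOID_CLASSES)
        days = ev.disp_day[sel]
        days = days[(days >= w.start) & (days <= w.end)]
        mask[days - w.start] = True
        return mask
    raise ConfigError(f"unknown exposure {exposure!r}")


def _build_one(ev: _PatientEvents, spec: PredictorSpec, w: _Window,
               built: dict | None = None) -> float:
    p = spec.params
    fam = spec.family

    if fam == "diagnosis_flag":
        return float(_dx_in_window(ev, w, _resolve_group(p)).any())

    if fam == "diagnosis_count":
        mask = _dx_in_window(ev, w, _resolve_group(p))
        grain = p.get("grain", "overall")
        if grain == "overall":
            return float(mask.sum())
        if grain == "month":
            counts = _grain_counts(ev.dx_month[mask], w.start_month, w.end_month) \
                if mask.any() else np.zeros(1)
            return float(counts.max())
        if grain == "quarter":
            counts = _grain_counts(ev.dx_quarter[mask], w.start_q, w.end_q) \
                if mask.any() else np.zeros(1)
            return float(counts.max())
        raise ConfigError(f"unknown grain {grain!r}")

    if fam == "pct_quarters":
        mask = _dx_in_window(ev, w, _resolve_group(p))
        return _pct_quarters(ev, w, mask)

    if fam == "pain_site_count":
        return float(sum(_dx_in_window(ev, w, DIAGNOSIS_GROUPS[g]).any()
                         for g in _PAIN_GROUPS))

    if fam == "days_supply_agg":
        classes = tuple(p.get("drug_classes", OPIOID_CLASSES))
        sel = np.isin(ev.disp_class, classes) & \
            (ev.disp_day >= w.start) & (ev.disp_day <= w.end)
        grain = p.get("grain", "overall")
        if grain == "overall":
            return float(ev.disp_supply[sel].sum())
        if grain not in ("month", "quarter"):
            raise ConfigError(f"unknown grain {grain!r}")
        lo, hi = (w.start_month, w.end_month) if grain == "month" \
            else (w.start_q, w.end_q)
        m, q = _month_quarter(ev.disp_day[sel]) if sel.any() else (_EMPTY_I, _EMPTY_I)
        bucket = m if grain == "month" else q
        sums = np.zeros(hi - lo + 1)
        np.add.at(sums, bucket - lo, ev.disp_supply[sel])
        stat = p.get("stat", "max")
        return float(sums.max() if stat == "max" else sums.mean())

    if fam == "fill_count":
        classes = tuple(p.get("drug_classes", OPIOID_CLASSES))
        sel = np.isin(ev.disp_class, classes) & \
            (ev.disp_day >= w.start) & (ev.disp_day <= w.end)
        if p.get("dow_set"):
            dows = [_DOW_NAMES[d] for d in p["dow_set"]]
            sel &= np.isin(ev.disp_dow, dows)
        grain = p.get("grain", "overall")
        if grain == "overall":
            return float(sel.sum())
        m, q = _month_quarter(ev.disp_day[sel]) if sel.any() else (_EMPTY_I, _EMPTY_I)
        if grain == "month":
            counts = _grain_counts(m, w.start_month, w.end_month) if sel.any() \
                else np.zeros(1)
        else:
            counts = _grain_counts(q, w.start_q, w.end_q) if sel.any() else np.zeros(1)
        return float(counts.max())

    if fam == "meq_measure":
        kind = p["kind"]
        series = _meq_series(ev, w)
        if kind == "mean_daily":
            return float(series.mean())
        if kind == "max_daily":
            return float(series.max()) if len(series) else 0.0
        if kind == "meq_per_supply_day":
            covered = series > 0
            return float(series[covered].mean()) if covered.any() else 0.0
        if kind == "days_above":
            return float((series >= p["threshold"]).sum())
        if kind == "pct_quarters_above":
            days = np.arange(w.start, w.end + 1)[series >= p["threshold"]]
            if len(days) == 0:
                return 0.0
            _, q = _month_quarter(days)
            return len(np.unique(q)) / w.n_quarters
        if kind == "quarter_pct_change":
            # flag: any consecutive-quarter increase in total MEQ >= threshold %
            days = np.arange(w.start, w.end + 1)
            _, q = _month_quarter(days)
            totals = np.zeros(w.n_quarters)
            np.add.at(totals, q - w.start_q, series)
            prev, nxt = totals[:-1], totals[1:]
            with np.errstate(divide="ignore", invalid="ignore"):
                change = np.where(prev > 0, (nxt - prev) / prev, np.nan)
            return float(np.nanmax(change) >= p["threshold"] / 100.0) \
                if np.isfinite(change).any() else 0.0
        raise ConfigError(f"unknown meq_measure kind {kind!r}")

    if fam == "overlap_fills":
        n = _overlap_events(ev, w, tuple(p.get("drug_classes", ("IR_opioid",))),
                            p.get("max_days_supply"), p.get("dow_set"),
                            p.get("window_len_months", 3),
                            p.get("min_fills", 3))
        return float(n) if spec.output_type == "count" else float(n > 0)

    if fam == "concomitant_use":
        a = _coverage_mask(ev, w, tuple(p.get("class_a", OPIOID_CLASSES)))
        b = _coverage_mask(ev, w, tuple(p.get("class_b", ("benzodiazepine",))))
        both = a & b
        stat = p.get("stat", "days")
        if stat == "days":
            return float(both.sum())
        if stat == "flag":
            return float(both.any())
        if stat == "pct_quarters":
            days = np.arange(w.start, w.end + 1)[both]
            if len(days) == 0:
                return 0.0
            _, q = _month_quarter(days)
            return len(np.unique(q)) / w.n_quarters
        raise ConfigError(f"unknown concomitant_use stat {stat!r}")

    if fam == "er_during_exposure":
        mask = _exposure_mask(ev, w, p.get("exposure", "opioid_coverage"),
                              p.get("threshold"))
        er_days = ev.enc_day[ev.enc_is_er]
        er_days = er_days[(er_days >= w.start) & (er_days <= w.end)]
        hits = mask[er_days - w.start]
        return float(hits.sum()) if spec.output_type == "count" else float(hits.any())

    if fam == "enc_count":
        er_days = ev.enc_day[ev.enc_is_er] if p.get("er_only", True) else ev.enc_day
        er_days = er_days[(er_days >= w.start) & (er_days <= w.end)]
        grain = p.get("grain", "overall")
        if grain == "overall":
            return float(len(er_days))
        _, q = _month_quarter(er_days) if len(er_days) else (_EMPTY_I, _EMPTY_I)
        if grain == "pct_quarters":
            return len(np.unique(q)) / w.n_quarters
        counts = _grain_counts(q, w.start_q, w.end_q) if len(er_days) else np.zeros(1)
        return float(counts.max())

    if fam == "procedure_proximity":
        sel = (ev.proc_cat == p["category"]) & \
            (ev.proc_day >= w.start) & (ev.proc_day <= w.end)
        days = ev.proc_day[sel]
        anchor = p.get("anchor")
        if anchor is not None:
            mask = _exposure_mask(ev, w, anchor, p.get("threshold"))
            k = int(p.get("k_days", 7))
            anchor_days = np.arange(w.start, w.end + 1)[mask]
            if len(anchor_days) == 0 or len(days) == 0:
                near = np.zeros(0, dtype=bool)
            else:
                idx = np.searchsorted(anchor_days, days)
                left = anchor_days[np.clip(idx - 1, 0, len(anchor_days) - 1)]
                right = anchor_days[np.clip(idx, 0, len(anchor_days) - 1)]
                near = np.minimum(np.abs(days - left), np.abs(days - right)) <= k
            days = days[near] if len(near) else days[:0]
        stat = p.get("stat", "count")
        if stat == "count":
            return float(len(days))
        if stat == "flag":
            return float(len(days) > 0)
        if stat == "pct_quarters":
            if len(days) == 0:
                return 0.0
            _, q = _month_quarter(days)
            return len(np.unique(q)) / w.n_quarters
        raise ConfigError(f"unknown procedure stat {stat!r}")

    if fam == "oud_treatment_med":
        sel = (ev.disp_class == "OUD_treatment") & \
            (ev.disp_day >= w.start) & (ev.disp_day <= w.end)
        stat = p.get("stat", "ever")
        if stat == "ever":
            return float(sel.any())
        if stat == "total_supply":
            return float(ev.disp_supply[sel].sum())
        if stat == "n_fills":
            return float(sel.sum())
        raise ConfigError(f"unknown oud_treatment_med stat {stat!r}")

    if fam == "charlson":
        in_w = (ev.dx_day >= w.start) & (ev.dx_day <= w.end)
        return float(charlson_index(ev.dx_code[in_w]))

    if fam == "demographic":
        which = p["field"]
        age = ev.age_at_index
        if which == "age_at_index":
            return float(age)
        if which == "age_18_34":
            return float(age < 35)
        if which == "age_35_54":
            return float(35 <= age < 55)
        if which == "age_55_64":
            return float(55 <= age < 65)
        if which == "age_65_plus":
            return float(age >= 65)
        if which == "sex_female":
            return float(ev.sex == "F")
        raise ConfigError(f"unknown demographic field {which!r}")

    if fam == "interaction":
        if built is None:
            raise ConfigError("interaction predictors require previously "
                              "built component columns")
        try:
            return float(built[p["left"]] * built[p["right"]])
        except KeyError as exc:
            raise ConfigError(f"interaction component {exc} not built before "
                              f"{spec.name!r}") from None

    raise ConfigError(f"unknown builder family {fam!r}")


def build_predictor(dataset_slice: dict, spec: PredictorSpec, member) -> float:
    """Build one predictor value for one cohort member.

    ``dataset_slice`` maps table names (dispensings, diagnoses, encounters,
    procedures) to that patient's records; ``member`` is a cohort row (mapping
    or namedtuple) with observation_start/observation_end, age_at_index, sex.
    """
    get = member.get if hasattr(member, "get") else lambda k: getattr(member, k)
    ev = _events_from_frames(dataset_slice.get("dispensings"),
                             dataset_slice.get("diagnoses"),
                             dataset_slice.get("encounters"),
                             dataset_slice.get("procedures"),
                             float(get("age_at_index")), str(get("sex")))
    w = _Window.from_dates(get("observation_start"), get("observation_end"))
    return _build_one(ev, spec, w, built=None)


@dataclass
class PredictorMatrix:
    """Patients x predictors value grid with per-column spec provenance."""

    values: pd.DataFrame
    specs: dict[str, PredictorSpec]

    @property
    def patient_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def to_csv(self, path, provenance_path=None) -> None:
        self.values.to_csv(path, index_label="patient_id")
        if provenance_path is not None:
            import yaml
            doc = {name: {"family": s.family, "output_type": s.output_type,
                          "params": _plain(s.params)}
                   for name, s in self.specs.items()}
            with open(provenance_path, "w") as fh:
                yaml.safe_dump(doc, fh, sort_keys=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, CodeGroup):
        return obj.name
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def build_matrix(dataset: ClaimsDataset, cohort: pd.DataFrame,
                 spec_library: list[PredictorSpec] | None = None,
                 sex_lookup: pd.Series | None = None) -> PredictorMatrix:
    """Operationalize every spec for every cohort member.

    Absence of events encodes as 0/False — the matrix has no missing cells.
    Interaction specs are built after their component columns.
    """
    specs = spec_library if spec_library is not None else default_spec_library()
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"duplicate predictor names: {dupes}")
    base = [s for s in specs if s.family != "interaction"]
    inter = [s for s in specs if s.family == "interaction"]

    if sex_lookup is None:
        sex_lookup = dataset.demographics.set_index("patient_id")["sex"]
    by_pid = {}
    for tname in ("dispensings", "diagnoses", "encounters", "procedures"):
        df = getattr(dataset, tname)
        by_pid[tname] = dict(iter(df.groupby("patient_id", sort=False))) \
            if len(df) else {}

    rows = np.zeros((len(cohort), len(specs)))
    col_of = {s.name: j for j, s in enumerate(specs)}
    for i, member in enumerate(cohort.itertuples(index=False)):
        pid = member.patient_id
        ev = _events_from_frames(
            by_pid["dispensings"].get(pid), by_pid["diagnoses"].get(pid),
            by_pid["encounters"].get(pid), by_pid["procedures"].get(pid),
            float(member.age_at_index), str(sex_lookup.get(pid, "")))
        w = _Window.from_dates(member.observation_start, member.observation_end)
        built: dict[str, float] = {}
        for s in base:
            built[s.name] = _build_one(ev, s, w)
        for s in inter:
            built[s.name] = _build_one(ev, s, w, built=built)
        for name, v in built.items():
            rows[i, col_of[name]] = v
    values = pd.DataFrame(rows, columns=names,
                          index=pd.Index(cohort["patient_id"], name="patient_id"))
    return PredictorMatrix(values, {s.name: s for s in specs})


# ---------------------------------------------------------------------------
# the shipped catalog
# ---------------------------------------------------------------------------

def default_spec_library() -> list[PredictorSpec]:
    """Curated catalog spanning every predictor category of the codebook."""
    S = PredictorSpec
    specs: list[PredictorSpec] = []

    # --- diagnoses ---------------------------------------------------------
    for g in _PAIN_GROUPS:
        specs.append(S(f"dx_{g}_ever", "diagnosis_flag", {"code_group": g}))
    specs.append(S("dx_pain_site_count", "pain_site_count", {}, "count"))
    for g in ("depression", "bipolar", "anxiety", "schizophrenia"):
        specs.append(S(f"dx_{g}_ever", "diagnosis_flag", {"code_group": g}))
    specs.append(S("dx_depression_n", "diagnosis_count",
                   {"code_group": "depression"}, "count"))
    specs.append(S("dx_mh_max_month", "diagnosis_count",
                   {"code_group": "depression", "grain": "month"}, "count"))
    for g in ("opioid_dependence", "opioid_abuse", "opioid_poisoning", "heroin"):
        specs.append(S(f"dx_{g}_ever", "diagnosis_flag", {"code_group": g}))
    specs.append(S("dx_oud_any_n", "diagnosis_count",
                   {"code_group": "problem_opioid_use"}, "count"))
    specs.append(S("dx_oud_max_quarter", "diagnosis_count",
                   {"code_group": "problem_opioid_use", "grain": "quarter"}, "count"))
    specs.append(S("dx_oud_pct_quarters", "pct_quarters",
                   {"code_group": "problem_opioid_use"}, "proportion"))
    for g in ("alcohol_disorder", "drug_dependence_nonopioid", "tobacco_use"):
        specs.append(S(f"dx_{g}_ever", "diagnosis_flag", {"code_group": g}))
    specs.append(S("dx_insomnia_ever", "diagnosis_flag",
                   {"code_group": "insomnia_sleep"}))
    specs.append(S("dx_insomnia_pct_quarters", "pct_quarters",
                   {"code_group": "insomnia_sleep"}, "proportion"))
    specs.append(S("dx_ptsd_ever", "diagnosis_flag", {"code_group": "ptsd"}))
    specs.append(S("dx_domestic_violence_ever", "diagnosis_flag",
                   {"code_group": "domestic_violence"}))
    specs.append(S("dx_hepatitis_ever", "diagnosis_flag",
                   {"code_group": "hepatitis_cirrhosis"}))
    specs.append(S("dx_hepatitis_n", "diagnosis_count",
                   {"code_group": "hepatitis_cirrhosis"}, "count"))
    specs.append(S("dx_hepatitis_pct_quarters", "pct_quarters",
                   {"code_group": "hepatitis_cirrhosis"}, "proportion"))
    specs.append(S("dx_endocarditis_ever", "diagnosis_flag",
                   {"code_group": "endocarditis"}))
    specs.append(S("dx_ecode_adverse_ever", "diagnosis_flag",
                   {"code_group": "drug_adverse_ecodes"}))
    specs.append(S("dx_ecode_adverse_n", "diagnosis_count",
                   {"code_group": "drug_adverse_ecodes"}, "count"))
    specs.append(S("charlson_index", "charlson", {}, "count"))

    # --- medications: days' supply ----------------------------------------
    for label, classes in (("erla", ("ERLA_opioid",)), ("ir", ("IR_opioid",)),
                           ("opioid", OPIOID_CLASSES),
                           ("benzo", ("benzodiazepine",)),
                           ("psych", ("other_psychoactive",))):
        specs.append(S(f"rx_{label}_supply_total", "days_supply_agg",
                       {"drug_classes": classes}, "count"))
        specs.append(S(f"rx_{label}_supply_max_month", "days_supply_agg",
                       {"drug_classes": classes, "grain": "month", "stat": "max"},
                       "count"))
        specs.append(S(f"rx_{label}_supply_mean_quarter", "days_supply_agg",
                       {"drug_classes": classes, "grain": "quarter", "stat": "mean"},
                       "continuous"))

    # --- fill counts -------------------------------------------------------
    for label, classes in (("erla", ("ERLA_opioid",)), ("ir", ("IR_opioid",)),
                           ("benzo", ("benzodiazepine",))):
        specs.append(S(f"rx_{label}_fills_n", "fill_count",
                       {"drug_classes": classes}, "count"))
        specs.append(S(f"rx_{label}_fills_max_month", "fill_count",
                       {"drug_classes": classes, "grain": "month"}, "count"))
    specs.append(S("rx_opioid_fills_wknd_n", "fill_count",
                   {"drug_classes": OPIOID_CLASSES, "dow_set": WEEKEND_DOW},
                   "count"))

    # --- OUD-treatment medications ----------------------------------------
    specs.append(S("rx_oud_treatment_ever", "oud_treatment_med", {"stat": "ever"}))
    specs.append(S("rx_oud_treatment_supply", "oud_treatment_med",
                   {"stat": "total_supply"}, "count"))
    specs.append(S("rx_oud_treatment_fills", "oud_treatment_med",
                   {"stat": "n_fills"}, "count"))

    # --- MEQ ---------------------------------------------------------------
    specs.append(S("meq_mean_daily", "meq_measure", {"kind": "mean_daily"},
                   "continuous"))
    specs.append(S("meq_max_daily", "meq_measure", {"kind": "max_daily"},
                   "continuous"))
    specs.append(S("meq_per_supply_day", "meq_measure",
                   {"kind": "meq_per_supply_day"}, "continuous"))
    for t in (50, 90, 120):
        specs.append(S(f"meq_days_above_{t}", "meq_measure",
                       {"kind": "days_above", "threshold": t}, "count"))
    for t in (50, 90):
        specs.append(S(f"meq_pct_quarters_above_{t}", "meq_measure",
                       {"kind": "pct_quarters_above", "threshold": t},
                       "proportion"))
    for t in (33, 50, 75):
        specs.append(S(f"meq_quarter_rise_ge_{t}pct", "meq_measure",
                       {"kind": "quarter_pct_change", "threshold": t}))

    # --- overlapping dispensings ("early fills") ---------------------------
    specs.append(S("overlap_ir14_wknd_3in3mo", "overlap_fills",
                   {"drug_classes": ("IR_opioid",), "max_days_supply": 14,
                    "dow_set": WEEKEND_DOW, "window_len_months": 3}))
    specs.append(S("overlap_ir14_3in3mo", "overlap_fills",
                   {"drug_classes": ("IR_opioid",), "max_days_supply": 14,
                    "window_len_months": 3}))
    specs.append(S("overlap_ir14_3in3mo_n", "overlap_fills",
                   {"drug_classes": ("IR_opioid",), "max_days_supply": 14,
                    "window_len_months": 3}, "count"))
    specs.append(S("overlap_erla_3in3mo", "overlap_fills",
                   {"drug_classes": ("ERLA_opioid",), "max_days_supply": 30,
                    "window_len_months": 3}))
    specs.append(S("overlap_opioid_3in3mo_n", "overlap_fills",
                   {"drug_classes": OPIOID_CLASSES, "window_len_months": 3},
                   "count"))
    specs.append(S("overlap_opioid_2in1mo", "overlap_fills",
                   {"drug_classes": OPIOID_CLASSES, "window_len_months": 1,
                    "min_fills": 2}))
    specs.append(S("overlap_days_n", "concomitant_use",
                   {"class_a": OPIOID_CLASSES, "class_b": OPIOID_CLASSES,
                    "stat": "days"}, "count"))

    # --- concomitant use ---------------------------------------------------
    specs.append(S("concom_opioid_benzo_days", "concomitant_use",
                   {"class_b": ("benzodiazepine",), "stat": "days"}, "count"))
    specs.append(S("concom_opioid_benzo_ever", "concomitant_use",
                   {"class_b": ("benzodiazepine",), "stat": "flag"}))
    specs.append(S("concom_opioid_benzo_pct_quarters", "concomitant_use",
                   {"class_b": ("benzodiazepine",), "stat": "pct_quarters"},
                   "proportion"))
    specs.append(S("concom_opioid_psych_days", "concomitant_use",
                   {"class_b": ("other_psychoactive",), "stat": "days"}, "count"))
    specs.append(S("concom_opioid_psych_ever", "concomitant_use",
                   {"class_b": ("other_psychoactive",), "stat": "flag"}))

    # --- encounters --------------------------------------------------------
    specs.append(S("er_visits_n", "enc_count", {}, "count"))
    specs.append(S("er_visits_max_quarter", "enc_count", {"grain": "quarter"},
                   "count"))
    specs.append(S("er_visits_pct_quarters", "enc_count",
                   {"grain": "pct_quarters"}, "proportion"))
    specs.append(S("er_during_opioid_n", "er_during_exposure",
                   {"exposure": "opioid_coverage"}, "count"))
    specs.append(S("er_during_opioid_ever", "er_during_exposure",
                   {"exposure": "opioid_coverage"}))
    specs.append(S("er_during_overlap_n", "er_during_exposure",
                   {"exposure": "overlap_coverage"}, "count"))
    specs.append(S("er_during_high_meq_n", "er_during_exposure",
                   {"exposure": "high_meq", "threshold": 90}, "count"))
    specs.append(S("er_same_day_fill_n", "er_during_exposure",
                   {"exposure": "same_day_dispense"}, "count"))
    specs.append(S("er_same_day_fill_ever", "er_during_exposure",
                   {"exposure": "same_day_dispense"}))

    # --- procedures --------------------------------------------------------
    specs.append(S("uds_n", "procedure_proximity",
                   {"category": "urine_drug_screen", "stat": "count"}, "count"))
    specs.append(S("uds_pct_quarters", "procedure_proximity",
                   {"category": "urine_drug_screen", "stat": "pct_quarters"},
                   "proportion"))
    specs.append(S("uds_near_overlap_n", "procedure_proximity",
                   {"category": "urine_drug_screen", "anchor": "overlap_coverage",
                    "k_days": 7, "stat": "count"}, "count"))
    specs.append(S("uds_near_high_meq_n", "procedure_proximity",
                   {"category": "urine_drug_screen", "anchor": "high_meq",
                    "threshold": 90, "k_days": 7, "stat": "count"}, "count"))
    specs.append(S("sud_treatment_ever", "procedure_proximity",
                   {"category": "SUD_treatment", "stat": "flag"}))
    specs.append(S("sud_treatment_n", "procedure_proximity",
                   {"category": "SUD_treatment", "stat": "count"}, "count"))
    specs.append(S("surgery_n", "procedure_proximity",
                   {"category": "surgery", "stat": "count"}, "count"))

    # --- demographics ------------------------------------------------------
    specs.append(S("age_at_index", "demographic", {"field": "age_at_index"},
                   "continuous"))
    for f in ("age_18_34", "age_35_54", "age_55_64", "age_65_plus", "sex_female"):
        specs.append(S(f, "demographic", {"field": f}))

    # --- interactions ------------------------------------------------------
    for left, right in (("age_18_34", "overlap_ir14_wknd_3in3mo"),
                        ("age_18_34", "dx_opioid_dependence_ever"),
                        ("age_18_34", "meq_mean_daily"),
                        ("age_18_34", "er_visits_n"),
                        ("sex_female", "concom_opioid_benzo_ever")):
        specs.append(S(f"ix_{left}_x_{right}", "interaction",
                       {"left": left, "right": right}, "continuous"))
    return specs


# ---------------------------------------------------------------------------
# RR screening
# ---------------------------------------------------------------------------

def risk_ratio_screen(matrix: PredictorMatrix | pd.DataFrame, outcomes,
                      dichotomization_rules: dict[str, float] | None = None
                      ) -> pd.DataFrame:
    """Per-predictor risk-ratio screen of discriminating signal.

    RR = (% of outcome-positives with the predictor TRUE) /
    (% of outcome-negatives with the predictor TRUE).  Binary columns are
    used as-is; other columns are dichotomized at their configured cut-point
    (value >= cut), defaulting to "any nonzero".  A zero denominator marks
    the RR undefined (NaN) rather than infinite.
    """
    values = matrix.values if isinstance(matrix, PredictorMatrix) else matrix
    specs = matrix.specs if isinstance(matrix, PredictorMatrix) else {}
    rules = dichotomization_rules or {}
    y = np.asarray(outcomes, dtype=bool)
    if len(y) != len(values):
        raise DataError("outcomes length does not match matrix rows")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    rows = []
    for name in values.columns:
        col = values[name].to_numpy(dtype=float)
        spec = specs.get(name)
        if name in rules:
            flag = col >= rules[name]
        elif spec is not None and spec.output_type == "binary":
            flag = col > 0.5
        elif set(np.unique(col)) <= {0.0, 1.0}:
            flag = col > 0.5
        else:
            flag = col > 0
        p_pos = flag[y].mean() * 100 if n_pos else np.nan
        p_neg = flag[~y].mean() * 100 if n_neg else np.nan
        undefined = not (p_neg and np.isfinite(p_neg))
        rr = np.nan if undefined else p_pos / p_neg
        rows.append((name, p_pos, p_neg, rr, int(flag.sum()), undefined))
    return pd.DataFrame(rows, columns=["predictor", "pct_true_among_positives",
                                       "pct_true_among_negatives", "rr",
                                       "n_true", "undefined"])
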