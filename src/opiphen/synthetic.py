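"""Seeded synthetic claims generator.

Emulates a simplified Sentinel-CDM-style data environment for a cohort of
adult patients receiving extended-release/long-acting (ER/LA) opioid therapy:
demographics, enrollment spans, encounters, diagnoses, procedures, pharmacy
dispensings, and a ground-truth reference label (latent "problem opioid use"
trait with a chart-documentation onset date).

The generative model is deliberately simple and fully documented:

* Streams are piecewise-constant-rate Poisson processes within enrollment.
* ER/LA therapy is a refill renewal process (next fill ~ previous fill +
  days' supply, with occasional early refills that create overlapping
  coverage); days' supply is drawn from class-specific categorical choices.
* A latent Bernoulli trait shifts stream intensities multiplicatively via an
  :class:`EffectProfile` (early refills, dose, ER visits, benzodiazepine
  co-dispensing, OUD-treatment medication) and raises the hazard of
  opioid-dependence/abuse/poisoning diagnosis codes after a latent onset.
* The chart-documented onset lags the latent onset by a geometric delay
  (mean 60 days by default), producing positives whose documented onset can
  fall before, inside, or after any downstream observation window.

All randomness flows through a single integer seed via
``numpy.random.SeedSequence``; identical config + seed reproduces identical
tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import DRUG_CATALOG, DrugProduct
from .errors import ConfigError

__all__ = [
    "EffectProfile",
    "StreamRates",
    "SimConfig",
    "ClaimsDataset",
    "PatientDemographics",
    "generate_population",
    "generate_patient_streams",
]

_RACES = ("White", "Black", "Native American", "Asian", "Pacific Islander", "Unknown")
_RACE_P = (0.793, 0.037, 0.035, 0.016, 0.006, 0.113)

_OUD_CODES = ("304.00", "304.01", "304.02", "305.50", "305.51",
              "965.00", "965.02", "965.09", "E850.2")
_PAIN_CODES = ("724.2", "724.5", "723.1", "346.90", "784.0", "729.1",
               "729.2", "715.90", "714.0")
_MH_CODES = ("311", "296.20", "300.00", "296.44", "295.30", "309.81",
             "303.90", "303.00")
_COMORBID_CODES = ("428.0", "250.00", "496", "571.5", "410.1", "585", "070.54")
_MISC_CODES = ("307.42", "327.23", "421.0", "E935.2", "V61.11")


@dataclass(frozen=True)
class EffectProfile:
    """Multiplicative stream-intensity shifts for trait-positive patients.

    All multipliers are relative to the trait-negative base rates; a profile
    of all ones makes the two groups statistically indistinguishable.
    """

    early_fill: float = 2.5
    high_meq: float = 1.8
    oud_dx_hazard: float = 8.0
    er_visit: float = 2.0
    benzo_codispense: float = 2.5
    oud_treatment: float = 10.0

    @classmethod
    def null(cls) -> "EffectProfile":
        return cls(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ConfigError(f"effects.{f.name} must be > 0, got {v}")


@dataclass(frozen=True)
class StreamRates:
    """Trait-negative base intensities (documented generator assumptions).

    The source data model publishes no marginal distributions for these
    streams; the defaults are plausible round numbers for a chronic-opioid
    population and are assumptions, not estimates from any health system.
    """

    ir_fills_per_month: float = 0.5
    benzo_fills_per_month: float = 0.10
    psych_fills_per_month: float = 0.10
    other_fills_per_month: float = 0.15
    pain_dx_per_year: float = 1.5
    mh_dx_per_year: float = 0.6
    comorbid_dx_per_year: float = 0.3
    misc_dx_per_year: float = 0.15
    oud_dx_per_year: float = 0.03
    outpatient_per_year: float = 5.0
    er_per_year: float = 0.35
    uds_per_year: float = 0.4
    surgery_per_year: float = 0.08
    early_refill_prob: float = 0.12
    oud_treatment_prob: float = 0.02
    sud_proc_per_oud_dx: float = 0.5

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ConfigError(f"rates.{f.name} must be >= 0, got {v}")
        if self.early_refill_prob > 1:
            raise ConfigError("rates.early_refill_prob must be a probability")
        if self.oud_treatment_prob > 1:
            raise ConfigError("rates.oud_treatment_prob must be a probability")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one synthetic population draw."""

    n_patients: int = 2000
    study_start: str = "2006-01-01"
    study_end: str = "2015-06-30"
    latent_prevalence: float = 0.25
    effects: EffectProfile = field(default_factory=EffectProfile)
    rates: StreamRates = field(default_factory=StreamRates)
    erla_user_fraction: float = 0.75
    enrollment_gap_hazard: float = 0.15
    enrollment_gap_mean_days: float = 45.0
    doc_delay_mean_days: float = 60.0
    excluded_care_prob: float = 0.02
    minor_prob: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError(f"n_patients must be >= 0, got {self.n_patients}")
        for name in ("latent_prevalence", "erla_user_fraction",
                     "enrollment_gap_hazard", "excluded_care_prob", "minor_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.doc_delay_mean_days <= 0:
            raise ConfigError("doc_delay_mean_days must be > 0")
        if self.enrollment_gap_mean_days <= 0:
            raise ConfigError("enrollment_gap_mean_days must be > 0")
        start, end = pd.Timestamp(self.study_start), pd.Timestamp(self.study_end)
        if end < start:
            raise ConfigError("study_end precedes study_start (empty study period)")
        self.effects.validate()
        self.rates.validate()

    @property
    def n_study_days(self) -> int:
        return (pd.Timestamp(self.study_end) - pd.Timestamp(self.study_start)).days + 1


@dataclass(frozen=True)
class PatientDemographics:
    patient_id: str
    birth_date: pd.Timestamp
    sex: str
    race: str
    excluded_care: bool = False


_TABLE_COLUMNS = {
    "demographics": ["patient_id", "birth_date", "sex", "race", "excluded_care"],
    "enrollment": ["patient_id", "start_date", "end_date"],
    "dispensings": ["patient_id", "dispense_date", "drug_code", "drug_class",
                    "days_supply", "quantity", "mg_per_unit", "meq_factor"],
    "diagnoses": ["patient_id", "date", "code", "setting"],
    "encounters": ["patient_id", "date", "setting"],
    "procedures": ["patient_id", "date", "category"],
    "labels": ["patient_id", "problem_use", "onset_date"],
}
_DATE_COLUMNS = {
    "demographics": ["birth_date"],
    "enrollment": ["start_date", "end_date"],
    "dispensings": ["dispense_date"],
    "diagnoses": ["date"],
    "encounters": ["date"],
    "procedures": ["date"],
    "labels": ["onset_date"],
}


@dataclass
class ClaimsDataset:
    """The seven-table simplified Sentinel-CDM-style dataset."""

    demographics: pd.DataFrame
    enrollment: pd.DataFrame
    dispensings: pd.DataFrame
    diagnoses: pd.DataFrame
    encounters: pd.DataFrame
    procedures: pd.DataFrame
    labels: pd.DataFrame
    study_start: pd.Timestamp = pd.Timestamp("2006-01-01")
    study_end: pd.Timestamp = pd.Timestamp("2015-06-30")

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in _TABLE_COLUMNS}

    def to_dir(self, path: str | Path) -> None:
        """Write the seven tables as CSV with ISO-8601 dates."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(path / f"{name}.csv", index=False, date_format="%Y-%m-%d")
        meta = pd.DataFrame({"key": ["study_start", "study_end"],
                             "value": [self.study_start.date().isoformat(),
                                       self.study_end.date().isoformat()]})
        meta.to_csv(path / "study_period.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "ClaimsDataset":
        path = Path(path)
        frames = {}
        for name, cols in _TABLE_COLUMNS.items():
            df = pd.read_csv(path / f"{name}.csv",
                             parse_dates=_DATE_COLUMNS[name])
            missing = set(cols) - set(df.columns)
            if missing:
                from .errors import SchemaError
                raise SchemaError(f"{name}.csv missing columns: {sorted(missing)}")
            frames[name] = df
        meta = pd.read_csv(path / "study_period.csv").set_index("key")["value"]
        return cls(**frames, study_start=pd.Timestamp(meta["study_start"]),
                   study_end=pd.Timestamp(meta["study_end"]))


def _poisson_days(rng: np.random.Generator, rate_per_day: float,
                  lo: int, hi: int) -> np.ndarray:
    """Event days of a homogeneous Poisson process on the closed span [lo, hi]."""
    length = hi - lo + 1
    if length <= 0 or rate_per_day <= 0:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate_per_day * length)
    return np.sort(rng.integers(lo, hi + 1, size=n))


def _pick(rng: np.random.Generator, seq):
    return seq[rng.integers(0, len(seq))]


def generate_patient_streams(trait: bool, demographics: PatientDemographics,
                             config: SimConfig,
                             rng: np.random.Generator) -> dict:
    """Generate one patient's records; day offsets are relative to study start.

    Returns a dict with keys ``enrollment`` (list of (start_day, end_day)),
    ``dispensings``, ``diagnoses``, ``encounters``, ``procedures`` (lists of
    tuples in table column order, dates as int day offsets) and ``onset_day``
    (documented onset day offset, or None).
    """
    config.validate()
    r = config.rates
    e = config.effects
    n_days = config.n_study_days
    pid = demographics.patient_id

    # --- enrollment: one long span, occasionally split by a gap -------------
    start = int(rng.integers(0, max(1, int(0.25 * n_days))))
    min_len = min(900, n_days - start - 1)
    end = int(rng.integers(start + max(min_len, 1), n_days)) if start + min_len < n_days \
        else n_days - 1
    spans = [(start, end)]
    if rng.random() < config.enrollment_gap_hazard and end - start > 400:
        gap_len = 1 + int(rng.geometric(1.0 / config.enrollment_gap_mean_days))
        gap_start = int(rng.integers(start + 100, end - 100 - gap_len)) \
            if end - 100 - gap_len > start + 100 else None
        if gap_start is not None:
            spans = [(start, gap_start - 1), (gap_start + gap_len, end)]

    dispensings: list[tuple] = []
    diagnoses: list[tuple] = []
    encounters: list[tuple] = []
    procedures: list[tuple] = []

    def add_fill(day: int, product: DrugProduct, days_supply: int,
                 units_per_day: float) -> None:
        quantity = float(max(1, round(days_supply * units_per_day)))
        dispensings.append((pid, day, product.drug_code, product.drug_class,
                            int(days_supply), quantity, product.mg_per_unit,
                            product.meq_factor))

    # --- ER/LA refill renewal process --------------------------------------
    erla_user = rng.random() < config.erla_user_fraction
    regimen = None
    if erla_user:
        span = max(spans, key=lambda s: s[1] - s[0])
        s0, s1 = span
        # place the regimen so that the 6-month-pre / 18-month-post enrollment
        # requirement around the index date is usually satisfiable
        lo = s0 + min(190, max(0, (s1 - s0) // 4))
        hi = max(lo + 1, s1 - 560)
        reg_start = int(rng.integers(lo, hi)) if hi > lo else lo
        total_days = float(np.exp(rng.normal(np.log(1100.0), 0.9)))
        reg_end = int(min(s1, reg_start + max(60.0, total_days)))
        regimen = (reg_start, reg_end)

        products = [p for p in DRUG_CATALOG.values() if p.drug_class == "ERLA_opioid"]
        product = _pick(rng, products)
        units = _pick(rng, (1.0, 1.0, 2.0, 3.0)) * (e.high_meq if trait else 1.0)
        p_early = min(0.9, r.early_refill_prob * (e.early_fill if trait else 1.0))
        day = reg_start
        while day <= reg_end:
            supply = int(_pick(rng, product.days_supply_choices))
            add_fill(day, product, supply, units)
            if rng.random() < p_early:
                step = max(1, int(round(supply * rng.uniform(0.5, 0.85))))
            else:
                step = supply + int(rng.poisson(2.0))
            day += step

    # --- IR opioid fills ----------------------------------------------------
    ir_window = regimen if regimen else (spans[0][0], spans[-1][1])
    ir_rate = (r.ir_fills_per_month / 30.4) * (e.early_fill if trait else 1.0)
    ir_products = [p for p in DRUG_CATALOG.values() if p.drug_class == "IR_opioid"]
    for day in _poisson_days(rng, ir_rate, *ir_window):
        product = _pick(rng, ir_products)
        supply = int(rng.choice(product.days_supply_choices,
                                p=_supply_probs(len(product.days_supply_choices))))
        add_fill(int(day), product, supply,
                 _pick(rng, (2.0, 3.0, 4.0)) * (e.high_meq if trait else 1.0))

    # --- benzodiazepines / other psychoactives / OUD treatment / other ------
    bz_rate = (r.benzo_fills_per_month / 30.4) * (e.benzo_codispense if trait else 1.0)
    bz_window = regimen if regimen else (spans[0][0], spans[-1][1])
    bz_products = [p for p in DRUG_CATALOG.values() if p.drug_class == "benzodiazepine"]
    for day in _poisson_days(rng, bz_rate, *bz_window):
        product = _pick(rng, bz_products)
        add_fill(int(day), product, int(_pick(rng, product.days_supply_choices)), 1.0)

    for cls_name, rate in (("other_psychoactive", r.psych_fills_per_month),
                           ("other", r.other_fills_per_month)):
        prods = [p for p in DRUG_CATALOG.values() if p.drug_class == cls_name]
        for day in _poisson_days(rng, rate / 30.4, spans[0][0], spans[-1][1]):
            product = _pick(rng, prods)
            add_fill(int(day), product, int(_pick(rng, product.days_supply_choices)), 1.0)

    # --- latent trait onset and documentation lag ---------------------------
    onset_day = None
    latent_onset = None
    if trait:
        anchor = regimen[0] if regimen else spans[0][0]
        latent_onset = int(np.clip(anchor + rng.integers(-90, 541),
                                   spans[0][0], spans[-1][1]))
        delay = int(rng.geometric(1.0 / config.doc_delay_mean_days))
        onset_day = int(min(latent_onset + delay, n_days - 1))

    oudt_p = min(1.0, r.oud_treatment_prob * (e.oud_treatment if trait else 1.0))
    if rng.random() < oudt_p:
        prods = [p for p in DRUG_CATALOG.values() if p.drug_class == "OUD_treatment"]
        product = _pick(rng, prods)
        t_start = (latent_onset + int(rng.integers(30, 300))) if latent_onset is not None \
            else int(rng.integers(spans[0][0], spans[-1][1] + 1))
        t_end = min(spans[-1][1], t_start + int(rng.integers(120, 540)))
        day = t_start
        while day <= t_end:
            supply = int(_pick(rng, product.days_supply_choices))
            add_fill(day, product, supply, 1.0)
            day += supply

    # --- diagnoses ----------------------------------------------------------
    def add_dx(days: np.ndarray, codes: tuple[str, ...]) -> None:
        for day in days:
            setting = _pick(rng, ("outpatient",) * 7 + ("ER",) * 2 + ("inpatient",))
            diagnoses.append((pid, int(day), _pick(rng, codes), setting))

    for (s0, s1) in spans:
        add_dx(_poisson_days(rng, r.pain_dx_per_year / 365.25, s0, s1), _PAIN_CODES)
        add_dx(_poisson_days(rng, r.mh_dx_per_year / 365.25, s0, s1), _MH_CODES)
        add_dx(_poisson_days(rng, r.comorbid_dx_per_year / 365.25, s0, s1),
               _COMORBID_CODES)
        add_dx(_poisson_days(rng, r.misc_dx_per_year / 365.25, s0, s1), _MISC_CODES)

    # opioid dependence/abuse/poisoning codes: base hazard for everyone,
    # elevated after the latent onset for trait-positives
    oud_days: list[int] = []
    for (s0, s1) in spans:
        if trait and latent_onset is not None and latent_onset <= s1:
            pre_end = min(s1, latent_onset - 1)
            if pre_end >= s0:
                oud_days += list(_poisson_days(rng, r.oud_dx_per_year / 365.25,
                                               s0, pre_end))
            post_start = max(s0, latent_onset)
            oud_days += list(_poisson_days(
                rng, r.oud_dx_per_year * e.oud_dx_hazard / 365.25, post_start, s1))
        else:
            oud_days += list(_poisson_days(rng, r.oud_dx_per_year / 365.25, s0, s1))
    for day in oud_days:
        code = "965.01" if rng.random() < 0.03 else _pick(rng, _OUD_CODES)
        setting = _pick(rng, ("outpatient",) * 5 + ("ER",) * 4 + ("inpatient",))
        diagnoses.append((pid, int(day), code, setting))
        if rng.random() < r.sud_proc_per_oud_dx:
            procedures.append((pid, int(min(day + rng.integers(0, 30), spans[-1][1])),
                               "SUD_treatment"))

    # --- encounters ---------------------------------------------------------
    er_rate = (r.er_per_year / 365.25) * (e.er_visit if trait else 1.0)
    for (s0, s1) in spans:
        for day in _poisson_days(rng, r.outpatient_per_year / 365.25, s0, s1):
            encounters.append((pid, int(day),
                               _pick(rng, ("outpatient",) * 9 + ("urgent",))))
        for day in _poisson_days(rng, er_rate, s0, s1):
            encounters.append((pid, int(day), "ER"))

    # --- procedures ---------------------------------------------------------
    uds_window = regimen if regimen else (spans[0][0], spans[-1][1])
    for day in _poisson_days(rng, r.uds_per_year / 365.25, *uds_window):
        procedures.append((pid, int(day), "urine_drug_screen"))
    for (s0, s1) in spans:
        for day in _poisson_days(rng, r.surgery_per_year / 365.25, s0, s1):
            procedures.append((pid, int(day), "surgery"))

    return {"enrollment": spans, "dispensings": dispensings,
            "diagnoses": diagnoses, "encounters": encounters,
            "procedures": procedures, "onset_day": onset_day}


def _supply_probs(k: int) -> np.ndarray:
    # favour short fills, matching the early-refill phenomena downstream
    w = np.array([0.30, 0.25, 0.20, 0.15, 0.10][:k], dtype=float)
    return w / w.sum()


def generate_population(config: SimConfig) -> ClaimsDataset:
    """Draw a full synthetic population; deterministic given ``config.seed``."""
    config.validate()
    start_ts = pd.Timestamp(config.study_start)
    root = np.random.SeedSequence(config.seed)
    head = np.random.default_rng(root.spawn(1)[0])
    children = root.spawn(config.n_patients + 1)[1:]

    n = config.n_patients
    traits = head.random(n) < config.latent_prevalence
    ages = np.clip(head.normal(52.0, 13.4, size=n), 18.0, 90.0)
    minors = head.random(n) < config.minor_prob
    ages[minors] = head.uniform(12.0, 17.9, size=int(minors.sum()))
    sexes = np.where(head.random(n) < 0.55, "F", "M")
    races = np.asarray(_RACES)[head.choice(len(_RACES), size=n, p=_RACE_P)]
    excluded = head.random(n) < config.excluded_care_prob

    demo_rows, enroll_rows, label_rows = [], [], []
    disp_rows, dx_rows, enc_rows, proc_rows = [], [], [], []
    for i in range(n):
        pid = f"P{i:06d}"
        birth = start_ts - pd.to_timedelta(int(ages[i] * 365.25), unit="D")
        demo = PatientDemographics(pid, birth, str(sexes[i]), str(races[i]),
                                   bool(excluded[i]))
        rng = np.random.default_rng(children[i])
        streams = generate_patient_streams(bool(traits[i]), demo, config, rng)
        demo_rows.append((pid, birth, demo.sex, demo.race, demo.excluded_care))
        for (s0, s1) in streams["enrollment"]:
            enroll_rows.append((pid, s0, s1))
        disp_rows += streams["dispensings"]
        dx_rows += streams["diagnoses"]
        enc_rows += streams["encounters"]
        proc_rows += streams["procedures"]
        label_rows.append((pid, bool(traits[i]), streams["onset_day"]))

    def days_to_dates(values) -> pd.Series:
        arr = pd.array([pd.NA if pd.isna(v) else int(v) for v in values],
                       dtype="Int64")
        return pd.Series(start_ts + pd.to_timedelta(arr.to_numpy(dtype="float64",
                                                                 na_value=np.nan),
                                                    unit="D"))

    demographics = pd.DataFrame(demo_rows, columns=_TABLE_COLUMNS["demographics"])
    enrollment = pd.DataFrame(enroll_rows, columns=_TABLE_COLUMNS["enrollment"])
    for col in ("start_date", "end_date"):
        enrollment[col] = days_to_dates(enrollment[col]) if len(enrollment) else \
            pd.Series([], dtype="datetime64[ns]")
    dispensings = pd.DataFrame(disp_rows, columns=_TABLE_COLUMNS["dispensings"])
    diagnoses = pd.DataFrame(dx_rows, columns=_TABLE_COLUMNS["diagnoses"])
    encounters = pd.DataFrame(enc_rows, columns=_TABLE_COLUMNS["encounters"])
    procedures = pd.DataFrame(proc_rows, columns=_TABLE_COLUMNS["procedures"])
    for df, col in ((dispensings, "dispense_date"), (diagnoses, "date"),
                    (encounters, "date"), (procedures, "date")):
        df[col] = days_to_dates(df[col]) if len(df) else \
            pd.Series([], dtype="datetime64[ns]")
    labels = pd.DataFrame(label_rows, columns=_TABLE_COLUMNS["labels"])
    labels["onset_date"] = days_to_dates(labels["onset_date"]) if len(labels) else \
        pd.Series([], dtype="datetime64[ns]")

    if len(demographics):
        demographics = demographics.sort_values("patient_id", ignore_index=True)
    return ClaimsDataset(demographics, enrollment, dispensings, diagnoses,
                         encounters, procedures, labels,
                         study_start=start_ts,
                         study_end=pd.Timestamp(config.study_end))
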