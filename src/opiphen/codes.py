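"""Code dictionaries: ICD-9-style diagnosis groups, drug catalog, Charlson map.

The diagnosis groups are configurable prefix/exact-match sets in the style of
a claims codebook.  The problem-opioid-use group follows the code list that
claims studies of the ICD-9 era conventionally use: dependence (304.*), abuse
(305.*), prescription-opioid poisoning (965.00, 965.02, 965.09) and the
accidental-poisoning E-code family (E850.*).  Heroin-specific poisoning
(965.01) is deliberately absent from that group — heroin poisoning is tracked
as its own group and never counts toward the prescription-opioid comparator
or the sampling enrichment stratum.

The drug catalog maps synthetic NDC-like codes to class, strength, and a
morphine-equivalence (MEQ) conversion factor.  No published conversion table
accompanies the source data model, so the factors here are the widely used
CDC-style per-milligram multipliers for the common molecules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "CodeGroup",
    "DIAGNOSIS_GROUPS",
    "PROBLEM_OPIOID_USE_CODES",
    "DRUG_CATALOG",
    "DrugProduct",
    "CHARLSON_WEIGHTS",
    "charlson_index",
    "OPIOID_CLASSES",
    "PSYCHOACTIVE_CLASSES",
    "DRUG_CLASSES",
]

_CODE_RE = re.compile(r"^[EV]?\d{2,3}(\.\d{0,2})?$")


@dataclass(frozen=True)
class CodeGroup:
    """A named set of ICD-9-style codes defined by prefixes and exact codes.

    A code matches if it equals an ``exact`` entry or starts with any
    ``prefixes`` entry.  ``excludes`` are checked first and always win.
    """

    name: str
    prefixes: tuple[str, ...] = ()
    exact: tuple[str, ...] = ()
    excludes: tuple[str, ...] = ()

    def matches(self, code: str) -> bool:
        from .errors import DataError

        code = code.strip()
        if not _CODE_RE.match(code):
            raise DataError(f"unparseable diagnosis code: {code!r}")
        for ex in self.excludes:
            if code == ex or code.startswith(ex):
                return False
        if code in self.exact:
            return True
        return any(code.startswith(p) for p in self.prefixes)


#: The comparator / enrichment code list: prescription-opioid dependence,
#: abuse and poisoning, excluding heroin-specific poisoning.
PROBLEM_OPIOID_USE_CODES = CodeGroup(
    name="problem_opioid_use",
    prefixes=("304.", "305.", "E850"),
    exact=("965.00", "965.02", "965.09"),
    excludes=("965.01",),
)

DIAGNOSIS_GROUPS: dict[str, CodeGroup] = {
    g.name: g
    for g in [
        PROBLEM_OPIOID_USE_CODES,
        CodeGroup("opioid_dependence", prefixes=("304.0", "304.7")),
        CodeGroup("opioid_abuse", prefixes=("305.5",)),
        CodeGroup("opioid_poisoning", exact=("965.00", "965.02", "965.09"),
                  prefixes=("E850",), excludes=("965.01",)),
        CodeGroup("heroin", exact=("965.01",), prefixes=("304.00",)),
        CodeGroup("back_pain", prefixes=("724.",)),
        CodeGroup("neck_disorder", prefixes=("723.",)),
        CodeGroup("headache_migraine", prefixes=("346.", "784.0")),
        CodeGroup("neuropathic_pain", prefixes=("729.2", "337.2")),
        CodeGroup("fibromyalgia", prefixes=("729.1",)),
        CodeGroup("arthritis", prefixes=("715.", "714.")),
        CodeGroup("depression", prefixes=("296.2", "296.3", "311")),
        CodeGroup("bipolar", prefixes=("296.0", "296.4", "296.5", "296.6", "296.7")),
        CodeGroup("anxiety", prefixes=("300.0",)),
        CodeGroup("schizophrenia", prefixes=("295.",)),
        CodeGroup("alcohol_disorder", prefixes=("303.",)),
        CodeGroup("drug_dependence_nonopioid",
                  prefixes=("304.1", "304.2", "304.3", "304.4", "304.5", "304.6",
                            "304.8", "304.9")),
        CodeGroup("tobacco_use", prefixes=("305.1",)),
        CodeGroup("insomnia_sleep", prefixes=("307.4", "327.", "780.5")),
        CodeGroup("ptsd", prefixes=("309.81",)),
        CodeGroup("domestic_violence", prefixes=("E967", "V61.1")),
        CodeGroup("hepatitis_cirrhosis", prefixes=("070.", "571.")),
        CodeGroup("endocarditis", prefixes=("421.",)),
        CodeGroup("drug_adverse_ecodes", prefixes=("E85", "E93")),
    ]
}


@dataclass(frozen=True)
class DrugProduct:
    drug_code: str
    drug_class: str  # ERLA_opioid | IR_opioid | benzodiazepine | other_psychoactive | OUD_treatment | other
    mg_per_unit: float
    meq_factor: float | None = None  # present only for opioid classes
    days_supply_choices: tuple[int, ...] = field(default=(30,))


DRUG_CATALOG: dict[str, DrugProduct] = {
    p.drug_code: p
    for p in [
        # extended-release / long-acting opioids (buprenorphine excluded by design)
        DrugProduct("ERLA-MSCONTIN-30", "ERLA_opioid", 30.0, 1.0, (28, 30, 90)),
        DrugProduct("ERLA-OXYCR-20", "ERLA_opioid", 20.0, 1.5, (28, 30, 90)),
        DrugProduct("ERLA-FENTPATCH-25", "ERLA_opioid", 2.5, 7.2, (28, 30)),
        DrugProduct("ERLA-METHADONE-10", "ERLA_opioid", 10.0, 3.0, (28, 30, 90)),
        # immediate-release / short-acting opioids
        DrugProduct("IR-HYDROCO-5", "IR_opioid", 5.0, 1.0, (5, 7, 10, 14, 30)),
        DrugProduct("IR-OXYIR-5", "IR_opioid", 5.0, 1.5, (5, 7, 10, 14, 30)),
        DrugProduct("IR-MORPHIR-15", "IR_opioid", 15.0, 1.0, (5, 7, 10, 14, 30)),
        DrugProduct("IR-TRAMADOL-50", "IR_opioid", 50.0, 0.1, (7, 10, 14, 30)),
        # benzodiazepines
        DrugProduct("BZD-DIAZEPAM-5", "benzodiazepine", 5.0, None, (14, 30)),
        DrugProduct("BZD-ALPRAZ-05", "benzodiazepine", 0.5, None, (14, 30)),
        DrugProduct("BZD-LORAZ-1", "benzodiazepine", 1.0, None, (14, 30)),
        # other psychoactives
        DrugProduct("PSY-SSRI-20", "other_psychoactive", 20.0, None, (30, 90)),
        DrugProduct("PSY-GABAPEN-300", "other_psychoactive", 300.0, None, (30,)),
        DrugProduct("PSY-ZOLPIDEM-10", "other_psychoactive", 10.0, None, (14, 30)),
        # medications used to treat opioid use disorder
        DrugProduct("OUDT-BUPNX-8", "OUD_treatment", 8.0, None, (14, 28, 30)),
        DrugProduct("OUDT-NALTREX-50", "OUD_treatment", 50.0, None, (30,)),
        # non-psychoactive background dispensing
        DrugProduct("OTH-STATIN-20", "other", 20.0, None, (30, 90)),
        DrugProduct("OTH-METFORMIN-500", "other", 500.0, None, (30, 90)),
    ]
}

OPIOID_CLASSES = ("ERLA_opioid", "IR_opioid")
PSYCHOACTIVE_CLASSES = ("benzodiazepine", "other_psychoactive")
DRUG_CLASSES = ("ERLA_opioid", "IR_opioid", "benzodiazepine",
                "other_psychoactive", "OUD_treatment", "other")

#: Simplified Deyo-style Charlson comorbidity mapping: category -> (prefixes, weight).
CHARLSON_WEIGHTS: dict[str, tuple[tuple[str, ...], int]] = {
    "myocardial_infarction": (("410.", "412"), 1),
    "congestive_heart_failure": (("428.",), 1),
    "peripheral_vascular": (("441.", "443.9"), 1),
    "cerebrovascular": (("430.", "431.", "432.", "433.", "434.", "435.",
                         "436", "437.", "438."), 1),
    "dementia": (("290.",), 1),
    "chronic_pulmonary": (("490", "491.", "492.", "493.", "494.", "495.", "496"), 1),
    "rheumatologic": (("710.", "714.0"), 1),
    "peptic_ulcer": (("531.", "532.", "533.", "534."), 1),
    "mild_liver": (("571.2", "571.5", "571.6"), 1),
    "diabetes": (("250.0", "250.1", "250.2", "250.3"), 1),
    "diabetes_complicated": (("250.4", "250.5", "250.6"), 2),
    "hemiplegia": (("342.", "344."), 2),
    "renal": (("582.", "583.", "585", "586", "588."), 2),
    "malignancy": (("14", "15", "16", "170.", "171.", "172.", "174.", "175.",
                    "18", "190.", "191.", "192.", "193", "194.", "195.",
                    "200.", "201.", "202.", "203.", "204.", "205.", "206.",
                    "207.", "208."), 2),
    "moderate_severe_liver": (("572.2", "572.3", "572.4", "572.8"), 3),
    "metastatic": (("196.", "197.", "198.", "199."), 6),
    "hiv": (("042", "043", "044"), 6),
}


def charlson_index(codes) -> int:
    """Weighted Charlson comorbidity index over an iterable of ICD-9 codes.

    Each category counts once regardless of how many codes hit it; the more
    severe of the diabetes / liver category pairs supersedes the milder one.
    """
    hit: set[str] = set()
    for code in codes:
        for cat, (prefixes, _w) in CHARLSON_WEIGHTS.items():
            if cat in hit:
                continue
            if any(str(code).startswith(p) for p in prefixes):
                hit.add(cat)
    if "diabetes_complicated" in hit:
        hit.discard("diabetes")
    if "moderate_severe_liver" in hit:
        hit.discard("mild_liver")
    if "metastatic" in hit:
        hit.discard("malignancy")
    return sum(CHARLSON_WEIGHTS[cat][1] for cat in hit)
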