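"""Cut-point selection and classification performance against the reference.

A patient is classified positive when their risk score is **at or above** the
cut point.  Metrics follow the usual confusion-matrix definitions —
sensitivity TP/(TP+FN), specificity TN/(FP+TN), PPV TP/(TP+FP), NPV
TN/(TN+FN) — with undefined ratios (empty denominators) surfaced as None,
never coerced to 0 or 1.  Predicted prevalence is the classified-positive
fraction (TP+FP)/n.

Cut points are always selected on training data.  Four schemes are
supported: target sensitivity, target specificity, or target PPV at levels
{0.90, 0.80, 0.75} (choosing, among cuts meeting the target, the one
maximizing the complementary metric — PPV for a sensitivity target,
sensitivity otherwise), and a balanced scheme minimizing |sensitivity -
PPV|.  Ties prefer the higher cut.

The comparator is the conventional diagnosis-code rule: positive iff any
opioid dependence/abuse/poisoning code (heroin-specific poisoning excluded)
falls inside the 36-month observation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codes import CodeGroup, PROBLEM_OPIOID_USE_CODES
from .errors import ConfigError, CutpointError, DataError

__all__ = [
    "ConfusionMetrics",
    "confusion_metrics",
    "roc_points",
    "roc_auc",
    "CutpointScheme",
    "select_cutpoint",
    "icd9_classifier",
    "binomial_ci",
    "table3_report",
    "DEFAULT_SCHEMES",
]

TARGET_LEVELS = (0.90, 0.80, 0.75)


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.fp + self.tn
        return self.tn / d if d else None

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return self.tn / d if d else None

    @property
    def predicted_prevalence(self) -> float:
        return (self.tp + self.fp) / self.n


def confusion_metrics(scores, outcomes, cut: float) -> ConfusionMetrics:
    """Classify at-or-above ``cut`` as positive and tabulate against outcomes."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape:
        raise DataError("scores and outcomes are not aligned")
    pred = s >= cut
    return ConfusionMetrics(tp=int((pred & y).sum()), fp=int((pred & ~y).sum()),
                            tn=int((~pred & ~y).sum()), fn=int((~pred & y).sum()))


def roc_points(scores, outcomes) -> pd.DataFrame:
    """ROC curve: one (1-specificity, sensitivity) point per distinct cut.

    Ties at a cut classify positive together ("at or above").  The returned
    frame includes the (0,0) and (1,1) endpoints and is ordered by
    descending cut (ascending false-positive rate).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC requires at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    last_of_tie = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = tp[last_of_tie] / n_pos
    fpr = fp[last_of_tie] / n_neg
    cuts = s_sorted[last_of_tie]
    return pd.DataFrame({"cut": np.r_[np.inf, cuts],
                         "fpr": np.r_[0.0, fpr],
                         "tpr": np.r_[0.0, tpr]})


def roc_auc(scores, outcomes) -> float:
    """Area under the ROC curve (trapezoidal over the distinct-cut points)."""
    pts = roc_points(scores, outcomes)
    return float(np.trapezoid(pts["tpr"], pts["fpr"]))


@dataclass(frozen=True)
class CutpointScheme:
    kind: str  # sensitivity | specificity | ppv | balanced
    target: float | None = None

    def __post_init__(self):
        if self.kind not in ("sensitivity", "specificity", "ppv", "balanced"):
            raise ConfigError(f"unknown cut-point scheme {self.kind!r}")
        if self.kind != "balanced" and not (self.target and 0 < self.target <= 1):
            raise ConfigError(f"scheme {self.kind!r} needs a target in (0, 1]")

    @property
    def label(self) -> str:
        return "balanced_sens_ppv" if self.kind == "balanced" \
            else f"{self.kind}@{self.target:.2f}"


DEFAULT_SCHEMES: tuple[CutpointScheme, ...] = tuple(
    [CutpointScheme(kind, t) for kind in ("sensitivity", "specificity", "ppv")
     for t in TARGET_LEVELS] + [CutpointScheme("balanced")])


def select_cutpoint(train_scores, train_outcomes,
                    scheme: CutpointScheme) -> float:
    """Choose the training cut for a scheme; ties go to the higher cut."""
    s = np.asarray(train_scores, dtype=float)
    candidates = np.unique(s)[::-1]  # descending: higher cut first
    rows = [(c, confusion_metrics(s, train_outcomes, c)) for c in candidates]

    if scheme.kind == "balanced":
        best, best_gap = None, np.inf
        for c, m in rows:
            if m.sensitivity is None or m.ppv is None:
                continue
            gap = abs(m.sensitivity - m.ppv)
            if gap < best_gap:  # ties keep the earlier (higher) cut
                best, best_gap = c, gap
        if best is None:
            raise CutpointError("balanced scheme found no cut with defined "
                                "sensitivity and PPV")
        return float(best)

    metric = {"sensitivity": lambda m: m.sensitivity,
              "specificity": lambda m: m.specificity,
              "ppv": lambda m: m.ppv}[scheme.kind]
    complementary = (lambda m: m.ppv) if scheme.kind == "sensitivity" \
        else (lambda m: m.sensitivity)
    feasible = [(c, m) for c, m in rows
                if metric(m) is not None and metric(m) >= scheme.target]
    if not feasible:
        achieved = [metric(m) for _, m in rows if metric(m) is not None]
        best_val = max(achieved) if achieved else None
        raise CutpointError(
            f"target {scheme.kind} >= {scheme.target} unattainable on training "
            f"data; best attainable is {best_val}")
    best, best_val = None, -np.inf
    for c, m in feasible:
        v = complementary(m)
        v = -np.inf if v is None else v
        if v > best_val:  # ties keep the earlier (higher) cut
            best, best_val = c, v
    return float(best)


def icd9_classifier(diagnoses: pd.DataFrame, cohort: pd.DataFrame,
                    code_group: CodeGroup = PROBLEM_OPIOID_USE_CODES) -> pd.Series:
    """Comparator: any qualifying code within the observation window.

    Returns a boolean Series indexed by patient_id, aligned to ``cohort``.
    """
    windows = cohort.set_index("patient_id")[
        ["observation_start", "observation_end"]]
    out = pd.Series(False, index=windows.index)
    if len(diagnoses):
        dx = diagnoses[diagnoses["patient_id"].isin(windows.index)]
        dx = dx[dx["code"].map(code_group.matches)]
        for pid, grp in dx.groupby("patient_id"):
            w = windows.loc[pid]
            hit = ((grp["date"] >= w["observation_start"]) &
                   (grp["date"] <= w["observation_end"])).any()
            out.loc[pid] = bool(hit)
    return out


def binomial_ci(p_hat: float, n: int, level: float = 0.95,
                method: str = "wald", whole_percent: bool = True):
    """Binomial confidence interval, reported in percent.

    Wald by default (``method='exact'`` for Clopper-Pearson), clipped to
    [0, 100]; by default rounded to whole percent as in report display.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ConfigError("p_hat must be in [0, 1]")
    if n < 1:
        raise ConfigError("n must be >= 1")
    if method == "wald":
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
        lo, hi = p_hat - half, p_hat + half
    elif method == "exact":
        k = int(round(p_hat * n))
        alpha = 1.0 - level
        lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    else:
        raise ConfigError(f"unknown CI method {method!r}")
    lo = float(np.clip(lo * 100.0, 0.0, 100.0))
    hi = float(np.clip(hi * 100.0, 0.0, 100.0))
    if whole_percent:
        return int(round(lo)), int(round(hi))
    return lo, hi


def _metric_row(m: ConfusionMetrics) -> dict:
    return {"sensitivity": m.sensitivity, "specificity": m.specificity,
            "ppv": m.ppv, "npv": m.npv,
            "predicted_prevalence": m.predicted_prevalence}


def table3_report(train_scores, train_outcomes, valid_scores, valid_outcomes,
                  comparator_train=None, comparator_valid=None,
                  schemes: tuple[CutpointScheme, ...] = DEFAULT_SCHEMES
                  ) -> pd.DataFrame:
    """Per-scheme cut points with train and validation metrics.

    Cuts are selected on training data only and applied unchanged to the
    validation split.  When comparator classifications are supplied, an
    ``icd9_comparator`` row (cut = NaN) is appended, evaluated on the same
    members.  Undefined metrics appear as None.
    """
    for name, arr in (("train", train_scores), ("validation", valid_scores)):
        if len(arr) == 0:
            raise DataError(f"empty {name} split")
    rows = []
    for scheme in schemes:
        cut = select_cutpoint(train_scores, train_outcomes, scheme)
        m_tr = confusion_metrics(train_scores, train_outcomes, cut)
        m_va = confusion_metrics(valid_scores, valid_outcomes, cut)
        row = {"scheme": scheme.label, "cut": cut}
        row.update({f"train_{k}": v for k, v in _metric_row(m_tr).items()})
        row.update({f"valid_{k}": v for k, v in _metric_row(m_va).items()})
        rows.append(row)
    if comparator_train is not None and comparator_valid is not None:
        m_tr = confusion_metrics(np.asarray(comparator_train, dtype=float),
                                 train_outcomes, 0.5)
        m_va = confusion_metrics(np.asarray(comparator_valid, dtype=float),
                                 valid_outcomes, 0.5)
        row = {"scheme": "icd9_comparator", "cut": np.nan}
        row.update({f"train_{k}": v for k, v in _metric_row(m_tr).items()})
        row.update({f"valid_{k}": v for k, v in _metric_row(m_va).items()})
        rows.append(row)
    return pd.DataFrame(rows)
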