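"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from opiphen import EligibilityConfig, SimConfig, build_cohort, generate_population


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-patient synthetic population shared across read-only tests."""
    return generate_population(SimConfig(n_patients=300, seed=42))


@pytest.fixture(scope="session")
def small_cohort(small_dataset):
    return build_cohort(small_dataset, EligibilityConfig())


def make_dispensings(rows, patient_id="P1"):
    """Rows of (date, drug_class, days_supply[, quantity, mg, meq]) -> frame."""
    recs = []
    for row in rows:
        date, cls, supply = row[:3]
        quantity = row[3] if len(row) > 3 else float(supply)
        mg = row[4] if len(row) > 4 else 10.0
        meq = row[5] if len(row) > 5 else \
            (1.0 if cls in ("ERLA_opioid", "IR_opioid") else np.nan)
        recs.append((patient_id, pd.Timestamp(date), f"{cls[:4]}-X", cls,
                     int(supply), float(quantity), float(mg), meq))
    return pd.DataFrame(recs, columns=[
        "patient_id", "dispense_date", "drug_code", "drug_class",
        "days_supply", "quantity", "mg_per_unit", "meq_factor"])


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def index_date_oracle(dispensings: pd.DataFrame, min_days_supply=60,
                      window_len=90):
    """Daily-grid brute force: scan every calendar day as a window anchor.

    The earliest day d whose window [d, d+window_len-1] accumulates the
    supply minimum determines the episode; the index is the earliest ER/LA
    fill inside that window.
    """
    erla = dispensings[dispensings["drug_class"] == "ERLA_opioid"]
    if len(erla) == 0:
        return None
    days = erla["dispense_date"].map(pd.Timestamp.toordinal).to_numpy()
    supply = erla["days_supply"].to_numpy(dtype=float)
    for d in range(days.min() - window_len, days.max() + 1):
        mask = (days >= d) & (days <= d + window_len - 1)
        if supply[mask].sum() >= min_days_supply:
            return pd.Timestamp.fromordinal(int(days[mask].min()))
    return None


def overlap_oracle(dispensings: pd.DataFrame, class_filter=("IR_opioid",),
                   max_days_supply=14, dow_set=("Sat", "Sun", "Mon"),
                   window_len_months=3, min_fills=3) -> bool:
    """Explicit coverage-day-set brute force for the early-refill pattern.

    Expands every qualifying fill into its coverage-day set, connects fills
    whose day sets intersect (graph components via BFS), and checks every
    combination of ``min_fills`` fills from one component for the rolling
    time span.
    """
    from itertools import combinations

    dow_idx = {"Mon": 0, "Tue": 1, "Wed": 2, "Thu": 3, "Fri": 4,
               "Sat": 5, "Sun": 6}
    span_days = int(round(30.4375 * window_len_months))
    fills = []
    for rec in dispensings.itertuples(index=False):
        if rec.drug_class not in class_filter:
            continue
        if max_days_supply is not None and rec.days_supply > max_days_supply:
            continue
        day = pd.Timestamp(rec.dispense_date)
        if dow_set is not None and day.weekday() not in \
                {dow_idx[d] for d in dow_set}:
            continue
        o = day.toordinal()
        fills.append((o, set(range(o, o + int(rec.days_supply)))))
    if len(fills) < min_fills:
        return False
    adj = {i: set() for i in range(len(fills))}
    for i, j in combinations(range(len(fills)), 2):
        if fills[i][1] & fills[j][1]:
            adj[i].add(j)
            adj[j].add(i)
    seen, components = set(), []
    for i in range(len(fills)):
        if i in seen:
            continue
        comp, stack = [], [i]
        seen.add(i)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u] - seen:
                seen.add(v)
                stack.append(v)
        components.append(comp)
    for comp in components:
        if len(comp) < min_fills:
            continue
        for combo in combinations(sorted(fills[i][0] for i in comp), min_fills):
            if combo[-1] - combo[0] <= span_days - 1:
                return True
    return False


def cutpoint_oracle(scores, outcomes, kind, target):
    """Exhaustive enumeration over every distinct score as a candidate cut."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)

    def metrics(cut):
        pred = s >= cut
        tp, fp = int((pred & y).sum()), int((pred & ~y).sum())
        tn, fn = int((~pred & ~y).sum()), int((~pred & y).sum())
        sens = tp / (tp + fn) if tp + fn else None
        spec = tn / (fp + tn) if fp + tn else None
        ppv = tp / (tp + fp) if tp + fp else None
        return sens, spec, ppv

    cands = sorted(set(s), reverse=True)
    if kind == "balanced":
        best, gap_best = None, np.inf
        for c in cands:
            sens, _, ppv = metrics(c)
            if sens is None or ppv is None:
                continue
            gap = abs(sens - ppv)
            if gap < gap_best:
                best, gap_best = c, gap
        return best
    pick = {"sensitivity": 0, "specificity": 1, "ppv": 2}[kind]
    comp = 2 if kind == "sensitivity" else 0
    best, val_best = None, -np.inf
    for c in cands:
        m = metrics(c)
        if m[pick] is None or m[pick] < target:
            continue
        v = -np.inf if m[comp] is None else m[comp]
        if v > val_best:
            best, val_best = c, v
    return best
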