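"""Stratified sampling with enrichment, design weights, and train/validation split.

The sampling frame is the eligible cohort, cross-stratified on two axes known
to correlate with problem opioid use: age 18-34 versus 35+ at the index date,
and the presence of any opioid dependence/abuse/poisoning diagnosis code
(heroin-specific poisoning excluded) during the study period.  Sampling is
without replacement within stratum at configured fractions; each sampled
patient carries a design weight equal to the inverse of their realized
selection probability, which makes the weighted prevalence estimator
Horvitz-Thompson unbiased for the eligible-pool prevalence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .codes import CodeGroup, PROBLEM_OPIOID_USE_CODES
from .errors import ConfigError, OpiphenError

__all__ = [
    "assign_strata",
    "enrichment_fractions",
    "draw_stratified_sample",
    "split_train_validation",
    "weighted_prevalence",
]

AGE_YOUNG, AGE_OLDER = "18-34", "35+"


def assign_strata(cohort: pd.DataFrame, diagnoses: pd.DataFrame,
                  code_group: CodeGroup = PROBLEM_OPIOID_USE_CODES,
                  age_cut: float = 35.0) -> pd.DataFrame:
    """Cross of age stratum (at index) and any-qualifying-code stratum.

    Returns one row per cohort member: patient_id, age_stratum,
    oud_code_stratum, stratum_id.
    """
    age_stratum = np.where(cohort["age_at_index"] < age_cut, AGE_YOUNG, AGE_OLDER)
    if len(diagnoses):
        qualifying = diagnoses[diagnoses["code"].map(code_group.matches)]
        flagged = set(qualifying["patient_id"])
    else:
        flagged = set()
    oud = cohort["patient_id"].isin(flagged).to_numpy()
    stratum_id = np.array([f"{a}|{'oud' if q else 'no-oud'}"
                           for a, q in zip(age_stratum, oud)])
    return pd.DataFrame({"patient_id": cohort["patient_id"].to_numpy(),
                         "age_stratum": age_stratum,
                         "oud_code_stratum": oud,
                         "stratum_id": stratum_id})


def enrichment_fractions(strata: pd.DataFrame, n_target: int) -> dict[str, float]:
    """Sampling fractions that take every enriched stratum in full.

    The two enrichment axes (young age, qualifying diagnosis codes) are
    sampled at fraction 1.0; the remaining base stratum is sampled at the
    fraction that brings the expected total to ``n_target``.
    """
    sizes = strata["stratum_id"].value_counts()
    enriched = [s for s in sizes.index if s.startswith(AGE_YOUNG) or s.endswith("|oud")]
    base = [s for s in sizes.index if s not in enriched]
    n_enriched = int(sizes[enriched].sum()) if enriched else 0
    n_base = int(sizes[base].sum()) if base else 0
    if n_enriched > n_target:
        raise ConfigError(
            f"n_target={n_target} below the enriched-strata size {n_enriched}")
    fractions = {s: 1.0 for s in enriched}
    if n_base:
        fractions.update({s: min(1.0, (n_target - n_enriched) / n_base)
                          for s in base})
    return fractions


def draw_stratified_sample(strata: pd.DataFrame, fractions: dict[str, float],
                           seed: int) -> pd.DataFrame:
    """Sample without replacement within each stratum at the given fraction.

    The per-stratum sample size is round(fraction * stratum size); the
    recorded selection probability is the realized k/N, so design weights are
    exact.  Returns patient_id, stratum_id, selection_probability,
    design_weight.
    """
    rng = np.random.default_rng(seed)
    out = []
    for stratum_id, members in strata.groupby("stratum_id", sort=True):
        if stratum_id not in fractions:
            raise ConfigError(f"no sampling fraction for stratum {stratum_id!r}")
        f = fractions[stratum_id]
        if not 0.0 < f <= 1.0:
            raise ConfigError(
                f"sampling fraction for {stratum_id!r} must be in (0, 1], got {f}")
        ids = np.sort(members["patient_id"].to_numpy())
        k = int(round(f * len(ids)))
        if k == 0:
            continue
        chosen = rng.choice(ids, size=k, replace=False)
        prob = k / len(ids)
        out.append(pd.DataFrame({"patient_id": np.sort(chosen),
                                 "stratum_id": stratum_id,
                                 "selection_probability": prob,
                                 "design_weight": 1.0 / prob}))
    if not out:
        return pd.DataFrame(columns=["patient_id", "stratum_id",
                                     "selection_probability", "design_weight"])
    return pd.concat(out, ignore_index=True)


def split_train_validation(patient_ids, train_fraction: float,
                           seed: int) -> pd.DataFrame:
    """Random disjoint split with exact sizes round(n*f) / remainder."""
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError(f"train_fraction must be in (0, 1), got {train_fraction}")
    ids = np.asarray(patient_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    split = np.full(len(ids), "validation", dtype=object)
    split[perm[:n_train]] = "train"
    return pd.DataFrame({"patient_id": ids, "split": split})


def weighted_prevalence(labels, weights) -> float:
    """Design-weighted prevalence: sum(w*y) / sum(w)."""
    y = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.size == 0:
        raise OpiphenError("weighted_prevalence of empty input")
    if y.shape != w.shape:
        raise OpiphenError("labels and weights have different lengths")
    if (w <= 0).any():
        raise OpiphenError("weights must be positive")
    return float(np.sum(w * y) / np.sum(w))
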