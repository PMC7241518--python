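"""End-to-end orchestration: simulate -> cohort -> sample -> features -> fit -> evaluate.

Mirrors the development procedure of the claims phenotyping study: build the
eligible long-term ER/LA cohort, draw an enriched stratified sample with
inverse-probability design weights, split 70/30 into training and
validation, operationalize the predictor catalog over each member's 36-month
observation window, fit the adaptive LASSO on the training split (design
weights are not used in model fitting, only for prevalence estimation), and
report cut-point performance on both splits next to the diagnosis-code
comparator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EligibilityConfig, build_cohort
from .evaluation import icd9_classifier, roc_auc, table3_report
from .features import PredictorMatrix, build_matrix, default_spec_library
from .lasso import AdaptiveLassoFit, PenaltyConfig, cv_grid_search, predict_risk
from .sampling import (assign_strata, draw_stratified_sample,
                       enrichment_fractions, split_train_validation,
                       weighted_prevalence)
from .synthetic import ClaimsDataset, SimConfig, generate_population

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    dataset: ClaimsDataset
    cohort: pd.DataFrame          # all eligible members
    design: pd.DataFrame          # sampled members with weights and split
    matrix: PredictorMatrix       # predictors for sampled members
    fit: AdaptiveLassoFit
    report: pd.DataFrame          # cut-point schemes + comparator
    auc_train: float
    auc_valid: float
    prevalence_weighted: float    # design-weighted 36-month outcome prevalence
    prevalence_pool: float        # unweighted prevalence in the eligible pool
    scores: pd.Series             # risk score per sampled member


def run_pipeline(sim_config: SimConfig | None = None,
                 eligibility: EligibilityConfig | None = None,
                 penalty: PenaltyConfig | None = None,
                 n_sample: int = 2000,
                 train_fraction: float = 0.7,
                 seed: int = 0,
                 dataset: ClaimsDataset | None = None,
                 spec_library=None) -> PipelineResult:
    """Run the full development-and-evaluation pipeline on synthetic claims.

    ``seed`` drives the sampling draw and the train/validation split (and
    the simulation, when ``dataset`` is not supplied and ``sim_config`` has
    no explicit seed).
    """
    if dataset is None:
        sim_config = sim_config or SimConfig(seed=seed)
        dataset = generate_population(sim_config)
    eligibility = eligibility or EligibilityConfig()
    penalty = penalty or PenaltyConfig(fold_seed=seed)

    cohort = build_cohort(dataset, eligibility)
    if len(cohort) == 0:
        raise ValueError("no eligible cohort members; check the simulation "
                         "configuration")
    strata = assign_strata(cohort, dataset.diagnoses)
    n_target = min(n_sample, len(cohort))
    fractions = enrichment_fractions(strata, n_target)
    design = draw_stratified_sample(strata, fractions, seed=seed)
    split = split_train_validation(design["patient_id"], train_fraction,
                                   seed=seed + 1)
    design = design.merge(split, on="patient_id")

    sampled = cohort[cohort["patient_id"].isin(design["patient_id"])]
    sampled = sampled.set_index("patient_id").loc[design["patient_id"]] \
        .reset_index()
    matrix = build_matrix(dataset, sampled, spec_library)
    y = sampled.set_index("patient_id")["outcome_36m"].astype(bool)

    is_train = (design.set_index("patient_id")["split"] == "train")
    X = matrix.values
    fit = cv_grid_search(X.loc[is_train[X.index.to_numpy()].to_numpy()],
                         y[is_train.reindex(y.index)].to_numpy(dtype=float),
                         penalty)

    scores = pd.Series(predict_risk(fit, X), index=X.index, name="risk_score")
    tr_ids = design.loc[design["split"] == "train", "patient_id"]
    va_ids = design.loc[design["split"] == "validation", "patient_id"]
    s_tr, y_tr = scores[tr_ids].to_numpy(), y[tr_ids].to_numpy()
    s_va, y_va = scores[va_ids].to_numpy(), y[va_ids].to_numpy()

    comparator = icd9_classifier(dataset.diagnoses, sampled)
    report = table3_report(s_tr, y_tr, s_va, y_va,
                           comparator_train=comparator[tr_ids].to_numpy(),
                           comparator_valid=comparator[va_ids].to_numpy())

    w = design.set_index("patient_id")["design_weight"]
    prev_w = weighted_prevalence(y[w.index].to_numpy(), w.to_numpy())
    prev_pool = float(cohort["outcome_36m"].mean())
    return PipelineResult(dataset=dataset, cohort=cohort, design=design,
                          matrix=matrix, fit=fit, report=report,
                          auc_train=roc_auc(s_tr, y_tr),
                          auc_valid=roc_auc(s_va, y_va),
                          prevalence_weighted=prev_w,
                          prevalence_pool=prev_pool, scores=scores)
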