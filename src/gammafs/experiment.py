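"""Simulation-study orchestration.

One repetition draws a paired train/validation dataset from a study
condition, runs every requested selector on the *same* training data, fits a
logistic model per selection and evaluates it on the shared validation data.
Repetitions are aggregated into a per-method indicator table (mean AUC,
Youden sensitivity/specificity, counts of informative / non-informative
selections, Jaccard stability across the repetitions' selected sets, and
mean selection wall-time), which feeds the TOPSIS ranking.  The ``full``
pseudo-method uses every feature and serves as the no-selection reference;
it is printed but excluded from the ranking.

Repetition ``r`` owns seed ``base_seed + r``, so results are independent of
the number of workers and reproducible end to end.
"""

from __future__ import annotations

import logging
import time
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .baselines import (cfs_select, cramers_v_scores, lasso_select, rfi_select,
                        step_aic_select, su_scores, svm_rfe_select)
from .datasets import LabeledDataset
from .evaluation import count_selected, fit_logistic, jaccard_stability, roc_auc, youden_point
from .gamma import GammaEvaluator
from .search import backward_search, best_first_search, forward_search
from .simdata import ScenarioSpec, generate_dataset, scenario_preset
from .topsis import DecisionMatrix, topsis_scores

__all__ = ["METHODS", "run_scenario", "report_table", "select_features"]

logger = logging.getLogger(__name__)


def _gamma_method(search) -> Callable:
    def run(train: LabeledDataset, seed: int) -> list[int]:
        return sorted(search(train.p, GammaEvaluator(train)).selected)
    return run


METHODS: dict[str, Callable[[LabeledDataset, int], list]] = {
    "full": lambda train, seed: list(range(train.p)),
    "gamma_forw": _gamma_method(forward_search),
    "gamma_back": _gamma_method(backward_search),
    "gamma_bf": _gamma_method(best_first_search),
    "chi2": lambda train, seed: cramers_v_scores(train).selected,
    "su": lambda train, seed: su_scores(train).selected,
    "cfs": lambda train, seed: cfs_select(train),
    "lasso": lambda train, seed: lasso_select(train, seed=seed),
    "rfi": lambda train, seed: rfi_select(train, seed=seed),
    "step": lambda train, seed: step_aic_select(train),
    "svm_rfe": lambda train, seed: svm_rfe_select(train, seed=seed),
}


def select_features(method: str, train: LabeledDataset, seed: int = 0) -> list[int]:
    """Run one named selector on a training dataset."""
    try:
        fn = METHODS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
    return list(fn(train, seed))


def _one_repetition(spec: ScenarioSpec, methods: Sequence[str], seed: int) -> dict:
    data = generate_dataset(spec, seed)
    truth = set(data.truth)
    out: dict[str, dict] = {}
    for method in methods:
        rec: dict = {"selected": None}
        try:
            t0 = time.perf_counter()
            selected = select_features(method, data.train, seed)
            rec["runtime_s"] = time.perf_counter() - t0
            model = fit_logistic(data.train, selected)
            probs = model.predict_proba(data.valid)
            rec["auc"] = roc_auc(probs, data.valid.labels)
            rec["sensitivity"], rec["specificity"] = youden_point(probs, data.valid.labels)
            rec["nsif"], rec["nsnif"] = count_selected(selected, truth, spec.p_total)
            rec["selected"] = tuple(selected)
        except Exception:
            logger.warning("method %s failed on seed %d", method, seed, exc_info=True)
            for key in ("auc", "sensitivity", "specificity", "nsif", "nsnif", "runtime_s"):
                rec[key] = np.nan
        out[method] = rec
    return out


def run_scenario(preset: str | ScenarioSpec, methods: Sequence[str],
                 reps: int, base_seed: int, workers: int = 1,
                 return_details: bool = False):
    """Aggregate indicator table over ``reps`` repetitions of one condition.

    Returns one row per method with columns ``auc``, ``sensitivity``,
    ``specificity``, ``nsif``, ``nsnif`` (means over repetitions, proportions
    in [0, 1] for the first three), ``stability`` and ``runtime_s``.  With
    ``return_details`` a tidy per-repetition indicator frame is returned as
    well (one row per method and repetition), e.g. for Monte-Carlo standard
    errors.
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    spec = scenario_preset(preset) if isinstance(preset, str) else preset
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    seeds = [base_seed + r for r in range(reps)]
    if workers > 1:
        rep_results = Parallel(n_jobs=workers)(
            delayed(_one_repetition)(spec, methods, s) for s in seeds)
    else:
        rep_results = [_one_repetition(spec, methods, s) for s in seeds]

    rows = []
    for method in methods:
        recs = [r[method] for r in rep_results]
        sel = [r["selected"] for r in recs if r["selected"] is not None]
        row = {"method": method}
        for key in ("auc", "sensitivity", "specificity", "nsif", "nsnif", "runtime_s"):
            vals = np.array([r[key] for r in recs], dtype=float)
            row[key] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan
        row["stability"] = jaccard_stability(sel) if len(sel) >= 2 else np.nan
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("method")
    if not return_details:
        return summary
    detail_rows = []
    for r, rep in enumerate(rep_results):
        for method in methods:
            rec = rep[method]
            detail_rows.append({"rep": r, "seed": seeds[r], "method": method,
                                **{k: rec[k] for k in ("auc", "sensitivity",
                                                       "specificity", "nsif",
                                                       "nsnif", "runtime_s")},
                                "selected": rec["selected"]})
    return summary, pd.DataFrame(detail_rows)


def report_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Publication-shaped table: percentages, TOPSIS rank, reference row.

    AUC/sensitivity/specificity are reported in percent.  The ``full``
    reference row (if present) is excluded from the ranking and gets no rank.
    """
    tbl = summary.copy()
    for col in ("auc", "sensitivity", "specificity"):
        tbl[col] = 100.0 * tbl[col]
    ranked = tbl.drop(index="full", errors="ignore")
    tbl["rank"] = np.nan
    if len(ranked) >= 2:
        matrix = DecisionMatrix(ranked[["auc", "sensitivity", "specificity",
                                        "nsif", "nsnif", "stability", "runtime_s"]])
        _, ranks = topsis_scores(matrix)
        tbl.loc[ranked.index, "rank"] = ranks
    out = tbl.reset_index().rename(columns={
        "method": "FSM", "auc": "AUC", "sensitivity": "Se", "specificity": "Spe",
        "nsif": "NSIF", "nsnif": "NSNIF", "stability": "Stability",
        "runtime_s": "Runtime", "rank": "Rank"})
    return out[["FSM", "AUC", "Se", "Spe", "NSIF", "NSNIF", "Stability", "Runtime", "Rank"]]
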