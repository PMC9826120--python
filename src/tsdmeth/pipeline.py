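"""End-to-end orchestration of the blood-methylome analysis.

Chains the stages in study order — filtering, the five contrasts, DMC
classification, KNN imputation, train/test split, candidate selection and
the two elastic-net predictors — and, when a simulation truth table is
available, scores planted-effect recovery and the empirical false-discovery
proportion.  Used by recovery tests and the acceptance script; real data
flows through the same call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diffmeth import classify_dmcs, knn_impute, run_contrasts
from .filtering import FilterConfig, FilterReport, apply_filters
from .io import CpGLocus, MethylomeMatrix, SampleRecord
from . import predict as _predict
from .simulate import treatment_groups


@dataclass
class StudyAnalysis:
    matrix: MethylomeMatrix
    filter_report: FilterReport
    contrasts: dict
    classes: pd.DataFrame
    percent_imputed: np.ndarray
    split: _predict.SplitPlan
    sex_model: _predict.SparsePredictor | None
    sex_eval: dict | None
    temp_model: _predict.SparsePredictor | None
    temp_eval: dict | None
    recovery: dict | None = None


def _design_matrix(
    pct: np.ndarray,
    loci: Sequence[CpGLocus],
    matrix: MethylomeMatrix,
    sample_ids: Sequence[str],
) -> np.ndarray:
    row = {loc: i for i, loc in enumerate(matrix.loci)}
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    return np.array([[pct[row[l], col[s]] for l in loci] for s in sample_ids])


def analyse_study(
    matrix: MethylomeMatrix,
    metadata: Sequence[SampleRecord],
    seed: int = 0,
    fdr: float = 0.1,
    fdr_train: float = 0.05,
    filter_config: FilterConfig | None = None,
    truth: pd.DataFrame | None = None,
    split_scheme: str = "one_per_cell",
) -> StudyAnalysis:
    """Run the full blood pipeline on a count matrix.

    ``truth`` (a simulation truth table with scaffold, pos, class) enables
    recovery scoring.  Prediction stages are skipped gracefully when no
    candidate loci survive (e.g. on a null simulation).
    """
    filtered, report = apply_filters(matrix, treatment_groups(metadata), filter_config)
    contrasts = run_contrasts(filtered, fdr=fdr)
    classes = classify_dmcs(contrasts, fdr=fdr)
    pct = knn_impute(filtered.percent())

    split = _predict.make_split(metadata, split_scheme, seed=seed)
    train_matrix = filtered.subset_samples(split.train)
    train_classes = classify_dmcs(run_contrasts(train_matrix, fdr=fdr_train), fdr=fdr_train)
    meta_by_id = {s.sample_id: s for s in metadata}

    def _fit(target: str, family: str, y_of):
        try:
            cand = _predict.select_candidates(train_classes, classes, target)
        except ValueError:
            return None, None
        X_train = _design_matrix(pct, cand, filtered, split.train)
        X_test = _design_matrix(pct, cand, filtered, split.test)
        y_train = np.array([y_of(meta_by_id[s]) for s in split.train])
        y_test = np.array([y_of(meta_by_id[s]) for s in split.test])
        model = _predict.fit_elastic_net(X_train, y_train, cand, family, seed=seed)
        metrics = _predict.evaluate(_predict.predict(model, X_test), y_test, family)
        return model, metrics

    sex_model, sex_eval = _fit("sex", "binomial", lambda r: 1.0 if r.sex == "M" else 0.0)
    temp_model, temp_eval = _fit("temperature", "gaussian", lambda r: float(r.temperature))

    recovery = None
    if truth is not None:
        tr = truth.set_index(["scaffold", "pos"])
        joined = classes.set_index(["scaffold", "pos"]).join(
            tr[["class"]], rsuffix="_true"
        )
        planted_sex = joined["class_true"] == "sex"
        planted_temp = joined["class_true"] == "temperature"
        found_sex = joined["class"].isin(["sex", "universal_sex"])
        found_any = joined["class"] != "none"
        n_disc = int(found_any.sum())
        recovery = {
            "n_loci": int(len(joined)),
            "n_planted_sex": int(planted_sex.sum()),
            "n_planted_temp": int(planted_temp.sum()),
            "sex_recovery": float((planted_sex & found_sex).sum() / max(planted_sex.sum(), 1)),
            "temp_recovery": float(
                (planted_temp & found_any).sum() / max(planted_temp.sum(), 1)
            ),
            "n_discoveries": n_disc,
            "n_false": int((found_any & (joined["class_true"] == "null")).sum()),
        }
        recovery["fdp"] = recovery["n_false"] / max(n_disc, 1)

    return StudyAnalysis(
        matrix=filtered,
        filter_report=report,
        contrasts=contrasts,
        classes=classes,
        percent_imputed=pct,
        split=split,
        sex_model=sex_model,
        sex_eval=sex_eval,
        temp_model=temp_model,
        temp_eval=temp_eval,
        recovery=recovery,
    )
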