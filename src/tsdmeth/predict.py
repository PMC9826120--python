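"""Sparse methylation-based predictors of hatchling sex and incubation temperature.

Candidate CpGs are those differentially methylated for the target both in
the training subset (at a stricter FDR) and in the full data set; their
imputed percent-methylation values feed an elastic-net model
(mixing parameter alpha = 0.5 by default):

    min_beta  (1/N) sum_i loss(y_i, b0 + x_i . beta)
              + lambda * [ alpha * |beta|_1 + (1 - alpha)/2 * |beta|_2^2 ]

with the binomial deviance loss for sex and squared error for temperature.
The penalty weight lambda is chosen to minimize mean cross-validated error
(5-fold) along a descending log-spaced path; features are standardized
internally and coefficients reported back on the percent-methylation scale.

scikit-learn provides the per-lambda solvers (ElasticNet for the gaussian
family, saga-solver LogisticRegression for the binomial family).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from .io import CpGLocus, SampleRecord


@dataclass
class SplitPlan:
    """A train/test partition of the study samples."""

    train: list[str]
    test: list[str]
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test sets overlap")


def make_split(
    metadata: Sequence[SampleRecord], scheme: str = "one_per_cell", seed: int = 0
) -> SplitPlan:
    """Draw a train/test split.

    ``one_per_cell`` holds out one randomly chosen individual from every
    temperature-sex combination (the held-out set mirrors the design);
    ``half_half`` holds out half the samples, stratified by cell.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    cells: dict[tuple[float, str], list[str]] = {}
    for s in metadata:
        cells.setdefault((float(s.temperature), s.sex), []).append(s.sample_id)
    test: list[str] = []
    if scheme == "one_per_cell":
        for key in sorted(cells):
            ids = sorted(cells[key])
            if not ids:
                raise ValueError(f"temperature-sex cell {key} is empty")
            test.append(ids[rng.integers(len(ids))])
    elif scheme == "half_half":
        for key in sorted(cells):
            ids = sorted(cells[key])
            take = len(ids) // 2
            test.extend(rng.choice(ids, size=take, replace=False).tolist())
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")
    train = [s.sample_id for s in metadata if s.sample_id not in set(test)]
    return SplitPlan(train=train, test=sorted(test), scheme=scheme, seed=seed)


def select_candidates(
    train_classes: pd.DataFrame,
    full_classes: pd.DataFrame,
    target: str,
    ) -> list[CpGLocus]:
    """Intersect training-set DMCs with full-data DMCs for the target.

    ``train_classes`` / ``full_classes`` are outputs of
    :func:`tsdmeth.diffmeth.classify_dmcs` — the training one computed on the
    training subset at the stricter FDR (0.05), the full one on all samples
    at the study FDR (0.1).  For ``target='sex'`` both sex classes count
    (universal or 34.5-specific); for ``target='temperature'`` only loci
    classified temperature-associated (sex precedence already applied).
    """
    if target == "sex":
        wanted = {"sex", "universal_sex"}
    elif target == "temperature":
        wanted = {"temperature"}
    else:
        raise ValueError(f"unknown target {target!r}")

    def _set(df: pd.DataFrame) -> set[CpGLocus]:
        m = df["class"].isin(wanted)
        return {
            CpGLocus(s, int(p))
            for s, p in zip(df.loc[m, "scaffold"], df.loc[m, "pos"])
        }

    candidates = sorted(_set(train_classes) & _set(full_classes))
    if not candidates:
        raise ValueError(
            f"no candidate loci for target {target!r}: training-set and full-data "
            "DMC sets do not intersect (planted effects may be too weak)"
        )
    return candidates


@dataclass
class SparsePredictor:
    """A fitted elastic-net model over candidate CpG loci.

    Coefficients are stored on the original percent-methylation scale;
    ``feature_mean``/``feature_sd`` record the standardization used at fit
    time (for provenance, not needed at predict time).
    """

    family: str
    alpha: float
    lam: float
    loci: list[CpGLocus]
    coef: np.ndarray  # per locus, original scale; 0 entries already dropped
    intercept: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    seed: int = 0
    cv_errors: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def selected_loci(self) -> list[CpGLocus]:
        return [loc for loc, c in zip(self.loci, self.coef) if c != 0.0]

    def to_json(self, path) -> None:
        payload = {
            "family": self.family,
            "alpha": self.alpha,
            "lambda": self.lam,
            "seed": self.seed,
            "intercept": self.intercept,
            "loci": [[l.scaffold, l.pos] for l in self.loci],
            "coef": list(map(float, self.coef)),
            "feature_mean": list(map(float, self.feature_mean)),
            "feature_sd": list(map(float, self.feature_sd)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SparsePredictor":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            family=d["family"],
            alpha=d["alpha"],
            lam=d["lambda"],
            loci=[CpGLocus(s, int(p)) for s, p in d["loci"]],
            coef=np.asarray(d["coef"], float),
            intercept=float(d["intercept"]),
            feature_mean=np.asarray(d["feature_mean"], float),
            feature_sd=np.asarray(d["feature_sd"], float),
            seed=int(d.get("seed", 0)),
        )


def _fit_at_lambda(
    Xs: np.ndarray, y: np.ndarray, family: str, lam: float, alpha: float
) -> tuple[np.ndarray, float]:
    """Solve the elastic-net problem at one lambda on standardized features."""
    n = Xs.shape[0]
    if family == "gaussian":
        if lam == 0.0:
            A = np.column_stack([np.ones(n), Xs])
            sol, *_ = np.linalg.lstsq(A, y, rcond=None)
            return sol[1:], float(sol[0])
        model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=50_000)
        model.fit(Xs, y)
        return model.coef_.copy(), float(model.intercept_)
    if family == "binomial":
        model = LogisticRegression(
            solver="saga",
            l1_ratio=0.0 if lam == 0.0 else alpha,
            C=1e12 if lam == 0.0 else 1.0 / (n * lam),
            max_iter=20_000,
            tol=1e-7,
        )
        model.fit(Xs, y)
        return model.coef_[0].copy(), float(model.intercept_[0])
    raise ValueError(f"unknown family {family!r}")


def _lambda_path(
    Xs: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int, ratio: float = 1e-4
) -> np.ndarray:
    """glmnet-style descending log-spaced path from the smallest lambda that
    zeroes every coefficient."""
    n = Xs.shape[0]
    resid = y - y.mean()
    lam_max = np.abs(Xs.T @ resid).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def fit_elastic_net(
    X: np.ndarray,
    y: Sequence[float],
    loci: Sequence[CpGLocus],
    family: str,
    alpha: float = 0.5,
    n_folds: int = 5,
    seed: int = 0,
    n_lambda: int = 50,
) -> SparsePredictor:
    """Fit the cross-validated elastic net over candidate loci.

    ``X`` is the imputed percent matrix with samples in rows and candidate
    loci in columns (no missing values); ``y`` is 0/1 for the binomial
    family (1 = male) or degrees Celsius for the gaussian family.  Lambda is
    chosen to minimize the mean cross-validated squared error (on predicted
    probabilities for the binomial family, matching the study's tuning
    criterion); folds are stratified by class for the binomial family.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute first")
    n, p = X.shape
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples for {n_folds}-fold CV")
    if len(loci) != p:
        raise ValueError("loci length must match number of columns of X")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd

    lambdas = _lambda_path(Xs, y, alpha, n_lambda)
    if family == "binomial":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(Xs, y))
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(Xs))

    cv_err = np.full(lambdas.size, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, lam in enumerate(lambdas):
            errs = []
            for tr, te in folds:
                try:
                    coef, b0 = _fit_at_lambda(Xs[tr], y[tr], family, lam, alpha)
                except Exception as exc:  # pragma: no cover - solver failure
                    warnings.warn(f"lambda {lam:.4g}: fold failed ({exc}); skipped")
                    continue
                eta = b0 + Xs[te] @ coef
                if family == "binomial":
                    pred = 1.0 / (1.0 + np.exp(-eta))
                else:
                    pred = eta
                errs.append(float(np.mean((y[te] - pred) ** 2)))
            if errs:
                cv_err[i] = float(np.mean(errs))

        best = int(np.nanargmin(cv_err))
        lam = float(lambdas[best])
        coef_s, b0 = _fit_at_lambda(Xs, y, family, lam, alpha)

    coef = coef_s / sd
    intercept = b0 - float((coef_s * mean / sd).sum())
    return SparsePredictor(
        family=family,
        alpha=alpha,
        lam=lam,
        loci=list(loci),
        coef=coef,
        intercept=intercept,
        feature_mean=mean,
        feature_sd=sd,
        seed=seed,
        cv_errors=pd.DataFrame({"lambda": lambdas, "cv_error": cv_err}),
    )


def predict(model: SparsePredictor, X_new: np.ndarray) -> np.ndarray:
    """Predicted P(male) (binomial) or degrees Celsius (gaussian).

    ``X_new`` must carry the model's loci as columns, in order, fully imputed.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != len(model.loci):
        raise ValueError(
            f"X_new must have {len(model.loci)} columns matching model loci: "
            + ", ".join(f"{l.scaffold}:{l.pos}" for l in model.loci[:5])
            + ("..." if len(model.loci) > 5 else "")
        )
    if np.isnan(X_new).any():
        raise ValueError("X_new contains missing values; impute first")
    eta = model.intercept + X_new @ model.coef
    if model.family == "binomial":
        return 1.0 / (1.0 + np.exp(-eta))
    return eta


def evaluate(
    predictions: np.ndarray, truth: Sequence[float], family: str
) -> dict[str, float]:
    """Held-out performance metrics.

    Binomial: accuracy at the 0.5 cutoff plus per-class mean and standard
    error of the predicted probability of being male.  Gaussian: R-squared
    of actual vs predicted and mean absolute error (degrees C).
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(truth, dtype=float)
    if family == "binomial":
        assigned = (pred >= 0.5).astype(float)
        out = {"accuracy": float((assigned == y).mean())}
        for label, name in ((0.0, "female"), (1.0, "male")):
            vals = pred[y == label]
            if vals.size:
                out[f"mean_p_male_{name}"] = float(vals.mean())
                out[f"se_p_male_{name}"] = float(
                    vals.std(ddof=1) / np.sqrt(vals.size)
                ) if vals.size > 1 else 0.0
        return out
    if family == "gaussian":
        ss_res = float(((y - pred) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return {"r2": r2, "mae": float(np.abs(y - pred).mean())}
    raise ValueError(f"unknown family {family!r}")
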