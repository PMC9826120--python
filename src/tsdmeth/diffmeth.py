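"""Per-CpG differential-methylation testing and downstream screens.

The core test models the methylated read count at one CpG, in sample j of
group g, as Binomial(n_j, p_g) and compares the two-group model against a
single-proportion null by likelihood ratio.  Biological replicate variation
makes counts overdispersed relative to the binomial, so the likelihood-ratio
statistic is deflated by the Pearson-residual overdispersion estimate

    phi_hat = sum_j r_j^2 / (J - 2),   r_j = (m_j - n_j p_g) / sqrt(n_j p_g (1 - p_g))

whenever phi_hat > 1, and referred to chi-square with 1 df (or optionally
F(1, J-2)).  With a single binary covariate the maximum-likelihood group
proportions are the pooled per-group proportions, so the whole test is
closed-form and vectorizes across loci.

Also here: Benjamini-Hochberg adjustment, the five study contrasts
(female-vs-male overall and at the highest temperature, and the three
pairwise temperature contrasts), DMC classification with sex precedence,
k-nearest-neighbour imputation of percent methylation, genome-wide Spearman
screens against a numeric covariate, and Mann-Whitney comparison of
absolute correlation strengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from sklearn.impute import KNNImputer

from .io import MethylomeMatrix

CONTRASTS = ("FvM", "F34.5vM34.5", "30v33.5", "30v34.5", "33.5v34.5")

# Sides of each contrast: group A minus group B, on the percent scale.
# Temperature contrasts put the lower temperature first, so meth_diff < 0
# means methylation increases with temperature.


def _group_loglik(meth: np.ndarray, cov: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood (without the constant binomial coefficient),
    summed over samples; `p` broadcast per locus."""
    return (xlogy(meth, p[:, None]) + xlogy(cov - meth, 1.0 - p[:, None])).sum(axis=1)


def dm_test_matrix(
    meth: np.ndarray,
    cov: np.ndarray,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    correction: str = "f",
) -> pd.DataFrame:
    """Vectorized overdispersion-corrected logistic-regression LRT.

    Parameters
    ----------
    meth, cov : (loci, samples) integer arrays; cov == 0 marks missing cells.
    mask_a, mask_b : boolean sample selectors for the two contrast sides.
    correction : "chisq" refers the deflated statistic to chi2(1); "f" refers
        it to F(1, J-2) when the overdispersion estimate exceeds 1.

    Returns a DataFrame with meth_diff (percent, A - B), lrt, phi, p; rows
    with an uncovered group side are NaN.
    """
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both contrast sides need at least one sample")
    mA, nA = meth[:, mask_a], cov[:, mask_a]
    mB, nB = meth[:, mask_b], cov[:, mask_b]

    totA, totB = nA.sum(axis=1), nB.sum(axis=1)
    methA, methB = mA.sum(axis=1), mB.sum(axis=1)
    jA, jB = (nA > 0).sum(axis=1), (nB > 0).sum(axis=1)
    ok = (jA >= 2) & (jB >= 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        pA = np.where(totA > 0, methA / np.maximum(totA, 1), np.nan)
        pB = np.where(totB > 0, methB / np.maximum(totB, 1), np.nan)
        p0 = (methA + methB) / np.maximum(totA + totB, 1)

    ll_full = _group_loglik(mA, nA, pA) + _group_loglik(mB, nB, pB)
    ll_null = _group_loglik(mA, nA, p0) + _group_loglik(mB, nB, p0)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)

    # Pearson residuals of the full (two-proportion) model; cells with
    # fitted proportion 0 or 1 have zero residual by continuity.
    def _pearson_sq(m, n, p):
        mu = n * p[:, None]
        var = mu * (1.0 - p[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (m - mu) ** 2 / var
        return np.where((n > 0) & (var > 0), r2, 0.0).sum(axis=1)

    J = jA + jB
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (_pearson_sq(mA, nA, pA) + _pearson_sq(mB, nB, pB)) / np.maximum(J - 2, 1)
    corrected = lrt / np.maximum(phi, 1.0)

    if correction == "chisq":
        p = stats.chi2.sf(corrected, df=1)
    elif correction == "f":
        # the dispersion scale is estimated on J-2 df, so the deflated
        # statistic is F-distributed; the F reference is used whether or not
        # the deflation floor at phi = 1 was active, which guards against
        # chance-underestimated dispersion as well
        p = stats.f.sf(corrected, 1, np.maximum(J - 2, 1))
    else:
        raise ValueError(f"unknown correction {correction!r}")

    meth_diff = 100.0 * (pA - pB)
    out = pd.DataFrame(
        {"meth_diff": meth_diff, "lrt": lrt, "phi": phi, "p": p}
    )
    out.loc[~ok, :] = np.nan
    return out


def dm_logistic_test(
    meth_a: Sequence[int],
    cov_a: Sequence[int],
    meth_b: Sequence[int],
    cov_b: Sequence[int],
    correction: str = "f",
) -> tuple[float, float, float, float]:
    """Single-locus convenience wrapper: returns (meth_diff, lrt, phi, p)."""
    meth = np.array([list(meth_a) + list(meth_b)])
    cov = np.array([list(cov_a) + list(cov_b)])
    mask_a = np.array([True] * len(list(meth_a)) + [False] * len(list(meth_b)))
    row = dm_test_matrix(meth, cov, mask_a, ~mask_a, correction).iloc[0]
    return float(row.meth_diff), float(row.lrt), float(row.phi), float(row.p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (NaNs pass through)."""
    p = np.asarray(p, dtype=float)
    finite = ~np.isnan(p)
    vals = p[finite]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = vals.size
    q = np.full_like(p, np.nan)
    if n:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * n / np.arange(1, n + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(n)
        qv[order] = np.minimum(ranked, 1.0)
        q[finite] = qv
    return q


@dataclass
class ContrastSpec:
    name: str
    mask_a: np.ndarray
    mask_b: np.ndarray


def _contrast_masks(samples) -> list[ContrastSpec]:
    sex = np.array([s.sex for s in samples])
    temp = np.array([float(s.temperature) for s in samples])
    specs = []
    for name in CONTRASTS:
        if name == "FvM":
            a, b = sex == "F", sex == "M"
        elif name == "F34.5vM34.5":
            a = (sex == "F") & (temp == 34.5)
            b = (sex == "M") & (temp == 34.5)
        else:
            lo, hi = (float(x) for x in name.split("v"))
            a, b = temp == lo, temp == hi
        specs.append(ContrastSpec(name, a, b))
    return specs


def run_contrasts(
    matrix: MethylomeMatrix,
    fdr: float = 0.1,
    correction: str = "f",
    contrasts: Sequence[str] = CONTRASTS,
) -> dict[str, pd.DataFrame]:
    """Run the study contrasts on a filtered matrix.

    FDR adjustment is applied within each contrast independently.  Returns a
    mapping from contrast name to a per-locus DataFrame (scaffold, pos,
    meth_diff, lrt, phi, p, q).
    """
    available = {c.name: c for c in _contrast_masks(matrix.samples)}
    results: dict[str, pd.DataFrame] = {}
    for name in contrasts:
        spec = available[name]
        if not spec.mask_a.any() or not spec.mask_b.any():
            raise ValueError(f"contrast {name}: one side has no samples")
        df = dm_test_matrix(matrix.meth, matrix.cov, spec.mask_a, spec.mask_b, correction)
        df.insert(0, "scaffold", [loc.scaffold for loc in matrix.loci])
        df.insert(1, "pos", [loc.pos for loc in matrix.loci])
        df["q"] = bh_adjust(df["p"].to_numpy())
        results[name] = df
    return results


def run_temperature_contrasts(
    matrix: MethylomeMatrix, fdr: float = 0.1, correction: str = "f"
) -> dict[str, pd.DataFrame]:
    """All pairwise temperature contrasts among the temperatures present
    (used for the gonad data set, where sex is unknown)."""
    temps = sorted({float(s.temperature) for s in matrix.samples})
    temp_arr = np.array([float(s.temperature) for s in matrix.samples])
    results = {}
    for i, lo in enumerate(temps):
        for hi in temps[i + 1 :]:
            name = f"{lo:g}v{hi:g}"
            df = dm_test_matrix(
                matrix.meth, matrix.cov, temp_arr == lo, temp_arr == hi, correction
            )
            df.insert(0, "scaffold", [loc.scaffold for loc in matrix.loci])
            df.insert(1, "pos", [loc.pos for loc in matrix.loci])
            df["q"] = bh_adjust(df["p"].to_numpy())
            results[name] = df
    return results


SEX_CONTRASTS = ("FvM", "F34.5vM34.5")
TEMP_CONTRASTS = ("30v33.5", "30v34.5", "33.5v34.5")


def classify_dmcs(
    contrast_results: Mapping[str, pd.DataFrame],
    fdr: float = 0.1,
    sex_contrasts: Sequence[str] = SEX_CONTRASTS,
    temp_contrasts: Sequence[str] = TEMP_CONTRASTS,
) -> pd.DataFrame:
    """Label each locus as universal_sex / sex / temperature / none.

    Sex takes precedence: a locus significant in any sex contrast is
    sex-associated even if it is also significant in a temperature contrast.
    ``universal_sex`` additionally requires significance in the all-female
    versus all-male contrast.  Direction comes from the sign of the percent
    difference (for temperature, from the higher-vs-lower-temperature sign
    of the most significant contributing contrast).
    """
    first = contrast_results[sex_contrasts[0]]
    out = first[["scaffold", "pos"]].copy()
    n = len(out)

    def _sig(name):
        q = contrast_results[name]["q"].to_numpy()
        return np.nan_to_num(q, nan=np.inf) < fdr

    sig = {name: _sig(name) for name in contrast_results}
    universal = sig.get("FvM", np.zeros(n, bool))
    sex_any = np.zeros(n, bool)
    for c in sex_contrasts:
        if c in sig:
            sex_any |= sig[c]
    temp_any = np.zeros(n, bool)
    for c in temp_contrasts:
        if c in sig:
            temp_any |= sig[c]

    cls = np.where(
        sex_any, np.where(universal, "universal_sex", "sex"),
        np.where(temp_any, "temperature", "none"),
    )

    direction = np.full(n, "n/a", dtype=object)
    # sex direction: female-biased when females are the more methylated sex
    sex_diff = np.full(n, np.nan)
    sex_q = np.full(n, np.inf)
    for c in sex_contrasts:
        if c not in contrast_results:
            continue
        q = np.nan_to_num(contrast_results[c]["q"].to_numpy(), nan=np.inf)
        d = contrast_results[c]["meth_diff"].to_numpy()
        better = sig[c] & (q < sex_q)
        sex_diff = np.where(better, d, sex_diff)
        sex_q = np.where(better, q, sex_q)
    is_sex = (cls == "sex") | (cls == "universal_sex")
    direction[is_sex & (sex_diff > 0)] = "female_biased"
    direction[is_sex & (sex_diff <= 0)] = "male_biased"

    # temperature direction: positive when methylation rises with temperature
    # (contrast sides are lower minus higher temperature, hence the sign flip)
    t_diff = np.full(n, np.nan)
    t_q = np.full(n, np.inf)
    for c in temp_contrasts:
        if c not in contrast_results:
            continue
        q = np.nan_to_num(contrast_results[c]["q"].to_numpy(), nan=np.inf)
        d = contrast_results[c]["meth_diff"].to_numpy()
        better = sig[c] & (q < t_q)
        t_diff = np.where(better, d, t_diff)
        t_q = np.where(better, q, t_q)
    is_temp = cls == "temperature"
    direction[is_temp & (t_diff < 0)] = "positive_with_temperature"
    direction[is_temp & (t_diff >= 0)] = "negative_with_temperature"

    sources = []
    for i in range(n):
        sources.append(",".join(sorted(c for c in contrast_results if sig[c][i])))
    out["class"] = cls
    out["direction"] = direction
    out["source_contrasts"] = sources
    return out


def summarize_dmc_rates(n_dmc: int, n_covered: int) -> float:
    """Percentage of covered loci that are DMCs, at 2 significant figures."""
    if n_covered <= 0:
        raise ValueError("n_covered must be positive")
    if not (0 <= n_dmc <= n_covered):
        raise ValueError("require 0 <= n_dmc <= n_covered")
    rate = 100.0 * n_dmc / n_covered
    return float(f"{rate:.2g}") if rate != 0 else 0.0


def knn_impute(
    percent: np.ndarray, k: int = 10, max_missing_frac: float = 0.5
) -> np.ndarray:
    """Impute missing percent-methylation values from the k nearest loci.

    Rows are loci, columns samples.  For a locus with missing cells the k
    nearest loci (Euclidean distance over jointly observed samples, scaled
    for missingness) supply the value: the imputed cell is the mean of the
    neighbours' values in that sample.  Loci missing in more than
    ``max_missing_frac`` of samples fall back to their row mean, as do cells
    whose candidate neighbours are all missing in the target sample.
    """
    X = np.asarray(percent, dtype=float).copy()
    if X.ndim != 2:
        raise ValueError("percent matrix must be 2-D (loci x samples)")
    row_obs = ~np.isnan(X)
    if not row_obs.any(axis=1).all():
        raise ValueError("every locus needs at least one observed value")
    if not np.isnan(X).any():
        return X
    row_means = np.nanmean(X, axis=1)
    high_missing = (~row_obs).mean(axis=1) > max_missing_frac
    for i in np.flatnonzero(high_missing):
        X[i, ~row_obs[i]] = row_means[i]
    if np.isnan(X).any():
        n_complete = int(row_obs.all(axis=1).sum())
        if n_complete < k:
            warnings.warn(
                f"only {n_complete} complete loci available for k={k} neighbours; "
                "using all available",
                stacklevel=2,
            )
        # rows are loci: a missing cell is filled from the k nearest loci
        imputer = KNNImputer(n_neighbors=min(k, max(X.shape[0] - 1, 1)))
        X = imputer.fit_transform(X)
    return X


def spearman_screen(
    percent_imputed: np.ndarray, covariate: Sequence[float]
) -> pd.DataFrame:
    """Spearman correlation of each locus's percent methylation with a
    per-sample covariate (e.g. incubation temperature or plasma E2).

    Uses average ranks for ties; p-values from the t approximation
    t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df; q by Benjamini-Hochberg.
    Constant loci (or a constant covariate) yield NaN rho and are flagged.
    """
    X = np.asarray(percent_imputed, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if X.shape[1] != y.size:
        raise ValueError("covariate length must equal number of samples")
    n = y.size
    ry = stats.rankdata(y)
    if np.ptp(ry) == 0:
        raise ValueError("covariate is constant")
    rX = stats.rankdata(X, axis=1)
    rXc = rX - rX.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    denom = np.sqrt((rXc**2).sum(axis=1) * (ryc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rXc @ ryc) / denom
    rho = np.where(denom > 0, rho, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(
        np.isnan(rho), np.nan,
        np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)),
    )
    return pd.DataFrame({"rho": rho, "p": p, "q": bh_adjust(p), "flagged": np.isnan(rho)})


def compare_abs_rho(
    rhos_a: Sequence[float], rhos_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing |rho| between two locus sets.

    Exact enumeration when both samples have <= 8 values; tie-corrected
    normal approximation otherwise.  Returns (U for the first sample, p).
    """
    a = np.abs(np.asarray(rhos_a, float))
    b = np.abs(np.asarray(rhos_b, float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the tie-corrected normal
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
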