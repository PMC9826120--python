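"""Locus-retention filters applied before differential-methylation testing.

The filters run in a fixed order, mirroring common RRBS practice:

1. :func:`drop_extreme_coverage` — per-sample removal of cells above the
   99.9th coverage percentile (PCR-duplication bias).
2. :func:`require_min_coverage` — a locus must reach >=5 reads in at least
   half the samples of *every* treatment group (temperature-sex combination).
3. :func:`normalize_coverage` — median-based per-sample coverage scaling.
4. :func:`remove_constitutive` — loci >95% methylated in all samples, or
   <5% in all samples, carry no contrast information and are dropped.
5. :func:`remove_near_zero_variance` — caret-style near-zero-variance rule
   on percent methylation.

Each function returns a new matrix; :func:`apply_filters` chains them and
records an audit trail of loci removed at each stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import MethylomeMatrix


@dataclass
class FilterConfig:
    top_coverage_pct: float = 99.9
    min_cov: int = 5
    min_prop_per_group: float = 0.5
    hyper_cut: float = 95.0
    hypo_cut: float = 5.0
    freq_cut: float = 95.0 / 5.0
    unique_cut: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.min_prop_per_group <= 1):
            raise ValueError("min_prop_per_group must be in (0, 1]")
        if self.hypo_cut >= self.hyper_cut:
            raise ValueError("hypo_cut must be below hyper_cut")


@dataclass
class FilterReport:
    """Loci (and cells) removed at each pipeline stage."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, before: int, after: int, **extra) -> None:
        self.stages.append(
            {"stage": stage, "loci_before": before, "loci_after": after, **extra}
        )


def drop_extreme_coverage(
    matrix: MethylomeMatrix, top_coverage_pct: float = 99.9
) -> MethylomeMatrix:
    """Mask cells whose coverage strictly exceeds the per-sample percentile.

    The percentile is computed per sample over covered cells only, with
    linear interpolation (numpy default).
    """
    out = matrix.copy()
    for j in range(out.n_samples):
        col = out.cov[:, j]
        covered = col > 0
        if not covered.any():
            continue
        cut = np.percentile(col[covered], top_coverage_pct)
        kill = covered & (col > cut)
        out.cov[kill, j] = 0
        out.meth[kill, j] = 0
    return out


def require_min_coverage(
    matrix: MethylomeMatrix,
    groups: Mapping[str, str],
    min_cov: int = 5,
    min_prop_per_group: float = 0.5,
) -> MethylomeMatrix:
    """Keep loci adequately covered in every treatment group.

    A locus is retained iff, in each group, the fraction of samples with
    coverage >= ``min_cov`` is at least ``min_prop_per_group`` (boundary
    inclusive).
    """
    sids = matrix.sample_ids
    unassigned = [s for s in sids if s not in groups]
    if unassigned:
        raise ValueError(f"samples missing a treatment group: {unassigned}")
    labels = np.array([groups[s] for s in sids])
    keep = np.ones(matrix.n_loci, dtype=bool)
    for g in np.unique(labels):
        cols = labels == g
        n = int(cols.sum())
        if n == 0:
            raise ValueError(f"group {g!r} has no samples")
        frac = (matrix.cov[:, cols] >= min_cov).sum(axis=1) / n
        keep &= frac >= min_prop_per_group
    return matrix.subset_loci(keep)


def normalize_coverage(matrix: MethylomeMatrix) -> MethylomeMatrix:
    """Median-scale coverage across samples (methylKit-style).

    Scale factor for sample s is median(per-sample median coverages) divided
    by sample s's median coverage; counts are scaled and rounded, coverage
    clamped to >=1 where a cell was covered, and the methylated count clamped
    to [0, coverage].  Per-cell percent methylation is preserved to within
    rounding.
    """
    if matrix.n_samples < 2:
        raise ValueError("coverage normalization requires >=2 samples")
    medians = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        col = matrix.cov[:, j]
        covered = col > 0
        if not covered.any():
            raise ValueError(f"sample {matrix.sample_ids[j]!r} has no covered cells")
        medians[j] = np.median(col[covered])
    target = np.median(medians)
    factors = target / medians

    out = matrix.copy()
    covered = matrix.cov > 0
    new_cov = np.rint(matrix.cov * factors[None, :]).astype(np.int64)
    new_cov = np.where(covered, np.maximum(new_cov, 1), 0)
    new_meth = np.rint(matrix.meth * factors[None, :]).astype(np.int64)
    new_meth = np.clip(new_meth, 0, new_cov)
    out.cov = new_cov
    out.meth = new_meth
    return out


def remove_constitutive(
    matrix: MethylomeMatrix, hyper_cut: float = 95.0, hypo_cut: float = 5.0
) -> MethylomeMatrix:
    """Drop loci constitutively hyper- (>hyper_cut in all samples) or
    hypomethylated (<hypo_cut in all samples); inequalities strict."""
    pct = matrix.percent()
    observed = ~np.isnan(pct)
    any_obs = observed.any(axis=1)
    with np.errstate(invalid="ignore"):
        all_hyper = np.where(observed, pct > hyper_cut, True).all(axis=1) & any_obs
        all_hypo = np.where(observed, pct < hypo_cut, True).all(axis=1) & any_obs
    return matrix.subset_loci(~(all_hyper | all_hypo))


def _nzv_flags(
    pct_row: np.ndarray, freq_cut: float, unique_cut: float
) -> bool:
    vals = pct_row[~np.isnan(pct_row)]
    if vals.size == 0:
        return True
    vals = np.round(vals, 4)
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size == 1:
        return True  # all-constant loci removed unconditionally
    counts = np.sort(counts)[::-1]
    freq_ratio = counts[0] / counts[1]
    pct_unique = 100.0 * uniq.size / vals.size
    return bool(freq_ratio >= freq_cut and pct_unique <= unique_cut)


def remove_near_zero_variance(
    matrix: MethylomeMatrix, freq_cut: float = 19.0, unique_cut: float = 10.0
) -> MethylomeMatrix:
    """caret-style near-zero-variance filter on percent methylation.

    A locus is dropped iff the ratio of the most common to second most
    common percent value is >= ``freq_cut`` AND the percentage of distinct
    values is <= ``unique_cut``; constant loci are always dropped.  Percent
    values are compared at 4-decimal precision.
    """
    pct = matrix.percent()
    drop = np.array(
        [_nzv_flags(pct[i], freq_cut, unique_cut) for i in range(matrix.n_loci)]
    )
    return matrix.subset_loci(~drop)


def apply_filters(
    matrix: MethylomeMatrix,
    groups: Mapping[str, str],
    config: FilterConfig | None = None,
) -> tuple[MethylomeMatrix, FilterReport]:
    """Run the full filter cascade in order, recording an audit trail."""
    cfg = config or FilterConfig()
    report = FilterReport()

    n0 = matrix.n_loci
    m = drop_extreme_coverage(matrix, cfg.top_coverage_pct)
    report.record(
        "drop_extreme_coverage", n0, m.n_loci,
        cells_masked=int((matrix.cov > 0).sum() - (m.cov > 0).sum()),
    )

    n0 = m.n_loci
    m = require_min_coverage(m, groups, cfg.min_cov, cfg.min_prop_per_group)
    report.record("require_min_coverage", n0, m.n_loci)

    n0 = m.n_loci
    m = normalize_coverage(m)
    report.record("normalize_coverage", n0, m.n_loci)

    n0 = m.n_loci
    m = remove_constitutive(m, cfg.hyper_cut, cfg.hypo_cut)
    report.record("remove_constitutive", n0, m.n_loci)

    n0 = m.n_loci
    m = remove_near_zero_variance(m, cfg.freq_cut, cfg.unique_cut)
    report.record("remove_near_zero_variance", n0, m.n_loci)

    return m, report
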