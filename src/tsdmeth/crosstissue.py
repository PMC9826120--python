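"""Cross-tissue comparison of temperature-associated methylation.

Blood (hatchling) and embryonic-gonad RRBS data sets are compared on the
loci that survive filtering in *both* tissues: the per-tissue proportion of
shared loci called temperature-associated, their overlap, and the gene-
context distribution of each tissue's DMCs against the shared background.
The gonad side reuses the same filtering and differential-methylation
machinery with sex unknown, so only temperature contrasts are available
there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .annotation import enrichment_test
from .io import CpGLocus, MethylomeMatrix


def shared_loci(
    matrix_a: MethylomeMatrix, matrix_b: MethylomeMatrix
) -> list[CpGLocus]:
    """Loci covered (post-filtering) in both matrices, sorted."""
    return sorted(set(matrix_a.loci) & set(matrix_b.loci))


def dm_proportion_test(
    n_dmc_a: int, n_dmc_b: int, n_shared: int
) -> tuple[float, float]:
    """Fisher exact test comparing the DM proportion between two tissues on
    the shared-locus universe.  Returns (odds ratio tissue A vs B, p)."""
    if not (0 <= n_dmc_a <= n_shared and 0 <= n_dmc_b <= n_shared):
        raise ValueError("DMC counts must lie within the shared universe")
    table = [[n_dmc_a, n_shared - n_dmc_a], [n_dmc_b, n_shared - n_dmc_b]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


@dataclass
class SharedLocusReport:
    """Summary of the blood-vs-gonad shared-locus comparison."""

    n_shared: int
    dmc_counts: dict[str, int]
    overlap: list[CpGLocus]
    proportion_odds: float
    proportion_p: float
    context_tables: dict[str, pd.DataFrame]
    direction_consistent: int | None = None  # reported, not tested


def context_distribution_compare(
    dmc_contexts: Mapping[str, Sequence[str]],
    shared_contexts: Mapping[CpGLocus, str] | Sequence[str],
    dmc_loci: Mapping[str, Sequence[CpGLocus]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-tissue Fisher enrichment of DMC gene contexts vs the shared set.

    For each tissue, builds category counts for that tissue's DMCs and for
    the shared background *excluding those DMCs*, then runs the per-category
    Fisher + BH machinery.
    """
    if isinstance(shared_contexts, Mapping):
        shared_items = list(shared_contexts.items())
    else:
        shared_items = [(None, c) for c in shared_contexts]

    out: dict[str, pd.DataFrame] = {}
    for tissue, contexts in dmc_contexts.items():
        dmc_counts: dict[str, int] = {}
        for c in contexts:
            dmc_counts[c] = dmc_counts.get(c, 0) + 1
        excluded = set()
        if dmc_loci is not None and isinstance(shared_contexts, Mapping):
            excluded = set(dmc_loci.get(tissue, ()))
        bg_counts: dict[str, int] = {}
        for loc, c in shared_items:
            if loc is not None and loc in excluded:
                continue
            bg_counts[c] = bg_counts.get(c, 0) + 1
        if dmc_loci is None or not isinstance(shared_contexts, Mapping):
            # background passed as plain context list: subtract DMC counts
            for c, k in dmc_counts.items():
                bg_counts[c] = max(bg_counts.get(c, 0) - k, 0)
        out[tissue] = enrichment_test(dmc_counts, bg_counts)
    return out


def compare_tissues(
    matrix_blood: MethylomeMatrix,
    matrix_gonad: MethylomeMatrix,
    temp_dmcs_blood: Sequence[CpGLocus],
    temp_dmcs_gonad: Sequence[CpGLocus],
    contexts: Mapping[CpGLocus, str] | None = None,
) -> SharedLocusReport:
    """Full shared-locus comparison between blood and gonad.

    DMC lists are each tissue's temperature-associated calls; only those on
    the shared-locus universe enter the comparison.  ``contexts`` optionally
    maps shared loci to gene contexts for the distribution comparison.
    """
    shared = shared_loci(matrix_blood, matrix_gonad)
    shared_set = set(shared)
    blood = sorted(set(temp_dmcs_blood) & shared_set)
    gonad = sorted(set(temp_dmcs_gonad) & shared_set)
    overlap = sorted(set(blood) & set(gonad))
    n = len(shared)
    odds, p = dm_proportion_test(len(blood), len(gonad), n)

    tables: dict[str, pd.DataFrame] = {}
    if contexts is not None:
        ctx_shared = {loc: contexts[loc] for loc in shared if loc in contexts}
        tables = context_distribution_compare(
            {
                "blood": [ctx_shared[l] for l in blood if l in ctx_shared],
                "gonad": [ctx_shared[l] for l in gonad if l in ctx_shared],
            },
            ctx_shared,
            dmc_loci={"blood": blood, "gonad": gonad},
        )
    return SharedLocusReport(
        n_shared=n,
        dmc_counts={"blood": len(blood), "gonad": len(gonad)},
        overlap=overlap,
        proportion_odds=odds,
        proportion_p=p,
        context_tables=tables,
    )
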