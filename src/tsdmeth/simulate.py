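"""Synthetic RRBS study generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage is testable without sequencing data:

* a genome of scaffolds with background base composition, CG-rich tracts at
  recorded CpG-island positions, gene models with promoters/exons/introns,
  and hormone-response-element consensus sequences planted at known sites;
* a 4-temperature x 2-sex x multi-clutch hatchling design (default: eight
  females at 30 C, eight males at 33.5 C, four females and four males at
  34.5 C, spread over five clutches);
* per-locus baseline methylation from a bimodal (hypo / intermediate /
  hyper) mixture; negative-binomial read coverage (mean 30x); methylated
  counts from a beta-binomial with intra-locus correlation rho and
  clutch-level random effects on the logit scale;
* planted sex- and temperature-associated effects on the logit scale, with
  a configurable fraction of the sex effects expressed only at the highest
  temperature (mirroring the observed 34.5 C-specific sexual dimorphism);
* lognormal plasma hormone levels with a subtle female E2 offset.

Every draw flows from a single seed; the returned truth table records the
planted class and effect of every locus for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .io import CpGLocus, MethylationCall, MethylomeMatrix, SampleRecord

# Table-style design: (temperature, sex, clutch, n_samples)
DEFAULT_DESIGN: tuple[tuple[float, str, str, int], ...] = (
    (30.0, "F", "AP-03", 2), (30.0, "F", "AP-04", 2), (30.0, "F", "AP-05", 1),
    (30.0, "F", "AP-06", 1), (30.0, "F", "AP-08", 2),
    (33.5, "M", "AP-03", 2), (33.5, "M", "AP-04", 2), (33.5, "M", "AP-05", 1),
    (33.5, "M", "AP-06", 1), (33.5, "M", "AP-08", 2),
    (34.5, "F", "AP-03", 2), (34.5, "F", "AP-04", 1), (34.5, "F", "AP-06", 1),
    (34.5, "M", "AP-03", 2), (34.5, "M", "AP-04", 1), (34.5, "M", "AP-06", 1),
)

# Embryonic-gonad design: four temperatures spanning the thermosensitive
# range, sex undetermined at sampling (temperature contrasts only).
GONAD_DESIGN: tuple[tuple[float, str, str, int], ...] = (
    (29.0, "unknown", "WL-01", 3), (29.0, "unknown", "WL-02", 2),
    (32.0, "unknown", "WL-01", 3), (32.0, "unknown", "WL-03", 3),
    (33.5, "unknown", "WL-02", 3), (33.5, "unknown", "WL-04", 3),
    (34.5, "unknown", "WL-03", 3), (34.5, "unknown", "WL-04", 2),
)


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_scaffolds: int = 2
    scaffold_length: int = 50_000
    gc_content: float = 0.42
    cgi_fraction: float = 0.02  # fraction of genome inside CG-rich tracts
    cgi_tract_length: int = 300
    n_genes_per_scaffold: int = 6
    gene_length: int = 3000
    # methylome
    n_loci: int = 5000
    tissue: str = "blood"
    design: tuple[tuple[float, str, str, int], ...] = DEFAULT_DESIGN
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0  # negative-binomial size parameter
    baseline_weights: tuple[float, float, float] = (0.35, 0.25, 0.40)
    beta_binomial_rho: float = 0.02
    frac_sex_dmc: float = 0.01
    frac_temp_dmc: float = 0.01
    frac_sex_conditional: float = 0.5  # sex effects expressed only at 34.5 C
    sex_effect_logit: float = 2.0
    temp_slope_logit_per_degc: float = 0.4
    clutch_sd_logit: float = 0.3
    # hormones (lognormal, natural-log scale)
    e2_meanlog: float = 5.5
    e2_sdlog: float = 0.4
    e2_female_offset: float = 0.25
    t_meanlog: float = 5.0
    t_sdlog: float = 0.5
    t_male_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.beta_binomial_rho < 1):
            raise ValueError("beta_binomial_rho must be in [0, 1)")
        for frac in (self.frac_sex_dmc, self.frac_temp_dmc, self.cgi_fraction,
                     self.frac_sex_conditional):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must be in [0, 1]")
        if abs(sum(self.baseline_weights) - 1.0) > 1e-9:
            raise ValueError("baseline mixture weights must sum to 1")


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    cgi_truth: dict[str, list[tuple[int, int]]]
    motif_positions: list[tuple[str, int, str]]  # (scaffold, start, motif_id)


def synthetic_ere_consensus() -> str:
    """Palindromic oestrogen-response-element-like consensus (synthetic)."""
    return "GGTCACGATGACC"


def synthetic_are_consensus() -> str:
    """Androgen-response-element-like hexamer repeat consensus (synthetic)."""
    return "GGTACATTTTGTTCT"


def synthetic_pwm_counts(consensus: str, depth: int = 100, off: int = 4) -> np.ndarray:
    """A (width, 4) count matrix concentrated on a consensus (synthetic
    stand-in for a curated motif; not derived from any database entry)."""
    base_idx = {b: i for i, b in enumerate("ACGT")}
    w = len(consensus)
    counts = np.full((w, 4), off, dtype=float)
    for i, b in enumerate(consensus):
        counts[i, base_idx[b]] = depth
    return counts


def _random_seq(
    rng: np.random.Generator, length: int, gc: float, cpg_depletion: float = 0.2
) -> np.ndarray:
    """Background sequence with vertebrate-style CpG depletion.

    First-order Markov chain: base composition set by ``gc``, but after a C
    the probability of G is multiplied by ``cpg_depletion`` (renormalized),
    emulating the genome-wide CpG deficit (observed/expected ~0.2) outside
    CpG islands.
    """
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    after_c = base.copy()
    after_c[2] *= cpg_depletion
    after_c /= after_c.sum()
    cum_base = np.cumsum(base)
    cum_after_c = np.cumsum(after_c)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    prev_is_c = False
    for i in range(length):
        cum = cum_after_c if prev_is_c else cum_base
        b = int(np.searchsorted(cum, u[i], side="right"))
        out[i] = b
        prev_is_c = b == 1
    return np.frombuffer(b"ACGT", dtype=np.uint8)[out]


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate scaffolds with CGI tracts, gene models and planted motifs."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    sequences: dict[str, str] = {}
    cgi_truth: dict[str, list[tuple[int, int]]] = {}
    genes: list[GeneModel] = []
    motif_positions: list[tuple[str, int, str]] = []

    gene_footprint = config.n_genes_per_scaffold * (config.gene_length + 2000)
    if gene_footprint > config.scaffold_length:
        raise ValueError(
            f"genes ({gene_footprint} bp) exceed scaffold length "
            f"{config.scaffold_length}"
        )

    for s in range(config.n_scaffolds):
        name = f"scaf{s + 1:02d}"
        L = config.scaffold_length
        arr = _random_seq(rng, L, config.gc_content)

        # CG-rich island tracts at recorded positions
        n_tracts = int(round(config.cgi_fraction * L / config.cgi_tract_length))
        tracts: list[tuple[int, int]] = []
        for _ in range(n_tracts):
            for _attempt in range(100):
                start = int(rng.integers(0, L - config.cgi_tract_length))
                end = start + config.cgi_tract_length
                if all(e + 500 < start or end + 500 < b for b, e in tracts):
                    break
            tract = np.tile(np.frombuffer(b"CG", dtype=np.uint8),
                            config.cgi_tract_length // 2)
            jitter = rng.random(tract.size) < 0.10
            tract = np.where(jitter, _random_seq(rng, tract.size, 0.6), tract)
            arr[start:end] = tract
            tracts.append((start, end))
        cgi_truth[name] = sorted(tracts)

        # non-overlapping genes on an even grid
        pitch = L // max(config.n_genes_per_scaffold, 1)
        for g in range(config.n_genes_per_scaffold):
            tx_start = g * pitch + 1500
            tx_end = tx_start + config.gene_length
            if tx_end >= L:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exon_len = config.gene_length // 6
            exons = [
                (tx_start, tx_start + exon_len),
                (tx_start + 2 * exon_len, tx_start + 3 * exon_len),
                (tx_end - exon_len, tx_end),
            ]
            genes.append(
                GeneModel(f"{name}_g{g + 1}", name, strand, tx_start, tx_end, exons)
            )

        # plant hormone-response-element consensus sequences between genes
        for motif_id, consensus in (
            ("ERE_synth", synthetic_ere_consensus()),
            ("ARE_synth", synthetic_are_consensus()),
        ):
            for _ in range(3):
                start = int(rng.integers(500, L - len(consensus) - 500))
                arr[start : start + len(consensus)] = np.frombuffer(
                    consensus.encode(), dtype=np.uint8
                )
                motif_positions.append((name, start, motif_id))

        sequences[name] = arr.tobytes().decode()

    return SimulatedGenome(sequences, genes, cgi_truth, motif_positions)


def _sample_records(config: SimulationConfig) -> list[SampleRecord]:
    records = []
    i = 0
    prefix = "B" if config.tissue == "blood" else "G"
    for temp, sex, clutch, n in config.design:
        for _ in range(n):
            i += 1
            records.append(
                SampleRecord(
                    sample_id=f"{prefix}{i:02d}", tissue=config.tissue, sex=sex,
                    temperature=temp, clutch=clutch,
                )
            )
    return records


def _baseline_mixture(rng: np.random.Generator, n: int,
                      weights: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Bimodal baseline methylation: hypo Beta(0.5, 10), intermediate
    Uniform(0.2, 0.8), hyper Beta(10, 0.5).  Returns (pi, component)."""
    comp = rng.choice(3, size=n, p=list(weights))
    pi = np.empty(n)
    hypo, mid, hyper = comp == 0, comp == 1, comp == 2
    pi[hypo] = rng.beta(0.5, 10.0, hypo.sum())
    pi[mid] = rng.uniform(0.2, 0.8, mid.sum())
    pi[hyper] = rng.beta(10.0, 0.5, hyper.sum())
    return np.clip(pi, 1e-4, 1 - 1e-4), comp


@dataclass
class SimulatedStudy:
    matrix: MethylomeMatrix
    metadata: list[SampleRecord]
    truth: pd.DataFrame


def simulate_methylomes(
    config: SimulationConfig,
    genome: SimulatedGenome | None = None,
) -> SimulatedStudy:
    """Simulate the locus-by-sample count matrix and its truth table.

    Model per locus i, sample j:

        logit(pi_ij) = logit(pi_i) + sex_effect_i * I(j female, effect active)
                       + temp_slope_i * (T_j - mean T) + clutch_(i, clutch_j)
        n_ij ~ NegBin(mean=coverage_mean, size=coverage_dispersion)
        m_ij | n_ij ~ BetaBinomial(n_ij, pi_ij, rho)

    Loci sit at CG positions of the supplied genome when one is given,
    otherwise on evenly spaced virtual scaffold positions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    samples = _sample_records(config)
    n_s = len(samples)
    n_l = config.n_loci

    # locus positions
    if genome is not None:
        pool: list[CpGLocus] = []
        for name, seq in genome.sequences.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
            pool.extend(CpGLocus(name, int(p)) for p in cg)
        if len(pool) < n_l:
            raise ValueError(
                f"genome has only {len(pool)} CpGs; reduce n_loci={n_l}"
            )
        pool.sort()
        idx = np.sort(rng.choice(len(pool), size=n_l, replace=False))
        loci = [pool[i] for i in idx]
    else:
        per_scaf = int(np.ceil(n_l / config.n_scaffolds))
        loci = []
        for s in range(config.n_scaffolds):
            name = f"scaf{s + 1:02d}"
            for k in range(per_scaf):
                if len(loci) >= n_l:
                    break
                loci.append(CpGLocus(name, 100 + 50 * k))

    pi0, comp = _baseline_mixture(rng, n_l, config.baseline_weights)

    # planted classes
    classes = np.array(["null"] * n_l, dtype=object)
    n_sex = int(round(config.frac_sex_dmc * n_l))
    n_temp = int(round(config.frac_temp_dmc * n_l))
    order = rng.permutation(n_l)
    sex_idx = order[:n_sex]
    temp_idx = order[n_sex : n_sex + n_temp]
    classes[sex_idx] = "sex"
    classes[temp_idx] = "temperature"

    # sex loci start hypermethylated and shift toward intermediate in one sex
    pi0[sex_idx] = np.clip(rng.beta(10.0, 0.5, n_sex), 0.80, 1 - 1e-4)
    sex_sign = rng.choice([-1.0, 1.0], size=n_l)  # -1: females shifted down
    sex_effect = np.zeros(n_l)
    sex_effect[sex_idx] = -config.sex_effect_logit  # shift away from hyper
    conditional = np.zeros(n_l, dtype=bool)
    conditional[sex_idx] = rng.random(n_sex) < config.frac_sex_conditional

    temp_effect = np.zeros(n_l)
    temp_effect[temp_idx] = (
        rng.choice([-1.0, 1.0], size=n_temp) * config.temp_slope_logit_per_degc
    )

    temps = np.array([s.temperature for s in samples])
    is_f = np.array([s.sex == "F" for s in samples])
    clutches = sorted({s.clutch for s in samples})
    clutch_col = np.array([clutches.index(s.clutch) for s in samples])
    t_centered = temps - temps.mean()

    clutch_re = rng.normal(0.0, config.clutch_sd_logit, size=(n_l, len(clutches)))

    logit0 = np.log(pi0 / (1 - pi0))
    # effect applies to females (the shifted sex is chosen by sex_sign:
    # +1 shifts females, -1 shifts males, keeping balance of directions)
    shift_female = sex_sign >= 0
    active = np.ones((n_l, n_s), dtype=bool)
    at_345 = temps == 34.5
    active[conditional] = at_345[None, :]
    sex_ind = np.where(shift_female[:, None], is_f[None, :], ~is_f[None, :])
    eta = (
        logit0[:, None]
        + sex_effect[:, None] * (sex_ind & active)
        + temp_effect[:, None] * t_centered[None, :]
        + clutch_re[:, clutch_col]
    )
    pi = 1.0 / (1.0 + np.exp(-eta))

    # coverage ~ NegBin(mean, size)
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)
    cov = rng.negative_binomial(k, p_nb, size=(n_l, n_s))

    rho = config.beta_binomial_rho
    if rho > 0:
        conc = 1.0 / rho - 1.0
        p_cell = rng.beta(np.maximum(pi * conc, 1e-8),
                          np.maximum((1 - pi) * conc, 1e-8))
    else:
        p_cell = pi
    meth = rng.binomial(cov, p_cell)

    matrix = MethylomeMatrix(loci, samples, meth, cov)
    truth = pd.DataFrame(
        {
            "scaffold": [l.scaffold for l in loci],
            "pos": [l.pos for l in loci],
            "class": classes,
            "baseline": pi0,
            "baseline_component": comp,
            "sex_effect_logit": sex_effect,
            "sex_shifted": np.where(shift_female, "F", "M"),
            "conditional_34_5": conditional,
            "temp_slope_logit": temp_effect,
        }
    )
    return SimulatedStudy(matrix=matrix, metadata=samples, truth=truth)


def simulate_hormones(
    metadata: Sequence[SampleRecord], config: SimulationConfig
) -> pd.DataFrame:
    """Lognormal plasma E2 and testosterone per sample (seeded); E2 carries a
    configurable female offset on the log scale."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    rows = []
    for s in metadata:
        female = s.sex == "F"
        e2 = rng.lognormal(
            config.e2_meanlog + (config.e2_female_offset if female else 0.0),
            config.e2_sdlog,
        )
        t = rng.lognormal(
            config.t_meanlog + (config.t_male_offset if not female else 0.0),
            config.t_sdlog,
        )
        rows.append((s.sample_id, e2, t))
        s.e2, s.testosterone = float(e2), float(t)
    return pd.DataFrame(rows, columns=["sample_id", "e2", "testosterone"])


def matrix_to_calls(matrix: MethylomeMatrix) -> dict[str, list[MethylationCall]]:
    """Explode a matrix into per-sample call lists (bismark-ready)."""
    out: dict[str, list[MethylationCall]] = {}
    for j, sid in enumerate(matrix.sample_ids):
        calls = []
        for i, loc in enumerate(matrix.loci):
            c = int(matrix.cov[i, j])
            if c == 0:
                continue
            m = int(matrix.meth[i, j])
            calls.append(MethylationCall(loc.scaffold, loc.pos, m, c - m))
        out[sid] = calls
    return out


def treatment_groups(metadata: Sequence[SampleRecord]) -> dict[str, str]:
    """sample_id -> temperature-sex treatment-group label."""
    return {
        s.sample_id: f"{s.temperature:g}{s.sex if s.sex != 'unknown' else ''}"
        for s in metadata
    }
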