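"""Position-weight-matrix scanning for hormone-response elements.

Locates putative oestrogen- and androgen-response elements (EREs / AREs)
genome-wide from JASPAR-format position frequency matrices, then relates
CpG loci to the nearest motif hit.

Scoring follows standard log-odds practice: counts are converted to
probabilities with a background-weighted pseudocount, scores are
log2(p / background), and the score threshold for a target p-value is found
from the exact score distribution under a zero-order background model,
computed by dynamic programming over scores discretized to 0.01 bits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffmeth import bh_adjust
from .io import CpGLocus

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PWM:
    """A position weight matrix with log-odds scores.

    ``probs`` has shape (width, 4) over A, C, G, T and rows summing to 1;
    ``log_odds`` is log2(probs / background).
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray
    log_odds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("probabilities must be positive (apply a pseudocount)")
        self.log_odds = np.log2(self.probs / self.background[None, :])

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


def pwm_from_counts(
    motif_id: str,
    counts: np.ndarray,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.8,
) -> PWM:
    """Build a PWM from a count matrix with a background-weighted pseudocount:
    p = (count + pseudocount * bg) / (column_total + pseudocount)."""
    counts = np.asarray(counts, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    totals = counts.sum(axis=1, keepdims=True)
    probs = (counts + pseudocount * bg[None, :]) / (totals + pseudocount)
    return PWM(motif_id, probs, bg)


def read_jaspar(path, background: Sequence[float] | None = None,
                pseudocount: float = 0.8) -> PWM:
    """Read the first motif from a JASPAR .pfm / .jaspar file.

    Format: a '>' header line, then four rows 'A [ 4 19 0 ... ]' (brackets
    optional) in A, C, G, T order.
    """
    with open(path) as fh:
        text = fh.read()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError(f"{path}: not a JASPAR matrix file")
    motif_id = lines[0][1:].split()[0]
    rows = {}
    for ln in lines[1:5]:
        m = re.match(r"^([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?$", ln)
        if not m:
            raise ValueError(f"{path}: malformed count row {ln!r}")
        rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    if set(rows) != set(BASES):
        raise ValueError(f"{path}: need rows for A, C, G, T")
    counts = np.array([rows[b] for b in BASES]).T  # (width, 4)
    return pwm_from_counts(motif_id, counts, background, pseudocount)


def pwm_threshold(pwm: PWM, p_value: float = 2e-6, precision: float = 0.01) -> float:
    """Score threshold achieving a tail probability <= p_value.

    The exact distribution of the score of a random background sequence is
    computed by dynamic programming over integer-discretized scores (bin
    width ``precision``); the threshold is the smallest achievable score s
    with P(score >= s) <= p_value.
    """
    if not (0 < p_value <= 1):
        raise ValueError("p_value must be in (0, 1]")
    scores, dist = pwm_score_distribution(pwm, precision)
    lo = np.rint(pwm.log_odds / precision).astype(np.int64).min(axis=1).sum()
    hi = np.rint(pwm.log_odds / precision).astype(np.int64).max(axis=1).sum()
    tail = np.cumsum(dist[::-1])[::-1]
    achievable = dist > 0
    idx = np.flatnonzero(achievable & (tail <= p_value))
    if idx.size == 0:
        # no achievable score is rare enough; return just above the max
        return float((hi + 1) * precision)
    if p_value >= 1.0:
        return float(lo * precision)
    return float((lo + idx[0]) * precision)


def pwm_score_distribution(pwm: PWM, precision: float = 0.01):
    """(scores, probabilities) of the exact background score distribution."""
    scaled = np.rint(pwm.log_odds / precision).astype(np.int64)
    lo = scaled.min(axis=1).sum()
    hi = scaled.max(axis=1).sum()
    size = int(hi - lo + 1)
    dist = np.zeros(size)
    dist[0] = 1.0
    for i in range(pwm.width):
        row = scaled[i]
        rlo = int(row.min())
        new = np.zeros(size)
        for b in range(4):
            shift = int(row[b] - rlo)
            upto = size - shift
            new[shift:] += pwm.background[b] * dist[:upto]
        dist = new
    scores = (lo + np.arange(size)) * precision
    return scores, dist


@dataclass
class MotifHit:
    scaffold: str
    start: int  # 0-based plus-strand start of the motif window
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.size, 4, dtype=np.int8)
    for i, b in enumerate(BASES):
        code[arr == ord(b)] = i
    return code


def _scan_strand(code: np.ndarray, log_odds: np.ndarray, threshold: float) -> np.ndarray:
    w = log_odds.shape[0]
    L = code.size
    if L < w:
        return np.empty((0, 2))
    n_win = L - w + 1
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for k in range(w):
        col = code[k : k + n_win]
        valid &= col < 4
        safe = np.where(col < 4, col, 0)
        scores += log_odds[k, safe]
    hits = np.flatnonzero(valid & (scores >= threshold))
    return np.column_stack([hits, scores[hits]])


def scan_pwm(
    sequences: Mapping[str, str], pwm: PWM, threshold: float
) -> list[MotifHit]:
    """Scan both strands of every scaffold; report hits in plus-strand
    coordinates.  Windows containing N are skipped."""
    hits: list[MotifHit] = []
    w = pwm.width
    for name, seq in sequences.items():
        code = _encode(seq)
        for start, score in _scan_strand(code, pwm.log_odds, threshold):
            hits.append(MotifHit(name, int(start), "+", float(score)))
        rc = _encode(revcomp(seq))
        L = len(seq)
        for start, score in _scan_strand(rc, pwm.log_odds, threshold):
            hits.append(MotifHit(name, int(L - w - start), "-", float(score)))
    hits.sort(key=lambda h: (h.scaffold, h.start, h.strand))
    return hits


def write_hits_bed(hits: Sequence[MotifHit], width: int, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.scaffold}\t{h.start}\t{h.start + width}\t{h.scaffold}:{h.start}\t{h.score:.3f}\t{h.strand}\n")


def distance_to_nearest_hit(
    loci: Sequence[CpGLocus], hits: Sequence[MotifHit], width: int
) -> np.ndarray:
    """Minimal bp gap from each locus to any motif window (0 if inside;
    +inf on scaffolds without hits)."""
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold, []).append((h.start, h.start + width))
    starts_ends = {
        k: (np.array(sorted(s for s, _ in v)), np.array(sorted(e for _, e in v)))
        for k, v in by_scaffold.items()
    }
    out = np.full(len(loci), np.inf)
    for i, loc in enumerate(loci):
        if loc.scaffold not in by_scaffold:
            continue
        best = np.inf
        for s, e in by_scaffold[loc.scaffold]:
            if s <= loc.pos < e:
                best = 0
                break
            gap = s - loc.pos if loc.pos < s else loc.pos - e
            best = min(best, gap)
        out[i] = best
    return out


def motif_proximity(
    distances: np.ndarray, cutoffs: Sequence[int] = (1000, 2500, 5000)
) -> dict[int, float]:
    """Proportion of loci within each distance cutoff of a motif hit."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return {int(c): 0.0 for c in cutoffs}
    return {int(c): float((d <= c).mean()) for c in cutoffs}


def proximity_enrichment(
    dmc_distances: np.ndarray,
    background_distances: np.ndarray,
    cutoffs: Sequence[int] = (1000, 2500, 5000),
) -> pd.DataFrame:
    """Fisher tests of DMC vs background proportions within each cutoff,
    BH-adjusted across cutoffs."""
    from scipy import stats as _st

    rows = []
    d = np.asarray(dmc_distances, float)
    b = np.asarray(background_distances, float)
    for c in cutoffs:
        a_in = int((d <= c).sum())
        a_out = d.size - a_in
        b_in = int((b <= c).sum())
        b_out = b.size - b_in
        if min(a_in + a_out, b_in + b_out) == 0:
            rows.append((c, np.nan, np.nan, 1.0))
            continue
        odds, p = _st.fisher_exact([[a_in, a_out], [b_in, b_out]])
        rows.append((c, a_in / max(d.size, 1), odds, p))
    df = pd.DataFrame(rows, columns=["cutoff", "dmc_proportion", "odds_ratio", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
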