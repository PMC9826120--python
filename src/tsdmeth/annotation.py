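"""Genomic context annotation for CpG loci.

Covers four complementary annotation layers and the enrichment machinery
that compares a DMC set against the covered-CpG background:

* gene context (promoter > exon > intron > intergenic, with precedence) and
  nearest gene;
* predicted CpG islands (Gardiner-Garden & Frommer-style sliding-window
  rule: GC >= 50%, observed/expected CpG >= 0.6 over 100-bp windows, merged
  runs >= 200 bp) plus the derived shores (+-2 kb of islands), shelves
  (+-2 kb of shores) and open sea;
* CpG density of non-overlapping 1-kb tiles, binned at 20 CpG/kb;
* mean-methylation bins (five 20-percentage-point bins, right-closed).

Intervals are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust
from .io import CpGLocus

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GeneModel:
    """A gene with transcript span and exon structure (0-based half-open)."""

    gene_id: str
    scaffold: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: bad transcript span")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end or s >= e:
                raise ValueError(f"gene {self.gene_id}: exon outside transcript")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    def promoter(self, upstream: int = 1000, downstream: int = 200) -> Interval:
        """Strand-aware promoter window around the TSS (clipped at 0)."""
        if self.strand == "+":
            return (max(self.tx_start - upstream, 0), self.tx_start + downstream)
        return (max(self.tx_end - downstream, 0), self.tx_end + upstream)


def read_gene_table(path, sep: str = "\t") -> list[GeneModel]:
    """Read a gene table TSV: gene_id, scaffold, strand, tx_start, tx_end,
    exons (semicolon-separated start-end pairs)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    genes = []
    for _, row in df.iterrows():
        exons = []
        if isinstance(row.get("exons"), str) and row["exons"]:
            for part in row["exons"].split(";"):
                s, e = part.split("-")
                exons.append((int(s), int(e)))
        genes.append(
            GeneModel(
                gene_id=row["gene_id"],
                scaffold=row["scaffold"],
                strand=row["strand"],
                tx_start=int(row["tx_start"]),
                tx_end=int(row["tx_end"]),
                exons=exons,
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "scaffold": [g.scaffold for g in genes],
            "strand": [g.strand for g in genes],
            "tx_start": [g.tx_start for g in genes],
            "tx_end": [g.tx_end for g in genes],
            "exons": [";".join(f"{s}-{e}" for s, e in g.exons) for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def gene_context(
    locus: CpGLocus,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 1000,
    promoter_downstream: int = 200,
) -> str:
    """Classify a locus as promoter / exon / intron / intergenic.

    When a locus overlaps several features the highest-precedence class wins:
    promoter > exon > intron > intergenic.  Interval ends are exclusive, so a
    locus exactly at an exon's half-open end falls in the intron.
    """
    hit_exon = hit_intron = False
    for g in genes:
        if g.scaffold != locus.scaffold:
            continue
        ps, pe = g.promoter(promoter_upstream, promoter_downstream)
        if ps <= locus.pos < pe:
            return "promoter"
        if g.tx_start <= locus.pos < g.tx_end:
            if any(s <= locus.pos < e for s, e in g.exons):
                hit_exon = True
            else:
                hit_intron = True
    if hit_exon:
        return "exon"
    if hit_intron:
        return "intron"
    return "intergenic"


def nearest_gene(
    locus: CpGLocus, genes: Sequence[GeneModel]
) -> tuple[str, int] | None:
    """Closest gene on the locus's scaffold and the bp gap to its span.

    Distance is 0 inside the transcript span.  Ties break toward the lower
    transcript start, then the lexicographically smaller gene id.  Returns
    None when the scaffold carries no gene.
    """
    best: tuple[int, int, str] | None = None
    for g in genes:
        if g.scaffold != locus.scaffold:
            continue
        if g.tx_start <= locus.pos < g.tx_end:
            d = 0
        elif locus.pos < g.tx_start:
            d = g.tx_start - locus.pos
        else:
            # half-open span: gap measured from tx_end
            d = locus.pos - g.tx_end
        key = (d, g.tx_start, g.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    d, _, gid = best
    return gid, d


# ---------------------------------------------------------------------------
# CpG islands, shores, shelves


def find_cgis(
    sequence: str,
    window: int = 100,
    minlen: int = 200,
    min_oe: float = 0.6,
    min_gc: float = 50.0,
) -> list[Interval]:
    """Predict CpG islands with a sliding-window rule.

    A 100-bp window starting at each position is scored by GC percentage and
    by the observed/expected CpG ratio  (N_CG * len) / (N_C * N_G), taken as
    0 when the window has no C or no G.  Every base covered by at least one
    window passing both thresholds is island-flagged; maximal flagged runs of
    at least ``minlen`` bp are reported.  'N' bases count as neither C nor G
    and break CG dinucleotides.
    """
    seq = sequence.upper()
    L = len(seq)
    if L < window:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    if L > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    csum_c = np.concatenate([[0], np.cumsum(is_c)])
    csum_g = np.concatenate([[0], np.cumsum(is_g)])
    csum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(L - window + 1)
    n_c = csum_c[starts + window] - csum_c[starts]
    n_g = csum_g[starts + window] - csum_g[starts]
    # CG dinucleotides fully inside the window: C at start .. start+window-2
    n_cg = csum_cg[starts + window - 1] - csum_cg[starts]

    gc_ok = 100.0 * (n_c + n_g) / window >= min_gc
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(n_c * n_g > 0, n_cg * window / np.maximum(n_c * n_g, 1), 0.0)
    good = gc_ok & (oe >= min_oe)

    # positions covered by any good window, via a difference array
    cover = np.zeros(L + 1, dtype=np.int64)
    gs = starts[good]
    np.add.at(cover, gs, 1)
    np.add.at(cover, gs + window, -1)
    flagged = np.cumsum(cover[:-1]) > 0

    islands: list[Interval] = []
    i = 0
    while i < L:
        if flagged[i]:
            j = i
            while j < L and flagged[j]:
                j += 1
            if j - i >= minlen:
                islands.append((i, j))
            i = j
        else:
            i += 1
    return islands


def _merge_intervals(ivs: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _expand_clip(ivs: Sequence[Interval], pad: int, length: int) -> list[Interval]:
    return _merge_intervals([(max(s - pad, 0), min(e + pad, length)) for s, e in ivs])


def _subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Interval-set difference a \\ b (both sorted, merged)."""
    out: list[Interval] = []
    bi = 0
    b = list(b)
    for s, e in a:
        cur = s
        while bi < len(b) and b[bi][1] <= cur:
            bi += 1
        k = bi
        while cur < e:
            if k < len(b) and b[k][0] < e:
                bs, be = b[k]
                if bs > cur:
                    out.append((cur, bs))
                cur = max(cur, be)
                k += 1
            else:
                out.append((cur, e))
                cur = e
    return out


@dataclass
class CGIAnnotation:
    """Island / shore / shelf / open-sea partition of each scaffold."""

    scaffold_lengths: dict[str, int]
    islands: dict[str, list[Interval]]
    shores: dict[str, list[Interval]]
    shelves: dict[str, list[Interval]]
    open_sea: dict[str, list[Interval]]

    def context(self, locus: CpGLocus) -> str:
        """Class of a position, precedence island > shore > shelf > open_sea."""
        if locus.scaffold not in self.scaffold_lengths:
            raise KeyError(f"scaffold {locus.scaffold!r} not annotated")
        for name in ("islands", "shores", "shelves"):
            for s, e in getattr(self, name)[locus.scaffold]:
                if s <= locus.pos < e:
                    return {"islands": "island", "shores": "shore", "shelves": "shelf"}[name]
        return "open_sea"


def annotate_cgi_classes(
    sequences: Mapping[str, str],
    window: int = 100,
    minlen: int = 200,
    min_oe: float = 0.6,
    min_gc: float = 50.0,
    flank: int = 2000,
) -> CGIAnnotation:
    """Predict islands per scaffold and derive shores, shelves and open sea.

    Shores are the +-2-kb flanks of islands minus the islands; shelves the
    +-2-kb flanks of shores minus shores and islands; everything else is
    open sea.  Flanks are clipped at scaffold edges; islands closer than the
    flank width share merged shores/shelves.  The four classes partition
    every scaffold.
    """
    lengths = {k: len(v) for k, v in sequences.items()}
    islands, shores, shelves, open_sea = {}, {}, {}, {}
    for name, seq in sequences.items():
        L = lengths[name]
        isl = _merge_intervals(find_cgis(seq, window, minlen, min_oe, min_gc))
        sho_full = _expand_clip(isl, flank, L)
        she_full = _expand_clip(isl, 2 * flank, L)
        sho = _subtract(sho_full, isl)
        she = _subtract(she_full, sho_full)
        rest = _subtract([(0, L)], she_full)
        islands[name], shores[name], shelves[name], open_sea[name] = isl, sho, she, rest
    return CGIAnnotation(lengths, islands, shores, shelves, open_sea)


# ---------------------------------------------------------------------------
# density tiles and methylation bins


@dataclass
class DensityTile:
    scaffold: str
    start: int
    end: int
    cpg_count: int

    @property
    def density_bin(self) -> int:
        return self.cpg_count // 20


def tile_cpg_density(
    sequences: Mapping[str, str], tile_size: int = 1000
) -> list[DensityTile]:
    """Tile each scaffold into non-overlapping 1-kb windows and count the CG
    dinucleotide start positions falling in each tile (final partial tiles
    included, so tile counts sum to the genome CG total)."""
    tiles = []
    for name, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        L = arr.size
        cg_starts = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        for start in range(0, L, tile_size):
            end = min(start + tile_size, L)
            count = int(((cg_starts >= start) & (cg_starts < end)).sum())
            tiles.append(DensityTile(name, start, end, count))
    return tiles


MEAN_METH_BINS = ("0-20", "20-40", "40-60", "60-80", "80-100")


def mean_meth_bin(percent: np.ndarray) -> np.ndarray:
    """Assign each locus to a five-way mean-methylation bin.

    The mean is over non-missing samples; bins are right-closed with 0
    included in the first bin (a mean of exactly 20 falls in '0-20').
    All-missing loci get None and should be excluded by the caller.
    """
    X = np.asarray(percent, dtype=float)
    out = np.full(X.shape[0], None, dtype=object)
    observed = ~np.isnan(X)
    ok = observed.any(axis=1)
    means = np.full(X.shape[0], np.nan)
    means[ok] = np.nanmean(X[ok], axis=1)
    idx = np.clip(np.ceil(np.nan_to_num(means) / 20.0).astype(np.int64) - 1, 0, 4)
    for i in np.flatnonzero(ok):
        out[i] = MEAN_METH_BINS[idx[i]]
    return out


# ---------------------------------------------------------------------------
# enrichment


def enrichment_test(
    dmc_counts: Mapping[str, int], background_counts: Mapping[str, int]
) -> pd.DataFrame:
    """Per-category Fisher exact enrichment of a DMC set vs background.

    The background must already exclude the DMCs under test.  Each category
    yields the 2x2 table [[dmc_in, dmc_out], [bg_in, bg_out]], a two-sided
    Fisher exact p, the odds ratio, and BH-adjusted q across categories.
    Zero-margin tables give p = 1 and an undefined (NaN) odds ratio.
    """
    cats = sorted(set(dmc_counts) | set(background_counts))
    n_dmc = sum(dmc_counts.values())
    n_bg = sum(background_counts.values())
    rows = []
    for cat in cats:
        a = dmc_counts.get(cat, 0)
        b = n_dmc - a
        c = background_counts.get(cat, 0)
        d = n_bg - c
        if min(a + b, c + d, a + c, b + d) == 0:
            rows.append((cat, a, c, np.nan, 1.0))
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((cat, a, c, odds, p))
    df = pd.DataFrame(rows, columns=["category", "dmc_in", "background_in", "odds_ratio", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def annotate_loci(
    loci: Sequence[CpGLocus],
    genes: Sequence[GeneModel] | None = None,
    cgi: CGIAnnotation | None = None,
    tiles: Sequence[DensityTile] | None = None,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 200,
) -> pd.DataFrame:
    """Tabulate every annotation layer for a list of loci."""
    rows: dict[str, list] = {"scaffold": [], "pos": []}
    tile_lookup: dict[str, list[DensityTile]] = {}
    if tiles is not None:
        for t in tiles:
            tile_lookup.setdefault(t.scaffold, []).append(t)
    for loc in loci:
        rows["scaffold"].append(loc.scaffold)
        rows["pos"].append(loc.pos)
        if genes is not None:
            rows.setdefault("gene_context", []).append(
                gene_context(loc, genes, promoter_upstream, promoter_downstream)
            )
            ng = nearest_gene(loc, genes)
            rows.setdefault("nearest_gene", []).append(ng[0] if ng else None)
            rows.setdefault("nearest_gene_distance", []).append(ng[1] if ng else None)
        if cgi is not None:
            rows.setdefault("cgi_context", []).append(cgi.context(loc))
        if tiles is not None:
            binval = None
            for t in tile_lookup.get(loc.scaffold, []):
                if t.start <= loc.pos < t.end:
                    binval = t.density_bin
                    break
            rows.setdefault("density_bin", []).append(binval)
    return pd.DataFrame(rows)
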