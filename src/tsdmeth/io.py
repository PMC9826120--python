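"""Reading, validation and assembly of per-sample CpG methylation calls.

The pipeline consumes bismark-style coverage files (one per sample), a
sample-metadata table, and optionally a reference FASTA used to merge
methylation calls from the two strands of each CpG dinucleotide.

All internal coordinates are 0-based, half-open.  Bismark coverage files
are 1-based inclusive; the conversion happens in :func:`read_bismark_coverage`
and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class CpGLocus(NamedTuple):
    """A CpG site addressed by the position of its plus-strand cytosine."""

    scaffold: str
    pos: int  # 0-based position of the C of the plus-strand CG


@dataclass(frozen=True)
class MethylationCall:
    """Methylated/unmethylated read counts at one CpG in one sample."""

    scaffold: str
    pos: int
    meth: int
    unmeth: int

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth

    @property
    def locus(self) -> CpGLocus:
        return CpGLocus(self.scaffold, self.pos)

    @property
    def percent(self) -> float:
        if self.coverage == 0:
            return float("nan")
        return 100.0 * self.meth / self.coverage


VALID_TISSUES = {"blood", "gonad"}
VALID_SEXES = {"F", "M", "unknown"}


@dataclass
class SampleRecord:
    """One sequenced individual and its experimental covariates."""

    sample_id: str
    tissue: str
    sex: str
    temperature: float
    clutch: str
    e2: float = float("nan")
    testosterone: float = float("nan")
    role: str = "unassigned"

    def __post_init__(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r} for sample {self.sample_id}")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for sample {self.sample_id}")
        if self.sex == "unknown" and self.tissue != "gonad":
            raise ValueError(
                f"sample {self.sample_id}: sex may be 'unknown' only for gonad samples"
            )
        if not (25.0 <= float(self.temperature) <= 40.0):
            raise ValueError(
                f"sample {self.sample_id}: temperature {self.temperature} outside [25, 40] degC"
            )
        if not self.clutch:
            raise ValueError(f"sample {self.sample_id}: clutch must be non-empty")


class BismarkParseError(ValueError):
    pass


def read_bismark_coverage(path: str | Path) -> list[MethylationCall]:
    """Parse a bismark coverage file into methylation calls.

    Expected columns (tab-separated): chrom, start (1-based), end, percent
    methylation, count methylated, count unmethylated.  The percent column is
    recomputed from the counts; discrepancies above 0.5 percentage points are
    reported as warnings but the call is retained with the counts as truth.
    """
    calls: list[MethylationCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise BismarkParseError(
                    f"{path}: line {lineno}: expected >=6 tab-separated fields, got {len(parts)}"
                )
            try:
                start = int(parts[1])
                pct = float(parts[3])
                meth = int(parts[4])
                unmeth = int(parts[5])
            except ValueError as exc:
                raise BismarkParseError(f"{path}: line {lineno}: {exc}") from exc
            if meth < 0 or unmeth < 0:
                raise BismarkParseError(f"{path}: line {lineno}: negative counts")
            cov = meth + unmeth
            if cov > 0:
                recomputed = 100.0 * meth / cov
                if abs(recomputed - pct) > 0.5:
                    warnings.warn(
                        f"{path}: line {lineno}: percent column {pct} disagrees with "
                        f"counts ({recomputed:.2f}); counts take precedence",
                        stacklevel=2,
                    )
            calls.append(MethylationCall(parts[0], start - 1, meth, unmeth))
    return calls


def cpg_index_from_fasta(path_or_records) -> dict[str, np.ndarray]:
    """Positions (0-based, plus-strand C) of every CG dinucleotide per scaffold."""
    if isinstance(path_or_records, (str, Path)):
        records = SeqIO.parse(str(path_or_records), "fasta")
        seqs = {rec.id: str(rec.seq).upper() for rec in records}
    else:
        seqs = {k: str(v).upper() for k, v in dict(path_or_records).items()}
    index: dict[str, np.ndarray] = {}
    for name, seq in seqs.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        index[name] = np.flatnonzero(is_cg)
    return index


def merge_strands(
    calls: Sequence[MethylationCall],
    cpg_index: Mapping[str, np.ndarray] | None = None,
) -> list[MethylationCall]:
    """Collapse the two strands of each CpG onto the plus-strand C position.

    A call on the minus-strand C of a CpG sits at plus-strand position ``p+1``
    of the plus-strand C at ``p``; its counts are added to the plus-strand
    call.  With a reference CpG index, positions are assigned strands exactly;
    calls at positions matching neither strand of a reference CpG are dropped
    with a warning.  Without a reference, calls at adjacent positions
    ``(p, p+1)`` are heuristically paired left-to-right.
    """
    merged: dict[CpGLocus, list[int]] = {}
    dropped = 0
    if cpg_index is not None:
        plus_sets = {k: set(v.tolist()) for k, v in cpg_index.items()}
        for c in calls:
            plus = plus_sets.get(c.scaffold, set())
            if c.pos in plus:
                key = CpGLocus(c.scaffold, c.pos)
            elif c.pos - 1 in plus:
                key = CpGLocus(c.scaffold, c.pos - 1)
            else:
                dropped += 1
                continue
            acc = merged.setdefault(key, [0, 0])
            acc[0] += c.meth
            acc[1] += c.unmeth
        if dropped:
            warnings.warn(
                f"merge_strands: dropped {dropped} calls not matching a reference CpG",
                stacklevel=2,
            )
    else:
        by_locus: dict[CpGLocus, list[int]] = {}
        for c in calls:
            acc = by_locus.setdefault(c.locus, [0, 0])
            acc[0] += c.meth
            acc[1] += c.unmeth
        taken: set[CpGLocus] = set()
        for locus in sorted(by_locus):
            if locus in taken:
                continue
            m, u = by_locus[locus]
            partner = CpGLocus(locus.scaffold, locus.pos + 1)
            if partner in by_locus and partner not in taken:
                m += by_locus[partner][0]
                u += by_locus[partner][1]
                taken.add(partner)
            taken.add(locus)
            merged[locus] = [m, u]
    return [
        MethylationCall(loc.scaffold, loc.pos, m, u)
        for loc, (m, u) in sorted(merged.items())
    ]


@dataclass
class MethylomeMatrix:
    """Loci x samples matrix of (methylated, coverage) read-count pairs.

    Missing cells are encoded as coverage 0.  ``percent()`` returns NaN there.
    """

    loci: list[CpGLocus]
    samples: list[SampleRecord]
    meth: np.ndarray  # int array, shape (n_loci, n_samples)
    cov: np.ndarray  # int array, same shape; 0 encodes missing

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.cov = np.asarray(self.cov, dtype=np.int64)
        if self.meth.shape != self.cov.shape:
            raise ValueError("meth and cov shapes differ")
        if self.meth.shape != (len(self.loci), len(self.samples)):
            raise ValueError("count shapes do not match loci/samples")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate loci in matrix")
        if np.any(self.meth < 0) or np.any(self.meth > self.cov):
            raise ValueError("require 0 <= meth <= coverage per cell")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def percent(self) -> np.ndarray:
        """Percent methylation per cell; NaN where coverage is 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 100.0 * self.meth / self.cov
        return np.where(self.cov > 0, out, np.nan)

    def subset_loci(self, keep: np.ndarray) -> "MethylomeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return MethylomeMatrix(
            [self.loci[i] for i in idx], self.samples, self.meth[idx], self.cov[idx]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylomeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return MethylomeMatrix(
            list(self.loci),
            [self.samples[i] for i in idx],
            self.meth[:, idx],
            self.cov[:, idx],
        )

    def copy(self) -> "MethylomeMatrix":
        return MethylomeMatrix(
            list(self.loci), list(self.samples), self.meth.copy(), self.cov.copy()
        )


def build_matrix(
    per_sample_calls: Mapping[str, Sequence[MethylationCall]],
    metadata: Sequence[SampleRecord],
    locus_policy: str = "union",
) -> MethylomeMatrix:
    """Assemble per-sample calls into a :class:`MethylomeMatrix`.

    Loci are ordered by scaffold (lexicographic) then position.  Under the
    ``union`` policy, loci absent from a sample are left missing; under
    ``intersection`` only loci present in every sample are kept.
    """
    meta_by_id = {s.sample_id: s for s in metadata}
    for sid in per_sample_calls:
        if sid not in meta_by_id:
            raise ValueError(f"sample {sid!r} has calls but no metadata record")
    samples = [meta_by_id[sid] for sid in per_sample_calls]

    locus_sets = []
    for sid, calls in per_sample_calls.items():
        loci = [c.locus for c in calls]
        if len(set(loci)) != len(loci):
            raise ValueError(f"sample {sid!r}: duplicate loci within one sample")
        locus_sets.append(set(loci))
    if not locus_sets:
        return MethylomeMatrix([], [], np.zeros((0, 0)), np.zeros((0, 0)))
    if locus_policy == "union":
        all_loci = set().union(*locus_sets)
    elif locus_policy == "intersection":
        all_loci = set.intersection(*locus_sets)
    else:
        raise ValueError(f"unknown locus_policy {locus_policy!r}")
    loci = sorted(all_loci)
    locus_row = {loc: i for i, loc in enumerate(loci)}

    meth = np.zeros((len(loci), len(samples)), dtype=np.int64)
    cov = np.zeros_like(meth)
    for j, (sid, calls) in enumerate(per_sample_calls.items()):
        for c in calls:
            i = locus_row.get(c.locus)
            if i is None:
                continue
            meth[i, j] = c.meth
            cov[i, j] = c.coverage
    return MethylomeMatrix(loci, samples, meth, cov)


_METADATA_COLUMNS = ["sample_id", "tissue", "sex", "temperature", "clutch"]


def read_metadata(path: str | Path, sep: str = "\t") -> list[SampleRecord]:
    """Read the sample-metadata table (TSV by default)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            temp = float(row["temperature"])
        except ValueError as exc:
            raise ValueError(
                f"sample {row['sample_id']}: temperature {row['temperature']!r} "
                "is not numeric"
            ) from exc
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                tissue=row["tissue"],
                sex=row["sex"],
                temperature=temp,
                clutch=row["clutch"],
                e2=float(row["e2"]) if "e2" in df.columns and pd.notna(row["e2"]) else float("nan"),
                testosterone=float(row["testosterone"])
                if "testosterone" in df.columns and pd.notna(row["testosterone"])
                else float("nan"),
            )
        )
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "tissue": [r.tissue for r in records],
            "sex": [r.sex for r in records],
            "temperature": [r.temperature for r in records],
            "clutch": [r.clutch for r in records],
            "e2": [r.e2 for r in records],
            "testosterone": [r.testosterone for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: MethylomeMatrix, path: str | Path) -> None:
    """Serialize a matrix as TSV: scaffold, pos, then <sample>:meth, <sample>:cov."""
    cols: dict[str, object] = {
        "scaffold": [loc.scaffold for loc in matrix.loci],
        "pos": [loc.pos for loc in matrix.loci],
    }
    for j, sid in enumerate(matrix.sample_ids):
        cols[f"{sid}:meth"] = matrix.meth[:, j]
        cols[f"{sid}:cov"] = matrix.cov[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, metadata: Sequence[SampleRecord]) -> MethylomeMatrix:
    """Inverse of :func:`write_matrix`; sample records come from metadata."""
    df = pd.read_csv(path, sep="\t")
    loci = [CpGLocus(s, int(p)) for s, p in zip(df["scaffold"], df["pos"])]
    sids = [c[:-5] for c in df.columns if c.endswith(":meth")]
    meta_by_id = {s.sample_id: s for s in metadata}
    samples = [meta_by_id[s] for s in sids]
    meth = np.column_stack([df[f"{s}:meth"].to_numpy() for s in sids])
    cov = np.column_stack([df[f"{s}:cov"].to_numpy() for s in sids])
    return MethylomeMatrix(loci, samples, meth, cov)


def write_bismark_coverage(calls: Iterable[MethylationCall], path: str | Path) -> None:
    """Write calls in the 6-column bismark coverage dialect (1-based)."""
    with open(path, "w") as fh:
        for c in calls:
            pct = 0.0 if c.coverage == 0 else 100.0 * c.meth / c.coverage
            fh.write(f"{c.scaffold}\t{c.pos + 1}\t{c.pos + 1}\t{pct:.6g}\t{c.meth}\t{c.unmeth}\n")
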