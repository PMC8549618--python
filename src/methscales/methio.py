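"""Reading, merging, filtering and windowing of per-sample CpG methylation counts.

Coordinates are 0-based half-open internally; the Bismark coverage dialect
(1-based) is converted on read.  Symmetric CpG dyads (plus-strand C at p,
minus-strand C at p+1) are merged by summing counts and reported at the
plus-strand coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CpGRecord",
    "MethylomeMatrix",
    "WindowMatrix",
    "read_methylation_table",
    "merge_symmetric_cpgs",
    "matrix_from_records",
    "filter_coverage",
    "window_methylation",
    "write_window_matrix",
    "read_window_matrix",
]


class CpGRecord(NamedTuple):
    chromosome: str
    position: int  # 0-based coordinate of the C on the plus strand
    strand: str
    context: str
    methylated_reads: int
    total_reads: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def read_methylation_table(path, dialect: str = "methpipe") -> list[CpGRecord]:
    """Parse a per-sample methylation table.

    ``methpipe``: chrom, pos(0-based), strand, context, methylation fraction,
    coverage; the methylated count is fraction x coverage rounded half-up.
    ``bismark_cov``: chrom, start(1-based), end, percent, count_meth,
    count_unmeth; start is converted to a 0-based position.
    """
    if dialect not in {"methpipe", "bismark_cov"}:
        raise ValueError(f"unknown dialect: {dialect!r}")
    records: list[CpGRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "methpipe":
                    chrom, pos, strand, context, frac, cov = fields[:6]
                    cov_i = int(cov)
                    meth = _round_half_up(float(frac) * cov_i)
                    rec = CpGRecord(chrom, int(pos), strand, context, meth, cov_i)
                else:
                    chrom, start, _end, _pct, n_meth, n_unmeth = fields[:6]
                    meth, unmeth = int(n_meth), int(n_unmeth)
                    rec = CpGRecord(chrom, int(start) - 1, "+", "CpG", meth, meth + unmeth)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if rec.methylated_reads > rec.total_reads or rec.total_reads < 0 or rec.position < 0:
                raise ValueError(
                    f"{path}: invalid counts at line {lineno}: "
                    f"methylated={rec.methylated_reads} coverage={rec.total_reads}"
                )
            records.append(rec)
    if not records:
        log.warning("empty methylation table: %s", path)
    records.sort(key=lambda r: (r.chromosome, r.position))
    return records


def merge_symmetric_cpgs(records: Iterable[CpGRecord]) -> list[CpGRecord]:
    """Combine the two cytosines of each CpG dyad into one site.

    A plus-strand record at position p and a minus-strand record at p+1 on the
    same chromosome are summed and reported at p; unpaired records pass through
    unchanged; non-CpG-context records are dropped.
    """
    recs = [r for r in records if r.context in {"CpG", "CpG:+", "CG"} or r.context.startswith("CpG")]
    merged: list[CpGRecord] = []
    i = 0
    while i < len(recs):
        r = recs[i]
        if (
            r.strand == "+"
            and i + 1 < len(recs)
            and recs[i + 1].strand == "-"
            and recs[i + 1].chromosome == r.chromosome
            and recs[i + 1].position == r.position + 1
        ):
            mate = recs[i + 1]
            merged.append(
                CpGRecord(
                    r.chromosome,
                    r.position,
                    "+",
                    "CpG",
                    r.methylated_reads + mate.methylated_reads,
                    r.total_reads + mate.total_reads,
                )
            )
            i += 2
        else:
            merged.append(r)
            i += 1
    return merged


@dataclass
class MethylomeMatrix:
    """Samples x sites methylated/coverage count matrices.

    ``sites`` is a (chromosome, position) frame sorted by coordinate; cells
    with zero coverage are treated as missing throughout.
    """

    samples: list[str]
    sites: pd.DataFrame
    methylated: np.ndarray  # (n_samples, n_sites)
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.methylated = np.asarray(self.methylated, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if np.any(self.methylated > self.coverage):
            raise ValueError("methylated counts exceed coverage")
        if np.any(self.coverage < 0):
            raise ValueError("negative coverage")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def fractions(self) -> np.ndarray:
        """Per-cell methylation fraction; NaN where coverage is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.methylated / self.coverage
        return np.where(self.coverage > 0, f, np.nan)

    def subset_sites(self, mask: np.ndarray) -> "MethylomeMatrix":
        return MethylomeMatrix(
            samples=list(self.samples),
            sites=self.sites.loc[mask].reset_index(drop=True),
            methylated=self.methylated[:, mask],
            coverage=self.coverage[:, mask],
        )


def matrix_from_records(sample_records: dict[str, list[CpGRecord]]) -> MethylomeMatrix:
    """Align per-sample record lists on the union of sites (outer join);
    sites absent from a sample get zero coverage (missing)."""
    frames = {}
    for sample, recs in sample_records.items():
        df = pd.DataFrame(recs, columns=CpGRecord._fields)
        df = df.set_index(["chromosome", "position"])
        frames[sample] = df[["methylated_reads", "total_reads"]]
    all_sites = sorted(set().union(*(f.index for f in frames.values())))
    index = pd.MultiIndex.from_tuples(all_sites, names=["chromosome", "position"])
    samples = list(sample_records)
    meth = np.zeros((len(samples), len(index)), dtype=np.int64)
    cov = np.zeros_like(meth)
    for i, sample in enumerate(samples):
        aligned = frames[sample].reindex(index)
        meth[i] = aligned["methylated_reads"].fillna(0).to_numpy()
        cov[i] = aligned["total_reads"].fillna(0).to_numpy()
    sites = index.to_frame(index=False)
    return MethylomeMatrix(samples=samples, sites=sites, methylated=meth, coverage=cov)


def filter_coverage(matrix: MethylomeMatrix, min_cov: int = 10) -> MethylomeMatrix:
    """Mark cells with coverage below ``min_cov`` as missing (zeroed).

    Sites missing in some sample are retained; the windowing stage enforces
    per-sample completeness.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    keep = matrix.coverage >= min_cov
    return MethylomeMatrix(
        samples=list(matrix.samples),
        sites=matrix.sites.copy(),
        methylated=np.where(keep, matrix.methylated, 0),
        coverage=np.where(keep, matrix.coverage, 0),
    )


@dataclass
class WindowMatrix:
    """Samples x windows mean-methylation matrix (no missing cells)."""

    samples: list[str]
    windows: pd.DataFrame  # chromosome, start, end
    values: np.ndarray  # (n_samples, n_windows) in [0, 1]
    n_cpgs: np.ndarray  # per-window minimum (over samples) covered-CpG count

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def subset_chromosome(self, chromosome: str) -> "WindowMatrix":
        mask = (self.windows["chromosome"] == chromosome).to_numpy()
        return WindowMatrix(
            samples=list(self.samples),
            windows=self.windows.loc[mask].reset_index(drop=True),
            values=self.values[:, mask],
            n_cpgs=self.n_cpgs[mask],
        )


def window_methylation(
    matrix: MethylomeMatrix,
    size_bp: int = 1000,
    step_bp: int = 1000,
    min_cpgs: int = 3,
) -> WindowMatrix:
    """Mean methylation per fixed-size genomic window.

    Window value = unweighted mean of per-CpG fractions over covered CpGs; a
    window is kept only when every sample has at least ``min_cpgs`` covered
    CpGs inside it (complete-case rule, yielding the gap-free matrix that the
    Euclidean distance requires).
    """
    if size_bp <= 0 or step_bp <= 0:
        raise ValueError("window size and step must be positive")
    frac = matrix.fractions()
    covered = matrix.coverage > 0
    rows = []
    values_cols = []
    ncpg_cols = []
    chroms = matrix.sites["chromosome"].to_numpy()
    positions = matrix.sites["position"].to_numpy()
    for chrom in pd.unique(matrix.sites["chromosome"]):
        cmask = chroms == chrom
        pos_c = positions[cmask]
        frac_c = frac[:, cmask]
        cov_c = covered[:, cmask]
        if pos_c.size == 0:
            continue
        last = pos_c.max()
        start = 0
        while start <= last:
            end = start + size_bp
            in_win = (pos_c >= start) & (pos_c < end)
            if in_win.any():
                n_cov = (cov_c[:, in_win]).sum(axis=1)
                if (n_cov >= min_cpgs).all():
                    with np.errstate(invalid="ignore"):
                        vals = np.nanmean(frac_c[:, in_win], axis=1)
                    rows.append((chrom, start, end))
                    values_cols.append(vals)
                    ncpg_cols.append(int(n_cov.min()))
            start += step_bp
    if not rows:
        return WindowMatrix(
            samples=list(matrix.samples),
            windows=pd.DataFrame(columns=["chromosome", "start", "end"]),
            values=np.zeros((len(matrix.samples), 0)),
            n_cpgs=np.zeros(0, dtype=int),
        )
    return WindowMatrix(
        samples=list(matrix.samples),
        windows=pd.DataFrame(rows, columns=["chromosome", "start", "end"]),
        values=np.column_stack(values_cols),
        n_cpgs=np.asarray(ncpg_cols, dtype=int),
    )


def write_window_matrix(wm: WindowMatrix, path) -> None:
    """Tab-delimited matrix with a BED-like window index."""
    df = wm.windows.copy()
    df["n_cpgs"] = wm.n_cpgs
    for i, s in enumerate(wm.samples):
        df[s] = wm.values[i]
    df.to_csv(path, sep="\t", index=False)


def read_window_matrix(path) -> WindowMatrix:
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c not in {"chromosome", "start", "end", "n_cpgs"}]
    return WindowMatrix(
        samples=samples,
        windows=df[["chromosome", "start", "end"]].copy(),
        values=df[samples].to_numpy().T,
        n_cpgs=df["n_cpgs"].to_numpy(),
    )
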