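"""Per-CpG multifactor differential-methylation testing and DMR calling.

The per-CpG test follows the arcsine / weighted-least-squares dispersion-
shrinkage approach for bisulfite count data: the per-sample methylation level
X/N is transformed as Y = arcsin(2 X/N - 1), regressed on a centered factor
design (environment + river + environment:river) with weights N, and the
per-site residual variance is shrunk toward the genome-wide mean residual
variance by empirical-Bayes weighting before forming per-term Wald statistics.
No smoothing across neighbouring CpGs is applied.

Regions are then called by a rule set: flag CpGs with p below a threshold,
grow maximal runs that start and end at flagged CpGs while the flagged
fraction stays above ``pct_sig`` (greedy left-to-right extension, trailing
unflagged CpGs trimmed), keep runs long enough in bp and CpG count, merge
nearby survivors, and finally require a minimum absolute mean methylation
difference between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from intervaltree import IntervalTree

from .methio import MethylomeMatrix
from .ordination import design_matrix

__all__ = [
    "Design",
    "DMRParams",
    "DMR",
    "build_design",
    "fit_cpg_model",
    "call_dmrs",
    "filter_dmrs_by_effect",
    "classify_direction",
    "enrichment_test",
    "annotate_dmrs",
    "read_intervals",
    "dmrs_to_bed",
]

#: dyad footprint in bp; a DMR interval closes after the second base of the
#: last CpG
_CPG_WIDTH = 2


@dataclass
class Design:
    """Centered factor encoding with an explicit intercept column."""

    terms: list[str]
    matrix: np.ndarray  # (n_samples, 1 + n_terms) with leading intercept
    column_terms: list[str]  # term name per non-intercept column
    metadata: pd.DataFrame


def build_design(
    metadata: pd.DataFrame,
    terms: tuple[str, ...] = ("environment", "river", "environment:river"),
) -> Design:
    x, names = design_matrix(metadata, list(terms))
    mat = np.column_stack([np.ones(len(metadata)), x])
    # map encoded column names back to their term
    col_terms = []
    for nm in names:
        base = nm.split("[")[0] if "[" in nm else nm
        col_terms.append(base)
    return Design(terms=list(terms), matrix=mat, column_terms=col_terms, metadata=metadata)


@dataclass
class DMRParams:
    min_len_bp: int = 100
    min_cpgs: int = 10
    p_threshold: float = 0.01
    merge_dist_bp: int = 50
    pct_sig: float = 0.4
    min_mean_diff: float = 0.10

    def __post_init__(self) -> None:
        if min(self.min_len_bp, self.min_cpgs, self.merge_dist_bp) <= 0:
            raise ValueError("length, CpG-count and merge-distance parameters must be positive")
        if not (0 < self.pct_sig < 1 and 0 < self.min_mean_diff < 1 and 0 < self.p_threshold <= 1):
            raise ValueError("pct_sig, min_mean_diff in (0,1); p_threshold in (0,1]")


@dataclass
class DMR:
    chromosome: str
    start: int
    end: int
    n_cpgs: int
    frac_significant: float
    mean_meth_hatchery: float
    mean_meth_wild: float
    term: str
    min_p: float
    cpg_positions: list[int] = field(default_factory=list, repr=False)

    @property
    def mean_diff(self) -> float:
        return self.mean_meth_hatchery - self.mean_meth_wild

    @property
    def direction(self) -> str:
        return classify_direction(self)


# ---------------------------------------------------------------------------
# per-CpG model


def fit_cpg_model(
    meth: MethylomeMatrix,
    design: Design,
    min_coverage: int = 10,
    min_per_cell: int = 2,
    d_prior: float = 20.0,
) -> pd.DataFrame:
    """Arcsine/WLS test of each CpG against the factor design.

    Cells with coverage below ``min_coverage`` get zero weight; a CpG is
    tested only when every design cell (river x environment) retains at least
    ``min_per_cell`` weighted samples and the residual df is positive.  The
    per-site residual variance s_i² (df d_i) is shrunk toward the genome-wide
    mean s̄²  with weight w = d_i / (d_i + d_prior); Wald statistics use the
    shrunk variance and a two-sided normal reference.

    Returns a frame with one row per tested CpG: coordinates, per-term
    ``coef_*``, ``se_*``, ``stat_*``, ``p_*``, the shrunk residual variance
    and the number of contributing samples.
    """
    x = design.matrix
    n, k = x.shape
    cov = meth.coverage.T.astype(float)  # (sites, samples)
    mt = meth.methylated.T.astype(float)
    w = np.where(cov >= min_coverage, cov, 0.0)
    used = w > 0

    # design-cell completeness
    cells = design.metadata.apply(
        lambda r: f"{r['river']}|{r['environment']}", axis=1
    ).to_numpy()
    ok = np.ones(cov.shape[0], dtype=bool)
    for cell in np.unique(cells):
        idx = cells == cell
        ok &= used[:, idx].sum(axis=1) >= min_per_cell

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(used, mt / np.where(cov > 0, cov, 1), 0.0)
    y = np.arcsin(np.clip(2 * frac - 1, -1, 1))

    # batched WLS: beta = (X'WX)^-1 X'Wy per site
    xtwx = np.einsum("sn,nj,nk->sjk", w, x, x)
    xtwy = np.einsum("sn,nj,sn->sj", w, x, y)
    dof = used.sum(axis=1) - k
    ok &= dof > 0
    if not ok.any():
        return _empty_test_frame(design)
    xtwx_ok = xtwx[ok]
    # guard: singular designs (e.g. a cell fully unweighted) -> skip site
    sign, logdet = np.linalg.slogdet(xtwx_ok)
    det_ok = (sign > 0) & np.isfinite(logdet)
    sites_idx = np.flatnonzero(ok)[det_ok]
    xtwx_ok = xtwx_ok[det_ok]
    beta = np.linalg.solve(xtwx_ok, xtwy[sites_idx][..., None])[..., 0]
    fitted = beta @ x.T  # (s, n)
    resid = y[sites_idx] - fitted
    rss = (w[sites_idx] * resid**2).sum(axis=1)
    d_i = dof[sites_idx].astype(float)
    s2 = rss / d_i
    s2_bar = float(s2.mean()) if s2.size else 0.0
    shrink_w = d_i / (d_i + d_prior)
    s2_shrunk = shrink_w * s2 + (1 - shrink_w) * s2_bar

    xtwx_inv = np.linalg.inv(xtwx_ok)
    var_beta = s2_shrunk[:, None] * np.einsum("sjj->sj", xtwx_inv)
    se = np.sqrt(np.maximum(var_beta, 1e-300))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))

    out = {
        "chromosome": meth.sites["chromosome"].to_numpy()[sites_idx],
        "position": meth.sites["position"].to_numpy()[sites_idx],
        "n_used": used[sites_idx].sum(axis=1),
        "shrunk_dispersion": s2_shrunk,
    }
    for j, term in enumerate(design.column_terms, start=1):
        out[f"coef_{term}"] = beta[:, j]
        out[f"se_{term}"] = se[:, j]
        out[f"stat_{term}"] = z[:, j]
        out[f"p_{term}"] = p[:, j]
    return pd.DataFrame(out)


def _empty_test_frame(design: Design) -> pd.DataFrame:
    cols = ["chromosome", "position", "n_used", "shrunk_dispersion"]
    for term in design.column_terms:
        cols += [f"coef_{term}", f"se_{term}", f"stat_{term}", f"p_{term}"]
    return pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# region calling


def _candidate_runs(flagged: np.ndarray, pct_sig: float) -> list[tuple[int, int]]:
    """Maximal CpG runs starting/ending at flagged CpGs whose flagged
    fraction stays >= pct_sig (greedy left-to-right extension, trailing
    unflagged CpGs trimmed).  Runs live in CpG-index space; genomic distance
    only enters later, when surviving regions within the merge distance are
    joined.  Returns (start_index, end_index) inclusive pairs.
    """
    runs = []
    m = flagged.size
    i = 0
    while i < m:
        if not flagged[i]:
            i += 1
            continue
        start = i
        last_flag = i
        n_flag = 1
        j = i + 1
        while j < m:
            if flagged[j]:
                if (n_flag + 1) / (j - start + 1) >= pct_sig:
                    n_flag += 1
                    last_flag = j
                    j += 1
                else:
                    break
            else:
                j += 1
        runs.append((start, last_flag))
        i = last_flag + 1
    return runs


def call_dmrs(
    tests: pd.DataFrame,
    meth: MethylomeMatrix,
    metadata: pd.DataFrame,
    term: str = "environment",
    params: DMRParams | None = None,
    group_column: str | None = None,
    focal_level: str | None = None,
) -> list[DMR]:
    """Rule-based DMR calling on sorted per-CpG test results.

    ``group_column`` / ``focal_level`` name the grouping whose mean difference
    is reported (defaults: the tested term; for ``environment`` the focal
    level is ``hatchery``, so mean_diff = hatchery - wild).
    """
    params = params or DMRParams()
    if tests.empty:
        return []
    group_column = group_column or term.split(":")[0]
    if focal_level is None:
        levels = sorted(metadata[group_column].unique())
        focal_level = "hatchery" if "hatchery" in levels else levels[-1]
    pcol = f"p_{term}"
    if pcol not in tests.columns:
        raise KeyError(f"no test column for term {term!r}")
    tests = tests.sort_values(["chromosome", "position"]).reset_index(drop=True)

    dmrs: list[DMR] = []
    for chrom, sub in tests.groupby("chromosome", sort=True):
        pos = sub["position"].to_numpy()
        pv = sub[pcol].to_numpy()
        flagged = pv < params.p_threshold  # ties at the threshold are non-significant
        regions = []
        for a, b in _candidate_runs(flagged, params.pct_sig):
            span = pos[b] + _CPG_WIDTH - pos[a]
            n_cpg = b - a + 1
            if span >= params.min_len_bp and n_cpg >= params.min_cpgs:
                regions.append([int(pos[a]), int(pos[b]) + _CPG_WIDTH])
        # merge close survivors
        merged = []
        for r in regions:
            if merged and r[0] - merged[-1][1] <= params.merge_dist_bp:
                merged[-1][1] = max(merged[-1][1], r[1])
            else:
                merged.append(r)
        for start, end in merged:
            in_reg = (pos >= start) & (pos < end)
            reg_pos = pos[in_reg]
            frac_sig = float(flagged[in_reg].mean())
            min_p = float(pv[in_reg].min())
            mu_focal, mu_other = _group_means(
                meth, metadata, chrom, reg_pos, group_column, focal_level
            )
            dmrs.append(
                DMR(
                    chromosome=str(chrom),
                    start=int(start),
                    end=int(end),
                    n_cpgs=int(in_reg.sum()),
                    frac_significant=frac_sig,
                    mean_meth_hatchery=mu_focal,
                    mean_meth_wild=mu_other,
                    term=term,
                    min_p=min_p,
                    cpg_positions=[int(p) for p in reg_pos],
                )
            )
    return dmrs


def _group_means(
    meth: MethylomeMatrix,
    metadata: pd.DataFrame,
    chromosome: str,
    positions: np.ndarray,
    group_column: str,
    focal_level: str,
) -> tuple[float, float]:
    """Unweighted per-group mean methylation over the region's CpGs:
    per CpG, mean of per-sample fractions within the group; then mean over
    CpGs."""
    site_mask = (
        (meth.sites["chromosome"] == chromosome).to_numpy()
        & meth.sites["position"].isin(positions).to_numpy()
    )
    frac = meth.fractions()[:, site_mask]
    grp = metadata.set_index("sample_id").loc[meth.samples, group_column].to_numpy()
    focal = grp == focal_level
    with np.errstate(invalid="ignore"):
        mu_f = float(np.nanmean(np.nanmean(frac[focal], axis=0)))
        mu_o = float(np.nanmean(np.nanmean(frac[~focal], axis=0)))
    return mu_f, mu_o


def filter_dmrs_by_effect(dmrs: list[DMR], min_mean_diff: float = 0.10) -> list[DMR]:
    """Keep DMRs with |mean difference| strictly above ``min_mean_diff``."""
    return [d for d in dmrs if abs(d.mean_diff) > min_mean_diff]


def classify_direction(dmr: DMR) -> str:
    """``hyper`` when the focal (hatchery) group is more methylated."""
    if dmr.mean_meth_hatchery == dmr.mean_meth_wild:
        raise ValueError("zero mean difference: direction undefined")
    return "hyper" if dmr.mean_meth_hatchery > dmr.mean_meth_wild else "hypo"


def enrichment_test(n_hyper: int, n_hypo: int) -> tuple[float, float]:
    """df=1 goodness-of-fit of the hyper:hypo split against 1:1."""
    total = n_hyper + n_hypo
    if total == 0:
        raise ValueError("no classified DMRs")
    m = total / 2
    chi2 = (n_hyper - m) ** 2 / m + (n_hypo - m) ** 2 / m
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# annotation


def read_intervals(path, fmt: str | None = None) -> pd.DataFrame:
    """Read transcript intervals from BED (0-based half-open) or GFF3
    (1-based closed, converted on read)."""
    fmt = fmt or ("gff" if str(path).endswith((".gff", ".gff3")) else "bed")
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        out = df.iloc[:, :3].copy()
        out.columns = ["chromosome", "start", "end"]
        out["name"] = df.iloc[:, 3] if df.shape[1] > 3 else [f"iv{i}" for i in range(len(df))]
    elif fmt == "gff":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["seqid", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"])
        out = pd.DataFrame(
            {
                "chromosome": df["seqid"],
                "start": df["start"].astype(int) - 1,
                "end": df["end"].astype(int),
                "name": df["attributes"].str.extract(r"ID=([^;]+)", expand=False).fillna("iv"),
            }
        )
    else:
        raise ValueError(f"unknown interval format: {fmt!r}")
    return out.sort_values(["chromosome", "start"]).reset_index(drop=True)


def annotate_dmrs(
    dmrs: list[DMR], transcripts: pd.DataFrame, flank_bp: int = 0
) -> pd.DataFrame:
    """Half-open intersection of (DMR ± flank) with transcript intervals;
    one row per DMR x transcript overlap."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in transcripts.groupby("chromosome"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), nm)
            for s, e, nm in zip(sub["start"], sub["end"], sub["name"])
            if e > s
        )
    rows = []
    for d in dmrs:
        tree = trees.get(d.chromosome)
        if tree is None:
            continue
        lo = max(0, d.start - flank_bp)
        hi = d.end + flank_bp
        for iv in sorted(tree.overlap(lo, hi)):
            rows.append(
                {
                    "chromosome": d.chromosome,
                    "dmr_start": d.start,
                    "dmr_end": d.end,
                    "term": d.term,
                    "direction": d.direction,
                    "transcript": iv.data,
                    "transcript_start": iv.begin,
                    "transcript_end": iv.end,
                    "flank_bp": flank_bp,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome", "dmr_start", "dmr_end", "term", "direction",
            "transcript", "transcript_start", "transcript_end", "flank_bp",
        ],
    )


def dmrs_to_bed(dmrs: list[DMR]) -> pd.DataFrame:
    """BED6+ table: chrom, start, end, name, score (-log10 min p), strand,
    then n_cpgs, frac_sig, group means, mean_diff, direction, term."""
    rows = []
    for i, d in enumerate(dmrs):
        rows.append(
            {
                "chromosome": d.chromosome,
                "start": d.start,
                "end": d.end,
                "name": f"dmr_{d.term.replace(':', '_')}_{i}",
                "score": round(-np.log10(max(d.min_p, 1e-300)), 3),
                "strand": ".",
                "n_cpgs": d.n_cpgs,
                "frac_sig": round(d.frac_significant, 4),
                "mean_hatchery": round(d.mean_meth_hatchery, 6),
                "mean_wild": round(d.mean_meth_wild, 6),
                "mean_diff": round(d.mean_diff, 6),
                "direction": d.direction if d.mean_diff != 0 else "na",
                "term": d.term,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "name", "score", "strand", "n_cpgs",
                 "frac_sig", "mean_hatchery", "mean_wild", "mean_diff", "direction", "term"],
    )
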