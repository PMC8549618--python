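"""SNP filtering, Weir–Cockerham F_ST and genotype ordination.

Establishes the genetic baseline of the analysis: variants are filtered from
a VCF (biallelic SNPs; quality, per-genotype depth, site missingness and
minor-allele-frequency thresholds; removal of C/T and A/G polymorphisms that
bisulfite conversion renders unreliable), differentiation is estimated with
the Weir & Cockerham (1984) variance-component theta, and genotype structure
is examined by PCoA / db-RDA on the 0-1-2 dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import ordination

__all__ = [
    "GenotypeMatrix",
    "VariantFilterParams",
    "filter_variants",
    "weir_cockerham_fst",
    "genotype_pcoa_rda",
    "mean_impute",
]

# unreliable ref/alt pairs under bisulfite conversion (both strand orientations)
_BISULFITE_PAIRS = ({"C", "T"}, {"G", "A"})


@dataclass
class VariantFilterParams:
    min_depth: int = 5
    max_depth: int = 100
    min_maf: float = 0.01
    min_qual: float = 20.0
    max_missing: float = 0.20
    drop_ct_ga: bool = True
    max_missing_individuals: int | None = None  # optional absolute-count rule

    def __post_init__(self) -> None:
        if not (0 < self.min_maf < 0.5):
            raise ValueError("min_maf must lie in (0, 0.5)")
        if not (0 <= self.max_missing < 1):
            raise ValueError("max_missing must lie in [0, 1)")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth exceeds max_depth")


@dataclass
class GenotypeMatrix:
    """Biallelic dosages (0/1/2, NaN = missing) with variant coordinates."""

    samples: list[str]
    variants: pd.DataFrame  # chromosome, position, ref, alt
    dosages: np.ndarray  # (n_samples, n_variants) float with NaN

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


def filter_variants(vcf_path, params: VariantFilterParams | None = None) -> GenotypeMatrix:
    """Read and filter a VCF into a dosage matrix.

    Keeps biallelic SNPs with QUAL >= min_qual; genotypes whose depth falls
    outside [min_depth, max_depth] are set missing; sites are then dropped
    when missingness exceeds max_missing (or ``max_missing_individuals``
    called individuals, when set) or when the minor-allele frequency --
    computed from the remaining called genotypes -- is below min_maf.
    C/T and A/G ref/alt pairs are removed when ``drop_ct_ga`` is set.
    """
    params = params or VariantFilterParams()
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    n = len(samples)
    rows = []
    cols = []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        if var.QUAL is None or var.QUAL < params.min_qual:
            continue
        ref, alt = var.REF.upper(), var.ALT[0].upper()
        if params.drop_ct_ga and {ref, alt} in _BISULFITE_PAIRS:
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        try:
            depth = var.format("DP")
        except KeyError:
            depth = None
        if depth is None:
            raise ValueError(
                f"{vcf_path}: missing per-genotype DP field required for depth filtering"
            )
        depth = depth.reshape(n).astype(float)
        bad = (depth < params.min_depth) | (depth > params.max_depth)
        dos = np.where(bad, np.nan, dos)
        n_missing = int(np.isnan(dos).sum())
        if n_missing / n > params.max_missing:
            continue
        if (
            params.max_missing_individuals is not None
            and n_missing > params.max_missing_individuals
        ):
            continue
        called = dos[~np.isnan(dos)]
        if called.size == 0:
            continue
        p_alt = called.sum() / (2 * called.size)
        if min(p_alt, 1 - p_alt) < params.min_maf:
            continue
        rows.append((var.CHROM, var.POS, ref, alt))
        cols.append(dos)
    variants = pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt"])
    dosages = np.column_stack(cols) if cols else np.zeros((n, 0))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def weir_cockerham_fst(
    dosages: np.ndarray, groups: np.ndarray | list
) -> tuple[np.ndarray, float]:
    """Weir & Cockerham (1984) theta from diploid dosages.

    Per locus the variance components a (among populations), b (among
    individuals within populations) and c (within individuals) are computed;
    per-locus theta = a / (a + b + c) (NaN where the denominator vanishes,
    e.g. monomorphic loci) and the overall estimate is the weighted
    ratio-of-sums sum(a) / sum(a + b + c) over informative loci.  Missing
    genotypes (NaN) are excluded per locus.
    """
    d = np.asarray(dosages, dtype=float)
    groups = np.asarray(groups)
    pops = np.unique(groups)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two groups")
    n_loci = d.shape[1]
    n_i = np.zeros((r, n_loci))
    p_i = np.zeros((r, n_loci))
    h_i = np.zeros((r, n_loci))
    for k, pop in enumerate(pops):
        sub = d[groups == pop]
        called = ~np.isnan(sub)
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.nansum(sub, axis=0) / (2 * n_i[k])
            h_i[k] = np.nansum(sub == 1, axis=0) / n_i[k]
    if np.any(n_i < 2):
        bad = np.any(n_i < 2, axis=0)
        if bad.all():
            raise ValueError("every locus lacks two called genotypes in some group")
    n_bar = n_i.mean(axis=0)
    n_sum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_sum
        a = (n_bar / nc) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
        denom = a + b + c
        per_locus = np.where(np.abs(denom) > 1e-12, a / denom, np.nan)
    informative = np.isfinite(per_locus)
    if not informative.any():
        return per_locus, float("nan")
    overall = float(a[informative].sum() / denom[informative].sum())
    return per_locus, overall


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (for distance
    computation only; never used for F_ST)."""
    d = np.asarray(dosages, dtype=float).copy()
    col_mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    return d


def genotype_pcoa_rda(
    g: GenotypeMatrix,
    metadata: pd.DataFrame,
    axis_threshold: float = 0.03,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> dict[str, object]:
    """Genetic structure analysis: Euclidean distance on mean-imputed
    dosages -> PCoA -> >=3%-variance axes -> forward selection and (partial)
    db-RDA over river and rearing environment.

    Returns a dict with the retained axes, selected terms, the full-model
    RDA and per-term partial RDAs (each term conditioned on the other).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta = metadata.set_index("sample_id").loc[g.samples].reset_index()
    imputed = mean_impute(g.dosages)
    dist = ordination.euclidean_distance(imputed, labels=g.samples)
    pres = ordination.pcoa(dist)
    yaxes = ordination.retain_axes_min_variance(pres, threshold=axis_threshold)
    candidates = {
        term: ordination.design_matrix(meta, [term])[0] for term in ("river", "environment")
    }
    selected = ordination.forward_select(yaxes, candidates, alpha=alpha, n_perm=n_perm, seed=rng)
    x_all = np.hstack([candidates[t] for t in ("river", "environment")])
    full = ordination.partial_rda(
        yaxes, x_all, None, term_names=["river", "environment"], n_perm=n_perm, seed=rng
    )
    partials = {}
    for term in ("river", "environment"):
        other = [t for t in ("river", "environment") if t != term]
        partials[term] = ordination.partial_rda(
            yaxes,
            candidates[term],
            np.hstack([candidates[t] for t in other]),
            term_names=[term],
            conditioned_names=other,
            n_perm=n_perm,
            seed=rng,
        )
    return {
        "axes": yaxes,
        "pcoa": pres,
        "selected_terms": selected,
        "full": full,
        "partial": partials,
    }
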