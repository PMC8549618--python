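"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-river, two-rearing-environment sperm-methylome
study: beta-binomial CpG counts over geometrically spaced symmetric CpGs,
planted environment-associated DMRs that are parallel across rivers (same
coordinates and direction in the hatchery samples of both rivers),
river-associated methylation regions, and a biallelic genotype matrix with
weak river structure (Balding–Nichols) and no environment structure.

Simulation starts at the CpG count level: reads, bisulfite conversion error
and alignment artifacts are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .methio import MethylomeMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_cohort",
    "simulate_varpart_matrix",
    "write_fixtures",
]


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for :func:`simulate_cohort`.

    Defaults reproduce the emulated design: 2 rivers x 2 environments x 6
    males, ~15x mean CpG coverage, beta-binomial overdispersion phi = 0.05,
    20 parallel environment DMRs of 15 CpGs at an additive shift of 0.25
    (hyper:hypo 2:1 in the hatchery group), 20 river-associated regions, and
    5,000 SNPs at a Balding–Nichols divergence of F_ST = 0.01.
    """

    n_chromosomes: int = 2
    chromosome_length_bp: int = 300_000
    cpg_spacing_bp: float = 30.0
    n_samples_per_group: int = 6
    mean_coverage: float = 15.0
    coverage_dispersion: float = 10.0  # negative-binomial size parameter
    baseline_methylation: float = 0.70
    baseline_concentration: float = 3.0
    dispersion_phi: float = 0.05
    n_planted_dmrs: int = 20
    dmr_effect_delta: float = 0.25
    dmr_width_cpgs: int = 15
    hyper_fraction: float = 2.0 / 3.0
    river_effect_regions: int = 20
    river_effect_delta: float = 0.25
    n_snps: int = 5000
    river_fst_target: float = 0.01
    genotype_mean_depth: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chromosome_length_bp, self.n_samples_per_group) <= 0:
            raise ValueError("counts and lengths must be positive")
        if not (0 <= self.baseline_methylation <= 1):
            raise ValueError("baseline_methylation must lie in [0, 1]")
        if not (0 < self.dispersion_phi < 1):
            raise ValueError("dispersion_phi must lie in (0, 1)")
        for name in ("dmr_effect_delta", "river_effect_delta"):
            delta = getattr(self, name)
            if not (0 <= delta <= 0.98):
                raise ValueError(f"{name} would push proportions outside [0.01, 0.99]")
        if self.n_planted_dmrs < 0 or self.river_effect_regions < 0 or self.n_snps < 0:
            raise ValueError("region and SNP counts must be non-negative")
        if not (0 < self.river_fst_target < 1):
            raise ValueError("river_fst_target must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests.

    Intervals are 0-based half-open and non-overlapping within a chromosome.
    ``planted_env_fraction`` / ``planted_genetic_fraction`` are populated by
    the variance-partition construction (:func:`simulate_varpart_matrix`),
    not by the cohort generator whose effects are specified as deltas.
    """

    planted_dmrs: list[tuple[str, int, int, float, str]] = field(default_factory=list)
    planted_river_regions: list[tuple[str, int, int, float, str]] = field(default_factory=list)
    planted_env_fraction: float | None = None
    planted_genetic_fraction: float | None = None


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    methylomes: MethylomeMatrix
    genotypes: np.ndarray  # (n_samples, n_snps) dosages in {0,1,2}
    variants: pd.DataFrame  # chromosome, position, ref, alt
    metadata: pd.DataFrame  # sample_id, river, environment
    truth: SyntheticTruth


_RIVERS = ("conuma", "quinsam")
_ENVIRONMENTS = ("hatchery", "wild")
_BASES = "ACGT"


def _cpg_positions(rng: np.random.Generator, length: int, spacing: float) -> np.ndarray:
    gaps = rng.geometric(1.0 / spacing, size=int(2.5 * length / spacing) + 10)
    pos = np.cumsum(gaps) + 1
    return pos[pos < length - 2]


def _place_regions(
    rng: np.random.Generator,
    n_sites_per_chrom: dict[str, int],
    n_regions: int,
    width: int,
    occupied: dict[str, list[tuple[int, int]]],
) -> list[tuple[str, int, int]]:
    """Pick non-overlapping runs of ``width`` consecutive CpGs (site-index
    space), avoiding already-occupied runs; returns (chrom, i0, i1) inclusive
    index pairs."""
    chroms = list(n_sites_per_chrom)
    placed: list[tuple[str, int, int]] = []
    attempts = 0
    while len(placed) < n_regions and attempts < 20000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        m = n_sites_per_chrom[chrom]
        if m <= width + 2:
            continue
        i0 = int(rng.integers(1, m - width - 1))
        i1 = i0 + width - 1
        clash = any(not (i1 + 1 < a or i0 > b + 1) for a, b in occupied.get(chrom, []))
        if clash:
            continue
        occupied.setdefault(chrom, []).append((i0, i1))
        placed.append((chrom, i0, i1))
    if len(placed) < n_regions:
        raise ValueError("could not place the requested regions without overlap")
    return placed


def simulate_cohort(config: SimulationConfig) -> SyntheticDataset:
    """Simulate methylomes, genotypes, metadata and ground truth.

    The seed fully determines the output.  Hatchery samples of both rivers
    share the planted DMR coordinates and effect direction (parallelism);
    genotypes are drawn from river-specific Balding–Nichols allele
    frequencies, identically distributed across environments within a river.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    # ----- samples
    rows = []
    for river in _RIVERS:
        for env in _ENVIRONMENTS:
            for i in range(config.n_samples_per_group):
                rows.append((f"{river[:3]}_{env[:4]}_{i:02d}", river, env))
    metadata = pd.DataFrame(rows, columns=["sample_id", "river", "environment"])
    n_samples = len(metadata)
    is_hatchery = (metadata["environment"] == "hatchery").to_numpy()
    is_conuma = (metadata["river"] == "conuma").to_numpy()

    # ----- CpG coordinates
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    pos_by_chrom = {
        c: _cpg_positions(rng, config.chromosome_length_bp, config.cpg_spacing_bp)
        for c in chrom_names
    }
    sites = pd.concat(
        [
            pd.DataFrame({"chromosome": c, "position": pos_by_chrom[c]})
            for c in chrom_names
        ],
        ignore_index=True,
    )
    n_sites = len(sites)
    offsets = {}
    off = 0
    for c in chrom_names:
        offsets[c] = off
        off += len(pos_by_chrom[c])

    # ----- baseline methylation
    mu, nu = config.baseline_methylation, config.baseline_concentration
    base = rng.beta(mu * nu, (1 - mu) * nu, size=n_sites)
    base = np.clip(base, 0.02, 0.98)

    # ----- planted regions (site-index space, non-overlapping)
    n_sites_per_chrom = {c: len(pos_by_chrom[c]) for c in chrom_names}
    occupied: dict[str, list[tuple[int, int]]] = {}
    env_regions = _place_regions(
        rng, n_sites_per_chrom, config.n_planted_dmrs, config.dmr_width_cpgs, occupied
    )
    river_regions = _place_regions(
        rng, n_sites_per_chrom, config.river_effect_regions, config.dmr_width_cpgs, occupied
    )

    # differential methylation arises in regions of intermediate methylation:
    # planted regions redraw their baseline from U(0.30, 0.65) so that an
    # additive +/- delta shift never clamps against 0.01 / 0.99
    truth = SyntheticTruth()
    env_effect = np.zeros(n_sites)
    n_hyper = int(round(config.n_planted_dmrs * config.hyper_fraction))
    signs = np.array([1.0] * n_hyper + [-1.0] * (config.n_planted_dmrs - n_hyper))
    rng.shuffle(signs)
    for (chrom, i0, i1), sign in zip(env_regions, signs):
        g0, g1 = offsets[chrom] + i0, offsets[chrom] + i1
        base[g0 : g1 + 1] = rng.uniform(0.30, 0.65, size=g1 - g0 + 1)
        env_effect[g0 : g1 + 1] = sign * config.dmr_effect_delta
        pos = pos_by_chrom[chrom]
        truth.planted_dmrs.append(
            (
                chrom,
                int(pos[i0]),
                int(pos[i1]) + 2,
                sign * config.dmr_effect_delta,
                "hyper" if sign > 0 else "hypo",
            )
        )
    river_effect = np.zeros(n_sites)
    rsigns = rng.choice([-1.0, 1.0], size=config.river_effect_regions)
    for (chrom, i0, i1), sign in zip(river_regions, rsigns):
        g0, g1 = offsets[chrom] + i0, offsets[chrom] + i1
        base[g0 : g1 + 1] = rng.uniform(0.30, 0.65, size=g1 - g0 + 1)
        river_effect[g0 : g1 + 1] = sign * config.river_effect_delta
        pos = pos_by_chrom[chrom]
        truth.planted_river_regions.append(
            (
                chrom,
                int(pos[i0]),
                int(pos[i1]) + 2,
                sign * config.river_effect_delta,
                "hyper" if sign > 0 else "hypo",
            )
        )

    # ----- per-sample expected proportions, coverage and counts
    p_sample = np.broadcast_to(base, (n_samples, n_sites)).copy()
    p_sample[is_hatchery] += env_effect
    p_sample[is_conuma] += river_effect
    p_sample = np.clip(p_sample, 0.01, 0.99)

    size = config.coverage_dispersion
    nb_p = size / (size + config.mean_coverage)
    coverage = rng.negative_binomial(size, nb_p, size=(n_samples, n_sites))
    phi = config.dispersion_phi
    conc = (1 - phi) / phi
    p_cell = rng.beta(p_sample * conc, (1 - p_sample) * conc)
    methylated = rng.binomial(coverage, p_cell)

    methylomes = MethylomeMatrix(
        samples=list(metadata["sample_id"]),
        sites=sites,
        methylated=methylated,
        coverage=coverage,
    )

    # ----- genotypes (Balding–Nichols per river; no environment structure)
    f = config.river_fst_target
    anc = rng.uniform(0.1, 0.9, size=config.n_snps)
    a, b = anc * (1 - f) / f, (1 - anc) * (1 - f) / f
    freq = {r: rng.beta(a, b) for r in _RIVERS}
    genotypes = np.zeros((n_samples, config.n_snps), dtype=np.int64)
    for i, river in enumerate(metadata["river"]):
        genotypes[i] = rng.binomial(2, freq[river])
    snp_chrom = rng.choice(chrom_names, size=config.n_snps)
    snp_pos = rng.integers(1, config.chromosome_length_bp, size=config.n_snps)
    refalt = np.array([rng.choice(4, size=2, replace=False) for _ in range(config.n_snps)])
    variants = pd.DataFrame(
        {
            "chromosome": snp_chrom,
            "position": snp_pos,
            "ref": [_BASES[i] for i in refalt[:, 0]],
            "alt": [_BASES[i] for i in refalt[:, 1]],
        }
    ).sort_values(["chromosome", "position"])
    genotypes = genotypes[:, variants.index.to_numpy()]
    variants = variants.reset_index(drop=True)

    return SyntheticDataset(
        config=config,
        methylomes=methylomes,
        genotypes=genotypes,
        variants=variants,
        metadata=metadata,
        truth=truth,
    )


def simulate_varpart_matrix(
    n_samples: int,
    n_features: int,
    frac_env: float,
    frac_genetic: float,
    n_genetic_axes: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SyntheticTruth]:
    """Construct a samples x CpGs matrix with exact variance fractions.

    The environment contrast, the genetic axes and the noise component are
    mutually orthogonalized and rescaled so their realized sums of squares are
    exactly ``frac_env`` : ``frac_genetic`` : remainder.  Returns
    (Y, environment_indicator, genetic_axes, truth).
    """
    if frac_env < 0 or frac_genetic < 0 or frac_env + frac_genetic > 1:
        raise ValueError("fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    x_env = np.array([0.5] * half + [-0.5] * (n_samples - half))
    x_env = x_env - x_env.mean()
    g = rng.standard_normal((n_samples, n_genetic_axes))
    g -= g.mean(axis=0)
    # orthogonalize genetic axes against the environment contrast
    g -= np.outer(x_env, x_env @ g) / (x_env @ x_env)
    qg, _ = np.linalg.qr(g)

    def _scaled(component: np.ndarray, target_ss: float) -> np.ndarray:
        ss = (component**2).sum()
        return component * np.sqrt(target_ss / ss) if ss > 0 else component

    u_env = np.outer(x_env, rng.standard_normal(n_features))
    u_gen = qg @ rng.standard_normal((n_genetic_axes, n_features))
    noise = rng.standard_normal((n_samples, n_features))
    noise -= noise.mean(axis=0)
    basis = np.column_stack([x_env / np.linalg.norm(x_env), qg])
    noise -= basis @ (basis.T @ noise)
    y = (
        _scaled(u_env, frac_env)
        + _scaled(u_gen, frac_genetic)
        + _scaled(noise, 1 - frac_env - frac_genetic)
    )
    truth = SyntheticTruth(
        planted_env_fraction=frac_env, planted_genetic_fraction=frac_genetic
    )
    return y, x_env[:, None], qg, truth


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixtures(dataset: SyntheticDataset, out_dir) -> dict[str, object]:
    """Write the dataset as plain-text fixtures.

    One MethPipe-style symmetric-CpG table per sample, a multi-sample VCF 4.2
    (GT:DP), a metadata table and a BED6+ truth table.  Files round-trip
    losslessly through :mod:`methscales.methio` and :mod:`methscales.popgen`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {"methylomes": {}}

    mm = dataset.methylomes
    chroms = mm.sites["chromosome"].to_numpy()
    positions = mm.sites["position"].to_numpy()
    for i, sample in enumerate(mm.samples):
        p = out / f"{sample}.meth.tsv"
        with open(p, "w") as fh:
            for c, pos, x, n in zip(chroms, positions, mm.methylated[i], mm.coverage[i]):
                frac = x / n if n > 0 else 0.0
                fh.write(f"{c}\t{pos}\t+\tCpG\t{frac:.6f}\t{n}\n")
        paths["methylomes"][sample] = p

    vcf_path = out / "genotypes.vcf"
    _write_vcf(dataset, vcf_path)
    paths["vcf"] = vcf_path

    meta_path = out / "metadata.tsv"
    dataset.metadata.to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path

    truth_path = out / "truth_regions.bed"
    rows = []
    for kind, regions in (
        ("environment", dataset.truth.planted_dmrs),
        ("river", dataset.truth.planted_river_regions),
    ):
        for j, (chrom, start, end, delta, direction) in enumerate(regions):
            rows.append(
                (chrom, start, end, f"{kind}_{j}", 0, ".", f"{delta:.4f}", direction, kind)
            )
    pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "name", "score", "strand",
                 "delta", "direction", "kind"],
    ).sort_values(["chromosome", "start"]).to_csv(
        truth_path, sep="\t", index=False, header=False
    )
    paths["truth"] = truth_path
    return paths


def _write_vcf(dataset: SyntheticDataset, path) -> None:
    cfg = dataset.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD9]))
    n_samples, n_snps = dataset.genotypes.shape
    depth = rng.poisson(cfg.genotype_mean_depth, size=(n_snps, n_samples)) + 1
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=methscales-simulate\n")
        for c in sorted(dataset.variants["chromosome"].unique()):
            fh.write(f"##contig=<ID={c},length={cfg.chromosome_length_bp}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.metadata["sample_id"])
            + "\n"
        )
        for j in range(len(dataset.variants)):
            var = dataset.variants.iloc[j]
            dos = dataset.genotypes[:, j]
            cells = "\t".join(
                f"{gt_str[int(d)]}:{int(depth[j, i])}" for i, d in enumerate(dos)
            )
            fh.write(
                f"{var['chromosome']}\t{int(var['position'])}\t.\t{var['ref']}\t"
                f"{var['alt']}\t50\tPASS\t.\tGT:DP\t{cells}\n"
            )
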