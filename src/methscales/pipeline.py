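"""End-to-end orchestration: simulate/load -> window -> ordinate (genome-wide
and per chromosome) -> DMR calling -> label-randomization null -> F_ST and
genetic db-RDA -> variance partitioning -> annotation.

Every stage draws its randomness from a sub-seed derived deterministically
from the global seed and the stage name, so stage outputs are pure functions
of (inputs, config, seed) and reruns are bit-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dmr as dmr_mod
from . import methio, ordination, popgen, randomization, varpart
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "report_summary", "stage_rng"]


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults.

    ``simulation`` holds the synthetic-cohort block; alternatively
    ``methylation_tables``/``vcf``/``metadata`` point at input files.
    """

    out_dir: str = "methscales_out"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    methylation_tables: dict | None = None  # sample_id -> path
    methylation_dialect: str = "methpipe"
    vcf: str | None = None
    metadata: str | None = None
    transcripts: str | None = None
    min_coverage: int = 10
    window_size_bp: int = 1000
    window_step_bp: int = 1000
    window_min_cpgs: int = 3
    axis_threshold: float = 0.03
    n_perm: int = 999
    dmr_params: dict = field(default_factory=dict)
    n_randomizations: int = 100
    variant_filters: dict = field(default_factory=dict)
    genetic_variance_target: float = 0.90
    annotation_flank_bp: int = 5000
    bh_correction: bool = False  # optional BH column on per-chromosome p-values

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator: the stage name is hashed (CRC-32)
    and entangled with the global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


def _load_inputs(config: PipelineConfig):
    if config.methylation_tables:
        records = {
            s: methio.merge_symmetric_cpgs(
                methio.read_methylation_table(p, config.methylation_dialect)
            )
            for s, p in config.methylation_tables.items()
        }
        meth = methio.matrix_from_records(records)
        metadata = pd.read_csv(config.metadata, sep="\t")
        genotypes = None
        truth = None
        if config.vcf:
            params = popgen.VariantFilterParams(**config.variant_filters)
            genotypes = popgen.filter_variants(config.vcf, params)
        return meth, metadata, genotypes, truth
    sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
    ds = simulate_cohort(sim_cfg)
    gm = popgen.GenotypeMatrix(
        samples=list(ds.metadata["sample_id"]),
        variants=ds.variants,
        dosages=ds.genotypes.astype(float),
    )
    return ds.methylomes, ds.metadata, gm, ds.truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; writes tab-delimited artifacts plus a JSON manifest
    under ``config.out_dir`` and returns the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    bundle: dict[str, object] = {"config": config}

    meth_raw, metadata, genotypes, truth = _load_inputs(config)
    meth = methio.filter_coverage(meth_raw, min_cov=config.min_coverage)
    bundle["metadata"] = metadata
    bundle["truth"] = truth

    # ---- windowing
    wm = methio.window_methylation(
        meth,
        size_bp=config.window_size_bp,
        step_bp=config.window_step_bp,
        min_cpgs=config.window_min_cpgs,
    )
    methio.write_window_matrix(wm, out / "window_matrix.tsv")
    artifacts["window_matrix"] = "window_matrix.tsv"
    bundle["window_matrix"] = wm

    # ---- genome-wide db-RDA (+ partial models per term)
    rng_ord = stage_rng(config.seed, "ordinate")
    rows = []
    genome_full = ordination.dbrda(
        wm.values, metadata, ["environment", "river"],
        axis_threshold=config.axis_threshold, n_perm=config.n_perm, seed=rng_ord,
        labels=wm.samples,
    )
    rows.append(_rda_row("genome", "all", "environment+river", "", genome_full, config))
    genome_partials = {}
    for term in ("environment", "river"):
        other = "river" if term == "environment" else "environment"
        res = ordination.dbrda(
            wm.values, metadata, [term], conditioned=[other],
            axis_threshold=config.axis_threshold, n_perm=config.n_perm, seed=rng_ord,
            labels=wm.samples,
        )
        genome_partials[term] = res
        rows.append(_rda_row("genome", "all", term, other, res, config))
    bundle["genome_dbrda"] = {"full": genome_full, "partial": genome_partials}
    pd.DataFrame(rows).to_csv(out / "dbrda_genome.tsv", sep="\t", index=False)
    artifacts["dbrda_genome"] = "dbrda_genome.tsv"

    # ---- per-chromosome db-RDA
    chrom_rows = []
    chrom_results = {}
    for chrom in pd.unique(wm.windows["chromosome"]):
        sub = wm.subset_chromosome(chrom)
        if sub.n_windows < 3:
            continue
        full = ordination.dbrda(
            sub.values, metadata, ["environment", "river"],
            axis_threshold=config.axis_threshold, n_perm=config.n_perm, seed=rng_ord,
            labels=sub.samples,
        )
        entry = {"full": full, "partial": {}}
        chrom_rows.append(_rda_row("chromosome", chrom, "environment+river", "", full, config))
        for term in ("environment", "river"):
            other = "river" if term == "environment" else "environment"
            res = ordination.dbrda(
                sub.values, metadata, [term], conditioned=[other],
                axis_threshold=config.axis_threshold, n_perm=config.n_perm, seed=rng_ord,
                labels=sub.samples,
            )
            entry["partial"][term] = res
            chrom_rows.append(_rda_row("chromosome", chrom, term, other, res, config))
        chrom_results[chrom] = entry
    chrom_df = pd.DataFrame(chrom_rows)
    if config.bh_correction and not chrom_df.empty:
        from scipy.stats import false_discovery_control

        chrom_df["p_bh"] = false_discovery_control(chrom_df["p"].to_numpy())
    chrom_df.to_csv(out / "dbrda_chromosome.tsv", sep="\t", index=False)
    artifacts["dbrda_chromosome"] = "dbrda_chromosome.tsv"
    bundle["chromosome_dbrda"] = chrom_results

    # ---- DMR calling (environment and river terms)
    params = dmr_mod.DMRParams(**config.dmr_params)
    design = dmr_mod.build_design(metadata)
    tests = dmr_mod.fit_cpg_model(meth, design, min_coverage=config.min_coverage)
    bundle["cpg_tests"] = tests
    dmr_sets = {}
    for term in ("environment", "river"):
        called = dmr_mod.call_dmrs(tests, meth, metadata, term=term, params=params)
        kept = dmr_mod.filter_dmrs_by_effect(called, params.min_mean_diff)
        dmr_sets[term] = {"all": called, "filtered": kept}
        bed = dmr_mod.dmrs_to_bed(kept)
        bed.to_csv(out / f"dmrs_{term}.bed", sep="\t", index=False, header=False)
        artifacts[f"dmrs_{term}"] = f"dmrs_{term}.bed"
    bundle["dmrs"] = dmr_sets

    # ---- randomization null
    rng_rand = stage_rng(config.seed, "randomize")
    null = randomization.null_dmr_counts(
        meth,
        metadata,
        params=params,
        n_reps=config.n_randomizations,
        seed=int(rng_rand.integers(2**31)),
        min_coverage=config.min_coverage,
    )
    null_df = pd.DataFrame(
        {"replicate": range(1, len(null.replicate_counts) + 1),
         "seed": null.replicate_seeds,
         "dmr_count": null.replicate_counts}
    )
    null_df.to_csv(out / "randomization_null.tsv", sep="\t", index=False)
    artifacts["randomization_null"] = "randomization_null.tsv"
    bundle["randomization"] = null

    # ---- F_ST and genetic db-RDA
    if genotypes is not None and genotypes.n_variants > 0:
        fst_rows = []
        for grouping in ("river", "environment"):
            groups = metadata.set_index("sample_id").loc[genotypes.samples, grouping]
            _, overall = popgen.weir_cockerham_fst(genotypes.dosages, groups.to_numpy())
            fst_rows.append({"grouping": grouping, "overall_fst": overall,
                             "n_snps": genotypes.n_variants})
        fst_df = pd.DataFrame(fst_rows)
        fst_df.to_csv(out / "fst.tsv", sep="\t", index=False)
        artifacts["fst"] = "fst.tsv"
        bundle["fst"] = fst_df

        rng_gen = stage_rng(config.seed, "genetic_dbrda")
        gen = popgen.genotype_pcoa_rda(
            genotypes, metadata, axis_threshold=config.axis_threshold,
            n_perm=config.n_perm, seed=rng_gen,
        )
        gen_rows = [_rda_row("genetic", "all", "environment+river", "", gen["full"], config)]
        for term, res in gen["partial"].items():
            gen_rows.append(_rda_row("genetic", "all", term, res.conditioned_terms[0], res, config))
        pd.DataFrame(gen_rows).to_csv(out / "dbrda_genetic.tsv", sep="\t", index=False)
        artifacts["dbrda_genetic"] = "dbrda_genetic.tsv"
        bundle["genetic_dbrda"] = gen

        # ---- variance partitioning of DMR CpGs
        var_rows = []
        varpart_results = {}
        gen_pcoa = gen["pcoa"]
        gsel = varpart.axes_for_variance_fraction(
            gen_pcoa.relative_eigenvalues, target=config.genetic_variance_target
        )
        max_axes = len(metadata) - 3
        gen_axes = gen_pcoa.coordinates[:, : min(gsel.n_axes, max_axes)]
        env_x, _ = ordination.design_matrix(metadata, ["environment"])
        for term in ("environment", "river"):
            kept = dmr_sets[term]["filtered"]
            ymat = _dmr_cpg_matrix(meth, kept)
            if ymat is None:
                continue
            part, sel = varpart.partition_dmr_variation(ymat, env_x, gen_axes)
            varpart_results[term] = {"partition": part, "axes": sel,
                                     "n_genetic_axes": gen_axes.shape[1]}
            var_rows.append(
                {"dmr_set": term, "environment_pure": part.frac_x1_pure,
                 "genetic_pure": part.frac_x2_pure, "shared": part.frac_shared,
                 "residual": part.frac_residual, "response_axes": sel.n_axes,
                 "genetic_axes": gen_axes.shape[1]}
            )
        pd.DataFrame(var_rows).to_csv(out / "varpart.tsv", sep="\t", index=False)
        artifacts["varpart"] = "varpart.tsv"
        bundle["varpart"] = varpart_results

    # ---- annotation
    ann_frames = []
    if config.transcripts:
        transcripts = dmr_mod.read_intervals(config.transcripts)
        for term in ("environment", "river"):
            tab = dmr_mod.annotate_dmrs(
                dmr_sets[term]["filtered"], transcripts, flank_bp=config.annotation_flank_bp
            )
            ann_frames.append(tab)
    ann = pd.concat(ann_frames, ignore_index=True) if ann_frames else pd.DataFrame()
    ann.to_csv(out / "dmr_annotation.tsv", sep="\t", index=False)
    artifacts["dmr_annotation"] = "dmr_annotation.tsv"
    bundle["annotation"] = ann

    # ---- manifest
    artifacts["manifest"] = "manifest.json"
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    bundle["manifest"] = manifest
    return bundle


def _rda_row(scale, chrom, terms, conditioned, res, config):
    return {
        "scale": scale,
        "chromosome": chrom,
        "terms": terms,
        "conditioned": conditioned,
        "r2": res.r2,
        "adj_r2": res.adj_r2,
        "f": res.f_statistic,
        "p": res.permutation_p,
        "n_perm": config.n_perm,
        "seed": config.seed,
    }


def _dmr_cpg_matrix(meth, dmrs):
    """Samples x CpGs fraction matrix over the constituent CpGs of a DMR set
    (mean-imputed where a cell is uncovered)."""
    if not dmrs:
        return None
    masks = []
    chroms = meth.sites["chromosome"].to_numpy()
    positions = meth.sites["position"].to_numpy()
    for d in dmrs:
        masks.append((chroms == d.chromosome) & np.isin(positions, d.cpg_positions))
    mask = np.logical_or.reduce(masks)
    frac = meth.fractions()[:, mask]
    col_mean = np.nanmean(frac, axis=0)
    idx = np.where(np.isnan(frac))
    frac[idx] = col_mean[idx[1]]
    return frac


def report_summary(bundle: dict) -> str:
    """One-page human-readable summary of a pipeline bundle."""
    lines = ["methscales pipeline summary", "=" * 28]
    wm = bundle.get("window_matrix")
    if wm is not None:
        lines.append(f"windows retained: {wm.n_windows} ({len(wm.samples)} samples)")
    gd = bundle.get("genome_dbrda")
    if gd:
        full = gd["full"]
        lines.append(
            f"genome db-RDA (environment+river): adjR2={full.adj_r2:.4f} p={full.permutation_p}"
        )
        for term, res in gd["partial"].items():
            lines.append(
                f"  partial [{term} | {','.join(res.conditioned_terms)}]: "
                f"adjR2={res.adj_r2:.4f} p={res.permutation_p}"
            )
    cd = bundle.get("chromosome_dbrda")
    if cd:
        sig = [c for c, e in cd.items() if (e["full"].permutation_p or 1) <= 0.05]
        lines.append(f"chromosome models significant at alpha=0.05: {len(sig)}/{len(cd)} {sig}")
    dmrs = bundle.get("dmrs")
    if dmrs:
        for term, sets in dmrs.items():
            kept = sets["filtered"]
            lines.append(
                f"{term} DMRs: {len(sets['all'])} called, {len(kept)} after effect filter"
            )
            if kept:
                n_hyper = sum(1 for d in kept if d.mean_diff > 0)
                n_hypo = sum(1 for d in kept if d.mean_diff < 0)
                if n_hyper + n_hypo:
                    from .dmr import enrichment_test

                    chi2, p = enrichment_test(n_hyper, n_hypo)
                    lines.append(
                        f"  hyper/hypo {n_hyper}/{n_hypo}: chi2={chi2:.2f} p={p:.3g}"
                    )
            else:
                lines.append("  no DMRs retained; enrichment skipped")
    rnd = bundle.get("randomization")
    if rnd:
        lines.append(
            f"randomization null: observed={rnd.observed_count} mean={rnd.mean:.1f} "
            f"95% interval=({rnd.percentile_interval[0]:.1f}, "
            f"{rnd.percentile_interval[1]:.1f}) empirical p={rnd.empirical_p:.4f}"
        )
    fst = bundle.get("fst")
    if fst is not None:
        for _, row in fst.iterrows():
            lines.append(f"F_ST by {row['grouping']}: {row['overall_fst']:.4f}")
    vp = bundle.get("varpart")
    if vp:
        for term, entry in vp.items():
            part = entry["partition"]
            lines.append(
                f"varpart [{term} DMR CpGs]: environment pure={part.frac_x1_pure:.3f} "
                f"genetic pure={part.frac_x2_pure:.3f} shared={part.frac_shared:.3f}"
            )
    missing = [k for k in ("window_matrix", "genome_dbrda", "dmrs", "randomization")
               if k not in bundle]
    if missing:
        lines.append(f"sections unavailable: {', '.join(missing)}")
    return "\n".join(lines)
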