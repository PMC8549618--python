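import numpy as np
import pandas as pd
import pytest

from methscales import dmr as D
from methscales.methio import MethylomeMatrix, filter_coverage
from methscales.simulate import SimulationConfig, simulate_cohort

from conftest import make_metadata


def _matrix(positions, meth, cov, samples, chrom="chr1"):
    sites = pd.DataFrame({"chromosome": chrom, "position": positions})
    return MethylomeMatrix(
        samples=samples, sites=sites, methylated=np.asarray(meth), coverage=np.asarray(cov)
    )


def _meta8():
    return make_metadata(2)  # 2 rivers x 2 envs x 2 = 8 samples


# ---------------------------------------------------------------------------
# per-CpG model


class TestFitCpGModel:
    def test_identical_groups_give_zero_coefficient_and_p_one(self):
        meta = _meta8()
        cov = np.full((8, 1), 20)
        meth = np.full((8, 1), 10)
        m = _matrix([100], meth, cov, list(meta["sample_id"]))
        tests = D.fit_cpg_model(m, D.build_design(meta))
        assert tests["coef_environment"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert tests["p_environment"].iloc[0] == pytest.approx(1.0)

    def test_saturated_difference_gives_tiny_p(self):
        meta = _meta8()
        hatch = (meta["environment"] == "hatchery").to_numpy()
        cov = np.full((8, 1), 20)
        meth = np.where(hatch[:, None], 20, 0)
        m = _matrix([100], meth, cov, list(meta["sample_id"]))
        tests = D.fit_cpg_model(m, D.build_design(meta))
        assert tests["p_environment"].iloc[0] < 1e-10
        assert abs(tests["stat_environment"].iloc[0]) > 6

    def test_matches_statsmodels_wls_oracle(self):
        """Coefficients equal an independent weighted-least-squares fit of the
        arcsine-transformed fractions (shrinkage only rescales the SEs)."""
        import statsmodels.api as sm

        meta = _meta8()
        rng = np.random.default_rng(0)
        cov = rng.integers(10, 40, size=(8, 3))
        meth = rng.binomial(cov, 0.5)
        m = _matrix([100, 200, 300], meth, cov, list(meta["sample_id"]))
        design = D.build_design(meta)
        tests = D.fit_cpg_model(m, design)
        y = np.arcsin(2 * meth / cov - 1)
        for j in range(3):
            fit = sm.WLS(y[:, j], design.matrix, weights=cov[:, j]).fit()
            for k, term in enumerate(design.column_terms, start=1):
                assert tests[f"coef_{term}"].iloc[j] == pytest.approx(
                    fit.params[k], abs=1e-10
                )

    def test_low_coverage_cells_excluded(self):
        meta = make_metadata(3)  # 12 samples, 3 per cell
        cov = np.full((12, 1), 20)
        cov[0, 0] = 5  # below floor -> zero weight; cell keeps 2 samples
        meth = np.minimum(cov, 8)
        m = _matrix([100], meth, cov, list(meta["sample_id"]))
        tests = D.fit_cpg_model(m, D.build_design(meta), min_coverage=10)
        assert tests["n_used"].iloc[0] == 11

    def test_sparse_cell_skipped(self):
        meta = _meta8()
        cov = np.full((8, 1), 20)
        hatch_conuma = (
            (meta["environment"] == "hatchery") & (meta["river"] == "conuma")
        ).to_numpy()
        cov[hatch_conuma, 0] = 3  # entire design cell uncovered
        m = _matrix([100], np.minimum(cov, 2), cov, list(meta["sample_id"]))
        tests = D.fit_cpg_model(m, D.build_design(meta), min_coverage=10)
        assert tests.empty

    def test_null_p_values_uniform(self):
        """On a zero-effect cohort the environment p-value distribution is
        approximately uniform (KS D < 0.05 at ~10^4 CpGs)."""
        from scipy.stats import kstest

        cfg = SimulationConfig(
            seed=7, n_planted_dmrs=0, dmr_effect_delta=0.0,
            river_effect_regions=0, river_effect_delta=0.0,
            n_chromosomes=1, chromosome_length_bp=320_000, n_snps=10,
        )
        ds = simulate_cohort(cfg)
        meth = filter_coverage(ds.methylomes, 10)
        tests = D.fit_cpg_model(meth, D.build_design(ds.metadata))
        assert len(tests) > 8000
        stat = kstest(tests["p_environment"], "uniform").statistic
        assert stat < 0.05


# ---------------------------------------------------------------------------
# caller


def _tests_frame(positions, pvals, chrom="chr1"):
    return pd.DataFrame(
        {"chromosome": chrom, "position": positions, "p_environment": pvals}
    )


def _uniform_matrix(positions, meta, hatchery_frac, wild_frac, chrom="chr1"):
    """Coverage-20 matrix with group-constant methylation fractions."""
    hatch = (meta["environment"] == "hatchery").to_numpy()
    n, s = len(meta), len(positions)
    cov = np.full((n, s), 20)
    meth = np.where(hatch[:, None], int(hatchery_frac * 20), int(wild_frac * 20))
    return _matrix(positions, meth, cov, list(meta["sample_id"]), chrom=chrom)


class TestCallDMRs:
    def test_twelve_significant_cpgs_over_150bp_give_one_dmr(self):
        meta = _meta8()
        positions = [100 + round(i * 150 / 11) for i in range(12)]
        tests = _tests_frame(positions, [0.001] * 12)
        m = _uniform_matrix(positions, meta, 0.8, 0.4)
        dmrs = D.call_dmrs(tests, m, meta, term="environment")
        assert len(dmrs) == 1
        assert dmrs[0].n_cpgs == 12
        assert dmrs[0].frac_significant == 1.0

    def test_short_span_rejected_by_min_length(self):
        meta = _meta8()
        positions = [100 + round(i * 90 / 11) for i in range(12)]  # 90 bp span
        tests = _tests_frame(positions, [0.001] * 12)
        m = _uniform_matrix(positions, meta, 0.8, 0.4)
        assert D.call_dmrs(tests, m, meta, term="environment") == []

    def test_nine_cpgs_rejected_by_min_count(self):
        meta = _meta8()
        positions = [100 + i * 20 for i in range(9)]  # 160 bp span, 9 CpGs
        tests = _tests_frame(positions, [0.001] * 9)
        m = _uniform_matrix(positions, meta, 0.8, 0.4)
        assert D.call_dmrs(tests, m, meta, term="environment") == []

    @staticmethod
    def _two_blocks(unflagged_spacing):
        """Two 12-CpG fully flagged blocks separated by 20 unflagged CpGs
        (enough to break the run on the flagged-fraction rule); the genomic
        gap between the surviving regions is set by the unflagged spacing."""
        pos_a = [100 + i * 15 for i in range(12)]  # span 165, region end 267
        between = [pos_a[-1] + 5 + unflagged_spacing * k for k in range(20)]
        start_b = between[-1] + unflagged_spacing + 2
        pos_b = [start_b + i * 15 for i in range(12)]
        positions = pos_a + between + pos_b
        pvals = [0.001] * 12 + [0.5] * 20 + [0.001] * 12
        return positions, pvals, (start_b - (pos_a[-1] + 2))

    def test_regions_forty_four_bp_apart_are_merged(self):
        meta = _meta8()
        positions, pvals, gap = self._two_blocks(unflagged_spacing=2)
        assert gap <= 50
        tests = _tests_frame(positions, pvals)
        m = _uniform_matrix(positions, meta, 0.8, 0.4)
        dmrs = D.call_dmrs(tests, m, meta, term="environment")
        assert len(dmrs) == 1
        assert dmrs[0].n_cpgs == 44  # both blocks plus intervening CpGs

    def test_regions_beyond_merge_distance_stay_separate(self):
        meta = _meta8()
        positions, pvals, gap = self._two_blocks(unflagged_spacing=3)
        assert gap > 50
        tests = _tests_frame(positions, pvals)
        m = _uniform_matrix(positions, meta, 0.8, 0.4)
        assert len(D.call_dmrs(tests, m, meta, term="environment")) == 2

    def test_p_equal_to_threshold_is_not_significant(self):
        meta = _meta8()
        positions = [100 + i * 15 for i in range(12)]
        tests = _tests_frame(positions, [0.01] * 12)  # ties at threshold
        m = _uniform_matrix(positions, meta, 0.8, 0.4)
        assert D.call_dmrs(tests, m, meta, term="environment") == []

    def test_empty_tests_give_empty_result(self):
        meta = _meta8()
        m = _uniform_matrix([100], meta, 0.5, 0.5)
        assert D.call_dmrs(_tests_frame([], []), m, meta) == []

    def test_output_invariant_to_chromosome_order(self, cohort, filtered_meth):
        tests = D.fit_cpg_model(filtered_meth, D.build_design(cohort.metadata))
        shuffled = tests.sort_values(
            ["chromosome", "position"], ascending=[False, True]
        )
        a = D.call_dmrs(tests, filtered_meth, cohort.metadata)
        b = D.call_dmrs(shuffled, filtered_meth, cohort.metadata)
        key = lambda d: (d.chromosome, d.start, d.end, d.n_cpgs)
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_every_dmr_satisfies_caller_constraints(self, cohort, filtered_meth):
        params = D.DMRParams()
        tests = D.fit_cpg_model(filtered_meth, D.build_design(cohort.metadata))
        for d in D.call_dmrs(tests, filtered_meth, cohort.metadata, params=params):
            assert d.end - d.start >= params.min_len_bp
            assert d.n_cpgs >= params.min_cpgs
            assert d.frac_significant >= params.pct_sig
            assert 0 <= d.mean_meth_hatchery <= 1 and 0 <= d.mean_meth_wild <= 1

    def test_group_means_match_raw_count_recomputation(self, cohort, filtered_meth):
        tests = D.fit_cpg_model(filtered_meth, D.build_design(cohort.metadata))
        dmrs = D.call_dmrs(tests, filtered_meth, cohort.metadata)
        assert dmrs, "expected planted DMRs to be called"
        frac = filtered_meth.fractions()
        hatch = (
            cohort.metadata.set_index("sample_id")
            .loc[filtered_meth.samples, "environment"]
            .to_numpy()
            == "hatchery"
        )
        chroms = filtered_meth.sites["chromosome"].to_numpy()
        positions = filtered_meth.sites["position"].to_numpy()
        for d in dmrs[:5]:
            mask = (chroms == d.chromosome) & np.isin(positions, d.cpg_positions)
            mu_h = np.nanmean(np.nanmean(frac[hatch][:, mask], axis=0))
            mu_w = np.nanmean(np.nanmean(frac[~hatch][:, mask], axis=0))
            assert d.mean_meth_hatchery == pytest.approx(mu_h, abs=1e-9)
            assert d.mean_meth_wild == pytest.approx(mu_w, abs=1e-9)


# ---------------------------------------------------------------------------
# effect filter, direction, enrichment


def _dmr(mean_h, mean_w):
    return D.DMR(
        chromosome="chr1", start=0, end=200, n_cpgs=12, frac_significant=1.0,
        mean_meth_hatchery=mean_h, mean_meth_wild=mean_w, term="environment",
        min_p=1e-4,
    )


class TestEffectFilterAndDirection:
    @pytest.mark.parametrize(
        "diff,kept", [(0.09, False), (0.10, False), (0.11, True), (-0.11, True)]
    )
    def test_effect_filter_is_strict(self, diff, kept):
        dmrs = D.filter_dmrs_by_effect([_dmr(0.5 + diff, 0.5)], 0.10)
        assert bool(dmrs) is kept

    def test_empty_input(self):
        assert D.filter_dmrs_by_effect([]) == []

    def test_direction_hyper(self):
        assert D.classify_direction(_dmr(0.6, 0.4)) == "hyper"

    def test_direction_hypo(self):
        assert D.classify_direction(_dmr(0.2, 0.5)) == "hypo"

    def test_equal_means_undefined(self):
        with pytest.raises(ValueError):
            D.classify_direction(_dmr(0.5, 0.5))


class TestEnrichment:
    def test_balanced_counts(self):
        chi2, p = D.enrichment_test(50, 50)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_ten_vs_zero(self):
        chi2, _ = D.enrichment_test(10, 0)
        assert chi2 == pytest.approx(10.0)

    def test_116_vs_67_closed_form(self):
        chi2, p = D.enrichment_test(116, 67)
        assert chi2 == pytest.approx((116 - 91.5) ** 2 / 91.5 * 2, abs=1e-9)
        assert chi2 == pytest.approx(13.12, abs=0.01)
        assert p < 0.001

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            D.enrichment_test(0, 0)


# ---------------------------------------------------------------------------
# annotation


class TestAnnotateDMRs:
    def _transcripts(self, rows):
        return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name"])

    def test_direct_overlap_reported(self):
        tab = D.annotate_dmrs(
            [_dmr(0.6, 0.4)], self._transcripts([("chr1", 100, 3000, "t1")])
        )
        assert len(tab) == 1 and tab["transcript"].iloc[0] == "t1"

    def test_flank_rescues_nearby_transcript(self):
        tx = self._transcripts([("chr1", 4200, 6000, "t1")])  # 4 kb past DMR end
        assert len(D.annotate_dmrs([_dmr(0.6, 0.4)], tx, flank_bp=0)) == 0
        assert len(D.annotate_dmrs([_dmr(0.6, 0.4)], tx, flank_bp=5000)) == 1

    def test_abutting_interval_not_overlapping(self):
        # half-open: transcript starting exactly at dmr.end does not overlap
        tx = self._transcripts([("chr1", 200, 300, "t1")])
        assert len(D.annotate_dmrs([_dmr(0.6, 0.4)], tx, flank_bp=0)) == 0

    def test_empty_transcripts(self):
        tab = D.annotate_dmrs([_dmr(0.6, 0.4)], self._transcripts([]))
        assert tab.empty

    def test_gff_intervals_converted_to_zero_based(self, tmp_path):
        p = tmp_path / "tx.gff3"
        p.write_text("chr1\tsrc\tmRNA\t101\t300\t.\t+\t.\tID=tx1\n")
        df = D.read_intervals(p)
        assert df.iloc[0]["start"] == 100 and df.iloc[0]["end"] == 300
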