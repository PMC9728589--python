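"""Generator contracts: determinism, frequency conservation, selection
closed form, noise calibration, cheater structure, coverage and pooled
reads."""

import numpy as np
import pytest

import haplovolve as hv
from haplovolve.classify import per_site_heterozygosity
from haplovolve.simulate import SimulationConfig, expected_selected_frequency


class TestFounderPanel:
    def test_panel_shape_and_base_normalization(self, toy_grid, panel_and_base):
        panel, base = panel_and_base
        assert len(panel.labels) == 18
        assert panel.n_snps > 0
        # every SNP segregates
        counts = panel.genotypes.sum(axis=1)
        assert counts.min() >= 1 and counts.max() <= 17
        assert np.allclose(base.freqs.sum(axis=1), 1.0, atol=1e-9)
        assert base.n_loci == toy_grid.n_loci()

    def test_private_snp_maf_matches_design(self, panel, base_table):
        # private-SNP minor-allele frequency tracks the carrier haplotype
        # frequency, near-uniform across 18 founders (~5%)
        priv = panel.private
        assert 0.2 < priv.mean() < 0.5
        carrier = panel.genotypes[priv].argmax(axis=1)
        maf = base_table.freqs.mean(axis=0)[carrier]
        assert 0.03 < maf.mean() < 0.08

    def test_determinism(self, toy_grid):
        p1, b1 = hv.simulate_founder_panel(toy_grid, seed=5)
        p2, b2 = hv.simulate_founder_panel(toy_grid, seed=5)
        assert np.array_equal(p1.genotypes, p2.genotypes)
        assert np.array_equal(b1.freqs, b2.freqs)

    def test_invalid_parameters(self, toy_grid):
        with pytest.raises(ValueError):
            hv.simulate_founder_panel(toy_grid, n_founders=1)
        with pytest.raises(ValueError):
            hv.simulate_founder_panel(toy_grid, snp_density=0.0)

    def test_twin_windows_exercise_merging(self, toy_grid, panel):
        # at least one window holds an indistinguishable founder pair
        merged = 0
        for chrom in toy_grid.chromosomes:
            for pos in toy_grid.loci(chrom)[::10]:
                start, end = toy_grid.window_of(chrom, int(pos))
                fmap = hv.collapse_indistinguishable(panel, (chrom, start, end))
                if len(fmap.groups) < len(panel.labels):
                    merged += 1
        assert merged > 0


class TestEvolution:
    def test_neutral_infinite_ne_preserves_frequencies(self, base_table):
        cfg = SimulationConfig(ne=np.inf, n_replicates=2, seed=3)
        reps, _ = hv.simulate_evolution(base_table, cfg)
        for rep in reps:
            assert np.allclose(rep.freqs, base_table.freqs, atol=1e-9)

    def test_selection_matches_closed_form(self, base_table):
        cfg = SimulationConfig(
            ne=np.inf,
            selected_loci=(("chr01", 150_000),),
            selection_coefficients=(0.05,),
            target_haplotypes=("A3",),
            n_replicates=1,
            seed=3,
        )
        reps, truth = hv.simulate_evolution(base_table, cfg)
        i = np.flatnonzero(
            (base_table.chrom == "chr01") & (base_table.pos == 150_000)
        )[0]
        p0 = base_table.freqs[i, 2]
        expected = expected_selected_frequency(p0, 0.05, 216)
        assert reps[0].freqs[i, 2] == pytest.approx(expected, abs=1e-9)
        assert truth.expected_trajectories[0][-1] == pytest.approx(expected)

    def test_closed_form_example(self):
        # p0=0.05, s=0.05, 216 generations
        expected = 0.05 * 1.05**216 / (0.05 * 1.05**216 + 0.95)
        assert expected_selected_frequency(0.05, 0.05, 216) == pytest.approx(
            expected, rel=1e-12
        )

    def test_drift_determinism_and_normalization(self, base_table):
        cfg = SimulationConfig(ne=750_000, n_replicates=2, seed=5)
        r1, _ = hv.simulate_evolution(base_table, cfg)
        r2, _ = hv.simulate_evolution(base_table, cfg)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.freqs, b.freqs)
        assert np.allclose(r1[0].freqs.sum(axis=1), 1.0, atol=1e-9)
        # replicates use independent streams
        assert not np.array_equal(r1[0].freqs, r1[1].freqs)

    def test_absent_target_skipped_with_warning(self, base_table):
        base = base_table.copy()
        i = 0
        base.freqs[i] /= base.freqs[i, 1:].sum()
        base.freqs[i, 0] = 0.0
        base.freqs[i] /= base.freqs[i].sum()
        cfg = SimulationConfig(
            ne=np.inf,
            selected_loci=((str(base.chrom[i]), int(base.pos[i])),),
            selection_coefficients=(0.05,),
            target_haplotypes=("A1",),
            n_replicates=1,
            seed=1,
        )
        with pytest.warns(UserWarning, match="skipped"):
            reps, truth = hv.simulate_evolution(base, cfg)
        assert truth.selected_loci == ()
        assert np.allclose(reps[0].freqs, base.freqs, atol=1e-9)


class TestMeasurementNoise:
    def test_zero_sigma_is_identity(self, base_table):
        out = hv.add_measurement_noise(base_table, 0.0, seed=1)
        assert np.array_equal(out.freqs, base_table.freqs)

    def test_rows_renormalized(self, base_table):
        out = hv.add_measurement_noise(base_table, 0.01, seed=2)
        assert np.allclose(out.freqs.sum(axis=1), 1.0, atol=1e-12)
        assert out.freqs.min() >= 0.0

    def test_perturbation_magnitude_folded_normal(self, base_table):
        # for interior frequencies the mean absolute perturbation is close
        # to sigma * sqrt(2/pi); renormalization shifts it only slightly
        sigma = 0.01
        out = hv.add_measurement_noise(base_table, sigma, seed=3)
        mean_abs = np.abs(out.freqs - base_table.freqs).mean()
        assert mean_abs == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.15)


class TestCheaters:
    def test_haploid_heterozygosity_zero_off_mating_type(self, base_table):
        mt = ("chr01", 145_000, 155_000)
        t = hv.simulate_cheater(
            base_table, "aneuploid_haploid", seed=7, mating_type_window=mt
        )
        h = per_site_heterozygosity(t.freqs)
        in_mt = (t.chrom == "chr01") & (t.pos >= 145_000) & (t.pos <= 155_000)
        assert np.all(h[~in_mt] == 0.0)
        assert np.allclose(h[in_mt], 0.5)

    def test_diploid_heterozygosity_bimodal(self, base_table):
        t = hv.simulate_cheater(base_table, "clonal_diploid", seed=7)
        h = per_site_heterozygosity(t.freqs)
        assert set(np.round(np.unique(h), 6)) <= {0.0, 0.5}
        # both modes populated: the clone's two genomes share ancestry
        assert (h == 0.0).mean() > 0.1
        assert (h == 0.5).mean() > 0.1

    def test_determinism_and_unknown_kind(self, base_table):
        a = hv.simulate_cheater(base_table, "clonal_diploid", seed=9)
        b = hv.simulate_cheater(base_table, "clonal_diploid", seed=9)
        assert np.array_equal(a.freqs, b.freqs)
        with pytest.raises(ValueError, match="unknown cheater kind"):
            hv.simulate_cheater(base_table, "triploid", seed=9)


class TestCoverage:
    def test_no_duplications_gives_flat_ratio(self, toy_grid):
        cb, ce = hv.simulate_coverage(toy_grid, [], mean_cov=200, seed=3)
        ratio = hv.normalized_fold_coverage(cb, ce)
        assert np.nanmean(ratio) == pytest.approx(1.0, abs=0.02)

    def test_planted_duplication_doubles_fold_coverage(self, toy_grid):
        # small interval so the genome-mean normalization is barely moved
        dup = (("chr03", 100_001, 140_000), 2)
        cb, ce = hv.simulate_coverage(toy_grid, [dup], mean_cov=500, seed=4)
        ratio = hv.normalized_fold_coverage(cb, ce)
        inside = (
            (cb.chrom == "chr03") & (cb.start >= 100_001) & (cb.end <= 140_000)
        )
        assert np.nanmean(ratio[inside]) == pytest.approx(2.0, rel=0.05)

    def test_overlapping_duplications_rejected(self, toy_grid):
        dups = [(("chr01", 1000, 50_000), 1), (("chr01", 40_000, 90_000), 1)]
        with pytest.raises(ValueError, match="overlapping"):
            hv.simulate_coverage(toy_grid, dups, mean_cov=50, seed=1)

    def test_determinism(self, toy_grid):
        a = hv.simulate_coverage(toy_grid, [], mean_cov=50, seed=6)
        b = hv.simulate_coverage(toy_grid, [], mean_cov=50, seed=6)
        assert np.array_equal(a[0].coverage, b[0].coverage)
        assert np.array_equal(a[1].coverage, b[1].coverage)


class TestPoolReads:
    def test_high_coverage_recovers_truth(self, panel, base_table):
        df = hv.simulate_pool_reads(base_table, panel, coverage=10_000_000, seed=1)
        geno = panel.genotypes.astype(float)
        # recompute truth at the nearest locus for a subset
        sub = df.iloc[:: max(1, len(df) // 200)]
        for _, row in sub.iterrows():
            i = np.flatnonzero(panel.chrom == row["chrom"])
            j = i[panel.pos[i] == row["pos"]][0]
            loc = np.flatnonzero(base_table.chrom == row["chrom"])
            nearest = loc[np.argmin(np.abs(base_table.pos[loc] - row["pos"]))]
            truth = float(geno[j] @ base_table.freqs[nearest])
            assert row["freq"] == pytest.approx(truth, abs=1e-3)

    def test_binomial_variance(self, panel, base_table):
        cov = 100
        reps = np.stack(
            [
                hv.simulate_pool_reads(base_table, panel, coverage=cov, seed=s)[
                    "freq"
                ].to_numpy()
                for s in range(60)
            ]
        )
        mean_p = reps.mean(axis=0)
        interior = (mean_p > 0.2) & (mean_p < 0.8)
        ratio = reps.var(axis=0, ddof=1)[interior] / (
            mean_p[interior] * (1 - mean_p[interior]) / cov
        )
        assert ratio.mean() == pytest.approx(1.0, abs=0.15)

    def test_fixed_pool_reproduces_genotype(self, panel, base_table):
        fixed = base_table.copy()
        fixed.freqs[:] = 0.0
        fixed.freqs[:, 0] = 1.0
        df = hv.simulate_pool_reads(fixed, panel, coverage=100_000, seed=2)
        key = {(c, int(p)): i for i, (c, p) in enumerate(zip(panel.chrom, panel.pos))}
        idx = np.array([key[(c, int(p))] for c, p in zip(df["chrom"], df["pos"])])
        expected = panel.genotypes[idx, 0].astype(float)
        assert np.allclose(df["freq"], expected, atol=1e-2)
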