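"""MIH identification, repeatability metrics and the pleiotropy screen."""

import numpy as np
import pytest
from scipy import stats

import haplovolve as hv
from haplovolve.dynamics import (
    EmptySummaryError,
    MIHRecord,
    mih_deviation,
    mih_summary,
    most_increased_haplotype,
    zscore_lod,
)
from haplovolve.classify import per_site_heterozygosity
from haplovolve.simulate import SimulationConfig


def _table(freqs, population="p", labels=None):
    freqs = np.asarray(freqs, dtype=float)
    n, k = freqs.shape
    return hv.HaplotypeFrequencyTable(
        population=population,
        chrom=np.array(["c"] * n, dtype=object),
        pos=np.arange(1, n + 1) * 1000,
        labels=labels or tuple(f"A{i + 1}" for i in range(k)),
        freqs=freqs,
    )


class TestMIH:
    def test_simple_ranking(self):
        rec = most_increased_haplotype(
            np.array([0.5, 0.5]), np.array([[0.9, 0.1]]), ["A1", "A2"]
        )
        assert rec.mih == "A1" and rec.mih_change == pytest.approx(0.4)
        assert rec.next_mih == "A2" and rec.next_change == pytest.approx(-0.4)
        assert rec.mih_change >= rec.next_change

    def test_tie_breaks_to_smaller_label(self):
        base = np.array([0.25, 0.25, 0.5])
        evo = np.array([[0.35, 0.35, 0.3]])
        for perm in ([0, 1, 2], [1, 0, 2], [2, 1, 0]):
            labels = list(np.array(["A1", "A2", "A3"])[perm])
            rec = most_increased_haplotype(base[perm], evo[:, perm], labels)
            # A1 and A2 tie at +0.10; smaller label wins wherever it sits
            assert rec.mih == min(l for l in labels if l in ("A1", "A2"))

    def test_degenerate_locus_rejected(self):
        with pytest.raises(ValueError):
            most_increased_haplotype(np.array([1.0]), np.array([[1.0]]), ["A1"])


class TestMIHSummary:
    def _records(self, n, mih_change=0.4, next_change=0.1, next_starts_higher=False):
        return [
            MIHRecord("c", i, "A1", mih_change, "A2", next_change,
                      0.05 if next_starts_higher else 0.2,
                      0.2 if next_starts_higher else 0.05)
            for i in range(n)
        ]

    def test_identical_records(self):
        m, nx, ratio = mih_summary(self._records(5))
        assert (m, nx, ratio) == (pytest.approx(0.4), pytest.approx(0.1), pytest.approx(4.0))

    def test_conditioning_empty_signals(self):
        with pytest.raises(EmptySummaryError):
            mih_summary(self._records(5), condition="next-MIH-starts-higher")

    def test_conditioning_keeps_qualifying(self):
        recs = self._records(3) + self._records(2, next_starts_higher=True)
        m, nx, _ = mih_summary(recs, condition="next-MIH-starts-higher")
        assert m == pytest.approx(0.4)

    def test_scale_consistency(self):
        recs = self._records(4, 0.3, 0.1)
        m1, n1, r1 = mih_summary(recs)
        doubled = [
            MIHRecord(r.chrom, r.pos, r.mih, 2 * r.mih_change, r.next_mih,
                      2 * r.next_change, r.mih_base, r.next_base)
            for r in recs
        ]
        m2, n2, r2 = mih_summary(doubled)
        assert m2 == pytest.approx(2 * m1) and n2 == pytest.approx(2 * n1)
        assert r2 == pytest.approx(r1)

    def test_planted_selection_dominated_by_one_haplotype(self, selected_run):
        base, base_obs, noisy, truth = selected_run
        on_sel = np.flatnonzero(
            (base.chrom == "chr02")
            & (np.abs(base.pos - 150_000) <= 10_000)
        )
        recs = hv.mih_table(base_obs, noisy)
        sel_recs = [recs[i] for i in on_sel]
        m, nx, _ = mih_summary(sel_recs)
        # a single favored founder sweeps: the MIH gains strongly while the
        # runner-up gains little or loses
        assert m > 0.5
        assert nx < 0.1
        assert all(r.mih == "A5" for r in sel_recs)


class TestReplicateSpearman:
    def test_identical_replicates(self, base_table):
        assert hv.replicate_spearman([base_table, base_table.copy()]) == pytest.approx(1.0)

    def test_reversed_rankings(self):
        a = _table([np.arange(1, 6) / 15.0] * 4)
        b = _table([np.arange(5, 0, -1) / 15.0] * 4)
        assert hv.replicate_spearman([a, b]) == pytest.approx(-1.0)

    def test_shuffled_near_zero(self):
        rng = np.random.default_rng(1)
        n_loci, k = 600, 10
        tables = []
        for r in range(2):
            f = rng.dirichlet(np.ones(k), size=n_loci)
            tables.append(_table(f, f"r{r}"))
        assert abs(hv.replicate_spearman(tables)) < 0.1


class TestSplitHalfLOD:
    def test_duplicated_halves_correlate_perfectly(self, selected_run):
        base, base_obs, noisy, _ = selected_run
        tables = noisy[:2] + [t.copy() for t in noisy[:2]]
        for i, t in enumerate(tables):
            t.population = f"r{i}"
        # force halves that are copies of each other by symmetry of rho=1
        rho, halves = hv.split_half_lod_correlation(base_obs, tables, seed=3)
        g1, g2 = halves
        if {p[:2] for p in g1} == {p[:2] for p in g2}:
            assert rho == pytest.approx(1.0, abs=1e-9)
        # regardless of assignment, both halves carry the same signal
        assert rho > 0.9

    def test_planted_shared_selection_correlates(self, selected_run):
        base, base_obs, noisy, _ = selected_run
        rho, _ = hv.split_half_lod_correlation(base_obs, noisy, seed=1)
        assert rho > 0.5

    def test_pure_noise_uncorrelated(self, long_grid):
        _, base = hv.simulate_founder_panel(long_grid, snp_density=0.5, seed=2)
        reps = [hv.add_measurement_noise(base, 0.01, seed=300 + i) for i in range(4)]
        base_obs = hv.add_measurement_noise(base, 0.004, seed=299)
        rho, _ = hv.split_half_lod_correlation(base_obs, reps, seed=5)
        assert abs(rho) < 0.15

    def test_deterministic_given_seed(self, selected_run):
        base, base_obs, noisy, _ = selected_run
        r1 = hv.split_half_lod_correlation(base_obs, noisy, seed=9)
        r2 = hv.split_half_lod_correlation(base_obs, noisy, seed=9)
        assert r1 == r2

    def test_needs_four_replicates(self, selected_run):
        base, base_obs, noisy, _ = selected_run
        with pytest.raises(ValueError):
            hv.split_half_lod_correlation(base_obs, noisy[:3])


class TestZScore:
    def test_standardization(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.0, size=500)
        z = zscore_lod(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)
        z2 = zscore_lod(3.0 * x + 7.0)
        assert np.allclose(z, z2, atol=1e-10)

    def test_degenerate_input(self):
        with pytest.raises(ValueError):
            zscore_lod(np.array([2.0, 2.0, 2.0]))


class TestMIHDeviation:
    def test_identical_replicates_zero(self, base_table):
        tables = []
        for i in range(3):
            t = base_table.copy()
            t.population = f"r{i}"
            tables.append(t)
        dev, avg = mih_deviation(base_table, tables, "r0")
        assert np.all(dev == 0.0) and avg == 0.0

    def test_known_offset(self):
        base = _table([[0.5, 0.5]] * 3)
        others = [_table([[0.8, 0.2]] * 3, f"o{i}") for i in range(2)]
        held = _table([[1.0, 0.0]] * 3, "held")
        dev, avg = mih_deviation(base, others + [held], "held")
        assert np.allclose(dev, 0.2)
        assert avg == pytest.approx(0.2)

    def test_bounded(self, selected_run):
        base, base_obs, noisy, _ = selected_run
        dev, avg = mih_deviation(base_obs, noisy, noisy[0].population)
        assert np.all((dev >= 0) & (dev <= 1))
        assert 0 <= avg <= 1

    def test_selection_intensity_lowers_h_and_raises_deviation(self, base_table):
        # cohort of 6 treatments with 0..5 selected loci: genomes losing
        # more heterozygosity evolve less repeatably (finite-Ne drift)
        loci = [("chr01", 100_000), ("chr02", 150_000), ("chr03", 200_000),
                ("chr04", 100_000), ("chr01", 250_000), ("chr03", 60_000)]
        targets = ["A2", "A5", "A7", "A11", "A14", "A17"]
        h_means, devs = [], []
        for j in range(6):
            cfg = SimulationConfig(
                ne=2_000,
                selected_loci=tuple(loci[:j]),
                selection_coefficients=(0.03,) * j,
                target_haplotypes=tuple(targets[:j]),
                n_replicates=6,
                seed=40 + j,
            )
            reps, _ = hv.simulate_evolution(base_table, cfg)
            noisy = []
            for i, r in enumerate(reps):
                t = hv.add_measurement_noise(r, 0.01, seed=900 + 10 * j + i)
                t.population = f"t{j}_{i}"
                noisy.append(t)
            h_means.append(
                np.mean([per_site_heterozygosity(t.freqs).mean() for t in noisy])
            )
            devs.append(mih_deviation(base_table, noisy, noisy[0].population)[1])
        rho = stats.spearmanr(h_means, devs).statistic
        assert rho < 0  # lower heterozygosity, larger deviation


class TestPleiotropy:
    def test_self_correlation_unity_and_shared_region(self, base_table):
        # two treatments share one planted target with the same founder
        shared_locus = ("chr02", 150_000)

        def scan_for(seed):
            cfg = SimulationConfig(
                selected_loci=(shared_locus,),
                selection_coefficients=(0.05,),
                target_haplotypes=("A5",),
                n_replicates=4,
                seed=seed,
            )
            reps, _ = hv.simulate_evolution(base_table, cfg)
            noisy = [
                hv.add_measurement_noise(r, 0.01, seed=seed * 13 + i)
                for i, r in enumerate(reps)
            ]
            return hv.chi_square_scan(base_table, noisy), noisy

        scan_a, reps_a = scan_for(61)
        scan_b, reps_b = scan_for(62)
        mih = {
            "ta": hv.mih_table(base_table, reps_a),
            "tb": hv.mih_table(base_table, reps_b),
        }
        rho, shared = hv.pleiotropy_screen(
            {"ta": scan_a, "tb": scan_b}, mih
        )
        assert rho.loc["ta", "ta"] == 1.0
        assert np.allclose(rho, rho.T)
        near = shared[
            (shared["chrom"] == "chr02")
            & (shared["start"] <= 150_000)
            & (shared["end"] >= 150_000)
        ]
        assert len(near) == 1
        assert bool(near.iloc[0]["same_mih"]) is True

    def test_independent_null_scans_uncorrelated(self, long_grid):
        _, base = hv.simulate_founder_panel(long_grid, snp_density=0.5, seed=3)
        scans = {}
        for name, seed in (("x", 71), ("y", 72)):
            reps = [
                hv.add_measurement_noise(base, 0.01, seed=seed * 10 + i)
                for i in range(4)
            ]
            scans[name] = hv.chi_square_scan(base, reps)
        rho, _ = hv.pleiotropy_screen(scans)
        assert abs(rho.loc["x", "y"]) < 0.15
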