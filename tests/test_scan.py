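"""Genome-scan core: kinship, null LMM, scans, thresholds, intervals,
peaks, founder effects."""

import numpy as np
import pandas as pd
import pytest

import pleioscan as ps
from pleioscan.scan import (
    SUM_ZERO_BASIS,
    ScanResult,
    bayes_interval,
    compute_kinship_loco,
    compute_kinship_overall,
    covariate_design,
    find_peaks,
    fit_null_lmm,
    founder_effects,
    genome_scan,
    permutation_thresholds,
)
from conftest import gaussian_qtl_trait


class TestKinship:
    def test_matches_double_loop_oracle(self, small_map):
        dos = ps.simulate_do_genomes(small_map, 20, seed=3)
        ks = compute_kinship_loco(dos, small_map)
        chrom = "2"
        keep = np.concatenate([small_map.chrom_slice(c) for c in small_map.chromosomes if c != chrom])
        P = dos.dosage / 2.0
        K_ref = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                K_ref[i, j] = sum(P[i, m] @ P[j, m] for m in keep) / len(keep)
        np.testing.assert_allclose(ks.matrices[chrom], K_ref, atol=1e-10)

    def test_identical_individuals_share_diagonal_value(self, small_map):
        dos = ps.simulate_do_genomes(small_map, 5, seed=4)
        dos.dosage[1] = dos.dosage[0]
        ks = compute_kinship_loco(dos, small_map)
        K = ks.matrices["1"]
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)

    def test_disjoint_ancestry_zero(self):
        gmap = ps.simulate_map(2, 5, 50.0)
        dosage = np.zeros((2, 10, 8))
        dosage[0, :, 0] = 2.0
        dosage[1, :, 1] = 2.0
        dos = ps.FounderDosage(["a", "b"], list(gmap.markers.index), dosage)
        ks = compute_kinship_loco(dos, gmap)
        assert ks.matrices["1"][0, 1] == 0.0

    def test_single_chromosome_rejected(self):
        gmap = ps.simulate_map(1, 5, 50.0)
        dos = ps.simulate_do_genomes(gmap, 5, seed=1)
        with pytest.raises(ValueError, match="LOCO"):
            compute_kinship_loco(dos, gmap)

    def test_psd_and_symmetric(self, small_kinship):
        for K in small_kinship.matrices.values():
            assert np.abs(K - K.T).max() < 1e-10
            assert np.linalg.eigvalsh(K).min() > -1e-8
            assert np.all(np.diag(K) > 0) and np.all(np.diag(K) <= 1 + 1e-12)


class TestNullLmm:
    def test_identity_kinship_boundary_convention(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=80)
        h2, _ = fit_null_lmm(y, np.ones((80, 1)), K=np.eye(80))
        assert h2 == 0.0

    def test_h2_recovery_median(self, medium_dosage):
        K = compute_kinship_overall(medium_dosage)
        w, U = np.linalg.eigh(K)
        rng = np.random.default_rng(1)
        wc = np.clip(w, 0, None)
        L = U * np.sqrt(wc)
        ests = []
        for _ in range(50):
            u = L @ rng.normal(size=400)
            u = (u - u.mean()) / u.std()
            y = np.sqrt(0.5) * u + np.sqrt(0.5) * rng.normal(size=400)
            h2, _ = fit_null_lmm(y, np.ones((400, 1)), eigen=(w, U))
            ests.append(h2)
        assert abs(np.median(ests) - 0.5) < 0.15

    def test_zero_residual_variance_rejected(self):
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        y = X @ np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="residual"):
            fit_null_lmm(y, X, K=np.eye(30))

    def test_rank_deficient_covariates_rejected(self):
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="rank"):
            fit_null_lmm(np.random.default_rng(2).normal(size=30), X, K=np.eye(30))


def brute_force_lod(y, X, dosage_at_markers):
    """Independent ordinary-regression LOD via explicit projection matrices."""
    n = len(y)
    H0 = X @ np.linalg.pinv(X)
    r0 = y - H0 @ y
    rss0 = r0 @ r0
    lods = []
    for m in range(dosage_at_markers.shape[1]):
        Z = np.hstack([X, dosage_at_markers[:, m, :]])  # all 8 founder columns
        HZ = Z @ np.linalg.pinv(Z)
        r1 = y - HZ @ y
        lods.append((n / 2) * np.log10(rss0 / (r1 @ r1)))
    return np.array(lods)


class TestGenomeScan:
    def test_constant_phenotype_zero_lod(self, small_map, small_dosage):
        y = pd.Series(np.ones(200), index=small_dosage.individuals)
        res = genome_scan(y, small_dosage, small_map)
        assert np.all(res.lod.to_numpy() == 0.0)

    def test_matches_ols_oracle_without_kinship(self):
        rng = np.random.default_rng(7)
        gmap = ps.simulate_map(2, 10, 60.0)
        for _ in range(10):
            dos = ps.simulate_do_genomes(gmap, 60, seed=int(rng.integers(2**31)))
            y = rng.normal(size=60)
            res = genome_scan(y, dos, gmap)
            ref = brute_force_lod(y, np.ones((60, 1)), dos.dosage)
            np.testing.assert_allclose(res.lod.to_numpy(), ref, atol=1e-8)

    def test_lod_nonnegative_with_kinship(self, small_map, small_dosage, small_covariates, small_kinship):
        rng = np.random.default_rng(8)
        y, _ = gaussian_qtl_trait(small_dosage, 30, 0.15, rng)
        res = genome_scan(y, small_dosage, small_map, small_covariates, small_kinship)
        assert res.lod.min() >= 0
        assert np.all(np.isfinite(res.lod))

    def test_missing_values_dropped_trait_wise(self, small_map, small_dosage):
        rng = np.random.default_rng(9)
        y = rng.normal(size=200)
        y[:20] = np.nan
        res = genome_scan(y, small_dosage, small_map)
        assert res.n_used == 180

    def test_qtl_recovered_at_true_marker(self, medium_map, medium_dosage, medium_kinship):
        rng = np.random.default_rng(10)
        true_idx = medium_map.chrom_slice("4")[12]
        y, _ = gaussian_qtl_trait(medium_dosage, true_idx, 0.2, rng)
        res = genome_scan(y, medium_dosage, medium_map, None, medium_kinship)
        peak = res.lod.idxmax()
        true_cm = medium_map.markers["pos_cM"].iloc[true_idx]
        assert medium_map.markers.loc[peak, "chromosome"] == "4"
        assert abs(medium_map.markers.loc[peak, "pos_cM"] - true_cm) <= 10


class TestPermutationThresholds:
    def test_thresholds_monotone_in_alpha(self, small_map, small_dosage):
        rng = np.random.default_rng(11)
        traits = pd.DataFrame(rng.normal(size=(200, 5)), index=small_dosage.individuals)
        ts = permutation_thresholds(
            traits, small_dosage, small_map, n_perm=20, alphas=(0.05, 0.2, 0.5), seed=1
        )
        assert ts[0.05] >= ts[0.2] >= ts[0.5]

    def test_invariant_to_id_relabeling(self, small_map, small_dosage):
        rng = np.random.default_rng(12)
        traits = pd.DataFrame(rng.normal(size=(200, 3)), index=small_dosage.individuals)
        ts1 = permutation_thresholds(traits, small_dosage, small_map, n_perm=15, seed=5)
        renamed = traits.copy()
        renamed.index = [f"mouse_{i}" for i in range(200)]
        dos2 = ps.FounderDosage(list(renamed.index), small_dosage.markers, small_dosage.dosage)
        ts2 = permutation_thresholds(renamed, dos2, small_map, n_perm=15, seed=5)
        assert ts1.thresholds == ts2.thresholds

    def test_too_few_permutations_rejected(self, small_map, small_dosage):
        traits = pd.DataFrame(np.random.default_rng(0).normal(size=(200, 2)), index=small_dosage.individuals)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_thresholds(traits, small_dosage, small_map, n_perm=5)


class TestBayesInterval:
    def test_hand_normalized_toy(self):
        lod = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        lo, hi = bayes_interval(lod, prob=0.95)
        assert (lo, hi) == (1, 3)  # markers 2-4, 1-based

    def test_flat_curve_covers_chromosome(self):
        lod = np.zeros(100)
        lo, hi = bayes_interval(lod, prob=0.95)
        assert (hi - lo + 1) / 100 >= 0.95

    def test_single_spike(self):
        lod = np.zeros(30)
        lod[12] = 20.0
        lo, hi = bayes_interval(lod, prob=0.95)
        assert lo == hi == 12

    def test_contains_peak(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            lod = np.abs(rng.normal(size=40))
            lo, hi = bayes_interval(lod)
            assert lo <= np.argmax(lod) <= hi

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bayes_interval(np.array([1.0, np.inf]))

    def test_empirical_coverage_of_true_qtl(self):
        # the interval is approximate by construction: coverage of the true
        # QTL position should be high but not degenerate
        gmap = ps.simulate_map(1, 91, 90.0)  # 1-cM grid
        dos = ps.simulate_do_genomes(gmap, 400, seed=31)
        rng = np.random.default_rng(72)
        mbp = gmap.markers["pos_Mbp"].to_numpy()
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            ti = int(rng.integers(gmap.n_markers))
            y, _ = gaussian_qtl_trait(dos, ti, 0.10, rng)
            lod = genome_scan(y, dos, gmap).lod.to_numpy()
            lo, hi = bayes_interval(lod, mbp, 0.95)
            if lo - 1e-9 <= mbp[ti] <= hi + 1e-9:
                cover += 1
        assert 0.80 <= cover / n_rep <= 0.995


class TestFindPeaks:
    def _scan(self, gmap, lod):
        return ScanResult("t", pd.Series(lod, index=gmap.markers.index), {}, 100, [])

    def test_below_threshold_empty(self):
        gmap = ps.simulate_map(1, 20, 80.0)
        lod = np.full(20, 5.0) * np.hanning(20)
        peaks = find_peaks(self._scan(gmap, lod), gmap, threshold=6.1)
        assert peaks == []

    def test_close_maxima_merged(self):
        gmap = ps.simulate_map(1, 41, 80.0)  # 2 cM spacing
        lod = np.zeros(41)
        lod[20], lod[21] = 8.0, 7.5  # 2 cM apart
        peaks = find_peaks(self._scan(gmap, lod), gmap, threshold=6.0, min_peak_separation_cM=5.0)
        assert len(peaks) == 1 and peaks[0].lod == 8.0

    def test_two_distant_peaks_kept(self):
        gmap = ps.simulate_map(1, 41, 80.0)
        lod = np.zeros(41)
        lod[5], lod[35] = 9.0, 8.0  # 60 cM apart
        peaks = find_peaks(self._scan(gmap, lod), gmap, threshold=6.0, min_peak_separation_cM=10.0)
        assert len(peaks) == 2

    def test_peak_inside_interval(self):
        gmap = ps.simulate_map(2, 30, 90.0)
        rng = np.random.default_rng(14)
        lod = np.abs(rng.normal(size=60)) + 1
        lod[40] = 12.0
        for p in find_peaks(self._scan(gmap, lod), gmap, threshold=6.0):
            assert p.ci_lo <= p.pos_Mbp <= p.ci_hi


class TestFounderEffects:
    def test_recovery_of_planted_contrast(self, medium_dosage):
        rng = np.random.default_rng(15)
        effects = np.array([1.0, 0, 0, 0, 0, 0, 0, -1.0])
        y, _ = gaussian_qtl_trait(medium_dosage, 100, 0.3, rng, effects=effects)
        est = founder_effects(y, medium_dosage.dosage[:, 100, :])
        assert np.corrcoef(est, effects)[0, 1] > 0.9

    def test_sum_to_zero_constraint(self, medium_dosage):
        rng = np.random.default_rng(16)
        y, _ = gaussian_qtl_trait(medium_dosage, 50, 0.2, rng)
        est = founder_effects(y, medium_dosage.dosage[:, 50, :])
        assert est.sum() == pytest.approx(0.0, abs=1e-10)

    def test_permuted_trait_coefficients_near_null(self, medium_dosage):
        rng = np.random.default_rng(17)
        y, _ = gaussian_qtl_trait(medium_dosage, 60, 0.3, rng)
        obs = founder_effects(y, medium_dosage.dosage[:, 60, :])
        null_max = []
        for _ in range(50):
            null_max.append(
                np.abs(founder_effects(rng.permutation(y), medium_dosage.dosage[:, 60, :])).max()
            )
        assert np.median(null_max) < np.abs(obs).max()

    def test_constant_trait_zero(self, medium_dosage):
        est = founder_effects(np.ones(400), medium_dosage.dosage[:, 10, :])
        np.testing.assert_array_equal(est, np.zeros(8))


class TestCovariateDesign:
    def test_wave_dummies_and_intercept(self, small_covariates):
        X, names = covariate_design(small_covariates)
        assert names[0] == "intercept"
        n_waves = small_covariates["wave"].nunique()
        assert X.shape[1] == 1 + 1 + (n_waves - 1) + 1  # intercept, sex, waves, days
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_sum_zero_basis_orthonormal(self):
        # 8x7 basis: columns orthonormal and orthogonal to the ones vector
        assert SUM_ZERO_BASIS.shape == (8, 7)
        np.testing.assert_allclose(SUM_ZERO_BASIS.T @ SUM_ZERO_BASIS, np.eye(7), atol=1e-12)
        np.testing.assert_allclose(SUM_ZERO_BASIS.sum(axis=0), 0.0, atol=1e-12)
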