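"""Synthetic DO genome and trait generator."""

import numpy as np
import pandas as pd
import pytest

import pleioscan as ps
from pleioscan.scan import compute_kinship_overall


class TestSimulateMap:
    def test_even_grid_arithmetic(self):
        gmap = ps.simulate_map(1, 6, 100.0, 2.0, seed=1)
        np.testing.assert_allclose(gmap.markers["pos_cM"], [0, 20, 40, 60, 80, 100])
        np.testing.assert_allclose(gmap.markers["pos_Mbp"], [0, 10, 20, 30, 40, 50])

    def test_marker_count(self):
        gmap = ps.simulate_map(19, 50, 90.0)
        assert gmap.n_markers == 950
        assert gmap.chromosomes == [str(i) for i in range(1, 20)]

    def test_fine_grid_spacing(self):
        # 0.02-cM spacing on a 10-cM toy chromosome
        gmap = ps.simulate_map(1, 501, 10.0)
        assert gmap.n_markers == 501
        spacing = np.diff(gmap.markers["pos_cM"].to_numpy())
        np.testing.assert_allclose(spacing, 0.02)

    @pytest.mark.parametrize("kwargs", [
        {"n_chromosomes": 1, "markers_per_chr": 1, "chr_length_cM": 10},
        {"n_chromosomes": 1, "markers_per_chr": 5, "chr_length_cM": -3},
        {"n_chromosomes": 0, "markers_per_chr": 5, "chr_length_cM": 10},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ps.simulate_map(**kwargs)


class TestSimulateGenomes:
    def test_dosage_slices_sum_to_two(self, small_dosage):
        sums = small_dosage.dosage.sum(axis=2)
        np.testing.assert_allclose(sums, 2.0, atol=1e-8)

    def test_smoothing_preserves_slice_sums(self, small_map):
        dos = ps.simulate_do_genomes(small_map, 30, seed=5, smoothing_weight=0.05)
        np.testing.assert_allclose(dos.dosage.sum(axis=2), 2.0, atol=1e-8)
        assert dos.dosage.min() >= 0

    def test_no_recombination_gives_single_founder_pair(self, small_map):
        dos = ps.simulate_do_genomes(small_map, 20, switch_density_per_cM=0.0, seed=7)
        for i in range(20):
            for chrom in small_map.chromosomes:
                idx = small_map.chrom_slice(chrom)
                slice_ = dos.dosage[i, idx, :]
                # same founder pair at every marker, at most two founders
                assert (slice_ > 0).any(axis=0).sum() <= 2
                assert (slice_ == slice_[0]).all()

    def test_founder_frequencies_near_one_eighth(self):
        gmap = ps.simulate_map(1, 10, 100.0)
        dos = ps.simulate_do_genomes(gmap, 2000, seed=13)
        freq = dos.dosage.mean(axis=0) / 2.0  # markers x founders
        se = np.sqrt((1 / 8) * (7 / 8) / (2 * 2000))
        assert np.abs(freq - 1 / 8).max() < 3 * se * np.sqrt(2)  # haplotypes paired

    def test_block_count_matches_poisson_rate(self):
        # mean mosaic blocks per gamete = 1 + density * length
        from pleioscan.simulate import _mosaic_haplotype

        rng = np.random.default_rng(2)
        lengths = [len(_mosaic_haplotype(100.0, 0.1, rng)[1]) for _ in range(1000)]
        assert np.mean(lengths) == pytest.approx(1 + 0.1 * 100.0, rel=0.05)

    def test_deterministic_given_seed(self, small_map):
        a = ps.simulate_do_genomes(small_map, 15, seed=42)
        b = ps.simulate_do_genomes(small_map, 15, seed=42)
        assert np.array_equal(a.dosage, b.dosage)

    def test_empty_map_rejected(self):
        gmap = ps.simulate_map(1, 2, 10.0)
        gmap.markers = gmap.markers.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            ps.simulate_do_genomes(gmap, 5)


class TestSimulateTraits:
    def test_qtl_variance_fraction(self, medium_map, medium_dosage):
        marker = medium_map.markers.index[medium_map.chrom_slice("2")[10]]
        spec = ps.TraitSpec("t", "clinical", qtl_marker=marker, qtl_var=0.20)
        _, _, clin, truth = ps.simulate_traits(medium_dosage, medium_map, None, [spec], seed=8)
        eff = np.asarray(truth.traits["t"]["founder_effects"])
        g = medium_dosage.dosage[:, medium_map.marker_index(marker), :] @ eff
        r = np.corrcoef(clin["t"], g)[0, 1]
        assert r == pytest.approx(np.sqrt(0.20), abs=0.07)

    def test_prevalence_is_controllable(self, medium_map, medium_dosage):
        for pi in (0.3, 0.6, 0.9):
            spec = ps.TraitSpec("m", "microbial", prevalence=pi)
            counts, _, _, _ = ps.simulate_traits(medium_dosage, medium_map, None, [spec], seed=9)
            emp = (counts["m"] > 0).mean()
            assert emp == pytest.approx(pi, abs=0.05)

    def test_causal_pair_d_separation(self, medium_map, medium_dosage):
        # with no direct QTL->target edge, target _||_ QTL | mediator
        marker = medium_map.markers.index[medium_map.chrom_slice("1")[5]]
        pair = ps.PairSpec("m", "b", "causal", qtl_marker=marker, qtl_var=0.3, mediation_strength=1.0)
        counts, metab, _, truth = ps.simulate_traits(medium_dosage, medium_map, None, [], [pair], seed=10)
        assert truth.pairs["m|b"]["architecture"] == "causal"
        eff = np.asarray(truth.traits["m"]["founder_effects"])
        q = medium_dosage.dosage[:, medium_map.marker_index(marker), :] @ eff
        # work on latent scale: mediator latent reconstructed via source truth
        # is unavailable, so check on generated latents via a fresh pair
        from pleioscan.simulate import _architecture_pair
        rng = np.random.default_rng(3)
        la, lb, _ = _architecture_pair(medium_dosage, medium_map, pair, None, None, rng)
        resid_t = lb - np.polyval(np.polyfit(la, lb, 1), la)
        assert abs(np.corrcoef(resid_t, q)[0, 1]) < 0.12

    def test_polygenic_trait_tracks_kinship(self, medium_map, medium_dosage):
        # Mantel-style check: trait cross-products correlate with kinship
        spec = ps.TraitSpec("t", "clinical", h2=0.5)
        _, _, clin, _ = ps.simulate_traits(medium_dosage, medium_map, None, [spec], seed=12)
        y = clin["t"].to_numpy()
        y = (y - y.mean()) / y.std()
        K = compute_kinship_overall(medium_dosage)
        iu = np.triu_indices(len(y), k=1)
        prod = np.outer(y, y)[iu]
        kin = K[iu]
        r_obs = np.corrcoef(prod, kin)[0, 1]
        rng = np.random.default_rng(0)
        null = []
        for _ in range(99):
            p = rng.permutation(len(y))
            null.append(np.corrcoef(np.outer(y[p], y[p])[iu], kin)[0, 1])
        assert r_obs > np.quantile(null, 0.95)

    def test_h2_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ps.TraitSpec("t", h2=1.0)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="architecture"):
            ps.PairSpec("a", "b", "entangled")

    def test_outputs_deterministic_given_seed(self, small_map, small_dosage, small_covariates):
        spec = ps.TraitSpec("m", "microbial", prevalence=0.8)
        out1 = ps.simulate_traits(small_dosage, small_map, small_covariates, [spec], seed=77)
        out2 = ps.simulate_traits(small_dosage, small_map, small_covariates, [spec], seed=77)
        pd.testing.assert_frame_equal(out1[0], out2[0])
        pd.testing.assert_frame_equal(out1[1], out2[1])
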