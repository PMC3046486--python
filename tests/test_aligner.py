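import numpy as np
import pytest

from chromalign import (
    RegionMatrix,
    SeedPair,
    WindowPlacement,
    aligned_windows,
    chosen_seed_alignment,
    generate_dataset,
    quality_assessment,
    recovery_fraction,
    seed_sampling_alignment,
    single_best_pair_alignment,
)
from chromalign.similarity import n_starts

from oracles import (
    brute_best_pair,
    brute_chosen_seed,
    brute_quality,
    brute_seed_sampling,
    brute_window,
)

FRAME = 8


def small_matrix(rng, n=6, m=18):
    """S = 10 with the default 8-bin frame."""
    return RegionMatrix.from_values(rng.normal(size=(n, m)), bin_size=10)


def center_seed(matrix, frame):
    s = n_starts(matrix.m, frame)
    return SeedPair(
        WindowPlacement(0, s // 2, False), WindowPlacement(1, s // 2, False), 0.0
    )


class TestChosenSeedAlignment:
    def test_identical_regions(self, rng):
        row = rng.normal(size=18)
        matrix = RegionMatrix.from_values(np.tile(row, (5, 1)), bin_size=10)
        aln = chosen_seed_alignment(center_seed(matrix, FRAME), matrix, FRAME)
        s = n_starts(18, FRAME)
        assert all(p.start_bin == s // 2 for p in aln.placements)
        assert np.allclose(aln.consensus, row[s // 2 : s // 2 + FRAME])
        # greedy scores of the non-seed commits are all 1.0
        for r in aln.addition_order[2:]:
            assert aln.scores[r] == pytest.approx(1.0)

    def test_planted_shifts_recovered_exactly(self, planted_matrix):
        # seed the first two regions consistently with their planted shifts
        # (start = S/2 - shift); the greedy core must then recover the rest
        matrix, truth = planted_matrix
        s = n_starts(matrix.m, 40)
        seed = SeedPair(
            WindowPlacement(0, s // 2 - int(truth.shift_bins[0]), False),
            WindowPlacement(1, s // 2 - int(truth.shift_bins[1]), False),
            0.0,
        )
        aln = chosen_seed_alignment(seed, matrix, 40, "pearson")
        assert recovery_fraction(
            aln, truth.shift_bins, 10, matrix.m, tol_bins=0
        ) == 1.0

    def test_consensus_is_mean_of_windows(self, rng):
        matrix = small_matrix(rng)
        aln = chosen_seed_alignment(center_seed(matrix, FRAME), matrix, FRAME)
        assert np.allclose(
            aln.consensus, aligned_windows(aln, matrix).mean(axis=0), rtol=1e-9
        )

    def test_addition_order_is_permutation(self, rng):
        matrix = small_matrix(rng, n=7)
        aln = chosen_seed_alignment(center_seed(matrix, FRAME), matrix, FRAME)
        assert sorted(aln.addition_order) == list(range(7))

    @pytest.mark.parametrize("metric", ["pearson", "spearman", "euclidean"])
    @pytest.mark.parametrize("allow_reversal", [False, True])
    def test_matches_brute_force(self, metric, allow_reversal, rng):
        for trial in range(10):
            matrix = small_matrix(rng, n=5, m=14)
            seed = center_seed(matrix, FRAME)
            aln = chosen_seed_alignment(
                seed, matrix, FRAME, metric, allow_reversal
            )
            placements, consensus, order = brute_chosen_seed(
                [row.tolist() for row in matrix.values],
                (0, seed.placement_a.start_bin, False),
                (1, seed.placement_b.start_bin, False),
                FRAME, metric, allow_reversal,
            )
            for r in range(5):
                p = aln.placements[r]
                assert (p.start_bin, p.reversed) == placements[r]
            assert aln.addition_order == order
            assert np.allclose(aln.consensus, consensus)

    def test_degenerate_frame_rejected(self, rng):
        matrix = small_matrix(rng)
        with pytest.raises(ValueError):
            chosen_seed_alignment(center_seed(matrix, 18), matrix, 18)


class TestSingleBestPair:
    def test_planted_identical_pair_is_seed(self, rng):
        values = rng.normal(size=(9, 18))
        values[7] = values[3]
        matrix = RegionMatrix.from_values(values, bin_size=10)
        aln = single_best_pair_alignment(matrix, FRAME)
        assert {aln.seed.placement_a.region_index,
                aln.seed.placement_b.region_index} == {3, 7}
        assert aln.seed.score == pytest.approx(1.0)

    def test_seed_matches_brute_scan(self, rng):
        for _ in range(10):
            matrix = small_matrix(rng, n=5, m=18)
            aln = single_best_pair_alignment(matrix, FRAME)
            best = None
            for i in range(4):
                for j in range(i + 1, 5):
                    start, rev, sc = brute_best_pair(
                        matrix.values[i].tolist(), matrix.values[j].tolist(),
                        FRAME, "pearson", False,
                    )
                    if best is None or sc > best[4]:
                        best = (i, j, start, rev, sc)
            assert aln.seed.placement_a.region_index == best[0]
            assert aln.seed.placement_b.region_index == best[1]
            assert aln.seed.placement_b.start_bin == best[2]
            assert aln.seed.score == pytest.approx(best[4], abs=1e-10)

    def test_too_few_regions_rejected(self, rng):
        matrix = RegionMatrix.from_values(rng.normal(size=(1, 18)), bin_size=10)
        with pytest.raises(ValueError):
            single_best_pair_alignment(matrix, FRAME)


class TestSeedSampling:
    def test_identical_regions_quality_one(self, rng):
        row = rng.normal(size=18)
        matrix = RegionMatrix.from_values(np.tile(row, (4, 1)), bin_size=10)
        aln, qualities = seed_sampling_alignment(matrix, FRAME)
        assert np.allclose(qualities, 1.0)
        assert aln.quality == pytest.approx(1.0)
        # tie broken by lowest seed index
        assert aln.seed.placement_a.region_index == 0

    def test_dominates_single_best_pair(self, rng):
        matrix = small_matrix(rng, n=6)
        best_pair = single_best_pair_alignment(matrix, FRAME)
        best_pair.quality = quality_assessment(best_pair, matrix)
        sampled, qualities = seed_sampling_alignment(matrix, FRAME)
        assert sampled.quality >= np.max(qualities) - 1e-12
        assert sampled.quality >= best_pair.quality - 1e-12

    @pytest.mark.parametrize("metric", ["pearson", "euclidean"])
    def test_matches_straight_line_reference(self, metric, rng):
        for _ in range(5):
            matrix = small_matrix(rng, n=6, m=16)
            aln, qualities = seed_sampling_alignment(matrix, FRAME, metric)
            (seed_i, placements, order, quality), all_q = brute_seed_sampling(
                [row.tolist() for row in matrix.values], FRAME, metric, False
            )
            assert np.allclose(qualities, all_q, atol=1e-10)
            assert aln.seed.placement_a.region_index == seed_i
            assert aln.addition_order == order
            for r in range(6):
                p = aln.placements[r]
                assert (p.start_bin, p.reversed) == placements[r]
            assert aln.quality == pytest.approx(quality, abs=1e-10)


class TestQualityAssessment:
    def test_identical_windows(self, rng):
        row = rng.normal(size=18)
        matrix = RegionMatrix.from_values(np.tile(row, (4, 1)), bin_size=10)
        aln = chosen_seed_alignment(center_seed(matrix, FRAME), matrix, FRAME)
        assert quality_assessment(aln, matrix) == pytest.approx(1.0)

    def test_two_regions_equals_pairwise_score(self, rng):
        matrix = small_matrix(rng, n=2)
        aln = chosen_seed_alignment(center_seed(matrix, FRAME), matrix, FRAME)
        windows = aligned_windows(aln, matrix)
        expect = brute_quality([w.tolist() for w in windows], "pearson")
        assert quality_assessment(aln, matrix) == pytest.approx(expect)

    @pytest.mark.parametrize("metric", ["pearson", "spearman", "euclidean"])
    def test_matches_pairwise_mean_oracle(self, metric, rng):
        matrix = small_matrix(rng, n=5)
        aln = chosen_seed_alignment(
            center_seed(matrix, FRAME), matrix, FRAME, metric
        )
        windows = aligned_windows(aln, matrix)
        expect = brute_quality([w.tolist() for w in windows], metric)
        assert quality_assessment(aln, matrix, metric) == pytest.approx(
            expect, abs=1e-10
        )

    def test_single_region_rejected(self, rng):
        matrix = small_matrix(rng, n=2)
        aln = chosen_seed_alignment(center_seed(matrix, FRAME), matrix, FRAME)
        aln.placements = aln.placements[:1]
        with pytest.raises(ValueError):
            quality_assessment(aln, matrix)


class TestRecoveryProperties:
    def test_noise_free_shift_recovery_both_strategies(self):
        matrix, truth = generate_dataset(
            "origin_like", n=12, length_bins=100, max_shift_bins=10,
            noise_sd=0.0, master_seed=7,
        )
        for aln in (
            single_best_pair_alignment(matrix, 60),
            seed_sampling_alignment(matrix, 60)[0],
        ):
            assert recovery_fraction(
                aln, truth.shift_bins, 10, matrix.m, tol_bins=0
            ) == 1.0

    def test_noisy_seed_sampling_recovery(self):
        matrix, truth = generate_dataset(
            "tss_like", n=40, length_bins=150, max_shift_bins=10,
            noise_sd=0.1, master_seed=11,
        )
        aln, _ = seed_sampling_alignment(matrix, 100)
        assert recovery_fraction(
            aln, truth.shift_bins, 10, matrix.m, tol_bins=1
        ) >= 0.9

    def test_reversal_recovery_up_to_global_flip(self):
        matrix, truth = generate_dataset(
            "tss_like", n=16, length_bins=100, max_shift_bins=8,
            reversal_prob=0.5, noise_sd=0.0, master_seed=13,
        )
        aln, _ = seed_sampling_alignment(matrix, 60, allow_reversal=True)
        rev = aln.reversed_flags()
        agree = (rev == truth.reversed).mean()
        assert agree in (0.0, 1.0)  # exact match up to one global flip
        assert recovery_fraction(
            aln, truth.shift_bins, 10, matrix.m, tol_bins=0,
            true_reversed=truth.reversed,
        ) == 1.0

    def test_null_consensus_flatter_than_planted(self):
        planted, _ = generate_dataset(
            "tss_like", n=30, length_bins=100, max_shift_bins=8,
            noise_sd=0.1, master_seed=17,
        )
        null, _ = generate_dataset(
            "null", n=30, length_bins=100, max_shift_bins=8,
            noise_sd=0.1, master_seed=17,
        )
        aln_p, _ = seed_sampling_alignment(planted, 60)
        aln_n, _ = seed_sampling_alignment(null, 60)
        amp = lambda a: np.ptp(a.consensus)
        assert amp(aln_n) < amp(aln_p)

    def test_global_flip_equivalence_of_consensus(self, rng):
        # reversing every region's orientation mirrors the consensus
        matrix = small_matrix(rng, n=5)
        aln = chosen_seed_alignment(
            center_seed(matrix, FRAME), matrix, FRAME, allow_reversal=True
        )
        flipped = [
            WindowPlacement(p.region_index, p.start_bin, not p.reversed)
            for p in aln.placements
        ]
        aln.placements = flipped
        windows = aligned_windows(aln, matrix)
        assert np.allclose(windows.mean(axis=0), aln.consensus[::-1])
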