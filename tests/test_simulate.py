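import math

import numpy as np
import pandas as pd
import pytest

from clonemap.mapping import SimilarityTransform
from clonemap.plate import make_grid
from clonemap.simulate import (DistortionField, PyroErrorModel,
                               SynthesisErrorModel, apply_distortion, gen_pool,
                               populate_plate, render_image, render_tiles,
                               sample_abundances, simulate_reads,
                               synthesize_molecules)


class TestGenPool:
    def test_same_seed_reproduces_pool(self):
        assert gen_pool(5, 30, seed=7) == gen_pool(5, 30, seed=7)

    def test_sizes_and_lengths(self):
        pool = gen_pool(100, 120, seed=1)
        assert len(pool) == 100
        assert all(len(s) == 120 for s in pool.sequences)

    def test_base_composition_is_uniform(self):
        pool = gen_pool(1000, 100, seed=2)
        counts = pd.Series(list("".join(pool.sequences))).value_counts()
        n = counts.sum()
        sigma = math.sqrt(n * 0.25 * 0.75)
        for b in "ACGT":
            assert abs(counts[b] - n / 4) < 3 * sigma

    def test_duplicates_flagged_when_space_exhausted(self):
        pool = gen_pool(20, 2, seed=3)  # only 16 distinct 2-mers exist
        assert pool.has_duplicates


class TestAbundances:
    def test_unit_bias_gives_equal_weights(self, small_pool):
        prof = sample_abundances(small_pool, 1.0, seed=1)
        assert np.allclose(prof.weights, 1.0)

    def test_loguniform_ratio_is_exact(self, small_pool):
        prof = sample_abundances(small_pool, 10.0, "loguniform", seed=2)
        assert prof.bias == pytest.approx(10.0, abs=0)

    def test_twoclass_is_half_and_half(self, small_pool):
        prof = sample_abundances(small_pool, 10.0, "twoclass", seed=3)
        w = np.sort(prof.weights)
        assert np.allclose(w[:25], 1.0) and np.allclose(w[25:], 10.0)

    def test_bias_below_one_rejected(self, small_pool):
        with pytest.raises(ValueError):
            sample_abundances(small_pool, 0.5)


class TestSynthesis:
    def test_zero_rates_copy_designs(self, small_pool):
        prof = sample_abundances(small_pool, 1.0, seed=1)
        mols = synthesize_molecules(small_pool, prof,
                                    SynthesisErrorModel.error_free(), 50, seed=4)
        designs = dict(zip(small_pool.ids, small_pool.sequences))
        assert all(m.sequence == designs[m.design_id]
                   for m in mols.itertuples(index=False))
        assert (mols[["n_sub", "n_ins", "n_del"]].to_numpy() == 0).all()

    def test_error_count_matches_binomial_expectation(self, small_pool):
        # total rate 1/70 over 10^4 molecules x 120 nt -> ~17,143 edits
        prof = sample_abundances(small_pool, 1.0, seed=1)
        mols = synthesize_molecules(small_pool, prof, SynthesisErrorModel(),
                                    10_000, seed=5)
        total = int(mols[["n_sub", "n_ins", "n_del"]].to_numpy().sum())
        expected = 10_000 * 120 / 70
        assert abs(total - expected) < 3 * math.sqrt(expected)

    def test_error_free_fraction_matches_closed_form(self, small_pool):
        prof = sample_abundances(small_pool, 1.0, seed=1)
        mols = synthesize_molecules(small_pool, prof, SynthesisErrorModel(),
                                    10_000, seed=6)
        frac = float((mols[["n_sub", "n_ins", "n_del"]].sum(axis=1) == 0).mean())
        p = (1 - 1 / 70) ** 120  # ~0.178
        assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / 10_000)


class TestPlate:
    def test_full_occupancy_fills_every_well(self, small_pool):
        prof = sample_abundances(small_pool, 1.0, seed=1)
        mols = synthesize_molecules(small_pool, prof,
                                    SynthesisErrorModel.error_free(), 10, seed=1)
        grid = make_grid(2, 2, 10, "square")
        plate = populate_plate(grid, mols, 1.0, seed=1)
        assert len(plate.beads) == 4

    def test_occupancy_uses_floor_and_is_reproducible(self, small_pool):
        prof = sample_abundances(small_pool, 1.0, seed=1)
        mols = synthesize_molecules(small_pool, prof,
                                    SynthesisErrorModel.error_free(), 1100, seed=1)
        grid = make_grid(100, 100, 50, "hex")
        p1 = populate_plate(grid, mols, 0.1, seed=9)
        p2 = populate_plate(grid, mols, 0.1, seed=9)
        assert len(p1.beads) == 1000
        pd.testing.assert_frame_equal(p1.beads, p2.beads)

    def test_insufficient_molecules_rejected(self, small_pool):
        prof = sample_abundances(small_pool, 1.0, seed=1)
        mols = synthesize_molecules(small_pool, prof,
                                    SynthesisErrorModel.error_free(), 3, seed=1)
        with pytest.raises(ValueError, match="molecules"):
            populate_plate(make_grid(2, 2, 10, "square"), mols, 1.0, seed=1)


class TestReads:
    def test_error_free_model_reproduces_molecules(self, clean_readset):
        reads, plate, _ = clean_readset
        assert (reads["sequence"].to_numpy()
                == plate.beads["sequence"].to_numpy()).all()
        assert reads["quality"].str.strip("I").eq("").all()  # Q40 everywhere

    def test_homopolymer_indel_probability_escalates_geometrically(self):
        m = PyroErrorModel(indel_rate=0.004, multiplier=2.0)
        assert m.run_indel_prob(5) == pytest.approx(0.004 * 2 ** 4)
        assert m.run_indel_prob(1) == pytest.approx(0.004)
        assert PyroErrorModel(indel_rate=0.5, multiplier=3.0).run_indel_prob(9) == 1.0

    def test_mean_error_rate_matches_model_expectation(self, small_pool):
        # substitutions only, no read-to-read variation: per-base error is
        # exactly sub_rate and the observed count must sit within 3 sigma
        prof = sample_abundances(small_pool, 1.0, seed=1)
        mols = synthesize_molecules(small_pool, prof,
                                    SynthesisErrorModel.error_free(), 1000, seed=2)
        grid = make_grid(100, 100, 50, "hex")
        plate = populate_plate(grid, mols, 0.1, seed=3)
        pyro = PyroErrorModel(sub_rate=0.01, indel_rate=0.0, read_sigma=0.0,
                              quality_jitter=0.0)
        reads = simulate_reads(plate, pyro, None, seed=4).reads
        n_bases = int(reads["sequence"].str.len().sum())
        n_err = int(reads["pyro_sub"].sum())
        expected = n_bases * 0.01
        assert abs(n_err - expected) < 3 * math.sqrt(expected)

    def test_pixels_are_the_distorted_truth_well_centres(self, small_pool):
        prof = sample_abundances(small_pool, 1.0, seed=1)
        mols = synthesize_molecules(small_pool, prof,
                                    SynthesisErrorModel.error_free(), 100, seed=2)
        grid = make_grid(20, 20, 50, "hex")
        plate = populate_plate(grid, mols, 0.2, seed=3)
        field = DistortionField(
            similarity=SimilarityTransform(0.5, 0.1, 7.0, -3.0))
        reads = simulate_reads(plate, PyroErrorModel.error_free(), field,
                               seed=4).reads
        expected = field.apply(grid.centers()[plate.beads["well_index"]])
        assert np.allclose(reads[["x_px", "y_px"]].to_numpy(), expected)


class TestDistortion:
    def test_zero_warp_zero_radial_is_pure_similarity(self):
        sim = SimilarityTransform(1.3, 0.2, 5.0, -2.0)
        field = DistortionField(similarity=sim, amplitude=0.0)
        pts = np.array([[0.0, 0.0], [10.0, 20.0], [-5.0, 3.0]])
        assert np.allclose(apply_distortion(field, pts), sim.apply(pts))

    def test_warp_displacement_bounded_by_amplitude(self):
        field = DistortionField(amplitude=3.0, correlation_length=50.0,
                                world_bounds=(0, 0, 400, 400), seed=3)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 400, size=(5000, 2))
        disp = field.warp_displacement(pts)
        # normalisation probes a dense grid; off-grid spline overshoot stays
        # below half a percent of the stated amplitude
        assert np.hypot(disp[:, 0], disp[:, 1]).max() <= 3.0 * 1.005

    def test_same_seed_same_field(self):
        pts = np.random.default_rng(1).uniform(0, 400, size=(100, 2))
        a = DistortionField(amplitude=2.0, world_bounds=(0, 0, 400, 400), seed=5)
        b = DistortionField(amplitude=2.0, world_bounds=(0, 0, 400, 400), seed=5)
        assert np.array_equal(a.apply(pts), b.apply(pts))


class TestRender:
    def test_single_well_peak_lands_on_distorted_centre(self):
        grid = make_grid(1, 1, 50, "square")
        field = DistortionField(
            similarity=SimilarityTransform(1.0, 0.0, 20.3, 17.8))
        img, spots = render_image(grid, field, spot_sigma=2.0, noise_sigma=0.0)
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert abs(peak[1] - spots[0, 0]) <= 0.5
        assert abs(peak[0] - spots[0, 1]) <= 0.5

    def test_spot_contrast_clears_noise_floor(self):
        grid = make_grid(3, 3, 50, "square")
        field = DistortionField(similarity=SimilarityTransform(1.0, 0.0, 0, 0))
        noise = 100.0
        img, spots = render_image(grid, field, spot_sigma=2.0,
                                  noise_sigma=noise, seed=1)
        centre = img[int(round(spots[0, 1])), int(round(spots[0, 0]))]
        background = np.median(img.astype(float))
        assert centre > background + 10 * noise

    def test_oversized_raster_rejected(self):
        grid = make_grid(2, 2, 5000, "square")
        field = DistortionField()
        with pytest.raises(ValueError, match="maximum side"):
            render_image(grid, field, max_side=512)

    def test_tiles_cover_image_with_jittered_offsets(self):
        img = np.arange(300 * 300, dtype=np.uint16).reshape(300, 300)
        tiles = render_tiles(img, (120, 120), overlap_fraction=0.2,
                             jitter_px=2, seed=0)
        for tile, nominal, true in tiles:
            assert tile.shape == (120, 120)
            assert abs(true[0] - nominal[0]) <= 2
            assert abs(true[1] - nominal[1]) <= 2
            assert np.array_equal(tile, img[true[1]:true[1] + 120,
                                            true[0]:true[0] + 120])
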