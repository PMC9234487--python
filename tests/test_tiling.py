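import numpy as np
import pytest

from forestcast.errors import EmptyStudyAreaError, InvalidParametersError
from forestcast.raster_io import RasterGrid, StudyAreaMask
from forestcast.tiling import (
    BlockSpec,
    coverage_completion,
    crop_block,
    plan_blocks,
    stitch,
)


def coverage_ok(plan, mask):
    """Brute-force per-pixel membership oracle."""
    covered = np.zeros(mask.shape, bool)
    for b in plan.blocks:
        covered[b.row_off : b.row_off + b.window, b.col_off : b.col_off + b.window] = True
    return bool((covered | ~mask.values).all())


class TestPlanBlocks:
    def test_exact_lattice_on_all_true_mask(self, full_mask):
        plan = plan_blocks(full_mask(8, 8), window=4, stride=4)
        assert [(b.row_off, b.col_off) for b in plan.blocks] == [
            (0, 0),
            (0, 4),
            (4, 0),
            (4, 4),
        ]
        assert coverage_ok(plan, full_mask(8, 8))

    def test_single_true_pixel_yields_single_containing_block(self):
        values = np.zeros((16, 16), bool)
        values[9, 9] = True
        mask = StudyAreaMask(values)
        plan = plan_blocks(mask, window=4, stride=4)
        assert len(plan.blocks) == 1
        b = plan.blocks[0]
        assert b.row_off <= 9 < b.row_off + 4 and b.col_off <= 9 < b.col_off + 4

    def test_completion_covers_lattice_remainder(self, full_mask):
        # 10x10 grid: phase-1 lattice reaches rows/cols 0..7 only
        mask = full_mask(10, 10)
        plan = plan_blocks(mask, window=4, stride=4)
        covered = np.zeros((10, 10), int)
        for b in plan.blocks:
            covered[b.row_off : b.row_off + 4, b.col_off : b.col_off + 4] += 1
        assert (covered > 0).sum() == 100

    def test_every_block_contains_study_pixels(self, rng):
        for _ in range(5):
            values = rng.random((24, 24)) < 0.2
            if not values.any():
                continue
            mask = StudyAreaMask(values)
            plan = plan_blocks(mask, window=6, stride=3)
            for b in plan.blocks:
                assert values[b.row_off : b.row_off + 6, b.col_off : b.col_off + 6].any()

    def test_random_masks_fully_covered(self, rng):
        """Coverage + relevance oracle over random blobby masks up to 64x64."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = int(r.integers(16, 65))
            values = r.random((n, n)) < 0.1
            if not values.any():
                values[n // 2, n // 2] = True
            mask = StudyAreaMask(values)
            plan = plan_blocks(mask, window=8, stride=4)
            assert coverage_ok(plan, mask), f"seed {seed} not covered"

    def test_determinism(self, rng):
        values = rng.random((32, 32)) < 0.3
        values[0, 0] = True
        mask = StudyAreaMask(values)
        p1 = plan_blocks(mask, 8, 4)
        p2 = plan_blocks(mask, 8, 4)
        assert [(b.ordinal, b.row_off, b.col_off) for b in p1.blocks] == [
            (b.ordinal, b.row_off, b.col_off) for b in p2.blocks
        ]

    def test_ordinals_row_major_contiguous(self, full_mask):
        plan = plan_blocks(full_mask(20, 20), 8, 4)
        offs = [(b.row_off, b.col_off) for b in plan.blocks]
        assert offs == sorted(offs)
        assert [b.ordinal for b in plan.blocks] == list(range(len(plan.blocks)))

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyStudyAreaError):
            plan_blocks(StudyAreaMask(np.zeros((8, 8), bool)), 4, 4)

    def test_window_larger_than_grid_rejected(self, full_mask):
        with pytest.raises(InvalidParametersError):
            plan_blocks(full_mask(8, 8), window=16, stride=4)


class TestCoverageCompletion:
    def test_no_uncovered_pixels_returns_empty(self, full_mask):
        mask = full_mask(8, 8)
        assert coverage_completion(mask, np.ones((8, 8), bool), 4) == []

    def test_single_uncovered_pixel_covered_by_one_block(self):
        values = np.zeros((16, 16), bool)
        values[3, 12] = True
        mask = StudyAreaMask(values)
        out = coverage_completion(mask, np.zeros((16, 16), bool), 4)
        assert len(out) == 1
        b = out[0]
        assert b.row_off <= 3 < b.row_off + 4 and b.col_off <= 12 < b.col_off + 4

    def test_l_shape_covered_within_greedy_budget(self):
        values = np.zeros((32, 32), bool)
        values[0:24, 0:6] = True
        values[18:24, 0:24] = True
        mask = StudyAreaMask(values)
        out = coverage_completion(mask, np.zeros((32, 32), bool), 8)
        covered = np.zeros((32, 32), bool)
        for b in out:
            covered[b.row_off : b.row_off + 8, b.col_off : b.col_off + 8] = True
        assert (covered | ~values).all()
        # brute-force greedy set-cover oracle over all window positions
        greedy = 0
        uncovered = values.copy()
        while uncovered.any():
            best = 0
            for r in range(25):
                for c in range(25):
                    g = uncovered[r : r + 8, c : c + 8].sum()
                    if g > best:
                        best, br, bc = g, r, c
            uncovered[br : br + 8, bc : bc + 8] = False
            greedy += 1
        assert len(out) <= 2 * greedy  # hill climb is local, allow slack factor


class TestCropStitch:
    def grid(self, values):
        values = np.asarray(values)
        return RasterGrid(values=values, nodata_mask=np.zeros(values.shape, bool))

    def test_full_extent_crop_is_identity(self):
        g = self.grid(np.arange(16).reshape(4, 4))
        spec = BlockSpec(0, 0, 0, 4)
        np.testing.assert_array_equal(crop_block(g, spec), g.values)

    def test_crop_indexing(self):
        rows, cols = np.meshgrid(range(4), range(4), indexing="ij")
        g = self.grid(10 * rows + cols)
        np.testing.assert_array_equal(
            crop_block(g, BlockSpec(0, 1, 1, 2)), [[11, 12], [21, 22]]
        )

    def test_out_of_bounds_crop_rejected(self):
        g = self.grid(np.zeros((4, 4)))
        with pytest.raises(IndexError):
            crop_block(g, BlockSpec(0, 2, 2, 4))

    def test_overlap_mean_of_constants(self, full_mask):
        from forestcast.tiling import BlockPlan

        plan = BlockPlan(
            blocks=[BlockSpec(0, 0, 0, 4), BlockSpec(1, 0, 2, 4)],
            window=4,
            stride=2,
            source_rows=4,
            source_cols=6,
        )
        frames = [
            (plan.blocks[0], np.zeros((4, 4))),
            (plan.blocks[1], np.ones((4, 4))),
        ]
        out = stitch(frames, plan)
        np.testing.assert_array_equal(out.values[:, 0:2], 0.0)
        np.testing.assert_array_equal(out.values[:, 2:4], 0.5)
        np.testing.assert_array_equal(out.values[:, 4:6], 1.0)
        assert not out.nodata_mask.any()

    def test_crop_stitch_round_trip_on_random_grids(self, rng, full_mask):
        """Stitching ground-truth crops reproduces the source exactly."""
        for _ in range(5):
            n = int(rng.integers(12, 33))
            g = self.grid(rng.random((n, n)) * 255)
            window = 8 if n >= 8 else n
            plan = plan_blocks(full_mask(n, n), window, max(1, window // 2))
            frames = [(s, crop_block(g, s)) for s in plan.blocks]
            out = stitch(frames, plan)
            covered = ~out.nodata_mask
            np.testing.assert_allclose(out.values[covered], g.values[covered], rtol=0, atol=1e-12)

    def test_shape_mismatch_rejected(self, full_mask):
        plan = plan_blocks(full_mask(8, 8), 4, 4)
        with pytest.raises(ValueError, match="shape"):
            stitch([(plan.blocks[0], np.zeros((3, 3)))], plan)
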