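import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccemap.ingest import EffectiveRegionMask
from ccemap.patching import (
    ExclusionReason,
    ExclusionRule,
    PatchSpec,
    extract_patches,
    is_excluded,
    patch_gray_stats,
    tile_grid,
)


def brute_force_grid(h, w, size, stride):
    """Independent enumeration: every stride-multiple offset whose window fits."""
    return [
        (r, c)
        for r in range(0, max(h, 1), stride)
        for c in range(0, max(w, 1), stride)
        if r + size <= h and c + size <= w
    ]


def _patch_still(values: np.ndarray):
    """Embed a 128x128 grayscale patch as an RGB still."""
    return np.repeat(values[..., None], 3, axis=-1).astype(np.uint8)


class TestTileGrid:
    def test_native_still_yields_225_windows(self):
        specs = tile_grid(576, 576)
        assert len(specs) == 225
        assert specs[0] == PatchSpec(0, 0)
        assert specs[1] == PatchSpec(0, 32)  # rightwards first
        assert specs[-1] == PatchSpec(448, 448)

    def test_exact_fit_single_window(self):
        assert tile_grid(128, 128) == [PatchSpec(0, 0)]

    def test_image_smaller_than_patch_yields_nothing(self):
        assert tile_grid(127, 576) == []

    @settings(max_examples=200, derandomize=True)
    @given(
        h=st.integers(0, 100),
        w=st.integers(0, 100),
        size=st.integers(1, 40),
        stride=st.integers(1, 20),
    )
    def test_matches_brute_force_enumeration(self, h, w, size, stride):
        specs = tile_grid(h, w, size, stride)
        assert [(s.row, s.col) for s in specs] == brute_force_grid(h, w, size, stride)


class TestGrayStats:
    def test_all_dark_patch(self):
        n_low, n_high = patch_gray_stats(
            _patch_still(np.zeros((128, 128))), PatchSpec(0, 0)
        )
        assert (n_low, n_high) == (16384, 0)

    def test_all_bright_patch(self):
        n_low, n_high = patch_gray_stats(
            _patch_still(np.full((128, 128), 255)), PatchSpec(0, 0)
        )
        assert (n_low, n_high) == (0, 16384)

    def test_exact_dark_count(self):
        values = np.full((128, 128), 128)
        values.flat[:164] = 0
        assert patch_gray_stats(_patch_still(values), PatchSpec(0, 0)) == (164, 0)

    def test_thresholds_are_strict(self):
        # intensity exactly 70 is not "low"; exactly 230 is not "high"
        at_cuts = np.full((128, 128), 70)
        at_cuts[64:] = 230
        assert patch_gray_stats(_patch_still(at_cuts), PatchSpec(0, 0)) == (0, 0)

    def test_out_of_bounds_spec(self):
        with pytest.raises(IndexError):
            patch_gray_stats(_patch_still(np.zeros((128, 128))), PatchSpec(0, 32))


class TestExclusionBoundaries:
    @pytest.mark.parametrize(
        "n_dark,expect",
        [(163, (False, ExclusionReason.NONE)), (164, (True, ExclusionReason.BLACKOUT))],
    )
    def test_blackout_tipping_point(self, n_dark, expect):
        values = np.full((128, 128), 128)
        values.flat[:n_dark] = 0
        assert is_excluded(_patch_still(values), PatchSpec(0, 0)) == expect

    @pytest.mark.parametrize(
        "n_bright,expect",
        [
            (819, (False, ExclusionReason.NONE)),
            (820, (True, ExclusionReason.OVEREXPOSED)),
        ],
    )
    def test_overexposure_tipping_point(self, n_bright, expect):
        values = np.full((128, 128), 128)
        values.flat[:n_bright] = 255
        assert is_excluded(_patch_still(values), PatchSpec(0, 0)) == expect

    def test_blackout_takes_precedence(self):
        values = np.full((128, 128), 128)
        values.flat[:164] = 0
        values.flat[164 : 164 + 820] = 255
        assert is_excluded(_patch_still(values), PatchSpec(0, 0)) == (
            True,
            ExclusionReason.BLACKOUT,
        )

    def test_decision_is_permutation_invariant(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 256, (128, 128))
        shuffled = rng.permutation(values.ravel()).reshape(128, 128)
        assert is_excluded(_patch_still(values), PatchSpec(0, 0)) == is_excluded(
            _patch_still(shuffled), PatchSpec(0, 0)
        )


class TestExtractPatches:
    def test_uniform_gray_keeps_all_windows(self, mid_gray_still):
        assert len(extract_patches(mid_gray_still)) == 225

    def test_all_black_keeps_nothing(self):
        px = np.zeros((576, 576, 3), dtype=np.uint8)
        assert extract_patches(px) == []

    def test_mask_restricts_to_fully_inside_windows(self, mid_gray_still):
        mask = np.zeros((576, 576), dtype=bool)
        mask[:160, :160] = True
        specs = extract_patches(mid_gray_still, EffectiveRegionMask(mask))
        assert {(s.row, s.col) for s in specs} == {(0, 0), (0, 32), (32, 0), (32, 32)}

    def test_subset_of_tile_grid_and_mask_monotonicity(self, mid_gray_still):
        grid = set(tile_grid(576, 576))
        full_mask = EffectiveRegionMask(np.ones((576, 576), dtype=bool))
        small = np.zeros((576, 576), dtype=bool)
        small[:300, :300] = True
        all_specs = extract_patches(mid_gray_still, full_mask)
        masked_specs = extract_patches(mid_gray_still, EffectiveRegionMask(small))
        assert set(all_specs) <= grid
        assert set(masked_specs) <= set(all_specs)

    def test_raising_fractions_never_drops_patches(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 256, (256, 256, 3), dtype=np.uint8)
        loose = ExclusionRule(low_frac=0.9, high_frac=0.9)
        strict = ExclusionRule(low_frac=0.005, high_frac=0.005)
        assert set(extract_patches(px, rule=strict)) <= set(
            extract_patches(px, rule=loose)
        )

    def test_dimension_mismatch(self, mid_gray_still):
        with pytest.raises(ValueError, match="mask shape"):
            extract_patches(
                mid_gray_still, EffectiveRegionMask(np.ones((10, 10), dtype=bool))
            )


def test_exclusion_rule_validation():
    with pytest.raises(ValueError):
        ExclusionRule(low_cut=250, high_cut=230)
    with pytest.raises(ValueError):
        ExclusionRule(low_frac=0.0)
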