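import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccemap.classify import ClassLabel
from ccemap.patching import PatchSpec
from ccemap.severity import (
    ClassifiedGrid,
    SeverityProfile,
    class_area,
    severity_profile,
    union_area,
)


def pixel_set_area(specs):
    """Independent union oracle: enumerate covered pixels as a set."""
    covered = set()
    for s in specs:
        covered |= {
            (r, c)
            for r in range(s.row, s.row + s.size)
            for c in range(s.col, s.col + s.size)
        }
    return len(covered)


def grid_of(items, h=576, w=576):
    return ClassifiedGrid("s", items, h, w)


class TestClassArea:
    def test_single_window(self):
        g = grid_of([(PatchSpec(0, 0), ClassLabel.MES0)])
        assert class_area(g, ClassLabel.MES0) == 16384

    def test_two_overlapping_windows_one_stride_apart(self):
        g = grid_of(
            [(PatchSpec(0, 0), ClassLabel.MES0), (PatchSpec(0, 32), ClassLabel.MES0)]
        )
        assert class_area(g, ClassLabel.MES0) == 128 * 160  # 20480

    def test_absent_class_has_zero_area(self):
        g = grid_of([(PatchSpec(0, 0), ClassLabel.MES0)])
        assert class_area(g, ClassLabel.MES2) == 0

    def test_order_and_duplicate_invariance(self):
        items = [
            (PatchSpec(0, 0), ClassLabel.MES1),
            (PatchSpec(32, 32), ClassLabel.MES1),
            (PatchSpec(0, 0), ClassLabel.MES1),  # duplicate pair
        ]
        a = class_area(grid_of(items), ClassLabel.MES1)
        b = class_area(grid_of(items[::-1]), ClassLabel.MES1)
        assert a == b == pixel_set_area([PatchSpec(0, 0), PatchSpec(32, 32)])

    def test_nonoverlapping_closed_form(self):
        specs = [PatchSpec(r, c) for r in (0, 128) for c in (0, 128, 256)]
        g = grid_of([(s, ClassLabel.MES3) for s in specs])
        assert class_area(g, ClassLabel.MES3) == 16384 * 6

    @settings(max_examples=150, derandomize=True)
    @given(st.data())
    def test_union_matches_pixel_set_oracle(self, data):
        h = data.draw(st.integers(8, 48))
        w = data.draw(st.integers(8, 48))
        size = data.draw(st.integers(1, 8))
        n = data.draw(st.integers(0, 6))
        specs = [
            PatchSpec(
                data.draw(st.integers(0, h - size)),
                data.draw(st.integers(0, w - size)),
                size,
            )
            for _ in range(n)
        ]
        assert union_area(specs, h, w) == pixel_set_area(specs)


class TestSeverityProfile:
    def test_all_inadequate_grid_is_excluded(self):
        g = grid_of([(PatchSpec(0, 0), ClassLabel.INADEQUATE)])
        p = severity_profile(g)
        assert p.excluded and p.total_area == 0 and p.fractions is None

    def test_two_disjoint_classes_split_evenly(self):
        g = grid_of(
            [(PatchSpec(0, 0), ClassLabel.MES0), (PatchSpec(0, 256), ClassLabel.MES2)]
        )
        assert severity_profile(g).fractions == (0.5, 0.0, 0.5, 0.0)

    def test_three_overlapping_windows_single_class(self):
        g = grid_of(
            [(PatchSpec(0, c), ClassLabel.MES1) for c in (0, 32, 64)]
        )
        p = severity_profile(g)
        assert p.areas[1] == 128 * 192  # 24576
        assert p.fractions == (0.0, 1.0, 0.0, 0.0)

    def test_fractions_sum_to_one_whenever_total_positive(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            items = [
                (
                    PatchSpec(int(rng.integers(0, 15)) * 32,
                              int(rng.integers(0, 15)) * 32),
                    ClassLabel(int(rng.integers(0, 6))),
                )
                for _ in range(rng.integers(1, 12))
            ]
            # deduplicate conflicting labels on the same window
            dedup = dict(items)
            p = severity_profile(grid_of(list(dedup.items())))
            if not p.excluded:
                assert abs(sum(p.fractions) - 1.0) < 1e-9
                assert p.total_area == sum(p.areas)

    def test_inadequate_and_ileal_windows_never_move_fractions(self):
        base = [(PatchSpec(0, 0), ClassLabel.MES0), (PatchSpec(256, 256), ClassLabel.MES3)]
        extra = base + [
            (PatchSpec(128, 128), ClassLabel.INADEQUATE),
            (PatchSpec(448, 0), ClassLabel.ILEAL),
        ]
        assert severity_profile(grid_of(base)).fractions == severity_profile(
            grid_of(extra)
        ).fractions

    def test_fractions_invariant_to_uniform_translation(self):
        items = [
            (PatchSpec(0, 0), ClassLabel.MES0),
            (PatchSpec(32, 64), ClassLabel.MES2),
        ]
        shifted = [
            (PatchSpec(s.row + 96, s.col + 128), lab) for s, lab in items
        ]
        assert (
            severity_profile(grid_of(items)).fractions
            == severity_profile(grid_of(shifted)).fractions
        )


class TestValidation:
    def test_conflicting_labels_on_same_window_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            grid_of(
                [(PatchSpec(0, 0), ClassLabel.MES0), (PatchSpec(0, 0), ClassLabel.MES1)]
            )

    def test_out_of_bounds_window_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            grid_of([(PatchSpec(500, 500), ClassLabel.MES0)])

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValueError):
            SeverityProfile("s", (1, 0, 0, 0), 2, (0.5, 0.5, 0, 0), False)
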