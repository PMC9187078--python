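import numpy as np
import pytest

from ccemap.ingest import Camera, Segment
from ccemap.severity import SeverityProfile
from ccemap.topomap import (
    build_topographic_map,
    export_table,
    map_to_json,
    read_table,
    render_map,
)


def profile(camera, segment, index, fractions=None, excluded=False):
    if excluded:
        return SeverityProfile(
            f"s:{camera.value}:{segment.value}:{index}", (0, 0, 0, 0), 0, None,
            True, camera, segment, index,
        )
    areas = tuple(int(round(f * 16384)) for f in fractions)
    total = sum(areas)
    return SeverityProfile(
        f"s:{camera.value}:{segment.value}:{index}", areas, total,
        tuple(a / total for a in areas), False, camera, segment, index,
    )


def one_camera_track(n_per_segment=50, camera=Camera.FORWARD):
    profiles = []
    for segment in Segment:
        for i in range(n_per_segment):
            profiles.append(profile(camera, segment, i, (0.5, 0.25, 0.25, 0.0)))
    return profiles


class TestBuild:
    def test_anatomical_ordering_of_a_full_track(self):
        tmap = build_topographic_map(one_camera_track(), study_id="p1")
        track = tmap.track(Camera.FORWARD)
        assert len(track) == 200
        segs = [p.segment for p in track]
        assert segs == sorted(segs, key=list(Segment).index)
        idx = [p.index_in_segment for p in track[:50]]
        assert idx == list(range(50))

    def test_input_order_is_irrelevant(self):
        profiles = one_camera_track(10)
        rng = np.random.default_rng(0)
        shuffled = [profiles[i] for i in rng.permutation(len(profiles))]
        a = build_topographic_map(profiles, "p")
        b = build_topographic_map(shuffled, "p")
        assert [p.still_id for p in a.track(Camera.FORWARD)] == [
            p.still_id for p in b.track(Camera.FORWARD)
        ]

    def test_duplicate_position_names_the_collision(self):
        p = profile(Camera.FORWARD, Segment.RECTUM, 7, (1.0, 0, 0, 0))
        with pytest.raises(ValueError, match="rectum.*7"):
            build_topographic_map([p, p])


class TestRender:
    def test_column_and_boundary_counts(self, tmp_path):
        tmap = build_topographic_map(one_camera_track(50), "p1")
        fig = render_map(tmap, tmp_path / "map.png")
        (ax,) = fig.axes
        assert len(ax.containers) == 4  # one stacked series per MES grade
        assert all(len(c) == 200 for c in ax.containers)
        assert len(ax.lines) == 3  # internal segment boundaries
        assert (tmp_path / "map.png").exists()

    def test_excluded_profile_renders_blank_column(self):
        tmap = build_topographic_map(
            [profile(Camera.FORWARD, Segment.RECTUM, 0, excluded=True)], "p"
        )
        fig = render_map(tmap)
        (ax,) = fig.axes
        heights = [bar.get_height() for c in ax.containers for bar in c]
        assert heights == [0.0] * 4

    def test_half_and_half_profile(self):
        tmap = build_topographic_map(
            [profile(Camera.FORWARD, Segment.RECTUM, 0, (0.5, 0, 0.5, 0))], "p"
        )
        fig = render_map(tmap)
        (ax,) = fig.axes
        heights = [c[0].get_height() for c in ax.containers]
        assert heights == [50.0, 0.0, 50.0, 0.0]

    def test_cameras_render_independently(self):
        fwd = one_camera_track(5, Camera.FORWARD)
        bwd = one_camera_track(5, Camera.BACKWARD)
        both = render_map(build_topographic_map(fwd + bwd, "p"))
        only_fwd = render_map(build_topographic_map(fwd, "p"))
        h_both = [b.get_height() for c in both.axes[0].containers for b in c]
        h_only = [b.get_height() for c in only_fwd.axes[0].containers for b in c]
        assert h_both == h_only

    def test_empty_map_rejected(self):
        from ccemap.topomap import TopographicMap

        with pytest.raises(ValueError, match="empty"):
            render_map(TopographicMap("p", {}))


class TestExport:
    def test_pure_profile_row(self, tmp_path):
        tmap = build_topographic_map(
            [profile(Camera.FORWARD, Segment.RECTUM, 0, (1.0, 0, 0, 0))], "p"
        )
        df = export_table(tmap, tmp_path / "t.csv")
        row = df.iloc[0]
        assert [row.pct0, row.pct1, row.pct2, row.pct3] == [100.0, 0.0, 0.0, 0.0]

    def test_excluded_row_flagged_with_empty_percentages(self, tmp_path):
        tmap = build_topographic_map(
            [profile(Camera.FORWARD, Segment.RECTUM, 0, excluded=True)], "p"
        )
        path = tmp_path / "t.csv"
        export_table(tmap, path)
        df = read_table(path)
        assert bool(df.iloc[0].excluded)
        assert df.iloc[0][["pct0", "pct1", "pct2", "pct3"]].isna().all()

    def test_third_splits_round_half_up(self):
        tmap = build_topographic_map(
            [profile(Camera.FORWARD, Segment.RECTUM, 0, (1 / 3, 1 / 3, 1 / 3, 0.0))],
            "p",
        )
        df = export_table(tmap)
        row = df.iloc[0]
        assert [row.pct0, row.pct1, row.pct2, row.pct3] == [33.3, 33.3, 33.3, 0.0]

    def test_roundtrip_reconstructs_fractions_to_one_decimal(self, tmp_path):
        rng = np.random.default_rng(2)
        profiles = []
        for i in range(20):
            f = rng.dirichlet(np.ones(4))
            profiles.append(profile(Camera.FORWARD, Segment.TRANSVERSE, i, f))
        tmap = build_topographic_map(profiles, "p")
        path = tmp_path / "t.csv"
        export_table(tmap, path)
        df = read_table(path)
        for p, (_, row) in zip(tmap.track(Camera.FORWARD), df.iterrows()):
            for k in range(4):
                assert row[f"pct{k}"] == pytest.approx(
                    p.fractions[k] * 100, abs=0.05000001
                )

    def test_json_dump_is_parseable(self):
        import json

        tmap = build_topographic_map(one_camera_track(3), "p")
        payload = json.loads(map_to_json(tmap))
        assert len(payload["tracks"]["f"]) == 12
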