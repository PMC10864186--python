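import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cafi.core_io import (
    FormatError,
    ImageSequence,
    LabelSequence,
    Track,
    TrackParseError,
    TrackSet,
    VolumeSequence,
    max_project_z,
    normalize_sequence,
    read_image_stack,
    read_isbi_xml,
    read_tracks_table,
    write_image_stack,
    write_isbi_xml,
    write_tracks_table,
)


def _random_tracks(rng, n=3):
    tracks = []
    for tid in range(n):
        length = int(rng.integers(1, 8))
        frames = np.sort(rng.choice(50, size=length, replace=False))
        positions = np.column_stack(
            [rng.uniform(0, 100, length), rng.uniform(0, 100, length), np.zeros(length)]
        )
        tracks.append(Track(track_id=tid, frames=frames, positions=positions))
    return TrackSet(tracks)


class TestImageStackIO:
    @pytest.mark.parametrize("dtype", [np.uint8, np.uint16, np.float32])
    def test_tiff_round_trip_is_lossless(self, tmp_path, rng, dtype):
        data = (rng.random((5, 32, 32)) * 200).astype(dtype)
        path = tmp_path / "stack.tif"
        write_image_stack(ImageSequence(frames=data), path)
        back = read_image_stack(path)
        assert isinstance(back, ImageSequence)
        np.testing.assert_array_equal(back.frames, data)

    def test_single_page_becomes_length_one_sequence(self, tmp_path, rng):
        data = rng.random((1, 16, 16)).astype(np.float32)
        path = tmp_path / "one.tif"
        write_image_stack(ImageSequence(frames=data), path)
        back = read_image_stack(path)
        assert len(back) == 1
        np.testing.assert_array_equal(back.frames, data)

    def test_four_dimensional_file_becomes_volume(self, tmp_path, rng):
        data = rng.random((4, 3, 16, 16)).astype(np.float32)
        path = tmp_path / "vol.tif"
        write_image_stack(VolumeSequence(frames=data), path)
        back = read_image_stack(path)
        assert isinstance(back, VolumeSequence)
        assert back.frames.shape == (4, 3, 16, 16)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image_stack(tmp_path / "nope.tif")

    def test_rgb_file_rejected(self, tmp_path):
        import tifffile

        rgb = np.zeros((8, 8, 3), dtype=np.uint8)
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, rgb, photometric="rgb")
        with pytest.raises(FormatError):
            read_image_stack(path)

    def test_non_finite_values_refused_on_write(self, tmp_path):
        data = np.ones((2, 8, 8))
        seq = ImageSequence(frames=data)
        seq.frames[0, 0, 0] = np.nan  # bypass constructor validation
        with pytest.raises(ValueError):
            write_image_stack(seq, tmp_path / "bad.tif")

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            write_image_stack(ImageSequence(frames=np.ones((1, 4, 4))), "")


class TestTrackIO:
    def test_isbi_xml_round_trip(self, tmp_path, rng):
        tracks = _random_tracks(rng)
        path = tmp_path / "tracks.xml"
        write_isbi_xml(tracks, path)
        back = read_isbi_xml(path)
        assert len(back) == len(tracks)
        for a, b in zip(tracks, back):
            np.testing.assert_array_equal(a.frames, b.frames)
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_single_detection_track_survives(self, tmp_path):
        tracks = TrackSet(
            [Track(track_id=0, frames=[7], positions=[[1.5, 2.5, 0.0]])]
        )
        path = tmp_path / "one.xml"
        write_isbi_xml(tracks, path)
        back = read_isbi_xml(path)
        assert len(back) == 1 and len(back[0]) == 1
        assert back[0].frames[0] == 7

    def test_missing_attribute_names_element(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text(
            "<root><particle><detection t='0' y='1' z='0'/></particle></root>"
        )
        with pytest.raises(TrackParseError, match="x"):
            read_isbi_xml(path)

    def test_table_round_trip(self, tmp_path, rng):
        tracks = _random_tracks(rng)
        path = tmp_path / "tracks.tsv"
        write_tracks_table(tracks, path)
        back = read_tracks_table(path)
        for a, b in zip(tracks, back):
            np.testing.assert_array_equal(a.frames, b.frames)
            np.testing.assert_allclose(a.positions, b.positions)

    def test_empty_table_gives_empty_trackset(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(read_tracks_table(path)) == 0

    def test_non_numeric_coordinate_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("track_id\tframe\tx\ty\tz\n0\t0\toops\t1\t0\n")
        with pytest.raises(TrackParseError):
            read_tracks_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("track_id\tframe\tx\ty\n0\t0\t1\t1\n")
        with pytest.raises(TrackParseError):
            read_tracks_table(path)

    @settings(deadline=None, max_examples=25)
    @given(
        coords=st.lists(
            st.tuples(
                st.floats(-1e3, 1e3, allow_nan=False),
                st.floats(-1e3, 1e3, allow_nan=False),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_xml_round_trip_any_coordinates(self, tmp_path_factory, coords):
        positions = [[x, y, 0.0] for x, y in coords]
        tracks = TrackSet(
            [Track(track_id=0, frames=np.arange(len(coords)), positions=positions)]
        )
        path = tmp_path_factory.mktemp("xml") / "t.xml"
        write_isbi_xml(tracks, path)
        back = read_isbi_xml(path)
        np.testing.assert_array_equal(back[0].positions, np.asarray(positions))


class TestDomainTypes:
    def test_track_requires_increasing_frames(self):
        with pytest.raises(ValueError):
            Track(track_id=0, frames=[3, 3], positions=[[0, 0, 0], [1, 1, 0]])

    def test_sequence_rejects_non_finite(self):
        bad = np.ones((2, 4, 4))
        bad[1, 1, 1] = np.inf
        with pytest.raises(ValueError):
            ImageSequence(frames=bad)

    def test_labels_must_be_integer(self):
        with pytest.raises(ValueError):
            LabelSequence(masks=np.zeros((1, 4, 4), dtype=float))


class TestPreprocessing:
    def test_max_projection_dominates_every_slice(self, rng):
        vol = VolumeSequence(frames=rng.random((3, 4, 8, 8)))
        proj = max_project_z(vol)
        for z in range(4):
            assert (proj.frames >= vol.frames[:, z]).all()

    def test_single_slice_projection_is_identity(self, rng):
        vol = VolumeSequence(frames=rng.random((2, 1, 8, 8)))
        np.testing.assert_array_equal(max_project_z(vol).frames, vol.frames[:, 0])

    def test_disjoint_spots_both_survive_projection(self):
        vol = np.zeros((1, 2, 8, 8))
        vol[0, 0, 1, 1] = 5.0
        vol[0, 1, 6, 6] = 7.0
        proj = max_project_z(VolumeSequence(frames=vol))
        assert proj.frames[0, 1, 1] == 5.0 and proj.frames[0, 6, 6] == 7.0

    def test_minmax_attains_zero_and_one(self, rng):
        seq = ImageSequence(frames=rng.random((3, 8, 8)) * 255)
        out = normalize_sequence(seq)
        assert out.frames.min() == 0.0 and out.frames.max() == 1.0

    def test_constant_input_maps_to_zero_with_warning(self):
        seq = ImageSequence(frames=np.full((2, 8, 8), 3.0))
        with pytest.warns(UserWarning):
            out = normalize_sequence(seq)
        assert (out.frames == 0).all()

    def test_none_mode_keeps_values(self, rng):
        seq = ImageSequence(frames=rng.random((2, 8, 8)))
        np.testing.assert_array_equal(
            normalize_sequence(seq, "none").frames, seq.frames
        )
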