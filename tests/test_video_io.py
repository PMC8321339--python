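import numpy as np
import pytest

from frozenframes import (
    FrameStack,
    ROISpec,
    SyntheticSpec,
    crop_roi,
    generate_sequence,
    load_annotations,
    load_frames,
    partition_scenes,
    save_frames,
)


def write_images(directory, frames):
    import imageio.v2 as iio

    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames, start=1):
        iio.imwrite(directory / f"f_{i:03d}.png", frame.astype(np.uint8))


class TestLoadFrames:
    def test_identical_images_load_as_equal_frames(self, tmp_path):
        frame = np.full((8, 8), 120, dtype=np.uint8)
        write_images(tmp_path / "seq", [frame] * 3)
        stack = load_frames(tmp_path / "seq", fps=25.0)
        assert stack.n_frames == 3
        assert stack.fps == 25.0
        assert np.array_equal(stack.frames[0], stack.frames[1])
        assert np.array_equal(stack.frames[1], stack.frames[2])

    def test_save_load_round_trip(self, tmp_path):
        spec = SyntheticSpec(T=12, frame_shape=(16, 16), seed=3)
        stack, _ = generate_sequence(spec)
        quantized = np.clip(np.rint(stack.frames), 0, 255)
        save_frames(stack, tmp_path / "rt")
        reloaded = load_frames(tmp_path / "rt", fps=stack.fps)
        assert reloaded.n_frames == stack.n_frames
        np.testing.assert_array_equal(reloaded.frames, quantized)

    def test_generator_clip_has_declared_shape(self, tmp_path):
        spec = SyntheticSpec(T=64, frame_shape=(32, 24), seed=1)
        stack, _ = generate_sequence(spec)
        save_frames(stack, tmp_path / "gen")
        reloaded = load_frames(tmp_path / "gen", fps=25.0)
        assert reloaded.n_frames == 64
        assert reloaded.frame_shape == (32, 24)

    def test_deterministic_for_fixed_source(self, tmp_path):
        rng = np.random.default_rng(0)
        write_images(tmp_path / "d", list(rng.integers(0, 255, size=(3, 8, 8))))
        a = load_frames(tmp_path / "d", fps=30.0)
        b = load_frames(tmp_path / "d", fps=30.0)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_missing_source_and_missing_fps(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_frames(tmp_path / "nope", fps=25.0)
        write_images(tmp_path / "s", [np.zeros((4, 4))] * 2)
        with pytest.raises(ValueError, match="fps"):
            load_frames(tmp_path / "s")

    def test_inconsistent_shapes_rejected(self, tmp_path):
        import imageio.v2 as iio

        d = tmp_path / "bad"
        d.mkdir()
        iio.imwrite(d / "a.png", np.zeros((4, 4), dtype=np.uint8))
        iio.imwrite(d / "b.png", np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="inconsistent"):
            load_frames(d, fps=25.0)


class TestAnnotations:
    def test_default_event_length_follows_frame_rate(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text(
            "sequence_id,onset,apex,offset,fps\n"
            "1.1,49,,62,25\n"
            "casme_x,100,120,140,200\n"
        )
        anns = load_annotations(path)
        assert anns[0].onset == 49 and anns[0].offset == 62 and anns[0].N == 8
        assert anns[0].apex is None
        assert anns[1].N == 64

    def test_invalid_ordering_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sequence_id,onset,apex,offset,fps\ns,10,12,11,25\n")
        with pytest.raises(ValueError, match="row 0"):
            load_annotations(path)

    def test_explicit_N_column_wins(self, tmp_path):
        path = tmp_path / "n.csv"
        path.write_text("sequence_id,onset,apex,offset,fps,N\nx,5,,9,25,20\n")
        assert load_annotations(path)[0].N == 20


class TestCropRoi:
    def test_full_frame_is_identity(self, random_stack):
        roi = ROISpec(0, 0, 16, 16)
        np.testing.assert_array_equal(crop_roi(random_stack, roi).frames, random_stack.frames)

    def test_crop_shape_and_values(self, random_stack):
        roi = ROISpec(2, 3, 10, 10)
        cropped = crop_roi(random_stack, roi)
        assert cropped.frame_shape == (10, 10)
        assert cropped.n_frames == random_stack.n_frames
        np.testing.assert_array_equal(
            cropped.frames.mean(axis=(1, 2)),
            random_stack.frames[:, 3:13, 2:12].mean(axis=(1, 2)),
        )

    def test_nested_crops_compose(self, random_stack):
        outer = ROISpec(1, 2, 12, 10)
        inner = ROISpec(3, 1, 5, 6)
        twice = crop_roi(crop_roi(random_stack, outer), inner)
        once = crop_roi(random_stack, ROISpec(1 + 3, 2 + 1, 5, 6))
        np.testing.assert_array_equal(twice.frames, once.frames)

    def test_out_of_bounds_rejected(self, random_stack):
        with pytest.raises(ValueError, match="bounds"):
            crop_roi(random_stack, ROISpec(10, 10, 10, 10))


class TestPartitionScenes:
    def test_static_video_is_one_segment(self):
        stack = FrameStack(np.full((50, 4, 4), 10.0), fps=25.0)
        segs = partition_scenes(stack, cut_threshold=0.1)
        assert [(s.start, s.end) for s in segs] == [(1, 50)]

    def test_luminance_jump_forces_cut(self):
        frames = np.concatenate(
            [np.zeros((25, 4, 4)), np.full((25, 4, 4), 200.0)]
        )
        segs = partition_scenes(FrameStack(frames, fps=25.0), cut_threshold=0.1)
        assert [(s.start, s.end) for s in segs] == [(1, 25), (26, 50)]

    def test_user_cuts_take_precedence(self):
        stack = FrameStack(np.zeros((60, 4, 4)), fps=25.0)
        segs = partition_scenes(stack, user_cuts=[30])
        assert [(s.start, s.end) for s in segs] == [(1, 29), (30, 60)]

    def test_partition_covers_and_is_disjoint(self):
        rng = np.random.default_rng(5)
        frames = rng.uniform(0, 255, size=(40, 6, 6))
        segs = partition_scenes(FrameStack(frames, fps=25.0), cut_threshold=0.05)
        covered = [t for s in segs for t in range(s.start, s.end + 1)]
        assert covered == list(range(1, 41))


class TestFrameStack:
    def test_validation(self):
        with pytest.raises(ValueError):
            FrameStack(np.zeros((1, 4, 4)), fps=25.0)  # too few frames
        with pytest.raises(ValueError):
            FrameStack(np.zeros((5, 4, 4)), fps=0.0)
        with pytest.raises(ValueError):
            FrameStack(np.full((5, 4, 4), np.nan), fps=25.0)

    def test_slice_time_preserves_origin(self, random_stack):
        sub = random_stack.slice_time(3, 7)
        assert sub.t0 == 3
        assert list(sub.t_index) == [3, 4, 5, 6, 7]
        np.testing.assert_array_equal(sub.frames, random_stack.frames[2:7])
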