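"""Changed-block JPEG codec: delta detection, quality policy, wire format."""

import logging

import numpy as np
import pytest

import ctstream as cs
from ctstream.codec import (
    DEFAULT_KEYFRAME_INTERVAL,
    QUALITY_INTERACTIVE,
    QUALITY_STATIC,
)
from ctstream.errors import (
    DecodeFailureError,
    FrameSizeChangedError,
    NoTrafficError,
)


@pytest.fixture(scope="module")
def smooth_frame(ncct_medium):
    """A windowed phantom slice in the 320x480 handheld viewport."""
    vol, _ = ncct_medium
    plane = cs.orthogonal_plane(vol, "axial", 6 * vol.spacing[2])
    hu = cs.extract_slice(vol, plane)
    hu_view = cs.apply_view(hu, cs.ViewTransform(), (320, 480),
                            background=cs.mpr.BACKGROUND_HU)
    return cs.apply_window(hu_view, cs.WindowLevel(40, 80))


class TestEncode:
    def test_unchanged_frame_transmits_zero_blocks(self, smooth_frame):
        state = cs.CodecState()
        cs.encode_frame(state, smooth_frame, interactive=False)
        again = cs.encode_frame(state, smooth_frame, interactive=False)
        assert len(again.blocks) == 0

    def test_single_changed_pixel_transmits_one_of_2400_blocks(self):
        state = cs.CodecState()
        frame = np.zeros((320, 480), dtype=np.uint8)
        kf = cs.encode_frame(state, frame, interactive=False)
        assert len(kf.blocks) == 40 * 60 == 2400
        changed = frame.copy()
        changed[100, 250] = 255
        delta = cs.encode_frame(state, changed, interactive=True)
        assert len(delta.blocks) == 1
        assert delta.blocks[0][:2] == (100 // 8, 250 // 8)

    def test_quality_policy_interactive_25_static_100(self, smooth_frame):
        state = cs.CodecState()
        drag = cs.encode_frame(state, smooth_frame, interactive=True)
        assert drag.quality == QUALITY_INTERACTIVE == 25
        release = cs.encode_frame(state, 255 - smooth_frame, interactive=False)
        assert release.quality == QUALITY_STATIC == 100

    def test_static_frame_refines_blocks_sent_at_low_quality(self, smooth_frame):
        # blocks transmitted at quality 25 during a drag are re-sent at
        # quality 100 on release even when their pixels no longer change
        state = cs.CodecState()
        cs.encode_frame(state, smooth_frame, interactive=False)
        changed = smooth_frame.copy()
        changed[100:140, 200:280] = 255 - changed[100:140, 200:280]
        drag = cs.encode_frame(state, changed, interactive=True)
        assert drag.quality == QUALITY_INTERACTIVE
        release = cs.encode_frame(state, changed, interactive=False)
        assert release.quality == QUALITY_STATIC
        assert {b[:2] for b in release.blocks} == {b[:2] for b in drag.blocks}
        # and the refinement is one-shot: the next static frame is empty
        again = cs.encode_frame(state, changed, interactive=False)
        assert len(again.blocks) == 0

    def test_first_frame_is_keyframe_covering_grid(self, smooth_frame):
        state = cs.CodecState()
        kf = cs.encode_frame(state, smooth_frame, interactive=False)
        assert kf.keyframe
        assert len(kf.blocks) == (320 // 8) * (480 // 8)

    def test_periodic_keyframe_at_configured_interval(self):
        state = cs.CodecState(keyframe_interval=4)
        frame = np.zeros((32, 32), dtype=np.uint8)
        flags = []
        for i in range(9):
            frame = frame.copy()
            frame[0, 0] = i  # keep the stream changing
            flags.append(cs.encode_frame(state, frame, True).keyframe)
        assert flags == [True, False, False, False,
                         True, False, False, False, True]

    def test_dimension_change_without_reset_rejected(self):
        state = cs.CodecState()
        cs.encode_frame(state, np.zeros((32, 32), np.uint8), True)
        with pytest.raises(FrameSizeChangedError):
            cs.encode_frame(state, np.zeros((16, 16), np.uint8), True)
        state.reset()
        kf = cs.encode_frame(state, np.zeros((16, 16), np.uint8), True)
        assert kf.keyframe

    def test_payload_monotone_in_quality(self, smooth_frame):
        changed = smooth_frame.copy()
        changed[50:90, 100:180] = 255 - changed[50:90, 100:180]
        payloads = {}
        for interactive in (True, False):
            state = cs.CodecState()
            cs.encode_frame(state, smooth_frame, interactive=False)
            f = cs.encode_frame(state, changed, interactive=interactive)
            payloads[f.quality] = f.payload_bytes
        assert payloads[25] <= payloads[100]


class TestDecode:
    def test_keyframe_roundtrip_within_q100_tolerance(self, smooth_frame):
        state = cs.CodecState()
        kf = cs.encode_frame(state, smooth_frame, interactive=False)
        canvas = cs.decode_frame(None, kf)
        err = np.abs(canvas.astype(int) - smooth_frame.astype(int)).max()
        assert err <= 2

    def test_empty_frame_leaves_canvas_unchanged(self, smooth_frame):
        state = cs.CodecState()
        kf = cs.encode_frame(state, smooth_frame, interactive=False)
        canvas = cs.decode_frame(None, kf)
        empty = cs.encode_frame(state, smooth_frame, interactive=False)
        after = cs.decode_frame(canvas, empty)
        assert np.array_equal(after, canvas)

    def test_blocks_commute_within_one_frame(self, smooth_frame):
        state = cs.CodecState()
        cs.encode_frame(state, np.zeros_like(smooth_frame), interactive=False)
        frame = cs.encode_frame(state, smooth_frame, interactive=False)
        base = cs.decode_frame(None, cs.encode_frame(
            cs.CodecState(), np.zeros_like(smooth_frame), False))
        in_order = cs.decode_frame(base, frame)
        shuffled = cs.EncodedFrame(
            frame_size=frame.frame_size, keyframe=frame.keyframe,
            quality=frame.quality, blocks=list(reversed(frame.blocks)),
            sequence_number=frame.sequence_number)
        out_of_order = cs.decode_frame(base, shuffled)
        assert np.array_equal(in_order, out_of_order)

    def test_corrupt_block_names_coordinates(self):
        state = cs.CodecState()
        frame = cs.encode_frame(state, np.zeros((16, 16), np.uint8), False)
        br, bc, _ = frame.blocks[1]
        frame.blocks[1] = (br, bc, b"\xff\xc0\x00\x11")  # stray marker in scan
        with pytest.raises(DecodeFailureError) as exc:
            cs.decode_frame(None, frame)
        assert exc.value.block_row == br and exc.value.block_col == bc

    def test_edge_blocks_cropped_on_non_multiple_of_8_frames(self):
        rng = np.random.default_rng(4)
        img = (rng.uniform(80, 120, (21, 13))).astype(np.uint8)  # smooth-ish
        state = cs.CodecState()
        kf = cs.encode_frame(state, img, interactive=False)
        canvas = cs.decode_frame(None, kf)
        assert canvas.shape == (21, 13)
        assert np.abs(canvas.astype(int) - img.astype(int)).max() <= 25


class TestStreamInvariants:
    def test_zero_traffic_on_repeated_frames(self, smooth_frame):
        state = cs.CodecState()
        for img in (smooth_frame, 255 - smooth_frame, smooth_frame // 2):
            cs.encode_frame(state, img, interactive=True)
            again = cs.encode_frame(state, img, interactive=True)
            assert len(again.blocks) == 0

    def test_random_update_sequences_keep_client_canvas_tiled(self):
        # union of transmitted blocks since the keyframe plus untouched
        # canvas always tiles the viewport: decoding never leaves holes,
        # and server/client stay within JPEG error per block
        rng = np.random.default_rng(9)
        state = cs.CodecState()
        server_frame = np.full((64, 96), 128, dtype=np.uint8)
        canvas = cs.decode_frame(
            None, cs.encode_frame(state, server_frame, False))
        for _ in range(25):
            server_frame = server_frame.copy()
            r, c = rng.integers(0, 56), rng.integers(0, 88)
            server_frame[r:r + 8, c:c + 8] = rng.integers(0, 255)
            frame = cs.encode_frame(state, server_frame, interactive=False)
            canvas = cs.decode_frame(canvas, frame)
            assert canvas.shape == server_frame.shape
            assert np.abs(
                canvas.astype(int) - server_frame.astype(int)).max() <= 2

    def test_keyframe_resynchronizes_drifted_canvas(self, smooth_frame):
        state = cs.CodecState(keyframe_interval=3)
        canvas = cs.decode_frame(
            None, cs.encode_frame(state, smooth_frame, True))
        canvas[:] = 0  # simulate an arbitrarily drifted client
        img = smooth_frame
        for _ in range(3):  # reach the periodic keyframe
            img = np.roll(img, 1, axis=1)
            frame = cs.encode_frame(state, img, interactive=False)
            canvas = cs.decode_frame(canvas, frame)
        assert frame.keyframe
        assert np.abs(canvas.astype(int) - img.astype(int)).max() <= 2


class TestWireAndRatio:
    def test_wire_roundtrip_is_exact(self, smooth_frame):
        state = cs.CodecState()
        frame = cs.encode_frame(state, smooth_frame, interactive=True)
        back = cs.EncodedFrame.from_wire(frame.to_wire())
        assert back.frame_size == frame.frame_size
        assert back.quality == frame.quality
        assert back.keyframe == frame.keyframe
        assert back.sequence_number == frame.sequence_number
        assert back.blocks == frame.blocks

    def test_ratio_is_raw_over_payload(self):
        frame = cs.EncodedFrame(frame_size=(8, 8), keyframe=True, quality=100,
                                blocks=[(0, 0, b"x" * 100)], sequence_number=1)
        assert cs.compression_ratio(1000, frame) == pytest.approx(10.0)

    def test_constant_keyframe_exceeds_guideline_and_warns(self, caplog):
        state = cs.CodecState()
        frame = cs.encode_frame(
            state, np.full((64, 64), 100, np.uint8), interactive=False)
        raw = 64 * 64  # one byte per pixel
        with caplog.at_level(logging.WARNING, logger="ctstream.codec"):
            ratio = cs.compression_ratio(raw, frame)
        assert ratio > 12.0
        assert any("guideline" in rec.message for rec in caplog.records)

    def test_no_blocks_means_no_traffic(self, smooth_frame):
        state = cs.CodecState()
        cs.encode_frame(state, smooth_frame, False)
        empty = cs.encode_frame(state, smooth_frame, False)
        with pytest.raises(NoTrafficError):
            cs.compression_ratio(1000, empty)
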