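"""Session lifecycle, event handling, collaboration, confidentiality."""

import numpy as np
import pytest

import ctstream as cs
from ctstream.codec import QUALITY_INTERACTIVE, QUALITY_STATIC
from ctstream.errors import (
    BadEventError,
    ConnectionRefusedError_,
    SeriesNotFoundError,
    SessionClosedError,
)


def last_frame(client):
    return cs.EncodedFrame.from_wire(client.frame_log[-1])


class TestConnect:
    def test_catalog_lists_series_without_identifiers(self, registry):
        reg, _ = registry
        client = cs.Client(reg)
        catalog = client.connect()
        assert {e["series_id"] for e in catalog} == {"ncct1", "cta1"}
        for entry in catalog:
            assert "patient_name" not in entry
            assert "patient_id" not in entry
            assert entry["slice_count"] >= 2

    def test_default_address_used_when_none_given(self, registry):
        reg, server = registry
        assert server.address == cs.session.DEFAULT_SERVER_ADDRESS
        client = cs.Client(reg)  # no address
        client.connect()
        assert client.session_id is not None

    def test_bad_credentials_rejected(self, ncct_small):
        reg = cs.ServerRegistry()
        reg.register(cs.Server({"s": ncct_small[0]}, token="secret"))
        with pytest.raises(ConnectionRefusedError_):
            cs.Client(reg).connect(token="wrong")

    def test_unknown_address_unreachable(self, registry):
        reg, _ = registry
        with pytest.raises(ConnectionRefusedError_):
            cs.Client(reg, address="ctstream://nowhere:1").connect()


class TestSelectSeries:
    def test_first_frame_matches_offline_render(self, registry, ncct_small):
        reg, server = registry
        client = cs.Client(reg)
        client.connect()
        client.select_series("ncct1")
        frame = last_frame(client)
        assert frame.keyframe and frame.quality == QUALITY_STATIC
        # offline reference: middle axial slice, modality default window
        vol = ncct_small[0]
        sess = server.sessions[client.session_id]
        expected = server._render(sess)
        err = np.abs(client.canvas.astype(int) - expected.astype(int)).max()
        assert err <= 2  # q=100 round-trip tolerance
        mid = client.state.get("view/plane/index_mm")
        assert mid == pytest.approx((vol.n_slices // 2) * vol.spacing[2])

    def test_reselect_resets_codec_with_keyframe(self, registry):
        reg, _ = registry
        client = cs.Client(reg)
        client.connect()
        client.select_series("ncct1")
        client.send_event(cs.InteractionEvent("zoom", {"factor": 2.0}))
        client.select_series("cta1")
        assert last_frame(client).keyframe

    def test_unknown_series_rejected(self, registry):
        reg, _ = registry
        client = cs.Client(reg)
        client.connect()
        with pytest.raises(SeriesNotFoundError):
            client.select_series("nope")

    def test_select_on_closed_session_rejected(self, registry):
        reg, _ = registry
        client = cs.Client(reg)
        client.connect()
        sid = client.session_id
        client.disconnect()
        client.session_id = sid  # simulate a client reusing a dead session
        with pytest.raises(SessionClosedError):
            client.select_series("ncct1")


class TestEvents:
    @pytest.fixture()
    def live(self, registry):
        reg, server = registry
        client = cs.Client(reg)
        client.connect()
        client.select_series("ncct1")
        return client, server

    def test_drag_quality_25_release_quality_100(self, live):
        client, _ = live
        client.send_event(cs.InteractionEvent(
            "wl_delta", {"dc": 20, "dw": 0}, interactive=True))
        assert last_frame(client).quality == QUALITY_INTERACTIVE
        client.send_event(cs.InteractionEvent(
            "wl_delta", {"dc": 0, "dw": 40}, interactive=False))
        assert last_frame(client).quality == QUALITY_STATIC

    def test_no_op_pan_transmits_zero_blocks(self, live):
        client, _ = live
        client.send_event(cs.InteractionEvent("pan", {"dx": 0, "dy": 0}))
        assert len(last_frame(client).blocks) == 0

    def test_state_diff_tracks_event(self, live):
        client, _ = live
        before = client.state.get("view/transform/zoom")
        client.send_event(cs.InteractionEvent("zoom", {"factor": 2.0}))
        assert client.state.get("view/transform/zoom") == before * 2.0

    def test_probe_returns_text_statistics_not_frames(self, live, ncct_small):
        client, _ = live
        vol, truth = ncct_small
        mask = truth.mask_for("hemorrhage")
        k = int(np.argmax(mask.sum(axis=(1, 2))))
        client.send_event(cs.InteractionEvent(
            "scroll_slice", {"delta": k - vol.n_slices // 2}))
        n_frames = len(client.frame_log)
        rows, cols = np.where(mask[k])
        r, c = int(rows.mean()), int(cols.mean())
        result = client.send_event(cs.InteractionEvent(
            "probe", {"row": r, "col": c, "n_rows": 1, "n_cols": 1}))
        assert result["mean_hu"] == pytest.approx(70.0)  # configured insert HU
        assert len(client.frame_log) == n_frames  # textual update only

    def test_malformed_events_rejected(self, live):
        client, _ = live
        with pytest.raises(BadEventError):
            cs.InteractionEvent("warp", {})
        with pytest.raises(BadEventError):
            cs.InteractionEvent("pan", {"dx": 1})  # missing dy
        with pytest.raises(BadEventError):
            client.send_event(cs.InteractionEvent("set_mode", {"mode": "4D"}))

    def test_mode_switches_render(self, live):
        client, _ = live
        client.send_event(cs.InteractionEvent(
            "set_mode", {"mode": "2D-side-by-side"}))
        assert client.canvas.shape == (320, 480)
        client.send_event(cs.InteractionEvent("set_mode", {"mode": "3D"}))
        client.send_event(cs.InteractionEvent("set_preset", {"name": "bone"}))
        assert client.state.get("view/preset") == "bone"
        assert client.canvas.shape == (320, 480)


class TestDisconnect:
    def test_events_after_disconnect_rejected(self, registry):
        reg, _ = registry
        client = cs.Client(reg)
        client.connect()
        client.select_series("ncct1")
        sid = client.session_id
        client.disconnect()
        client.session_id = sid
        with pytest.raises(SessionClosedError):
            client.send_event(cs.InteractionEvent("zoom", {"factor": 2.0}))

    def test_client_cache_empty_after_disconnect(self, registry):
        reg, _ = registry
        client = cs.Client(reg)
        client.connect()
        client.select_series("ncct1")
        client.send_event(cs.InteractionEvent(
            "probe", {"row": 30, "col": 30, "n_rows": 2, "n_cols": 2}))
        assert not client.cache_empty
        client.disconnect()
        assert client.cache_empty
        assert client.canvas is None  # blank image

    def test_server_releases_volume_and_codec(self, registry):
        reg, server = registry
        client = cs.Client(reg)
        client.connect()
        client.select_series("ncct1")
        sess = server.sessions[client.session_id]
        client.disconnect()
        assert sess.volume is None
        assert sess.codec.last_sent is None

    def test_double_disconnect_is_noop(self, registry):
        reg, _ = registry
        client = cs.Client(reg)
        client.connect()
        client.disconnect()
        client.disconnect()  # must not raise


class TestCollaboration:
    def test_observer_client_receives_identical_frames_and_state(self, registry):
        reg, server = registry
        driver = cs.Client(reg)
        driver.connect()
        observer = cs.Client(reg)
        observer.observe_session(server, driver.session_id)
        driver.select_series("ncct1")
        for ev in (cs.InteractionEvent("wl_delta", {"dc": 15, "dw": 0},
                                       interactive=True),
                   cs.InteractionEvent("zoom", {"factor": 1.5}),
                   cs.InteractionEvent("scroll_slice", {"delta": 2})):
            driver.send_event(ev)
        assert np.array_equal(driver.canvas, observer.canvas)
        assert driver.state.leaves == observer.state.leaves
        assert driver.frame_log == observer.frame_log


class TestConfidentialityAndDeterminism:
    SCRIPT = [
        {"kind": "wl_delta", "payload": {"dc": 10, "dw": -5},
         "interactive": True},
        {"kind": "wl_delta", "payload": {"dc": 0, "dw": 0}},
        {"kind": "pan", "payload": {"dx": 12, "dy": -4}, "interactive": True},
        {"kind": "zoom", "payload": {"factor": 2.0}},
        {"kind": "rotate", "payload": {"degrees": 30.0}, "interactive": True},
        {"kind": "scroll_slice", "payload": {"delta": 1}},
        {"kind": "probe",
         "payload": {"row": 30, "col": 30, "n_rows": 3, "n_cols": 3}},
        {"kind": "set_mode", "payload": {"mode": "2D-side-by-side"}},
    ]

    def test_replay_is_byte_identical_across_runs(self, registry):
        reg, _ = registry
        first, _ = cs.replay_script(reg, "ncct1", self.SCRIPT)
        second, _ = cs.replay_script(reg, "ncct1", self.SCRIPT)
        assert len(first) == len(second)
        for a, b in zip(first, second):
            assert np.array_equal(a, b)

    def test_whole_session_traffic_is_confidential(self, registry):
        reg, _ = registry
        _, log = cs.replay_script(reg, "ncct1", self.SCRIPT)
        assert len(log.records) > 10
        cs.assert_confidential(log)  # raises on any violation
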