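"""Session server and scriptable reference client.

The server owns the volumes, the per-session view state and the frame
codec; clients send interaction events and receive encoded frames plus
state diffs. Patient data never crosses the wire: traffic consists only of
JSON control messages (catalog text, state-diff documents, probe text) and
binary block-JPEG frames, which :func:`assert_confidential` verifies
message by message.

Transport here is an in-process byte wire: every request and response is a
fully serialized message (length-prefixed kind + payload) recorded in a
:class:`WireLog`, so protocol-level assertions and replay determinism are
exercised exactly as over a socket. Servers register under a
``ctstream://`` address; clients connect by address (a packaged default is
used when none is given) and authenticate with a shared token.

Interactive drags are encoded at JPEG quality 25; on release (static
presentation) the frame is re-sent at quality 100.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import codec, mpr, render, volume_core
from .errors import (
    BadEventError,
    ConnectionRefusedError_,
    SeriesNotFoundError,
    SessionClosedError,
)
from .state import StateModel, compute_diff, parse_diff, serialize_diff
from .volume_core import ImageVolume, WindowLevel

DEFAULT_SERVER_ADDRESS = "ctstream://localhost:8080"
DEFAULT_VIEWPORT = (320, 480)  # (rows, cols) -> 40 x 60 grid of 8x8 blocks

#: default display windows per modality (center, width) in HU
DEFAULT_WINDOWS = {"NCCT": (40.0, 80.0), "CTA": (150.0, 600.0),
                   "OTHER": (40.0, 400.0)}

_MSG_JSON = 1
_MSG_FRAME = 2
_MSG_HEADER = struct.Struct(">BI")

#: event kind -> required payload keys
_EVENT_SCHEMA = {
    "wl_delta": ("dc", "dw"),
    "pan": ("dx", "dy"),
    "zoom": ("factor",),
    "rotate": ("degrees",),
    "scroll_slice": ("delta",),
    "set_mode": ("mode",),
    "set_preset": ("name",),
    "probe": ("row", "col", "n_rows", "n_cols"),
}


@dataclass(frozen=True)
class InteractionEvent:
    """One user gesture: kind, kind-specific payload, drag-vs-release flag."""

    kind: str
    payload: dict[str, Any] = field(default_factory=dict)
    interactive: bool = False

    def __post_init__(self):
        if self.kind not in _EVENT_SCHEMA:
            raise BadEventError(f"bad event: unknown kind {self.kind!r}")
        required = set(_EVENT_SCHEMA[self.kind])
        if set(self.payload) != required:
            raise BadEventError(
                f"bad event: {self.kind} payload needs exactly {sorted(required)}"
            )


def _pack(kind: int, payload: bytes) -> bytes:
    return _MSG_HEADER.pack(kind, len(payload)) + payload


def _unpack(message: bytes) -> tuple[int, bytes]:
    kind, length = _MSG_HEADER.unpack_from(message, 0)
    return kind, message[_MSG_HEADER.size:_MSG_HEADER.size + length]


def _json_msg(obj: dict) -> bytes:
    return _pack(_MSG_JSON, json.dumps(obj).encode("utf-8"))


@dataclass
class WireLog:
    """Every byte that crossed the client-server boundary."""

    records: list[tuple[str, bytes]] = field(default_factory=list)

    def add(self, direction: str, message: bytes) -> None:
        self.records.append((direction, bytes(message)))


class Session:
    """Server-side per-session state: volume, view tree, codec."""

    def __init__(self, session_id: str, viewport=DEFAULT_VIEWPORT,
                 keyframe_interval=codec.DEFAULT_KEYFRAME_INTERVAL):
        self.session_id = session_id
        self.viewport = tuple(viewport)
        self.volume: ImageVolume | None = None
        self.series_id: str | None = None
        self.state = StateModel()
        self.codec = codec.CodecState(keyframe_interval=keyframe_interval)
        self.open = True

    def close(self) -> None:
        self.open = False
        self.volume = None
        self.series_id = None
        self.codec.reset()
        self.state = StateModel()


class Server:
    """In-process visualization server hosting one or more CT series."""

    def __init__(self, series: dict[str, ImageVolume], *, token: str = "",
                 address: str = DEFAULT_SERVER_ADDRESS,
                 viewport=DEFAULT_VIEWPORT,
                 keyframe_interval: int = codec.DEFAULT_KEYFRAME_INTERVAL):
        self.series = dict(series)
        self.token = token
        self.address = address
        self.viewport = tuple(viewport)
        self.keyframe_interval = keyframe_interval
        self.sessions: dict[str, Session] = {}
        self.observers: dict[str, list] = {}
        self._next_session = 0

    # -- catalog -----------------------------------------------------------

    def catalog(self) -> list[dict]:
        """Whitelisted textual attributes only; never pixel data."""
        entries = []
        for sid, vol in sorted(self.series.items()):
            attrs = {k: v for k, v in vol.attributes.items()
                     if k in volume_core.ATTRIBUTE_WHITELIST}
            attrs["series_id"] = sid
            attrs["modality"] = vol.modality
            attrs["slice_count"] = int(vol.n_slices)
            entries.append(attrs)
        return entries

    # -- message endpoint --------------------------------------------------

    def handle_message(self, message: bytes) -> list[bytes]:
        """Process one wire message; returns the response messages."""
        kind, payload = _unpack(message)
        if kind != _MSG_JSON:
            return [_json_msg({"type": "error", "error": "bad request"})]
        req = json.loads(payload.decode("utf-8"))
        rtype = req.get("type")
        try:
            if rtype == "connect":
                return self._on_connect(req)
            if rtype == "select":
                responses = self._on_select(req)
            elif rtype == "event":
                responses = self._on_event(req)
            elif rtype == "disconnect":
                return self._on_disconnect(req)
            else:
                return [_json_msg(
                    {"type": "error", "error": f"unknown request {rtype!r}"})]
        except (SeriesNotFoundError, SessionClosedError, BadEventError) as exc:
            return [_json_msg({"type": "error", "error": str(exc)})]
        # collaborative viewing: rebroadcast frames/diffs to attached clients
        for deliver in self.observers.get(req.get("session_id", ""), []):
            deliver(list(responses))
        return responses

    def attach_observer(self, session_id: str, deliver) -> None:
        """Register a callback receiving every broadcast for a session."""
        self.observers.setdefault(session_id, []).append(deliver)

    # -- request handlers --------------------------------------------------

    def _on_connect(self, req) -> list[bytes]:
        if req.get("token", "") != self.token:
            raise ConnectionRefusedError_("connection refused: bad credentials")
        sid = f"s{self._next_session}"
        self._next_session += 1
        self.sessions[sid] = Session(
            sid, viewport=self.viewport,
            keyframe_interval=self.keyframe_interval)
        return [_json_msg({"type": "connected", "session_id": sid,
                           "catalog": self.catalog()})]

    def _session(self, req) -> Session:
        sess = self.sessions.get(req.get("session_id", ""))
        if sess is None or not sess.open:
            raise SessionClosedError("session closed or unknown")
        return sess

    def _on_select(self, req) -> list[bytes]:
        sess = self._session(req)
        series_id = req.get("series_id", "")
        if series_id not in self.series:
            raise SeriesNotFoundError(f"series {series_id!r} not found")
        vol = self.series[series_id]
        sess.volume = vol
        sess.series_id = series_id
        sess.codec.reset()

        old = sess.state.copy()
        sr, sc, ss = vol.spacing
        center, width = DEFAULT_WINDOWS.get(vol.modality, DEFAULT_WINDOWS["OTHER"])
        defaults = {
            "view/mode": "2D",
            "view/plane/axis": "axial",
            "view/plane/index_mm": (vol.n_slices // 2) * ss,
            "view/wl/center": center,
            "view/wl/width": width,
            "view/transform/pan_x": 0.0,
            "view/transform/pan_y": 0.0,
            "view/transform/zoom": 1.0,
            "view/transform/rotation": 0.0,
            "view/preset": "bone",
        }
        for path, value in defaults.items():
            sess.state.set(path, value)
        diff = compute_diff(old, sess.state)
        frame = codec.encode_frame(sess.codec, self._render(sess),
                                   interactive=False)
        return [
            _json_msg({"type": "selected", "series_id": series_id,
                       "diff": serialize_diff(diff)}),
            _pack(_MSG_FRAME, frame.to_wire()),
        ]

    def _on_event(self, req) -> list[bytes]:
        sess = self._session(req)
        if sess.volume is None:
            raise BadEventError("bad event: no series selected")
        event = InteractionEvent(
            kind=req.get("kind", ""),
            payload=req.get("payload", {}),
            interactive=bool(req.get("interactive", False)),
        )
        if event.kind == "probe":
            p = event.payload
            k = self._slice_index(sess)
            probe = volume_core.hu_probe(
                sess.volume, k,
                (int(p["row"]), int(p["col"]), int(p["n_rows"]), int(p["n_cols"])),
            )
            return [_json_msg({
                "type": "probe_result",
                "mean_hu": probe.mean, "sd_hu": probe.sd,
                "min_hu": probe.min, "max_hu": probe.max,
                "count": probe.count,
            })]

        old = sess.state.copy()
        self._mutate(sess, event)
        diff = compute_diff(old, sess.state)
        frame = codec.encode_frame(sess.codec, self._render(sess),
                                   interactive=event.interactive)
        return [
            _json_msg({"type": "updated", "diff": serialize_diff(diff)}),
            _pack(_MSG_FRAME, frame.to_wire()),
        ]

    def _on_disconnect(self, req) -> list[bytes]:
        sess = self.sessions.get(req.get("session_id", ""))
        if sess is not None and sess.open:
            sess.close()  # idempotent: double disconnect is a no-op
        return [_json_msg({"type": "disconnected"})]

    # -- view-state mutation and rendering --------------------------------

    def _slice_index(self, sess: Session) -> int:
        ss = sess.volume.spacing[2]
        k = int(round(sess.state.get("view/plane/index_mm", 0.0) / ss))
        return int(np.clip(k, 0, sess.volume.n_slices - 1))

    def _mutate(self, sess: Session, e: InteractionEvent) -> None:
        st, p = sess.state, e.payload
        if e.kind == "wl_delta":
            st.set("view/wl/center", st.get("view/wl/center") + float(p["dc"]))
            st.set("view/wl/width",
                   max(1.0, st.get("view/wl/width") + float(p["dw"])))
        elif e.kind == "pan":
            st.set("view/transform/pan_x",
                   st.get("view/transform/pan_x") + float(p["dx"]))
            st.set("view/transform/pan_y",
                   st.get("view/transform/pan_y") + float(p["dy"]))
        elif e.kind == "zoom":
            if float(p["factor"]) <= 0:
                raise BadEventError("bad event: zoom factor must be > 0")
            st.set("view/transform/zoom",
                   st.get("view/transform/zoom") * float(p["factor"]))
        elif e.kind == "rotate":
            st.set("view/transform/rotation",
                   st.get("view/transform/rotation") + float(p["degrees"]))
        elif e.kind == "scroll_slice":
            ss = sess.volume.spacing[2]
            max_mm = (sess.volume.n_slices - 1) * ss
            new = st.get("view/plane/index_mm") + float(p["delta"]) * ss
            st.set("view/plane/index_mm", float(np.clip(new, 0.0, max_mm)))
        elif e.kind == "set_mode":
            if p["mode"] not in ("2D", "2D-side-by-side", "3D"):
                raise BadEventError(f"bad event: unknown mode {p['mode']!r}")
            st.set("view/mode", p["mode"])
        elif e.kind == "set_preset":
            render.preset(p["name"])  # validates the name
            st.set("view/preset", p["name"])

    def _render_2d(self, sess: Session, viewport, index_mm=None) -> np.ndarray:
        st = sess.state
        vol = sess.volume
        if index_mm is None:
            index_mm = st.get("view/plane/index_mm")
        ss = vol.spacing[2]
        index_mm = float(np.clip(index_mm, 0.0, (vol.n_slices - 1) * ss))
        plane = mpr.orthogonal_plane(vol, st.get("view/plane/axis"), index_mm)
        hu = mpr.extract_slice(vol, plane)
        t = mpr.ViewTransform(
            pan=(st.get("view/transform/pan_x"), st.get("view/transform/pan_y")),
            zoom=st.get("view/transform/zoom"),
            rotation=st.get("view/transform/rotation"),
        )
        hu_view = mpr.apply_view(hu, t, viewport, background=mpr.BACKGROUND_HU)
        wl = WindowLevel(st.get("view/wl/center"), st.get("view/wl/width"))
        return volume_core.apply_window(hu_view, wl)

    def _render_3d(self, sess: Session, viewport) -> np.ndarray:
        vol = sess.volume
        ext = vol.extent_mm()
        center = vol.index_to_patient(
            (vol.n_slices - 1) / 2,
            (vol.shape[1] - 1) / 2,
            (vol.shape[2] - 1) / 2,
        )
        # anterior orthographic view, zoom folds into the half-extent
        zoom = sess.state.get("view/transform/zoom", 1.0)
        half = max(ext) / 2 / zoom + 1.0
        eye = center - vol.row_dir * (max(ext) + 20.0)
        camera = render.Camera(
            eye=eye, look_at=center, up=vol.slice_normal,
            half_extent=(half * viewport[0] / viewport[1], half),
            out_size=viewport,
        )
        tf = render.preset(sess.state.get("view/preset", "bone"))
        img = render.render_raycast(vol, camera, tf, step_mm=2.0)
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    def _render(self, sess: Session) -> np.ndarray:
        """Render the session's current view into the viewport, 8-bit."""
        mode = sess.state.get("view/mode", "2D")
        vr, vc = sess.viewport
        if mode == "2D":
            return self._render_2d(sess, (vr, vc))
        if mode == "2D-side-by-side":
            # two viewports sharing one state tree: current and next slice
            half = (vr, vc // 2)
            ss = sess.volume.spacing[2]
            left = self._render_2d(sess, half)
            right = self._render_2d(
                sess, half, index_mm=sess.state.get("view/plane/index_mm") + ss)
            out = np.zeros((vr, vc), dtype=np.uint8)
            out[:, :half[1]] = left
            out[:, half[1]:2 * half[1]] = right
            return out
        return self._render_3d(sess, (vr, vc))


# ---------------------------------------------------------------------------
# server registry (in-process "network") and reference client
# ---------------------------------------------------------------------------

class ServerRegistry:
    """Maps ctstream:// addresses to in-process servers."""

    def __init__(self):
        self._servers: dict[str, Server] = {}

    def register(self, server: Server) -> None:
        self._servers[server.address] = server

    def resolve(self, address: str) -> Server:
        try:
            return self._servers[address]
        except KeyError:
            raise ConnectionRefusedError_(
                f"connection refused: no server at {address!r}"
            ) from None


class Client:
    """Scriptable reference client.

    Maintains the decoded canvas, a shadow state tree and the cached
    catalog text; all of it volatile — cleared on disconnect.
    """

    def __init__(self, registry: ServerRegistry, address: str | None = None,
                 wire_log: WireLog | None = None):
        # the packaged default address removes one step before interpretation
        self.address = address or DEFAULT_SERVER_ADDRESS
        self._registry = registry
        self.wire_log = wire_log if wire_log is not None else WireLog()
        self._server: Server | None = None
        self.session_id: str | None = None
        self.canvas: np.ndarray | None = None
        self.state = StateModel()
        self.catalog: list[dict] | None = None
        self.last_probe: dict | None = None
        self.frame_log: list[bytes] = []

    # -- wire --------------------------------------------------------------

    def _exchange(self, request: dict) -> list[tuple[int, bytes]]:
        if self._server is None:
            self._server = self._registry.resolve(self.address)
        msg = _json_msg(request)
        self.wire_log.add("c->s", msg)
        responses = self._server.handle_message(msg)
        out = []
        for resp in responses:
            self.wire_log.add("s->c", resp)
            out.append(_unpack(resp))
        return out

    def _consume(self, messages) -> dict | None:
        """Apply frame/diff messages to local state; return last JSON body."""
        last = None
        for kind, payload in messages:
            if kind == _MSG_FRAME:
                frame = codec.EncodedFrame.from_wire(payload)
                self.canvas = codec.decode_frame(self.canvas, frame)
                self.frame_log.append(payload)
            else:
                body = json.loads(payload.decode("utf-8"))
                if body.get("type") == "error":
                    text = body["error"]
                    if "closed" in text:
                        raise SessionClosedError(text)
                    if "not found" in text:
                        raise SeriesNotFoundError(text)
                    raise BadEventError(text)
                if "diff" in body:
                    diff = parse_diff(body["diff"])
                    for path, value in diff.upserts:
                        self.state.leaves[path] = value
                    for path in diff.deletes:
                        self.state.leaves.pop(path, None)
                    self.state.revision = diff.new_revision
                last = body
        return last

    # -- session lifecycle -------------------------------------------------

    def observe_session(self, server: Server, session_id: str) -> None:
        """Attach to an existing session as a collaborating viewer."""
        self._server = server
        self.session_id = session_id
        server.attach_observer(session_id, self._receive_broadcast)

    def _receive_broadcast(self, messages: list[bytes]) -> None:
        unpacked = []
        for message in messages:
            self.wire_log.add("s->c", message)
            unpacked.append(_unpack(message))
        self._consume(unpacked)

    def connect(self, token: str = "") -> list[dict]:
        body = self._consume(self._exchange({"type": "connect", "token": token}))
        self.session_id = body["session_id"]
        self.catalog = body["catalog"]
        return self.catalog

    def select_series(self, series_id: str) -> None:
        self.canvas = None  # codec resets server-side; keyframe follows
        self._consume(self._exchange({
            "type": "select", "session_id": self.session_id,
            "series_id": series_id,
        }))

    def send_event(self, event: InteractionEvent) -> dict | None:
        body = self._consume(self._exchange({
            "type": "event", "session_id": self.session_id,
            "kind": event.kind, "payload": event.payload,
            "interactive": event.interactive,
        }))
        if body and body.get("type") == "probe_result":
            self.last_probe = body
        return body

    def disconnect(self) -> None:
        """Close the session and purge all volatile client state."""
        if self.session_id is not None:
            self._exchange({"type": "disconnect",
                            "session_id": self.session_id})
        self.session_id = None
        self.canvas = None       # blank image
        self.state = StateModel()
        self.catalog = None
        self.last_probe = None
        self.frame_log = []

    @property
    def cache_empty(self) -> bool:
        return (self.canvas is None and self.catalog is None
                and not self.state.leaves and not self.frame_log
                and self.last_probe is None)


# ---------------------------------------------------------------------------
# protocol-level confidentiality audit
# ---------------------------------------------------------------------------

_ALLOWED_JSON_TYPES = {
    "connect", "select", "event", "disconnect",
    "connected", "selected", "updated", "probe_result",
    "disconnected", "error",
}


def assert_confidential(log: WireLog) -> None:
    """Verify no DICOM payloads or raw pixel arrays ever crossed the wire.

    Every message must be either an allowed JSON control message or a
    block-JPEG encoded frame; DICOM magic bytes anywhere are a violation.
    """
    for direction, message in log.records:
        if b"DICM" in message:
            raise AssertionError(f"DICOM payload on the wire ({direction})")
        kind, payload = _unpack(message)
        if kind == _MSG_JSON:
            body = json.loads(payload.decode("utf-8"))
            if body.get("type") not in _ALLOWED_JSON_TYPES:
                raise AssertionError(
                    f"unexpected message type {body.get('type')!r}"
                )
            blob = json.dumps(body)
            if "pixel_data" in blob or "voxels" in blob:
                raise AssertionError("raw pixel payload in control message")
        elif kind == _MSG_FRAME:
            frame = codec.EncodedFrame.from_wire(payload)
            for br, bc, block in frame.blocks:
                try:
                    codec._decode_block(block, frame.quality)
                except Exception:
                    raise AssertionError(
                        f"non-JPEG block payload at ({br}, {bc})"
                    ) from None
        else:
            raise AssertionError(f"unknown wire message kind {kind}")


# ---------------------------------------------------------------------------
# scripted replay
# ---------------------------------------------------------------------------

def replay_script(
    registry: ServerRegistry,
    series_id: str,
    events: list[dict],
    *,
    address: str | None = None,
    token: str = "",
) -> tuple[list[np.ndarray], WireLog]:
    """Run a recorded event script; returns decoded canvases and the wire log.

    Each event dict has "kind", "payload" and optional "interactive" keys —
    the JSON form produced by recording a session.
    """
    client = Client(registry, address=address)
    client.connect(token=token)
    client.select_series(series_id)
    canvases = [client.canvas.copy()]
    for ev in events:
        event = InteractionEvent(
            kind=ev["kind"], payload=ev.get("payload", {}),
            interactive=bool(ev.get("interactive", False)),
        )
        client.send_event(event)
        if client.canvas is not None:
            canvases.append(client.canvas.copy())
    log = client.wire_log
    client.disconnect()
    return canvases, log
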