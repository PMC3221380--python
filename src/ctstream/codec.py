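"""Changed-block JPEG frame codec.

The server streams viewport updates as the set of 8x8 pixel blocks that
changed since the previous frame. Change detection compares the new frame
against the last *pre-compression* frame bit-exactly; each changed block is
an independent grayscale baseline-JPEG encoding whose quality factor is
25 during interactive presentation (drags) and 100 for static frames. The
first frame, any viewport resize, and every ``keyframe_interval`` frames
are keyframes carrying every block, which resynchronizes the client canvas
exactly to within the q=100 round-trip error.

Because every block in a stream shares the same dimensions (8x8,
grayscale) and quality-scaled tables, the JPEG header — quantization and
Huffman tables, frame and scan headers — is a protocol constant per
quality factor. Only the entropy-coded scan data is transmitted per block
(an abbreviated JPEG stream); both ends prepend the same header template
when decoding. A constant block costs 2-4 payload bytes this way instead
of ~330 with full per-block headers.

Wire format (big-endian, documented in docs/protocol.md):

    header:  sequence_number u32, rows u16, cols u16, quality u8,
             keyframe u8, block_count u16
    block:   block_row u16, block_col u16, payload_length u32,
             JPEG entropy-coded scan bytes
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .errors import DecodeFailureError, FrameSizeChangedError, NoTrafficError

logger = logging.getLogger(__name__)

BLOCK = 8
QUALITY_INTERACTIVE = 25
QUALITY_STATIC = 100
DEFAULT_KEYFRAME_INTERVAL = 120
#: published guideline bound on compression for static neurological CT
GUIDELINE_COMPRESSION_RATIO = 12.0

_HEADER = struct.Struct(">IHHBBH")
_BLOCK_HEADER = struct.Struct(">HHI")


@dataclass
class EncodedFrame:
    """One viewport update on the wire: changed-block JPEG records."""

    frame_size: tuple[int, int]            # (rows, cols)
    keyframe: bool
    quality: int
    blocks: list[tuple[int, int, bytes]]   # (block_row, block_col, payload)
    sequence_number: int

    def __post_init__(self):
        if not 1 <= self.quality <= 100:
            raise ValueError("quality must lie in [1, 100]")
        rows, cols = self.frame_size
        grid = (-(-rows // BLOCK), -(-cols // BLOCK))
        seen = set()
        for br, bc, _ in self.blocks:
            if not (0 <= br < grid[0] and 0 <= bc < grid[1]):
                raise ValueError(f"block ({br}, {bc}) outside grid {grid}")
            if (br, bc) in seen:
                raise ValueError(f"duplicate block ({br}, {bc})")
            seen.add((br, bc))
        if self.keyframe and len(self.blocks) != grid[0] * grid[1]:
            raise ValueError("keyframe must cover the full block grid")

    @property
    def payload_bytes(self) -> int:
        return sum(len(b) for _, _, b in self.blocks)

    def to_wire(self) -> bytes:
        """Serialize to the length-prefixed big-endian wire format."""
        rows, cols = self.frame_size
        out = [_HEADER.pack(self.sequence_number, rows, cols, self.quality,
                            int(self.keyframe), len(self.blocks))]
        for br, bc, payload in self.blocks:
            out.append(_BLOCK_HEADER.pack(br, bc, len(payload)))
            out.append(payload)
        return b"".join(out)

    @classmethod
    def from_wire(cls, data: bytes) -> "EncodedFrame":
        seq, rows, cols, quality, keyframe, n = _HEADER.unpack_from(data, 0)
        offset = _HEADER.size
        blocks = []
        for _ in range(n):
            br, bc, ln = _BLOCK_HEADER.unpack_from(data, offset)
            offset += _BLOCK_HEADER.size
            blocks.append((br, bc, bytes(data[offset:offset + ln])))
            offset += ln
        return cls(frame_size=(rows, cols), keyframe=bool(keyframe),
                   quality=quality, blocks=blocks, sequence_number=seq)


@dataclass
class CodecState:
    """Server-side encoder state: the last pre-compression frame sent."""

    last_sent: np.ndarray | None = None
    sequence_number: int = 0
    keyframe_interval: int = DEFAULT_KEYFRAME_INTERVAL
    frames_since_keyframe: int = 0
    #: blocks whose last transmission was interactive (quality 25); the
    #: next static frame re-sends them at quality 100 even if unchanged
    pending_refinement: set = None

    def __post_init__(self):
        if self.pending_refinement is None:
            self.pending_refinement = set()

    def reset(self) -> None:
        self.last_sent = None
        self.frames_since_keyframe = 0
        self.pending_refinement = set()


_EOI = b"\xff\xd9"
_template_cache: dict[int, bytes] = {}


def _split_at_sos(data: bytes) -> bytes:
    """Header of a JPEG stream up to and including the SOS segment."""
    i = 2  # skip SOI
    while i < len(data) - 1:
        if data[i] != 0xFF:
            raise ValueError("malformed JPEG stream")
        marker = data[i + 1]
        seglen = int.from_bytes(data[i + 2:i + 4], "big")
        if marker == 0xDA:
            return data[:i + 2 + seglen]
        i += 2 + seglen
    raise ValueError("no SOS segment found")


def _full_jpeg(block: np.ndarray, quality: int) -> bytes:
    buf = io.BytesIO()
    Image.fromarray(block, mode="L").save(buf, format="JPEG", quality=quality)
    return buf.getvalue()


def _header_template(quality: int) -> bytes:
    """The protocol-constant 8x8 grayscale JPEG header for one quality."""
    if quality not in _template_cache:
        zero = np.zeros((BLOCK, BLOCK), dtype=np.uint8)
        _template_cache[quality] = _split_at_sos(_full_jpeg(zero, quality))
    return _template_cache[quality]


def _encode_block(block: np.ndarray, quality: int) -> bytes:
    """Entropy-coded scan of one block, zero-padded to 8x8 at frame edges."""
    if block.shape != (BLOCK, BLOCK):
        padded = np.zeros((BLOCK, BLOCK), dtype=np.uint8)
        padded[: block.shape[0], : block.shape[1]] = block
        block = padded
    full = _full_jpeg(block, quality)
    header = _header_template(quality)
    if not full.startswith(header) or not full.endswith(_EOI):
        # encoder produced a non-canonical stream; ship it whole (decoder
        # detects the SOI prefix and skips template reassembly)
        return full
    return full[len(header):-len(_EOI)]


def _decode_block(payload: bytes, quality: int) -> np.ndarray:
    if payload.startswith(b"\xff\xd8"):
        data = payload
    else:
        data = _header_template(quality) + payload + _EOI
    return np.asarray(Image.open(io.BytesIO(data)))


def encode_frame(
    state: CodecState, current: np.ndarray, interactive: bool
) -> EncodedFrame:
    """Encode the next viewport frame as changed 8x8 blocks.

    A block is transmitted iff any of its pixels differs bit-exactly from
    the last pre-compression frame. Quality is 25 while the user is
    dragging (interactive) and 100 for static presentation.
    """
    current = np.ascontiguousarray(current, dtype=np.uint8)
    if current.ndim != 2:
        raise ValueError("frames must be single-channel 2-D images")
    rows, cols = current.shape

    if state.last_sent is not None and state.last_sent.shape != current.shape:
        raise FrameSizeChangedError(
            f"frame size changed {state.last_sent.shape} -> {current.shape}; "
            "reset the codec state"
        )

    keyframe = (
        state.last_sent is None
        or state.frames_since_keyframe + 1 >= state.keyframe_interval
    )
    quality = QUALITY_INTERACTIVE if interactive else QUALITY_STATIC
    grid_r, grid_c = -(-rows // BLOCK), -(-cols // BLOCK)

    if keyframe:
        changed = [(br, bc) for br in range(grid_r) for bc in range(grid_c)]
    else:
        diff = current != state.last_sent
        changed = []
        for br in range(grid_r):
            for bc in range(grid_c):
                if diff[br * BLOCK:(br + 1) * BLOCK,
                        bc * BLOCK:(bc + 1) * BLOCK].any():
                    changed.append((br, bc))
        if not interactive and state.pending_refinement:
            # refine tiles previously shown at interactive quality
            extra = sorted(state.pending_refinement.difference(changed))
            changed.extend(extra)

    blocks = [
        (br, bc, _encode_block(
            current[br * BLOCK:(br + 1) * BLOCK, bc * BLOCK:(bc + 1) * BLOCK],
            quality))
        for br, bc in changed
    ]

    state.sequence_number += 1
    state.last_sent = current.copy()
    if interactive:
        state.pending_refinement.update(changed)
    else:
        state.pending_refinement.clear()
    state.frames_since_keyframe = 0 if keyframe else state.frames_since_keyframe + 1
    return EncodedFrame(
        frame_size=(rows, cols), keyframe=keyframe, quality=quality,
        blocks=blocks, sequence_number=state.sequence_number,
    )


def decode_frame(
    client_canvas: np.ndarray | None, frame: EncodedFrame
) -> np.ndarray:
    """Composite an encoded frame onto the client canvas.

    Keyframes replace the whole canvas; otherwise each transmitted block is
    JPEG-decoded and written at its grid position while untouched blocks
    retain their prior content.
    """
    rows, cols = frame.frame_size
    if frame.keyframe or client_canvas is None:
        canvas = np.zeros((rows, cols), dtype=np.uint8)
    else:
        if client_canvas.shape != (rows, cols):
            raise FrameSizeChangedError(
                "canvas dimensions do not match frame size"
            )
        canvas = client_canvas.copy()

    for br, bc, payload in frame.blocks:
        try:
            block = _decode_block(payload, frame.quality)
        except Exception as exc:
            raise DecodeFailureError(br, bc, str(exc)) from exc
        if block.shape != (BLOCK, BLOCK):
            raise DecodeFailureError(br, bc, f"bad block shape {block.shape}")
        r0, c0 = br * BLOCK, bc * BLOCK
        h = min(BLOCK, rows - r0)
        w = min(BLOCK, cols - c0)
        canvas[r0:r0 + h, c0:c0 + w] = block[:h, :w]  # crop edge padding
    return canvas


def compression_ratio(
    raw_bytes: int,
    encoded: EncodedFrame,
    *,
    guideline_bound: float = GUIDELINE_COMPRESSION_RATIO,
) -> float:
    """raw_bytes / total payload bytes; warns on static frames beyond bound.

    The published guideline caps lossy compression of static neurological
    CT at 12:1; a static (q=100) full frame compressed beyond the bound is
    logged as a warning but not rejected.
    """
    if raw_bytes <= 0:
        raise ValueError("raw_bytes must be > 0")
    payload = encoded.payload_bytes
    if payload == 0:
        raise NoTrafficError("no traffic: encoded frame carries no blocks")
    ratio = raw_bytes / payload
    if encoded.quality == QUALITY_STATIC and encoded.keyframe and ratio > guideline_bound:
        logger.warning(
            "static keyframe compressed %.1f:1, beyond the %.0f:1 guideline",
            ratio, guideline_bound,
        )
    return ratio
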