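# Wire protocol and state-diff schema

Authoritative byte-level description of what crosses the client–server
wire. All integers are big-endian. The transport is in-process but every
message is fully serialized; a socket transport would carry exactly
these bytes.

## Message framing

Each message is

```
+--------+----------------+------------------+
| kind   | length         | body             |
| uint8  | uint32 (bytes) | `length` bytes   |
+--------+----------------+------------------+
```

(`struct` format `">BI"`). `kind` is `1` for a UTF-8 JSON document and
`2` for a frame packet.

## JSON messages

Client → server requests and server → client responses are JSON objects
with a `type` field. Allowed types (anything else fails the
confidentiality audit):

| type            | direction | payload                                          |
|-----------------|-----------|--------------------------------------------------|
| `connect`       | C→S       | `token`                                          |
| `connected`     | S→C       | `session_id`, `catalog`: list of whitelisted attributes plus `series_id`, `modality`, `slice_count` |
| `select`        | C→S       | `session_id`, `series_id`                        |
| `selected`      | S→C       | `series_id`, `diff` (state-diff XML setting the view defaults) |
| `event`         | C→S       | `session_id`, `kind`, `payload`, `interactive`   |
| `updated`       | S→C       | `diff` (state-diff XML)                          |
| `probe_result`  | S→C       | `mean_hu`, `sd_hu`, `min_hu`, `max_hu`, `count`  |
| `error`         | S→C       | `error` (message text)                           |
| `disconnect`    | C→S       | `session_id`                                     |
| `disconnected`  | S→C       | —                                                |

Event kinds and their exact payload keys: `wl_delta` (`dc`, `dw`),
`pan` (`dx`, `dy`), `zoom` (`factor`), `rotate` (`degrees`),
`scroll_slice` (`delta`), `set_mode` (`mode`), `set_preset` (`name`),
`probe` (`row`, `col`, `n_rows`, `n_cols`). Unknown kinds, missing or
extra keys are rejected before any state changes.

## Frame packets (kind = 2)

```
frame header (struct ">IHHBBH"):
    uint32  sequence_number
    uint16  viewport_rows
    uint16  viewport_cols
    uint8   quality          (1..100; 25 interactive, 100 static)
    uint8   keyframe         (0 or 1)
    uint16  block_count

then block_count records, each (struct ">HHI" + payload):
    uint16  block_row        (viewport row // 8)
    uint16  block_col        (viewport col // 8)
    uint32  payload_length
    bytes   payload          (abbreviated JPEG scan)
```

A block payload is the entropy-coded scan of an 8×8 grayscale baseline
JPEG. The bytes from SOI through the SOS segment are identical for every
8×8 block at a given quality, so that prefix is a protocol constant
shared by encoder and decoder; the decoder reconstitutes
`template(quality) + payload + FFD9` and decodes with a standard JPEG
library. A payload that itself begins with SOI (`FFD8`) is a complete
stream and is decoded as-is (fallback for non-canonical encoders).

Keyframes list every block of the grid. Delta frames list only blocks
whose pixels changed bit-exactly relative to the last *pre-compression*
transmitted frame. Viewports whose sides are not multiples of 8 are
padded by edge replication for coding and cropped after decode.

## State-diff XML

The shared view state is a flat tree of typed leaves keyed by
slash-separated paths. A diff between revision `base` and `new`:

```xml
<statediff base="4" new="5">
  <set path="view/wl/center" type="number">60</set>
  <set path="view/mode" type="string">2D</set>
  <set path="annot/visible" type="boolean">true</set>
  <del path="view/preset"/>
</statediff>
```

- `type` is `boolean` (`true`/`false`), `number` (integers have no `.`,
  floats always carry one, `repr` precision), or `string` (raw text,
  XML-escaped, Unicode preserved).
- `new` must be greater than `base`; applying a diff whose `base` does
  not equal the receiver's revision is refused and answered with a full
  resync (`base="0"` and every leaf as a `<set>`).
- Upsert and delete path sets are disjoint; a `<del>` for an unknown
  path is an error.
- Paths may not be simultaneously leaf and interior
  (`view` and `view/zoom` cannot both hold values).

Standard state paths used by the session layer: `view/mode`
(`2D`, `2D-side-by-side`, `3D`), `view/plane/axis`,
`view/plane/index_mm`, `view/wl/center`, `view/wl/width`,
`view/transform/pan_x`, `view/transform/pan_y`, `view/transform/zoom`,
`view/transform/rotation`, `view/preset`.
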