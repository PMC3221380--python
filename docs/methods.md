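# Methods

`ctstream` is a client–server CT streaming engine for acute-stroke
teleradiology scenarios: the server holds the calibrated volume and does
all heavy rendering; the handheld client receives only small compressed
image tiles and a synchronized view-state tree. This note records the
model, the numerical choices, and their limitations.

## Volume model

A CT series is a stack of single-frame DICOM slices. Stored values are
converted to Hounsfield units (HU) with the per-slice rescale slope and
intercept; slices are ordered by the projection of their
ImagePositionPatient onto the slice normal (the cross product of the
row/column direction cosines), so shuffled file order does not matter.
Slice spacing is taken from adjacent position deltas and must be uniform
within 5%; mixed dimensions, duplicate positions, or fewer than two
slices are rejected. On load, metadata is reduced to a whitelist
(`series_description`, modality, counts, spacing, acquisition date) so no
direct patient identifier survives into the engine.

Voxel index order is `(slice, row, column)`; patient coordinates are
millimetres in the LPS frame,
`p = origin + col·sc·col_dir + row·sr·row_dir + slice·ss·normal`.

**Window/level** follows the DICOM linear convention:
`out = clamp(((v − (c − 0.5)) / (w − 1) + 0.5) · 255)` with half-up
rounding; a width of 1 degenerates to a binary threshold at the center.
Defaults are center 40 / width 80 for noncontrast head CT and 150/600
for CT angiography.

## Reformatting and rendering

Oblique and orthogonal slices are resampled with trilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1, out-of-volume samples = −1024
HU). A slab of thickness *t* averages (or maximum-projects)
`max(1, round(t / slice_spacing))` samples taken at native slice-spacing
steps centered on the plane. In-plane view changes apply rotate → zoom →
pan about the viewport center with bilinear resampling, so a recorded
event stream replays to identical pixels.

3-D rendering is orthographic ray casting with front-to-back alpha
compositing, early ray termination at accumulated opacity 0.99, and
step-size opacity correction `1 − (1 − a)^(step/1 mm)`. Transfer
functions are piecewise-linear HU → (opacity, gray) tables; shipped
presets are `bone`, `soft_tissue`, `vessel`, and `mip`
(maximum-intensity). Accuracy is pinned by oracles: a pure-Python
scalar ray loop (vectorized renderer agrees to < 1 gray), a
semi-transparent slab with a closed-form composite, and a sphere whose
rendered silhouette area matches πr² within 2%.

## Frame codec

The client viewport (default 320×480) is tiled into 8×8 blocks. Each
update transmits only blocks whose pixels changed bit-exactly since the
last transmitted frame, JPEG-coded at quality 25 during interaction
(drags) and quality 100 at rest and for keyframes; blocks shown at
quality 25 during a drag are re-sent once at quality 100 on the next
static frame so the resting image is always full quality. Keyframes (all
blocks) are sent on the first frame, on viewport resize, and every 120
frames, letting a client that lost packets resynchronize.

Blocks travel as *abbreviated* JPEG streams: the header through the
start-of-scan marker is identical for every 8×8 grayscale block at a
given quality, so it is a protocol constant and only the entropy-coded
scan is transmitted (2–4 bytes for a uniform block). The decoder
prepends the shared template and appends the end-of-image marker; any
block still decodes independently. A constant keyframe compresses at
≈64:1, and a quality-100 round trip is within 2 gray levels.

## State synchronization

The view state is a flat tree of typed leaves
(`view/wl/center`, `view/transform/zoom`, …) with a monotone revision
counter. Clients exchange minimal diffs (upserts + deletes between two
revisions); a diff against a stale base is rejected and answered with a
full resync. Diffs serialize to a small XML document
(see `docs/protocol.md`). A hub applies concurrent diffs in arrival
order (last-writer-wins per leaf) and rebroadcasts, so all attached
clients converge; this is what keeps a consultant's phone and a
workstation showing the same slice, window, and zoom.

## Sessions and confidentiality

The server owns the volume, the renderer, the codec state, and the state
tree; the client sends interaction events (window drag, pan, zoom,
rotate, slice scroll, mode/preset changes, HU probe) and receives state
diffs plus frame packets. Probes return textual HU statistics only — no
frame. Disconnecting releases the server-side volume and codec and
empties the client cache. Every message crosses an explicit byte-level
wire and is logged; `assert_confidential` verifies that no DICOM
payload, raw pixel array, or non-whitelisted metadata ever appears in
the traffic — only rendered, windowed, JPEG-coded tiles and typed JSON.
The transport is in-process; swapping in a socket changes no message
format.

## Phantoms

Synthetic heads make every layer testable without patient data: an
elliptic-cylinder skull shell (HU 1000) around brain parenchyma (HU 35)
with two ventricle ellipsoids (HU 8) in air (HU −1000). Findings are
stamped as geometric inserts before optional Gaussian noise: hemorrhage
(sphere, HU 70), early ischemic change (ellipsoid, HU 27), hyperdense
vessel segment (tube, HU 80), contrast-filled vessel (tube, HU 250), and
occlusion (a gap restored to brain HU, valid only where a vessel lumen
exists). Default acquisitions: 220-mm field of view, 5-mm slices for
noncontrast CT, 0.6-mm slices for CTA. Every insert carries an exact
voxel mask and implies a case label, so reader studies against ground
truth need no manual annotation. The phantoms are geometric, not
anatomical: no beam hardening, no partial-volume texture, no vascular
tree — they validate the engine, not observer performance in the wild.

## Reader evaluation

Binary calls against case truth yield a contingency table;
sensitivity, specificity, and accuracy are reported in percent.
Published-style tables are matched by *truncating* (flooring) to the
printed number of decimals, which reproduces every packaged table cell
exactly. Interrater agreement uses Cohen's kappa from category
marginals (undefined when expected agreement is 1). For the
10-point ASPECTS scale, two readings are flagged discrepant when they
differ by more than one point. A seeded simulator draws reader calls at
configured sensitivity/specificity; over 10,000 replicates of an
18-positive / 47-negative CTA reading it recovers the generating
sensitivity within binomial error.

Two published kappa values for noncontrast findings cannot be
recomputed from marginal counts alone (the per-case reader
cross-tabulation is not public) and are therefore out of scope; the CTA
occlusion kappa of 1 is fully determined by the counts (both readers
agreed on every case, including one shared miss) and is reproduced.

## Problem sizes and determinism

The test suite runs phantoms between 12×64×64 and 40×512×512 voxels,
64³–128³ rendering volumes, and a 320×480 streaming viewport; the whole
suite completes in well under a minute. All stochastic steps
(noise, reader draws, fuzzers) use `numpy.random.default_rng` with
explicit seeds; a replayed session is byte-identical across runs.
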