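"""Synthetic head CT phantoms with exact ground truth.

Geometric phantoms stand in for patient scans so every layer of the engine
is testable without clinical data. A head is modeled as nested ellipsoids:
an air background, a high-density skull shell, brain parenchyma, and
ventricles; lesions are stamped as spheres, ellipsoids, or tubes at
configured HU before Gaussian noise is added. The generator is
deterministic given its seed, and every insert carries an exact voxel mask
plus case-level labels (hemorrhage / ischemic change / dense vessel /
occlusion present).

Default spacings follow typical acute-stroke acquisitions: 5-mm axial
slices for noncontrast brain CT, 0.6-mm slices for CT angiography of the
head, both with a 220-mm in-plane field of view. Layer HU values (air
-1000, brain 35, ventricle 8, skull 1000, hemorrhage 70, ischemia 27,
contrast-filled vessel 250) are engine defaults drawn from CT convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInsertError, InvalidOcclusionError
from .volume_core import ImageVolume

HU_AIR = -1000.0
HU_SKULL = 1000.0
HU_BRAIN = 35.0
HU_VENTRICLE = 8.0
HU_HEMORRHAGE = 70.0
HU_ISCHEMIA = HU_BRAIN - 8.0
HU_DENSE_VESSEL = 80.0
HU_CONTRAST_VESSEL = 250.0

INSERT_KINDS = (
    "hemorrhage", "ischemia", "dense_vessel", "vessel",
    "occlusion_gap", "mimic_mass",
)
#: insert kind -> case-level label it implies
_CASE_LABEL = {
    "hemorrhage": "hemorrhage",
    "ischemia": "ischemic_change",
    "dense_vessel": "dense_vessel",
    "occlusion_gap": "occlusion",
}


@dataclass(frozen=True)
class InsertSpec:
    """One lesion or vessel primitive.

    ``shape`` is "sphere" (center + radius), "ellipsoid" (center +
    semi_axes) or "tube" (endpoints + radius); all geometry in mm relative
    to the volume origin.
    """

    kind: str
    shape: str
    hu_value: float
    center: tuple[float, float, float] | None = None      # (x, y, z) mm
    radius: float | None = None
    semi_axes: tuple[float, float, float] | None = None
    endpoints: tuple[tuple[float, float, float],
                     tuple[float, float, float]] | None = None

    def __post_init__(self):
        if self.kind not in INSERT_KINDS:
            raise ValueError(f"unknown insert kind {self.kind!r}")
        if self.shape == "sphere" and (self.center is None or self.radius is None):
            raise ValueError("sphere needs center and radius")
        if self.shape == "ellipsoid" and (self.center is None or self.semi_axes is None):
            raise ValueError("ellipsoid needs center and semi_axes")
        if self.shape == "tube" and (self.endpoints is None or self.radius is None):
            raise ValueError("tube needs endpoints and radius")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of one synthetic head CT series."""

    grid: tuple[int, int, int] = (26, 512, 512)        # (slices, rows, cols)
    spacing: tuple[float, float, float] = (220 / 512, 220 / 512, 5.0)
    inserts: tuple[InsertSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    modality: str = "NCCT"

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Exact per-insert voxel masks and the case labels they imply."""

    insert_masks: list[np.ndarray]
    insert_kinds: list[str]
    brain_mask: np.ndarray
    case_labels: dict[str, bool] = field(default_factory=dict)

    def mask_for(self, kind: str) -> np.ndarray:
        """Union of all insert masks of one kind."""
        out = np.zeros_like(self.brain_mask)
        for m, k in zip(self.insert_masks, self.insert_kinds):
            if k == kind:
                out |= m
        return out


def _mm_grids(spec: PhantomSpec):
    """Per-voxel (x, y, z) mm coordinate grids, broadcastable."""
    ns, nr, nc = spec.grid
    sr, sc, ss = spec.spacing
    z = (np.arange(ns) * ss)[:, None, None]
    y = (np.arange(nr) * sr)[None, :, None]
    x = (np.arange(nc) * sc)[None, None, :]
    return x, y, z


def _insert_mask(spec: PhantomSpec, ins: InsertSpec) -> np.ndarray:
    x, y, z = _mm_grids(spec)
    if ins.shape == "sphere":
        cx, cy, cz = ins.center
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        return d2 <= ins.radius ** 2
    if ins.shape == "ellipsoid":
        cx, cy, cz = ins.center
        ax, ay, az = ins.semi_axes
        q = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        return q <= 1.0
    # tube: distance from the segment p0-p1
    p0 = np.array(ins.endpoints[0], dtype=float)
    p1 = np.array(ins.endpoints[1], dtype=float)
    axis = p1 - p0
    length2 = float(axis @ axis)
    px = x - p0[0]
    py = y - p0[1]
    pz = z - p0[2]
    t = (px * axis[0] + py * axis[1] + pz * axis[2]) / max(length2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    dx = px - t * axis[0]
    dy = py - t * axis[1]
    dz = pz - t * axis[2]
    return dx ** 2 + dy ** 2 + dz ** 2 <= ins.radius ** 2


def _head_layers(spec: PhantomSpec):
    """Background layers: air, skull shell, brain, ventricles; plus masks."""
    ns, nr, nc = spec.grid
    sr, sc, ss = spec.spacing
    x, y, z = _mm_grids(spec)
    cx, cy = (nc - 1) * sc / 2, (nr - 1) * sr / 2
    # skull: elliptic cylinder shell through all slices (vertex/base ignored)
    a_out, b_out = 0.44 * nc * sc, 0.44 * nr * sr
    shell = 0.055 * min(nc * sc, nr * sr)
    q_out = ((x - cx) / a_out) ** 2 + ((y - cy) / b_out) ** 2
    q_in = ((x - cx) / (a_out - shell)) ** 2 + ((y - cy) / (b_out - shell)) ** 2
    ones_z = np.ones((ns, 1, 1), dtype=bool)
    skull = ((q_out <= 1.0) & (q_in > 1.0)) & ones_z
    brain = (q_in <= 1.0) & ones_z

    # two lateral ventricles: small ellipsoids around the mid slice
    cz = (ns - 1) * ss / 2
    vent = np.zeros(spec.grid, dtype=bool)
    for side in (-1.0, 1.0):
        vcx = cx + side * 0.10 * nc * sc
        q = (
            ((x - vcx) / (0.05 * nc * sc)) ** 2
            + ((y - cy) / (0.12 * nr * sr)) ** 2
            + ((z - cz) / (0.25 * ns * ss + 1e-9)) ** 2
        )
        vent |= q <= 1.0
    vent &= brain

    vol = np.full(spec.grid, HU_AIR, dtype=np.float64)
    vol[skull] = HU_SKULL
    vol[brain] = HU_BRAIN
    vol[vent] = HU_VENTRICLE
    return vol, brain


def _build(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    vol, brain = _head_layers(spec)

    vessel_union = np.zeros(spec.grid, dtype=bool)
    masks: list[np.ndarray] = []
    kinds: list[str] = []
    # vessels first so occlusion gaps can be validated against them
    ordered = sorted(
        spec.inserts, key=lambda i: 0 if i.kind in ("vessel", "dense_vessel") else 1
    )
    for ins in ordered:
        mask = _insert_mask(spec, ins)
        if not mask.any() or not mask[brain].any() or (mask & ~brain).any():
            if ins.kind == "occlusion_gap" and mask.any() and (mask & ~vessel_union).sum() == 0:
                pass  # gap fully inside a vessel is fine even near the margin
            else:
                raise InvalidInsertError(
                    f"invalid insert: {ins.kind} not inside brain mask"
                )
        if ins.kind == "occlusion_gap":
            if not (mask & vessel_union).any():
                raise InvalidOcclusionError(
                    "invalid occlusion: gap has no enclosing vessel"
                )
            mask = mask & vessel_union  # the gap replaces vessel lumen only
        if ins.kind in ("vessel", "dense_vessel"):
            vessel_union |= mask
        vol[mask] = ins.hu_value
        masks.append(mask)
        kinds.append(ins.kind)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)

    labels = {lab: False for lab in
              ("hemorrhage", "ischemic_change", "dense_vessel", "occlusion")}
    for m, k in zip(masks, kinds):
        lab = _CASE_LABEL.get(k)
        if lab is not None and m.any():
            labels[lab] = True

    voxels = vol
    if spec.noise_sd == 0 and np.allclose(vol, np.round(vol)):
        voxels = np.round(vol).astype(np.int16)
    volume = ImageVolume(
        voxels=voxels,
        spacing=spec.spacing,
        origin=np.zeros(3),
        orientation=np.eye(3),
        modality=spec.modality,
        attributes={
            "series_description": f"synthetic {spec.modality} head phantom",
            "slice_count": spec.grid[0],
        },
    )
    truth = GroundTruth(
        insert_masks=masks, insert_kinds=kinds,
        brain_mask=brain, case_labels=labels,
    )
    return volume, truth


def generate_ncct(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """Noncontrast brain CT phantom: skull, parenchyma, ventricles, lesions."""
    if any(i.kind in ("vessel", "occlusion_gap") for i in spec.inserts):
        raise ValueError("contrast vessel inserts belong in a CTA phantom")
    return _build(replace(spec, modality="NCCT"))


def generate_cta(spec: PhantomSpec) -> tuple[ImageVolume, GroundTruth]:
    """CT angiography phantom: contrast-filled vessels, optional occlusion gap."""
    return _build(replace(spec, modality="CTA"))


# ---------------------------------------------------------------------------
# convenience builders used by the demo server, docs and tests
# ---------------------------------------------------------------------------

def default_ncct_spec(
    grid=(26, 512, 512), *, hemorrhage=True, ischemia=True,
    dense_vessel=True, noise_sd=0.0, seed=0,
) -> PhantomSpec:
    """A stroke-protocol noncontrast head CT with the standard findings."""
    ns, nr, nc = grid
    sr = sc = 220.0 / max(nr, nc)
    ss = 5.0
    cx, cy = (nc - 1) * sc / 2, (nr - 1) * sr / 2
    cz = (ns // 2) * ss  # on a stored slice so thin tubes hit voxel centers
    inserts = []
    if hemorrhage:
        inserts.append(InsertSpec(
            kind="hemorrhage", shape="sphere", hu_value=HU_HEMORRHAGE,
            center=(cx - 0.12 * nc * sc, cy + 0.08 * nr * sr, cz), radius=12.0))
    if ischemia:
        inserts.append(InsertSpec(
            kind="ischemia", shape="ellipsoid", hu_value=HU_ISCHEMIA,
            center=(cx + 0.15 * nc * sc, cy, cz),
            semi_axes=(18.0, 14.0, 8.0)))
    if dense_vessel:
        # one hyperdense middle-cerebral segment; the contralateral twin
        # stays at brain HU so mirrored probes expose the contrast
        inserts.append(InsertSpec(
            kind="dense_vessel", shape="tube", hu_value=HU_DENSE_VESSEL,
            endpoints=((cx - 0.20 * nc * sc, cy - 0.10 * nr * sr, cz),
                       (cx - 0.05 * nc * sc, cy - 0.18 * nr * sr, cz)),
            radius=2.5))
    return PhantomSpec(grid=grid, spacing=(sr, sc, ss),
                       inserts=tuple(inserts), noise_sd=noise_sd, seed=seed)


def default_cta_spec(
    grid=(40, 512, 512), *, occluded=True, noise_sd=0.0, seed=0,
) -> PhantomSpec:
    """A CTA head phantom with one contrast vessel, optionally occluded."""
    ns, nr, nc = grid
    sr = sc = 220.0 / max(nr, nc)
    ss = 0.6
    cx, cy = (nc - 1) * sc / 2, (nr - 1) * sr / 2
    cz = (ns // 2) * ss
    x0 = cx - 0.25 * nc * sc
    x1 = cx + 0.25 * nc * sc
    inserts = [InsertSpec(
        kind="vessel", shape="tube", hu_value=HU_CONTRAST_VESSEL,
        endpoints=((x0, cy, cz), (x1, cy, cz)), radius=2.0)]
    if occluded:
        inserts.append(InsertSpec(
            kind="occlusion_gap", shape="tube", hu_value=HU_BRAIN,
            endpoints=((cx - 3.0, cy, cz), (cx + 3.0, cy, cz)), radius=2.5))
    return PhantomSpec(grid=grid, spacing=(sr, sc, ss),
                       inserts=tuple(inserts), noise_sd=noise_sd, seed=seed,
                       modality="CTA")


def simulate_reader_responses(
    truths, sensitivity: float, specificity: float, seed: int
) -> np.ndarray:
    """Simulate one reader's binary calls against known case truths.

    Each positive case is called positive with probability ``sensitivity``;
    each negative case with probability ``1 - specificity``. Deterministic
    given the seed.
    """
    if not 0 <= sensitivity <= 1 or not 0 <= specificity <= 1:
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    truths = np.asarray(truths, dtype=bool)
    rng = np.random.default_rng(seed)
    u = rng.random(truths.shape)
    calls = np.where(truths, u < sensitivity, u < (1.0 - specificity))
    return calls.astype(bool)
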