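"""Orthographic ray-cast volume rendering with tissue presets.

Per-pixel rays traverse the HU volume front-to-back, compositing opacity
and grayscale/color sampled from a piecewise-linear transfer function, with
early termination once accumulated opacity reaches 0.99. A maximum-intensity
mode ("mip") replaces compositing with a running max of the sampled HU.

Per-sample opacity is corrected for the marching step as
``1 - (1 - a)**(step/1mm)`` so renders stay comparable across step sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidCameraError, UnknownPresetError
from .volume_core import ImageVolume

OPACITY_REFERENCE_STEP_MM = 1.0
EARLY_TERMINATION_ALPHA = 0.99


@dataclass
class TransferFunction:
    """Piecewise-linear map HU -> (opacity, gray value).

    Control points are (hu, opacity in [0,1], gray in [0,255]), sorted by
    strictly increasing HU. Outside the control range the endpoint values
    hold. ``mode`` is "composite" or "mip".
    """

    control_points: list[tuple[float, float, float]]
    name: str = "custom"
    mode: str = "composite"

    def __post_init__(self):
        hu = [p[0] for p in self.control_points]
        if any(b <= a for a, b in zip(hu, hu[1:])):
            raise ValueError("control points must be strictly increasing in HU")
        if any(not 0 <= p[1] <= 1 for p in self.control_points):
            raise ValueError("opacities must lie in [0, 1]")

    def sample(self, hu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (opacity, gray) for an array of HU values."""
        xs = np.array([p[0] for p in self.control_points])
        alphas = np.array([p[1] for p in self.control_points])
        grays = np.array([p[2] for p in self.control_points])
        return np.interp(hu, xs, alphas), np.interp(hu, xs, grays)


@dataclass
class Camera:
    """Orthographic camera.

    Rays start on the image plane through ``eye`` and run toward
    ``look_at``; ``half_extent`` is the half-width/height of the imaged
    region in mm.
    """

    eye: np.ndarray
    look_at: np.ndarray
    up: np.ndarray
    half_extent: tuple[float, float]   # (half-height, half-width) mm
    out_size: tuple[int, int]          # (rows, cols)

    def __post_init__(self):
        self.eye = np.asarray(self.eye, dtype=float)
        self.look_at = np.asarray(self.look_at, dtype=float)
        self.up = np.asarray(self.up, dtype=float)
        d = self.look_at - self.eye
        if np.linalg.norm(d) < 1e-9:
            raise InvalidCameraError("invalid camera: eye equals look-at")
        d = d / np.linalg.norm(d)
        if np.linalg.norm(np.cross(d, self.up)) < 1e-9:
            raise InvalidCameraError("invalid camera: up parallel to view axis")
        if any(h <= 0 for h in self.half_extent):
            raise InvalidCameraError("invalid camera: non-positive extent")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(view direction, right, down) orthonormal basis."""
        d = self.look_at - self.eye
        d = d / np.linalg.norm(d)
        right = np.cross(d, self.up)
        right = right / np.linalg.norm(right)
        down = np.cross(d, right)
        return d, right, down


def _ray_grid(camera: Camera) -> tuple[np.ndarray, np.ndarray]:
    """Ray origins (rows, cols, 3) and the shared direction."""
    d, right, down = camera.basis()
    rows, cols = camera.out_size
    hh, hw = camera.half_extent
    ys = np.linspace(-hh, hh, rows)
    xs = np.linspace(-hw, hw, cols)
    origins = (
        camera.eye
        + ys[:, None, None] * down
        + xs[None, :, None] * right
    )
    return origins, d


def render_raycast(
    volume: ImageVolume,
    camera: Camera,
    tf: TransferFunction,
    step_mm: float = 1.0,
    *,
    max_depth_mm: float | None = None,
    background: float = 0.0,
) -> np.ndarray:
    """Ray-cast the volume; returns a float grayscale image in [0, 255].

    Front-to-back alpha compositing with trilinear HU sampling; rays stop
    early once accumulated opacity reaches 0.99. In "mip" mode the maximum
    HU along each ray is mapped through the transfer function's gray ramp.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be > 0")
    origins, direction = _ray_grid(camera)
    if max_depth_mm is None:
        ext = volume.extent_mm()
        max_depth_mm = float(np.linalg.norm(ext)) + 2 * float(
            np.linalg.norm(camera.eye - camera.look_at)
        )
    n_steps = max(1, int(np.ceil(max_depth_mm / step_mm)))
    vox = volume.voxels.astype(np.float64)

    rows, cols = camera.out_size
    if tf.mode == "mip":
        best = np.full((rows, cols), -np.inf)
        for s in range(n_steps):
            pts = origins + (s * step_mm) * direction
            kij = volume.patient_to_index(pts)
            sample = ndimage.map_coordinates(
                vox, np.moveaxis(kij, -1, 0), order=1,
                mode="constant", cval=-1024.0,
            )
            np.maximum(best, sample, out=best)
        _, gray = tf.sample(best)
        alpha, _ = tf.sample(best)
        return gray * alpha + background * (1 - alpha)

    color = np.zeros((rows, cols))
    transparency = np.ones((rows, cols))
    alpha_exp = step_mm / OPACITY_REFERENCE_STEP_MM
    for s in range(n_steps):
        active = transparency > (1 - EARLY_TERMINATION_ALPHA)
        if not active.any():
            break
        pts = origins + (s * step_mm) * direction
        kij = volume.patient_to_index(pts)
        sample = ndimage.map_coordinates(
            vox, np.moveaxis(kij, -1, 0), order=1,
            mode="constant", cval=-1024.0,
        )
        a, g = tf.sample(sample)
        a = 1.0 - (1.0 - a) ** alpha_exp  # step-size opacity correction
        contrib = transparency * a
        color += np.where(active, contrib * g, 0.0)
        transparency = np.where(active, transparency * (1.0 - a), transparency)
    color += transparency * background
    return color


# ---------------------------------------------------------------------------
# packaged tissue presets — HU anchors are engine defaults from CT convention
# ---------------------------------------------------------------------------

_PRESETS: dict[str, TransferFunction] = {
    "bone": TransferFunction(
        [(-1024, 0.0, 0), (200, 0.0, 0), (400, 0.9, 220), (1500, 1.0, 255)],
        name="bone",
    ),
    "soft_tissue": TransferFunction(
        [(-1024, 0.0, 0), (-200, 0.0, 0), (0, 0.15, 90), (80, 0.45, 200),
         (300, 0.0, 255), (3000, 0.0, 255)],
        name="soft_tissue",
    ),
    "vessel": TransferFunction(
        [(-1024, 0.0, 0), (100, 0.0, 0), (200, 0.8, 230), (1200, 1.0, 255)],
        name="vessel",
    ),
    "mip": TransferFunction(
        [(-1024, 1.0, 0), (1200, 1.0, 255)],
        name="mip", mode="mip",
    ),
}


def preset(name: str) -> TransferFunction:
    """Return a packaged tissue transfer function by name.

    Known names: bone, soft_tissue, vessel, mip. "mip" switches the
    renderer to maximum-intensity compositing.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; known: {sorted(_PRESETS)}"
        ) from None
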