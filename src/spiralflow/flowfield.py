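"""Spiral-space optic-flow stimuli: 3D star cloud and idealized screen velocity fields.

The stimulus is the projected image of a camera moving through a 3D dot cloud.
Flow patterns live in a "spiral space" spanned by two orthogonal planes that
share the forward/backward radial axis:

* **roll plane** — self-rotation about the line of sight; the in-plane angle
  ``theta`` mixes forward motion (expansion, ``theta = 0``) with rotation
  (pure clockwise at ``theta = +90``, counter-clockwise at ``-90``).
* **translation plane** — lateral self-motion; ``theta`` mixes expansion with
  laminar flow (pure leftward screen flow at ``theta = +90``, rightward at
  ``-90``).

Sign conventions: positive roll angle = clockwise on the screen as seen by the
observer; positive translation angle = leftward screen flow. Screen coordinates
are degrees of visual angle, fovea at the origin, +x rightward, +y upward.

Motion coherence keeps a Bernoulli-drawn fraction of dots on the coherent
trajectory each frame and re-randomizes the remainder uniformly in the volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CloudSpec",
    "DotCloud",
    "FlowFieldSpec",
    "VelocityField",
    "init_cloud",
    "advance_frame",
    "screen_velocity_template",
    "project_to_screen",
    "square_grid",
    "export_trajectories",
]

ROLL = "roll"
TRANSLATION = "translation"


class InvalidSpecError(ValueError):
    """Raised for a stimulus specification that violates its invariants."""


@dataclass(frozen=True)
class CloudSpec:
    """Geometry of the 3D star cloud and the viewing configuration.

    The default volume is 100 x 100 x 40 cm at 0.01 dots/cm^3, viewed from
    ~32 cm so the display subtends ~90 x 90 deg.  The observer's eye sits at
    the origin looking along +z; the cloud straddles the screen plane, spanning
    ``viewing_distance +/- extent_z/2`` in depth.
    """

    extent_x: float = 100.0
    extent_y: float = 100.0
    extent_z: float = 40.0
    density: float = 0.01
    viewing_distance: float = 32.0
    field_of_view: tuple[float, float] = (90.0, 90.0)

    def __post_init__(self) -> None:
        if min(self.extent_x, self.extent_y, self.extent_z) <= 0:
            raise InvalidSpecError("cloud extents must be positive")
        if self.density < 0:
            raise InvalidSpecError("dot density must be non-negative")
        if self.viewing_distance <= 0:
            raise InvalidSpecError("viewing distance must be positive")

    @property
    def volume(self) -> float:
        return self.extent_x * self.extent_y * self.extent_z

    @property
    def n_dots(self) -> int:
        return int(round(self.density * self.volume))

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [lower, upper] corners in cm."""
        z0 = self.viewing_distance - self.extent_z / 2.0
        lo = np.array([-self.extent_x / 2.0, -self.extent_y / 2.0, z0])
        hi = lo + np.array([self.extent_x, self.extent_y, self.extent_z])
        return np.vstack([lo, hi])


@dataclass(frozen=True)
class FlowFieldSpec:
    """One point of the spiral space: a plane, an in-plane angle and a coherence.

    ``theta`` is the angle from straight-forward motion within the plane, in
    degrees, restricted to (-180, 180].  ``speed_scale`` sets the flow
    magnitude: deg/s at 1 deg eccentricity for the screen templates, and the
    camera speed (cm/s, or deg/s of roll) for the 3D cloud dynamics.
    """

    plane: str
    theta: float
    coherence: float = 1.0
    speed_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.plane not in (ROLL, TRANSLATION):
            raise InvalidSpecError(f"unknown plane {self.plane!r}")
        if not (-180.0 < self.theta <= 180.0):
            raise InvalidSpecError("theta must lie in (-180, 180] deg")
        if not (0.0 <= self.coherence <= 1.0):
            raise InvalidSpecError("coherence must lie in [0, 1]")


@dataclass
class DotCloud:
    """A frame of the star cloud: (n, 3) dot positions in cm.

    ``coherent_mask``/``reseeded_mask`` describe the transition that produced
    this frame (set by :func:`advance_frame`; empty for an initial cloud).
    """

    positions: np.ndarray
    frame_index: int = 0
    coherent_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    reseeded_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class VelocityField:
    """Screen-plane flow sample: positions (deg) and velocities (deg/s)."""

    grid: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.atleast_2d(np.asarray(self.grid, float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, float))
        if self.grid.shape != self.vectors.shape:
            raise ValueError("grid and vectors must have the same shape")
        if not (np.isfinite(self.grid).all() and np.isfinite(self.vectors).all()):
            raise ValueError("velocity field must be finite everywhere")


def init_cloud(spec: CloudSpec, seed: int | np.random.Generator) -> DotCloud:
    """Fill the volume with ``round(density * volume)`` i.i.d. uniform dots."""
    rng = np.random.default_rng(seed)
    lo, hi = spec.bounds
    pos = rng.uniform(lo, hi, size=(spec.n_dots, 3))
    return DotCloud(positions=pos, frame_index=0)


def _coherent_step(pos: np.ndarray, flow: FlowFieldSpec, dt: float) -> np.ndarray:
    """Displace dots by the camera-motion rule for (plane, theta)."""
    th = np.deg2rad(flow.theta)
    s = flow.speed_scale
    out = pos.copy()
    # forward self-motion: dots approach the observer
    out[:, 2] -= np.cos(th) * s * dt
    if flow.plane == ROLL:
        # positive theta = CW image rotation about the line of sight
        phi = np.deg2rad(np.sin(th) * s * dt)
        c, sn = np.cos(phi), np.sin(phi)
        x, y = out[:, 0].copy(), out[:, 1].copy()
        out[:, 0] = c * x + sn * y
        out[:, 1] = -sn * x + c * y
    else:
        # positive theta = leftward image flow (camera moves rightward)
        out[:, 0] -= np.sin(th) * s * dt
    return out


def advance_frame(
    cloud: DotCloud,
    flow: FlowFieldSpec,
    spec: CloudSpec,
    dt: float,
    rng: np.random.Generator,
) -> DotCloud:
    """Advance the cloud one frame.

    Each dot independently moves coherently with probability ``flow.coherence``
    and is otherwise re-drawn uniformly in the volume.  Coherent dots that exit
    the volume re-enter through the opposite face (periodic wrap), which keeps
    the density stationary; the wrap is recorded in ``reseeded_mask``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = len(cloud)
    lo, hi = spec.bounds
    extent = hi - lo
    coherent = rng.random(n) < flow.coherence

    new = cloud.positions.copy()
    if coherent.any():
        new[coherent] = _coherent_step(cloud.positions[coherent], flow, dt)
    if (~coherent).any():
        new[~coherent] = rng.uniform(lo, hi, size=((~coherent).sum(), 3))

    # wrap coherent leavers onto the entry face
    below = new < lo
    above = new >= hi
    reseeded = (below | above).any(axis=1) & coherent
    if reseeded.any():
        new = lo + np.mod(new - lo, extent)

    return DotCloud(
        positions=new,
        frame_index=cloud.frame_index + 1,
        coherent_mask=coherent,
        reseeded_mask=reseeded,
    )


def screen_velocity_template(flow: FlowFieldSpec, grid: np.ndarray) -> VelocityField:
    """Idealized first-order screen flow for one spiral-space stimulus.

    ``v(p) = cos(theta) * radial(p) + sin(theta) * secondary(p)`` where
    ``radial(p)`` points away from the fovea with magnitude proportional to
    eccentricity, and ``secondary`` is the tangential (CW for positive theta)
    field in the roll plane or a uniform leftward field in the translation
    plane.  These are the templates used for receptive-field flow-similarity
    analysis; they carry no per-dot depth dependence.
    """
    grid = np.atleast_2d(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    th = np.deg2rad(flow.theta)
    s = flow.speed_scale
    x, y = grid[:, 0], grid[:, 1]
    radial = s * np.column_stack([x, y])
    if flow.plane == ROLL:
        secondary = s * np.column_stack([y, -x])  # CW tangent, +y up
    else:
        secondary = np.tile([-s, 0.0], (len(grid), 1))  # uniform leftward
    return VelocityField(grid=grid, vectors=np.cos(th) * radial + np.sin(th) * secondary)


def project_to_screen(
    cloud: DotCloud, spec: CloudSpec, clip: bool = True
) -> np.ndarray:
    """Pinhole-project dots to screen coordinates (deg of visual angle).

    Dots at or behind the eye plane (z <= 0) are excluded with a warning; with
    ``clip`` the result is additionally restricted to the field of view.  A dot
    on the optical axis maps to (0, 0).
    """
    pos = cloud.positions
    front = pos[:, 2] > 0
    n_excluded = int((~front).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} dot(s) at or behind the eye plane")
    p = pos[front]
    screen = np.degrees(np.arctan2(p[:, :2], p[:, 2:3]))
    if clip:
        half = np.asarray(spec.field_of_view, float) / 2.0
        inside = (np.abs(screen) <= half).all(axis=1)
        screen = screen[inside]
    return screen


def square_grid(half_extent: float, step: float) -> np.ndarray:
    """Regular (n, 2) grid of screen positions covering a centered square."""
    axis = np.arange(-half_extent, half_extent + step / 2.0, step)
    gx, gy = np.meshgrid(axis, axis)
    return np.column_stack([gx.ravel(), gy.ravel()])


def export_trajectories(frames: list[DotCloud], spec: CloudSpec, path) -> pd.DataFrame:
    """Write per-frame dot trajectories to CSV.

    Columns: frame, dot_id, x_cm, y_cm, z_cm, x_deg, y_deg.  Screen columns are
    NaN for dots at or behind the eye plane.
    """
    rows = []
    for fr in frames:
        p = fr.positions
        with np.errstate(invalid="ignore", divide="ignore"):
            deg = np.degrees(np.arctan2(p[:, :2], p[:, 2:3]))
        deg[p[:, 2] <= 0] = np.nan
        rows.append(
            pd.DataFrame(
                {
                    "frame": fr.frame_index,
                    "dot_id": np.arange(len(fr)),
                    "x_cm": p[:, 0],
                    "y_cm": p[:, 1],
                    "z_cm": p[:, 2],
                    "x_deg": deg[:, 0],
                    "y_deg": deg[:, 1],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.to_csv(path, index=False)
    return df
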