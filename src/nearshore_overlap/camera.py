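"""Nadir camera photogrammetry: ground scale, frame footprints, pixel↔ground mapping.

All geometry assumes an orthogonal (nadir-pointing) camera over flat water, so
the mapping between image pixels and ground coordinates is a similarity
transform: a per-axis scale set by altitude and the camera's optics, plus a
rotation by the aircraft heading.  Two footprint conventions are provided
because consumer drones record video with a vertical field of view spanning
the full sensor height while cropping horizontally to the video aspect ratio
(``video_fov``), whereas ground-sample-distance calculators scale the full
sensor width across the image width (``gsd_width``).  The two differ by about
15% in footprint width; ``video_fov`` is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "FramePose",
    "ground_sample_distance",
    "frame_footprint",
    "frame_overlap_fraction",
    "pixel_to_ground",
    "ground_to_pixel",
    "footprint_polygon",
]

#: Footprint conventions understood by :func:`frame_footprint`.
FOOTPRINT_CONVENTIONS = ("video_fov", "gsd_width")


@dataclass(frozen=True)
class CameraModel:
    """Optical constants of the survey camera.

    Defaults are the DJI Phantom 4 Pro v2.0 recording 4k video: 8.8 mm focal
    length on a 13.2 x 8.8 mm 1" sensor, 3840 x 2160 px at 16:9.
    """

    focal_length_mm: float = 8.8
    sensor_width_mm: float = 13.2
    sensor_height_mm: float = 8.8
    image_width_px: int = 3840
    image_height_px: int = 2160

    def __post_init__(self) -> None:
        for name in ("focal_length_mm", "sensor_width_mm", "sensor_height_mm",
                     "image_width_px", "image_height_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CameraModel.{name} must be positive")

    @property
    def aspect(self) -> float:
        return self.image_width_px / self.image_height_px


@dataclass(frozen=True)
class FramePose:
    """One extracted survey frame: when, where (nadir point), how high, which way."""

    timestamp: float
    x: float
    y: float
    altitude_m: float
    heading_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (60.0 <= self.altitude_m <= 120.0):
            raise ValueError(
                f"altitude {self.altitude_m} m outside the 60-120 m survey envelope"
            )


def ground_sample_distance(camera: CameraModel, altitude_m: float) -> float:
    """Metres of ground per image pixel (width-basis calibration).

    GSD = sensor_width * altitude / (focal_length * image_width); linear in
    altitude.
    """
    if altitude_m <= 0:
        raise ValueError("altitude must be positive")
    return (camera.sensor_width_mm * altitude_m) / (
        camera.focal_length_mm * camera.image_width_px
    )


def frame_footprint(
    camera: CameraModel, altitude_m: float, convention: str = "video_fov"
) -> tuple[float, float, float]:
    """Ground footprint of one frame as ``(width_m, height_m, area_m2)``.

    ``video_fov``: the vertical field of view spans the full sensor height
    (ground_height = altitude * sensor_height / focal_length) and the width
    follows from the 16:9 video aspect; the area is the product of the
    dimensions rounded to whole metres, matching how surveyed areas are
    conventionally reported.  ``gsd_width``: both dimensions are the pixel
    counts times the width-basis GSD, with the exact (unrounded) product.
    """
    if altitude_m <= 0:
        raise ValueError("altitude must be positive")
    if convention == "video_fov":
        height = altitude_m * camera.sensor_height_mm / camera.focal_length_mm
        width = height * camera.aspect
        area = round(width) * round(height)
        return width, height, float(area)
    if convention == "gsd_width":
        gsd = ground_sample_distance(camera, altitude_m)
        width = gsd * camera.image_width_px
        height = gsd * camera.image_height_px
        return width, height, width * height
    raise ValueError(
        f"unknown footprint convention {convention!r}; expected one of {FOOTPRINT_CONVENTIONS}"
    )


def frame_overlap_fraction(
    speed_m_s: float, interval_s: float, along_track_extent_m: float
) -> float:
    """Fraction of ground shared by consecutive frames along track.

    max(0, 1 - speed*interval/extent): the drone advances speed*interval
    metres between frames whose footprints span ``along_track_extent_m``.
    """
    if speed_m_s <= 0 or interval_s <= 0 or along_track_extent_m <= 0:
        raise ValueError("speed, interval and extent must all be positive")
    return max(0.0, 1.0 - speed_m_s * interval_s / along_track_extent_m)


def _ground_extents(camera: CameraModel, altitude_m: float, convention: str) -> tuple[float, float]:
    width, height, _ = frame_footprint(camera, altitude_m, convention)
    return width, height


def _heading_rotation(heading_deg: float) -> np.ndarray:
    """Right-handed rotation taking camera axes to ground axes."""
    t = math.radians(heading_deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


def pixel_to_ground(
    pose: FramePose,
    camera: CameraModel,
    pixel: tuple[float, float],
    convention: str = "video_fov",
) -> tuple[float, float]:
    """Map an image pixel ``(col, row)`` to local ground coordinates.

    The principal point (image centre) maps to the nadir position; pixel
    offsets scale by the per-axis ground extent and rotate by heading.  Row
    increases "down" the image, which at heading 0 points along -y.
    """
    col, row = pixel
    if not (0 <= col <= camera.image_width_px and 0 <= row <= camera.image_height_px):
        raise ValueError(f"pixel {pixel} outside image bounds")
    width, height, _ = frame_footprint(camera, pose.altitude_m, convention)
    dx = (col / camera.image_width_px - 0.5) * width
    dy = -(row / camera.image_height_px - 0.5) * height
    gx, gy = _heading_rotation(pose.heading_deg) @ (dx, dy)
    return pose.x + gx, pose.y + gy


def ground_to_pixel(
    pose: FramePose,
    camera: CameraModel,
    point: tuple[float, float],
    convention: str = "video_fov",
) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_ground`; raises if the point is outside the frame."""
    width, height, _ = frame_footprint(camera, pose.altitude_m, convention)
    v = np.asarray(point, dtype=float) - (pose.x, pose.y)
    dx, dy = _heading_rotation(-pose.heading_deg) @ v
    col = (dx / width + 0.5) * camera.image_width_px
    row = (-dy / height + 0.5) * camera.image_height_px
    if not (0 <= col <= camera.image_width_px and 0 <= row <= camera.image_height_px):
        raise ValueError(f"ground point {point} outside frame footprint")
    return col, row


def footprint_polygon(
    pose: FramePose, camera: CameraModel, convention: str = "video_fov"
) -> np.ndarray:
    """Ground corners of the frame footprint, (4, 2), counter-clockwise."""
    width, height, _ = frame_footprint(camera, pose.altitude_m, convention)
    hw, hh = width / 2.0, height / 2.0
    corners = np.array([[-hw, -hh], [hw, -hh], [hw, hh], [-hw, hh]])
    rot = _heading_rotation(pose.heading_deg)
    return corners @ rot.T + (pose.x, pose.y)
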