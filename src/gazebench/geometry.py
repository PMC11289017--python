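"""Screen geometry and pixel/visual-angle conversions.

All gaze-quality metrics downstream are expressed in degrees of visual
angle, so every module funnels through the conversions here.  Angles are
computed per axis about the screen center with ``atan`` (not the exact
great-circle angle between gaze vectors): at a desktop geometry the
difference is below 0.1 degree and per-axis angles keep x and y separable
for the per-axis precision metrics.

Conventions
-----------
* Pixel origin top-left, y increases downward.
* Degree coordinates inherit the same sign convention (y positive
  downward), so no silent axis flips occur between pixel and degree space.
* The viewing distance is fixed; head-position-dependent geometry is out
  of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreenGeometry",
    "screen_from_diagonal",
    "px_to_deg",
    "deg_to_px",
    "angular_distance",
    "DEFAULT_SCREEN",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and pixel dimensions of the display plus viewing distance.

    Attributes
    ----------
    width_px, height_px : int
        Display resolution in pixels.
    width_mm, height_mm : float
        Physical display size in millimetres.  Pixels must be square:
        ``width_mm / height_mm`` must match ``width_px / height_px``
        within 0.1 %.
    viewing_distance_mm : float
        Eye-to-screen distance in millimetres.
    """

    width_px: int
    height_px: int
    width_mm: float
    height_mm: float
    viewing_distance_mm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm",
                     "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        aspect_mm = self.width_mm / self.height_mm
        aspect_px = self.width_px / self.height_px
        if abs(aspect_mm / aspect_px - 1.0) > 1e-3:
            raise ValueError(
                "non-square pixels: physical aspect "
                f"{aspect_mm:.5f} vs pixel aspect {aspect_px:.5f}"
            )

    @property
    def pitch_mm(self) -> float:
        """Size of one pixel in millimetres (square pixels assumed)."""
        return self.width_mm / self.width_px

    @property
    def center_px(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


def screen_from_diagonal(diagonal_mm: float, width_px: int, height_px: int,
                         distance_mm: float) -> ScreenGeometry:
    """Build a :class:`ScreenGeometry` from the display diagonal.

    ``width_mm = diagonal_mm * width_px / sqrt(width_px**2 + height_px**2)``
    and analogously for the height, i.e. square pixels are assumed.

    Raises
    ------
    ValueError
        If any argument is non-positive.
    """
    if diagonal_mm <= 0 or width_px <= 0 or height_px <= 0 or distance_mm <= 0:
        raise ValueError("all screen_from_diagonal arguments must be > 0")
    diag_px = math.hypot(width_px, height_px)
    return ScreenGeometry(
        width_px=int(width_px),
        height_px=int(height_px),
        width_mm=diagonal_mm * width_px / diag_px,
        height_mm=diagonal_mm * height_px / diag_px,
        viewing_distance_mm=distance_mm,
    )


#: 15-inch (381 mm) diagonal, 1440 x 900 px, viewed at 600 mm -- the
#: bench's reference desktop geometry.
DEFAULT_SCREEN = screen_from_diagonal(381.0, 1440, 900, 600.0)


def px_to_deg(point_px: np.ndarray, geom: ScreenGeometry) -> np.ndarray:
    """Convert pixel coordinates to signed visual angle about screen center.

    Accepts a single ``(x, y)`` pair or an ``(n, 2)`` array.  Off-screen
    points are allowed and extrapolated.  Output has the same shape.
    """
    p = np.asarray(point_px, dtype=float)
    cx, cy = geom.center_px
    out = np.empty_like(p)
    d = geom.viewing_distance_mm
    pitch = geom.pitch_mm
    out[..., 0] = np.degrees(np.arctan((p[..., 0] - cx) * pitch / d))
    out[..., 1] = np.degrees(np.arctan((p[..., 1] - cy) * pitch / d))
    return out


def deg_to_px(point_deg: np.ndarray, geom: ScreenGeometry) -> np.ndarray:
    """Inverse of :func:`px_to_deg`."""
    a = np.asarray(point_deg, dtype=float)
    cx, cy = geom.center_px
    out = np.empty_like(a)
    d = geom.viewing_distance_mm
    pitch = geom.pitch_mm
    out[..., 0] = cx + np.tan(np.radians(a[..., 0])) * d / pitch
    out[..., 1] = cy + np.tan(np.radians(a[..., 1])) * d / pitch
    return out


def angular_distance(a_px: np.ndarray, b_px: np.ndarray,
                     geom: ScreenGeometry) -> float | np.ndarray:
    """Euclidean distance in degree space between two pixel positions.

    This is the accuracy measure: the angular separation between, e.g., a
    fixation centroid and its target.  Symmetric and non-negative; a metric
    on the screen plane.
    """
    da = px_to_deg(a_px, geom) - px_to_deg(b_px, geom)
    return np.linalg.norm(da, axis=-1)
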