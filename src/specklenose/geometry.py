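"""Optical geometry of a defocused secondary-speckle imaging system.

A coherent spot of diameter ``D`` illuminates a rough surface; the
back-reflected field forms a secondary speckle pattern that, observed in
the far field, translates rigidly with surface tilt.  Two design
quantities matter when choosing a camera/lens for such a system:

* the far-field threshold distance ``D**2 / (4 * lam)`` that the
  surface-to-speckle-plane distance ``Z2`` must exceed, and
* the minimum focal length ``F = K * delta_x * Z3 * D / (Z2 * lam)``
  that resolves each speckle grain over at least ``K`` detector pixels.

The focal-length grouping follows from the far-field speckle grain size
``lam * Z2 / D`` magnified by ``F / Z3``: a larger spot produces finer
speckle and therefore demands a longer focal length.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OpticalGeometry",
    "InvalidGeometryError",
    "far_field_threshold",
    "is_far_field",
    "required_focal_length",
]


class InvalidGeometryError(ValueError):
    """Raised when a geometry field is non-positive or inconsistent."""


@dataclass(frozen=True)
class OpticalGeometry:
    """Geometry of the laser/camera arrangement.

    Parameters
    ----------
    K : float
        Minimum number of pixels over which one speckle grain must be
        resolved (dimensionless count, ``>= 1``).
    delta_x : float
        Detector pixel pitch in metres.
    Z2 : float
        Distance from the illuminated surface to the secondary speckle
        plane, metres.
    Z3 : float
        Distance from the speckle plane to the camera lens, metres.
    D : float
        Laser spot diameter on the surface, metres.
    lam : float
        Laser wavelength, metres.
    F : float, optional
        Camera focal length in metres; ``None`` means "derive it from
        the other fields" via :func:`required_focal_length`.
    """

    K: float
    delta_x: float
    Z2: float
    Z3: float
    D: float
    lam: float
    F: float | None = None

    def __post_init__(self) -> None:
        for name in ("K", "delta_x", "Z2", "Z3", "D", "lam"):
            value = getattr(self, name)
            if not (value > 0):
                raise InvalidGeometryError(
                    f"geometry field {name!r} must be strictly positive, got {value!r}"
                )
        if self.K < 1:
            raise InvalidGeometryError(f"K must be >= 1, got {self.K!r}")
        if self.F is not None and not (self.F > 0):
            raise InvalidGeometryError(f"F must be positive when given, got {self.F!r}")


def far_field_threshold(geom: OpticalGeometry) -> float:
    """Distance ``D**2 / (4 * lam)`` beyond which the far-field holds.

    The observation distance ``Z2`` must exceed this threshold for the
    speckle pattern to behave as a planar interference pattern that
    translates rigidly with surface tilt.
    """
    return geom.D**2 / (4.0 * geom.lam)


def is_far_field(geom: OpticalGeometry) -> bool:
    """Whether ``Z2`` exceeds the far-field threshold."""
    return geom.Z2 > far_field_threshold(geom)


def required_focal_length(geom: OpticalGeometry) -> float:
    """Minimum focal length ``F = K * delta_x * Z3 * D / (Z2 * lam)``.

    Ensures each speckle grain (far-field size ``lam * Z2 / D``, seen
    through the ``F / Z3`` magnification) covers at least ``K`` pixels
    of pitch ``delta_x`` on the detector.
    """
    return geom.K * geom.delta_x * geom.Z3 * geom.D / (geom.Z2 * geom.lam)
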