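"""Closed-form acquisition planning for parallel-beam inline phase-contrast micro-CT.

The planner answers the questions a beamline user asks before a scan:

* How far can the detector sit from the sample before Fresnel fringes from
  features of diameter ``a`` outgrow the features themselves?  In the
  near-field (Fresnel) regime the propagation distance must satisfy
  ``PD <= a**2 / lambda``.
* How many projections are needed over 180 degrees to sample the edge of
  the field of view without angular aliasing?  The classical answer is the
  detector width in pixels times ``pi/2``.
* How many concatenated (tiled) scans cover an elongated sample given the
  field of view and a tile-to-tile overlap?

All distances returned by these functions are unrounded floats (integers
only where the contract is a count); display rounding belongs to callers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "HC_KEV_M",
    "BeamSpec",
    "DetectorSpec",
    "kev_to_wavelength",
    "max_propagation_distance",
    "min_resolvable_feature",
    "nyquist_projection_count",
    "plan_tiled_scan",
    "fov_from_detector",
    "feature_width_um",
]

#: Planck constant times speed of light, in keV * m (CODATA, rounded).
HC_KEV_M = 1.239842e-9


def kev_to_wavelength(energy_kev: float) -> float:
    """Convert photon energy in keV to wavelength in metres.

    ``lambda = hc / E`` with ``hc`` = 1.239842e-9 keV*m, so 12.39842 keV
    maps to exactly 1 Angstrom and 25 keV to 4.959e-11 m.
    """
    if not energy_kev > 0:
        raise ValueError(f"energy_kev must be positive, got {energy_kev!r}")
    return HC_KEV_M / energy_kev


@dataclass(frozen=True)
class BeamSpec:
    """Monochromatic beam description.

    Parameters
    ----------
    energy_kev : float
        Photon energy in keV.  The wavelength is derived, never set.
    """

    energy_kev: float
    wavelength_m: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelength_m", kev_to_wavelength(self.energy_kev))


@dataclass(frozen=True)
class DetectorSpec:
    """Detector geometry after optical magnification.

    ``effective_pixel_um`` is the sample-space extent of one detector pixel
    (physical pixel divided by total magnification).
    """

    n_u: int
    n_v: int
    effective_pixel_um: float

    def __post_init__(self) -> None:
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("detector dimensions must be >= 1 pixel")
        if not self.effective_pixel_um > 0:
            raise ValueError("effective_pixel_um must be positive")


def max_propagation_distance(feature_diameter_um: float, beam: BeamSpec) -> float:
    """Largest near-field propagation distance for a feature, in mm.

    Evaluates the Fresnel-regime bound ``PD <= a**2 / lambda`` at equality.
    Beyond this distance the interference fringes generated by a feature of
    diameter ``a`` become wider than the feature and obscure rather than
    enhance it.

    Parameters
    ----------
    feature_diameter_um : float
        Feature diameter ``a`` in micrometres.
    beam : BeamSpec

    Returns
    -------
    float
        ``a**2 / lambda`` in millimetres, unrounded.
    """
    if not feature_diameter_um > 0:
        raise ValueError("feature diameter must be positive")
    a_m = feature_diameter_um * 1e-6
    return (a_m * a_m / beam.wavelength_m) * 1e3


def min_resolvable_feature(pd_mm: float, beam: BeamSpec) -> float:
    """Smallest feature still in the near field at a propagation distance.

    Inverse of :func:`max_propagation_distance`: ``a = sqrt(PD * lambda)``,
    returned in micrometres.  Features smaller than this are dominated by
    their own Fresnel fringes at distance ``pd_mm``.
    """
    if not pd_mm > 0:
        raise ValueError("propagation distance must be positive")
    return math.sqrt(pd_mm * 1e-3 * beam.wavelength_m) * 1e6


def nyquist_projection_count(width_px: int) -> int:
    """Minimal projection count over 180 deg for a given sampled width.

    Angular Nyquist sampling at the edge of a region ``width_px`` pixels
    wide (perpendicular to the rotation axis) requires about
    ``width_px * pi / 2`` equally spaced projections; the result is rounded
    to the nearest integer.
    """
    if int(width_px) != width_px or width_px < 1:
        raise ValueError("width_px must be a positive integer")
    return int(round(width_px * math.pi / 2.0))


def plan_tiled_scan(
    sample_length_mm: float, fov_width_mm: float, overlap_fraction: float = 0.0
) -> int:
    """Number of concatenated scans needed to cover an elongated sample.

    Each tile advances by ``fov * (1 - overlap_fraction)``; partial tiles
    round up.  ``overlap_fraction`` is the fraction of the field of view
    shared between neighbouring tiles.
    """
    if not sample_length_mm > 0:
        raise ValueError("sample_length_mm must be positive")
    if not fov_width_mm > 0:
        raise ValueError("fov_width_mm must be positive")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    stride = fov_width_mm * (1.0 - overlap_fraction)
    # tiny slack so exact tilings (e.g. 7.0 / 3.5) do not round up on
    # floating-point dust
    return math.ceil(sample_length_mm / stride - 1e-9)


def fov_from_detector(det: DetectorSpec) -> tuple[float, float]:
    """Field of view (width_mm, height_mm) of a detector specification."""
    return (
        det.n_u * det.effective_pixel_um / 1000.0,
        det.n_v * det.effective_pixel_um / 1000.0,
    )


def feature_width_um(n_pixels: float, effective_pixel_um: float) -> float:
    """Physical width of a feature spanning ``n_pixels`` detector pixels."""
    if not n_pixels > 0:
        raise ValueError("n_pixels must be positive")
    return n_pixels * effective_pixel_um
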