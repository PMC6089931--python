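"""Paganin single-distance phase retrieval and filtered back projection.

Phase retrieval follows the homogeneous-object transport-of-intensity
solution: the measured transmission is divided in Fourier space by
``1 + (lambda * PD * (delta/beta) / (4*pi)) * |k|**2`` (``|k|`` the angular
spatial frequency in rad/m) and the negative logarithm taken, yielding a
quantity proportional to projected thickness times attenuation.  A
``delta/beta`` ratio of 0 is the no-retrieval limit and returns
``-ln(T)`` exactly.

Reconstruction is classical filtered back projection (ramp or Hann-apodised
ramp, linear-interpolation backprojection) on equally spaced angles over
[0, 180); the 180-degree check projection is never used.  The evenly-spaced
projection-subset machinery for single-scan iterative downsampling studies
lives here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon as _sk_iradon

from .corrections import correct_scan, suppress_rings
from .forward import ProjectionSet

__all__ = [
    "RetrievalParams",
    "Tomogram",
    "paganin_filter",
    "fbp_reconstruct",
    "subset_projections",
    "reconstruct_scan",
]


@dataclass(frozen=True)
class RetrievalParams:
    """Physical settings of the Paganin filter.

    ``delta_beta_ratio = 0`` disables retrieval (pure absorption log).
    The effective pixel used for retrieval may legitimately differ in the
    fourth decimal from the geometric one; both are configuration values.
    """

    delta_beta_ratio: float
    pd_m: float
    wavelength_m: float
    pixel_m: float

    def __post_init__(self) -> None:
        if self.delta_beta_ratio < 0:
            raise ValueError("delta_beta_ratio must be >= 0")
        for name in ("pd_m", "wavelength_m", "pixel_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Tomogram:
    """Reconstructed slices with full provenance.

    ``slices`` has shape ``(n_slices, n_u, n_u)`` and holds linear
    attenuation-like values (1/m when the sinogram carried metre-path
    integrals and ``pixel_spacing_m`` was supplied to FBP).
    """

    slices: np.ndarray
    voxel_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim == 2:
            self.slices = self.slices[None]
        if self.slices.ndim != 3 or self.slices.shape[1] != self.slices.shape[2]:
            raise ValueError("slices must be (n_slices, n, n)")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("tomogram contains non-finite values")


def paganin_filter(transmission, params: RetrievalParams) -> np.ndarray:
    """Retrieve projected thickness-like data from transmission.

    Accepts a 1-D line or a 2-D image; the Fourier-domain denominator is
    ``1 + (lambda * PD * (delta/beta) / (4*pi)) * (kx**2 + ky**2)`` with
    angular frequencies derived from ``params.pixel_m``.  Input is
    edge-padded to twice its extent before the FFT.  Returns
    ``-ln(filtered transmission)``; the filter is a pure low-pass
    (denominator >= 1 everywhere) and the output is real.
    """
    t = np.asarray(transmission, dtype=float)
    if np.any(t <= 0):
        raise ValueError("transmission must be positive (floor it upstream)")
    if params.delta_beta_ratio == 0:
        return -np.log(t)
    coef = params.wavelength_m * params.pd_m * params.delta_beta_ratio / (4.0 * math.pi)
    squeeze = t.ndim == 1
    if squeeze:
        t = t[None, :]
    n_v, n_u = t.shape
    pad_u = n_u
    pad_v = n_v if n_v > 1 else 0
    tp = np.pad(t, ((pad_v // 2, pad_v - pad_v // 2),
                    (pad_u // 2, pad_u - pad_u // 2)), mode="edge")
    ky = 2.0 * math.pi * np.fft.fftfreq(tp.shape[0], d=params.pixel_m)
    kx = 2.0 * math.pi * np.fft.rfftfreq(tp.shape[1], d=params.pixel_m)
    denom = 1.0 + coef * (ky[:, None] ** 2 + kx[None, :] ** 2)
    filt = np.fft.irfft2(np.fft.rfft2(tp) / denom, s=tp.shape)
    filt = filt[pad_v // 2: pad_v // 2 + n_v, pad_u // 2: pad_u // 2 + n_u]
    out = -np.log(np.clip(filt, 1e-12, None))
    return out[0] if squeeze else out


def fbp_reconstruct(
    sinogram: np.ndarray,
    angles_deg: np.ndarray,
    filter_window: str = "ramp",
    pixel_spacing: float = 1.0,
) -> np.ndarray:
    """Filtered back projection of one sinogram.

    ``sinogram`` has shape ``(n_angles, n_u)``; ``angles_deg`` must be
    equally spaced over [0, 180).  ``pixel_spacing`` converts the ray
    integrals back to per-sample units: a sinogram of metre-path integrals
    with ``pixel_spacing`` = voxel size in metres reconstructs the
    underlying map in its native units (e.g. attenuation per metre).
    """
    sino = np.asarray(sinogram, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    if sino.ndim != 2:
        raise ValueError("sinogram must be 2-D (n_angles, n_u)")
    if angles.size < 2:
        raise ValueError("at least 2 angles are required")
    if sino.shape[0] != angles.size:
        raise ValueError("sinogram row count does not match angle count")
    steps = np.diff(angles)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
        raise ValueError("angles must be strictly increasing and equally spaced")
    if filter_window not in ("ramp", "hann"):
        raise ValueError("filter_window must be 'ramp' or 'hann'")
    n_u = sino.shape[1]
    rec = _sk_iradon(
        sino.T, theta=angles, filter_name=filter_window,
        interpolation="linear", circle=True, output_size=n_u,
    )
    return rec / pixel_spacing


def subset_projections(n_full: int, n_subset: int) -> np.ndarray:
    """Evenly spaced projection indices for a downsampled subset.

    Requires ``n_subset`` to divide ``n_full`` so the retained angles stay
    equally spaced over [0, 180); on failure the error names the nearest
    valid subset sizes.
    """
    if n_full < 1 or n_subset < 1:
        raise ValueError("counts must be >= 1")
    if n_full % n_subset != 0:
        divisors = [d for d in range(1, n_full + 1) if n_full % d == 0]
        below = max((d for d in divisors if d < n_subset), default=1)
        above = min((d for d in divisors if d > n_subset), default=n_full)
        raise ValueError(
            f"{n_subset} does not divide {n_full}; nearest valid sizes are "
            f"{below} and {above}"
        )
    stride = n_full // n_subset
    return np.arange(0, n_full, stride)


def reconstruct_scan(
    pset: ProjectionSet,
    params: RetrievalParams | None = None,
    n_subset: int | None = None,
    slice_rows=None,
    corrections: bool = True,
    suppress_rings_flag: bool = True,
    ring_window_px: int = 31,
    filter_window: str = "ramp",
    distortion="auto",
    precorrected: np.ndarray | None = None,
) -> Tomogram:
    """Full pipeline: corrections -> Paganin -> sinograms -> FBP.

    ``n_subset`` selects an evenly spaced projection subset (default: all);
    ``slice_rows`` selects detector rows (slices) to reconstruct (default:
    all).  ``precorrected`` lets sweep drivers reuse the transmission stack
    of a previous call on the same scan.  Provenance records projection
    count, propagation distance, delta/beta ratio, correction stages and
    filter window for downstream quality-curve labelling.
    """
    geom = pset.geometry
    n_full = geom.n_angles
    if corrections and precorrected is None:
        trans, report = correct_scan(pset, distortion=distortion)
        stages = list(report.stages)
    elif precorrected is not None:
        trans, report = precorrected, None
        stages = ["precorrected"]
    else:
        flat_mean = pset.flats.mean(axis=0)
        dark_mean = pset.darks.mean(axis=0)
        trans = np.clip(
            (pset.frames - dark_mean) / (flat_mean - dark_mean), 1e-6, None
        )
        report = None
        stages = ["flat_dark"]
    trans = trans[:n_full]  # the 180-degree check frame never reconstructs

    idx = subset_projections(n_full, n_subset) if n_subset else np.arange(n_full)
    angles = geom.angles_deg[idx]
    trans = trans[idx]

    ratio = params.delta_beta_ratio if params is not None else 0.0
    if params is not None and params.delta_beta_ratio > 0:
        retrieved = np.stack([paganin_filter(t, params) for t in trans])
    else:
        retrieved = -np.log(trans)

    n_v = retrieved.shape[1]
    rows = range(n_v) if slice_rows is None else list(np.atleast_1d(slice_rows))
    voxel_m = geom.det.effective_pixel_um * 1e-6
    slices = []
    for v in rows:
        sino = retrieved[:, v, :]
        if suppress_rings_flag:
            sino = suppress_rings(sino, ring_window_px)
        slices.append(fbp_reconstruct(sino, angles, filter_window, voxel_m))
    if suppress_rings_flag:
        stages.append("rings")

    provenance = {
        "n_projections": int(len(idx)),
        "n_full": int(n_full),
        "pd_mm": geom.propagation_distance_mm,
        "delta_beta": float(ratio),
        "corrections": stages,
        "filter_window": filter_window,
        "slice_rows": list(map(int, rows)),
        "zingers_removed": None if report is None else report.zingers_removed,
        "distortion_center_px": None if report is None else report.distortion_center_px,
    }
    return Tomogram(np.stack(slices), geom.det.effective_pixel_um, provenance)
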