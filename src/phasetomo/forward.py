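"""Parallel-beam scan simulator with inline phase contrast and artefacts.

The simulator follows the physical chain of a propagation-based micro-CT
measurement under the projection (thin-object) approximation at a single
energy:

1. :func:`project` — line integrals of delta and beta through the phantom
   at each rotation angle (the Radon transform, in metres of path).
2. :func:`transmit_and_propagate` — the exit wave
   ``psi0 = exp(-(2*pi/lambda)*B) * exp(-1j*(2*pi/lambda)*D)`` propagated to
   the detector with the 1-D angular-spectrum (Fresnel) kernel
   ``exp(-1j*pi*lambda*z*f**2)``; the recorded quantity is ``|psi|**2``,
   normalised so a ray through vacuum gives 1.
3. :func:`apply_detector` — scaling to counts against a flat-field profile,
   Poisson photon statistics, a dark offset, and full-well clipping.

On top of that, acquisition artefacts can be injected with ground-truth
provenance: zinger streaks from stray/cosmic rays (:func:`inject_zingers`),
radial lens distortion (:func:`apply_distortion`), and fixed-pattern
scintillator defects that become ring artefacts after reconstruction
(:func:`bake_ring_seeds`).  :func:`simulate_scan` composes the chain into a
:class:`ProjectionSet` with flats, darks and an optional 180-degree check
projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import radon as _sk_radon

from .planning import BeamSpec, DetectorSpec
from .phantom import Phantom

__all__ = [
    "ScanGeometry",
    "ProjectionSet",
    "DistortionModel",
    "ArtefactConfig",
    "project",
    "transmit_and_propagate",
    "apply_detector",
    "inject_zingers",
    "apply_distortion",
    "bake_ring_seeds",
    "simulate_scan",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Everything the forward model and the planners need about one scan."""

    beam: BeamSpec
    det: DetectorSpec
    propagation_distance_mm: float
    n_angles: int
    extra_check_projection: bool = False

    def __post_init__(self) -> None:
        if self.propagation_distance_mm < 0:
            raise ValueError("propagation_distance_mm must be >= 0")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")

    @property
    def angles_deg(self) -> np.ndarray:
        """Equally spaced angles over the half-open interval [0, 180)."""
        return np.linspace(0.0, 180.0, self.n_angles, endpoint=False)

    @property
    def frame_angles_deg(self) -> np.ndarray:
        """Angles actually acquired, including the 180-degree check frame."""
        a = self.angles_deg
        return np.concatenate([a, [180.0]]) if self.extra_check_projection else a


@dataclass(frozen=True)
class DistortionModel:
    """Radial lens distortion ``(x_c, y_c, k1, k2)``.

    The distorted frame samples the ideal frame at a radius scaled by
    ``s(r) = 1 + k1*r**2 + k2*r**4`` (``r`` in pixels from the centre), so a
    feature at undistorted radius ``r_u`` appears at the distorted radius
    ``r_d`` solving ``r_u = r_d * s(r_d)``; displacement grows towards the
    frame corners.  ``k1 = k2 = 0`` is the identity.
    """

    center_xy: tuple[float, float]
    k1: float = 0.0
    k2: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.k1 == 0.0 and self.k2 == 0.0

    def scale(self, r: np.ndarray) -> np.ndarray:
        r2 = r * r
        return 1.0 + self.k1 * r2 + self.k2 * r2 * r2


@dataclass
class ProjectionSet:
    """A simulated (or loaded) scan: raw frames plus flats, darks, geometry.

    ``frames`` has shape ``(n_frames, n_v, n_u)``; ``provenance`` carries
    the injected-artefact ground truth (zinger pixel coordinates, the
    distortion model, the ring-defect pattern seed) and the master seed.
    """

    frames: np.ndarray
    flats: np.ndarray
    darks: np.ndarray
    geometry: ScanGeometry
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.flats = np.asarray(self.flats)
        self.darks = np.asarray(self.darks)
        if self.frames.ndim != 3 or self.flats.ndim != 3 or self.darks.ndim != 3:
            raise ValueError("frames, flats and darks must be 3-D stacks")
        if self.flats.shape[1:] != self.frames.shape[1:] or \
                self.darks.shape[1:] != self.frames.shape[1:]:
            raise ValueError("flats/darks frame shape differs from projections")
        expected = self.geometry.n_angles + int(self.geometry.extra_check_projection)
        if self.frames.shape[0] != expected:
            raise ValueError(
                f"frame count {self.frames.shape[0]} does not match geometry "
                f"({expected} = n_angles"
                f"{' + check frame' if self.geometry.extra_check_projection else ''})"
            )
        if np.any(self.frames < 0) or np.any(self.flats < 0) or np.any(self.darks < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ArtefactConfig:
    """Switchboard for injected artefacts and detector statistics."""

    photon_noise: bool = True
    dark_level: float = 100.0
    full_well_counts: int = 2 ** 16
    exposure_fraction: float = 0.85
    n_flats: int = 20
    n_darks: int = 20
    flat_gradient: float = 0.03          # smooth beam-profile variation
    zinger_rate: float = 0.0             # streaks per frame
    zinger_amplitude: tuple[float, float] = (5000.0, 30000.0)
    zinger_length_px: tuple[int, int] = (1, 4)
    ring_defect_density: float = 0.0     # fraction of defective pixels
    ring_defect_contrast: float = 0.05   # rms gain error of a defect
    distortion: DistortionModel | None = None


# ---------------------------------------------------------------------------
# core physics

def project(phantom: Phantom, angles_deg: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Per-angle parallel-ray line integrals of delta and beta.

    Returns ``(D, B)`` of shape ``(n_slices, n_angles, n_u)`` in metres of
    path-integrated index (Radon transform of each slice, scaled by the
    voxel size).  The rotation axis is the grid centre column at index
    ``n_u // 2`` (scikit-image's convention, shared by the back projector);
    sampling uses linear interpolation.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size == 0:
        raise ValueError("angle list is empty")
    voxel_m = phantom.voxel_um * 1e-6
    d_out = []
    b_out = []
    for z in range(phantom.n_slices):
        d_out.append(_sk_radon(phantom.delta[z], theta=angles).T * voxel_m)
        b_out.append(_sk_radon(phantom.beta[z], theta=angles).T * voxel_m)
    return np.stack(d_out), np.stack(b_out)


def transmit_and_propagate(
    d_line: np.ndarray,
    b_line: np.ndarray,
    beam: BeamSpec,
    pd_mm: float,
    pixel_um: float,
) -> np.ndarray:
    """Detector-plane intensity for one projection (flat-field = 1).

    ``d_line``/``b_line`` are path integrals of delta and beta in metres,
    sampled on the detector grid (any leading axes, propagation along the
    last axis).  At ``pd_mm = 0`` this reduces exactly to Beer-Lambert
    ``exp(-4*pi*B/lambda)``; at positive distances the 1-D angular-spectrum
    kernel adds Fresnel edge fringes.  The line is edge-padded to twice its
    length (next power of two) before the FFT to suppress wrap-around.
    """
    if pd_mm < 0:
        raise ValueError("propagation distance must be >= 0")
    d_line = np.asarray(d_line, dtype=float)
    b_line = np.asarray(b_line, dtype=float)
    lam = beam.wavelength_m
    k = 2.0 * math.pi / lam
    if pd_mm == 0:
        return np.exp(-2.0 * k * b_line)
    psi = np.exp(-k * b_line) * np.exp(-1j * k * d_line)
    n = psi.shape[-1]
    n_pad = 1 << (2 * n - 1).bit_length()
    pad = n_pad - n
    psi_p = np.pad(psi, [(0, 0)] * (psi.ndim - 1) + [(pad // 2, pad - pad // 2)],
                   mode="edge")
    f = np.fft.fftfreq(n_pad, d=pixel_um * 1e-6)
    kernel = np.exp(-1j * math.pi * lam * (pd_mm * 1e-3) * f ** 2)
    psi_z = np.fft.ifft(np.fft.fft(psi_p, axis=-1) * kernel, axis=-1)
    out = np.abs(psi_z) ** 2
    sl = [slice(None)] * (out.ndim - 1) + [slice(pad // 2, pad // 2 + n)]
    return out[tuple(sl)]


def apply_detector(
    intensity: np.ndarray,
    flat_profile: np.ndarray | float = 1.0,
    dark_level: float = 100.0,
    full_well_counts: int = 2 ** 16,
    exposure_fraction: float = 0.85,
    rng: np.random.Generator | int | None = None,
    photon_noise: bool = True,
) -> np.ndarray:
    """Convert normalised intensity to detector counts.

    Expected counts are ``dark_level + intensity * flat_profile *
    full_well_counts * exposure_fraction``; Poisson statistics are applied
    per pixel and the result clipped at the full well (``2**16 - 1`` by
    default).  With the default 0.85 exposure fraction a flat frame sits at
    ~85% saturation, the usual operating point of an sCMOS detector.
    """
    if not 0 < exposure_fraction <= 1:
        raise ValueError("exposure_fraction must lie in (0, 1]")
    expected = dark_level + np.asarray(intensity) * np.asarray(flat_profile) \
        * full_well_counts * exposure_fraction
    if photon_noise:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        frame = gen.poisson(expected).astype(float)
    else:
        frame = expected.astype(float)
    return np.clip(frame, 0, full_well_counts - 1)


# ---------------------------------------------------------------------------
# artefact injection

def inject_zingers(
    frame: np.ndarray,
    rate_per_frame: int,
    amplitude_range: tuple[float, float] = (5000.0, 30000.0),
    streak_length_px: tuple[int, int] = (1, 4),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, list[list[tuple[int, int]]]]:
    """Add short bright streaks at random positions; return their pixels.

    Zingers are stray-X-ray/cosmic-ray hits: 1-pixel-wide linear streaks of
    1 to a few pixels whose amplitude is drawn uniformly from
    ``amplitude_range`` and *added* to the frame.  The returned coordinate
    list (one ``[(row, col), ...]`` entry per streak) is the injection
    ground truth used to score removal.
    """
    if rate_per_frame < 0:
        raise ValueError("rate_per_frame must be >= 0")
    frame = np.array(frame, dtype=float, copy=True)
    coords: list[list[tuple[int, int]]] = []
    if rate_per_frame == 0:
        return frame, coords
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_v, n_u = frame.shape
    for _ in range(int(rate_per_frame)):
        y0 = gen.integers(0, n_v)
        x0 = gen.integers(0, n_u)
        length = int(gen.integers(streak_length_px[0], streak_length_px[1] + 1))
        ang = gen.uniform(0, math.pi)
        amp = gen.uniform(*amplitude_range)
        pix = []
        for t in range(length):
            y = int(round(y0 + t * math.sin(ang)))
            x = int(round(x0 + t * math.cos(ang)))
            if 0 <= y < n_v and 0 <= x < n_u and (y, x) not in pix:
                pix.append((y, x))
        for (y, x) in pix:
            frame[y, x] += amp
        coords.append(pix)
    return frame, coords


def apply_distortion(frame: np.ndarray, model: DistortionModel) -> np.ndarray:
    """Resample a frame under the radial distortion model.

    Each output pixel at radius ``r`` from the distortion centre samples
    the input at radius ``r * (1 + k1*r**2 + k2*r**4)`` (linear
    interpolation, edge values extended), so displacement is zero at the
    centre and largest at the corners.  The identity model returns the
    frame unchanged.
    """
    frame = np.asarray(frame, dtype=float)
    if model.is_identity:
        return frame.copy()
    n_v, n_u = frame.shape
    xc, yc = model.center_xy
    y, x = np.mgrid[0:n_v, 0:n_u].astype(float)
    dy, dx = y - yc, x - xc
    s = model.scale(np.hypot(dy, dx))
    return ndimage.map_coordinates(
        frame, [yc + dy * s, xc + dx * s], order=1, mode="nearest"
    )


def bake_ring_seeds(
    flat_profile: np.ndarray,
    defect_density: float,
    defect_contrast: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Multiply fixed-pattern pixel gain errors into a flat profile.

    A random fraction ``defect_density`` of pixels gets a Gaussian gain
    error of rms ``defect_contrast``, emulating scintillator defects whose
    response drifts between the flat-field acquisition and the scan.
    Because the pattern is identical in every projection it reconstructs
    into concentric rings.
    """
    if not 0.0 <= defect_density <= 1.0:
        raise ValueError("defect_density must lie in [0, 1]")
    profile = np.array(flat_profile, dtype=float, copy=True)
    if defect_density == 0.0:
        return profile
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mask = gen.uniform(size=profile.shape) < defect_density
    gains = 1.0 + defect_contrast * gen.standard_normal(profile.shape)
    profile[mask] *= np.clip(gains[mask], 0.2, 5.0)
    return profile


# ---------------------------------------------------------------------------
# full scan

def _flat_profile(n_v: int, n_u: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth beam/scintillator illumination profile around 1."""
    if amplitude == 0:
        return np.ones((n_v, n_u))
    u = np.linspace(-1, 1, n_u)
    v = np.linspace(-1, 1, max(n_v, 2))[:n_v, None] if n_v > 1 else np.zeros((1, 1))
    phase = rng.uniform(0, 2 * math.pi, size=3)
    prof = (1.0
            + amplitude * np.cos(math.pi * u / 2 + phase[0])[None, :] * 0.7
            + amplitude * 0.3 * np.cos(math.pi * v + phase[1]))
    return np.broadcast_to(prof, (n_v, n_u)).copy()


def simulate_scan(
    phantom: Phantom,
    geometry: ScanGeometry,
    artefacts: ArtefactConfig | None = None,
    seed: int = 0,
) -> ProjectionSet:
    """Simulate a complete scan of a phantom.

    Runs project -> transmit_and_propagate -> (distortion) ->
    apply_detector -> (zingers) for every angle of ``geometry`` (plus the
    180-degree check frame if requested), and emits matching flat and dark
    stacks.  Per-frame random streams are spawned deterministically from
    ``seed``, so any subset of frames is reproducible independently and the
    whole ProjectionSet is byte-identical across calls.
    """
    art = artefacts or ArtefactConfig()
    if phantom.grid_px != geometry.det.n_u:
        raise ValueError(
            f"phantom grid ({phantom.grid_px}) and detector width "
            f"({geometry.det.n_u}) differ"
        )
    angles = geometry.frame_angles_deg
    d_all, b_all = project(phantom, angles)  # (n_slices, n_frames, n_u)
    n_slices = phantom.n_slices
    n_u = geometry.det.n_u
    n_frames = len(angles)

    ss = np.random.SeedSequence(seed)
    rng_setup, rng_rings = [np.random.default_rng(s) for s in ss.spawn(2)]
    frame_seeds = ss.spawn(n_frames + art.n_flats + art.n_darks)

    flat_profile = _flat_profile(n_slices, n_u, art.flat_gradient, rng_setup)
    ring_gain = bake_ring_seeds(
        np.ones((n_slices, n_u)), art.ring_defect_density,
        art.ring_defect_contrast, rng_rings,
    )

    frames = np.empty((n_frames, n_slices, n_u))
    zinger_truth: dict[int, list] = {}
    for i in range(n_frames):
        rng_i = np.random.default_rng(frame_seeds[i])
        inten = transmit_and_propagate(
            d_all[:, i, :], b_all[:, i, :], geometry.beam,
            geometry.propagation_distance_mm, geometry.det.effective_pixel_um,
        )
        inten = inten * ring_gain
        if art.distortion is not None:
            inten = apply_distortion(inten, art.distortion)
        frame = apply_detector(
            inten, flat_profile, art.dark_level, art.full_well_counts,
            art.exposure_fraction, rng_i, art.photon_noise,
        )
        if art.zinger_rate > 0:
            frame, coords = inject_zingers(
                frame, int(art.zinger_rate), art.zinger_amplitude,
                art.zinger_length_px, rng_i,
            )
            zinger_truth[i] = coords
        frames[i] = frame

    flats = np.empty((art.n_flats, n_slices, n_u))
    for j in range(art.n_flats):
        rng_j = np.random.default_rng(frame_seeds[n_frames + j])
        flats[j] = apply_detector(
            np.ones((n_slices, n_u)), flat_profile, art.dark_level,
            art.full_well_counts, art.exposure_fraction, rng_j, art.photon_noise,
        )
    darks = np.empty((art.n_darks, n_slices, n_u))
    for j in range(art.n_darks):
        rng_j = np.random.default_rng(frame_seeds[n_frames + art.n_flats + j])
        if art.photon_noise:
            darks[j] = rng_j.poisson(art.dark_level, size=(n_slices, n_u)).astype(float)
        else:
            darks[j] = np.full((n_slices, n_u), art.dark_level, dtype=float)

    provenance = {
        "seed": int(seed),
        "pd_mm": geometry.propagation_distance_mm,
        "energy_kev": geometry.beam.energy_kev,
        "pixel_um": geometry.det.effective_pixel_um,
        "n_angles": geometry.n_angles,
        "extra_check_projection": geometry.extra_check_projection,
        "zingers": {str(k): v for k, v in zinger_truth.items()},
        "distortion": None if art.distortion is None else {
            "center_xy": list(art.distortion.center_xy),
            "k1": art.distortion.k1, "k2": art.distortion.k2,
        },
        "ring_defect_density": art.ring_defect_density,
        "ring_defect_contrast": art.ring_defect_contrast,
        "artefacts": {k: v for k, v in asdict(art).items() if k != "distortion"},
        "phantom_params": dict(phantom.params),
    }
    return ProjectionSet(frames, flats, darks, geometry, provenance)
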