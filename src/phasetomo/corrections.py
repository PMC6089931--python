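"""Pre-reconstruction artefact-correction chain.

The chain mirrors standard synchrotron practice and is applied in a fixed
order: zinger removal on every raw frame, dark/flat-field normalisation to
transmission, radial-distortion correction, and ring suppression on the
assembled sinograms.  :func:`correct_scan` runs the frame-level stages and
returns a :class:`CorrectionReport` audit trail; ring suppression operates
per sinogram and is invoked by the reconstruction pipeline.

The distortion *coefficients* are treated as known (in practice they come
from a grid-target calibration; in simulation from injection provenance) —
only the distortion *centre* is estimated, by screening candidate centres
for the one that minimises the difference between the first projection and
the horizontally flipped 180-degree check projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .forward import DistortionModel, ProjectionSet

__all__ = [
    "CorrectionReport",
    "DegenerateInputError",
    "remove_zingers",
    "flat_dark_correct",
    "estimate_distortion_center",
    "undistort",
    "suppress_rings",
    "correct_scan",
]

#: Transmission floor keeping downstream logarithms finite.
TRANSMISSION_FLOOR = 1e-6

#: The only valid stage order; recorded in every report.
CHAIN_ORDER = ("zingers", "flat_dark", "undistort", "rings")


class DegenerateInputError(ValueError):
    """Raised when an estimator is handed featureless (constant) input."""


@dataclass
class CorrectionReport:
    """Audit trail of what the correction chain did to a scan."""

    zingers_removed: list[int] = field(default_factory=list)
    distortion_center_px: tuple[float, float] | None = None
    residual_mismatch: float | None = None
    rings_suppressed: bool = False
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.zingers_removed):
            raise ValueError("zinger counts must be >= 0")


def remove_zingers(
    frame: np.ndarray, neighbourhood_px: int = 3, threshold_sigma: float = 8.0
) -> tuple[np.ndarray, int]:
    """Replace outlier-bright pixels by their local median.

    A pixel is a zinger when it exceeds its ``neighbourhood_px`` median by
    more than ``threshold_sigma`` times a robust scale (1.4826 x the median
    absolute deviation of the median residuals over the frame).  Only
    positive excursions are touched — zingers are bright by construction.
    """
    if neighbourhood_px < 3 or neighbourhood_px % 2 == 0:
        raise ValueError("neighbourhood_px must be an odd integer >= 3")
    frame = np.asarray(frame, dtype=float)
    med = ndimage.median_filter(frame, size=neighbourhood_px, mode="reflect")
    resid = frame - med
    scale = 1.4826 * np.median(np.abs(resid))
    scale = max(scale, 1e-12)
    mask = resid > threshold_sigma * scale
    out = np.where(mask, med, frame)
    return out, int(mask.sum())


def flat_dark_correct(
    frame: np.ndarray,
    flat_mean: np.ndarray,
    dark_mean: np.ndarray,
    floor: float = TRANSMISSION_FLOOR,
) -> np.ndarray:
    """Normalise a raw frame to transmission: ``(f - d) / (flat - d)``.

    The result is clipped below at ``floor`` so logarithms stay finite.
    Raises if the averaged flat does not exceed the averaged dark
    everywhere (a broken calibration), naming the offending pixel count.
    """
    frame = np.asarray(frame, dtype=float)
    flat_mean = np.asarray(flat_mean, dtype=float)
    dark_mean = np.asarray(dark_mean, dtype=float)
    denom = flat_mean - dark_mean
    bad = int(np.sum(denom <= 0))
    if bad:
        raise ValueError(f"flat <= dark at {bad} pixel(s); cannot normalise")
    return np.clip((frame - dark_mean) / denom, floor, None)


def undistort(
    frame: np.ndarray,
    model: DistortionModel,
    tol_px: float = 1e-3,
    max_iter: int = 100,
) -> np.ndarray:
    """Invert :func:`phasetomo.forward.apply_distortion`.

    For each undistorted output pixel at radius ``r_u`` the distorted
    radius ``r_d`` solving ``r_d * (1 + k1*r_d**2 + k2*r_d**4) = r_u`` is
    found by fixed-point iteration (``r_d <- r_u / s(r_d)``) to ``tol_px``,
    then the distorted frame is sampled there with linear interpolation.
    """
    frame = np.asarray(frame, dtype=float)
    if model.is_identity:
        return frame.copy()
    n_v, n_u = frame.shape
    xc, yc = model.center_xy
    y, x = np.mgrid[0:n_v, 0:n_u].astype(float)
    dy, dx = y - yc, x - xc
    r_u = np.hypot(dy, dx)
    r_d = r_u.copy()
    for _ in range(max_iter):
        r_new = r_u / model.scale(r_d)
        step = np.max(np.abs(r_new - r_d))
        r_d = r_new
        if step < tol_px:
            break
    else:
        raise RuntimeError(
            f"distortion inversion did not converge (last step {step:.3g} px); "
            "coefficients too extreme"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(r_u > 0, r_d / np.maximum(r_u, 1e-12), 1.0)
    return ndimage.map_coordinates(
        frame, [yc + dy * ratio, xc + dx * ratio], order=1, mode="nearest"
    )


def _align_and_score(a: np.ndarray, b: np.ndarray, smooth_px: float = 2.0) -> float:
    """Mean squared difference of ``b`` against ``a`` after sub-pixel
    cross-correlation alignment (borders trimmed).

    Both frames are lightly Gaussian-smoothed first: photon noise is
    uncorrelated between the two frames and would otherwise put a flat
    floor under the score, hiding the residual-distortion mismatch the
    centre search looks for.
    """
    from skimage.registration import phase_cross_correlation

    if smooth_px > 0:
        a = ndimage.gaussian_filter(a, smooth_px)
        b = ndimage.gaussian_filter(b, smooth_px)
    shift, _, _ = phase_cross_correlation(a, b, upsample_factor=10,
                                          normalization=None)
    b_shift = ndimage.shift(b, shift, order=1, mode="nearest")
    m_v = max(int(abs(shift[0])) + 1, 2)
    m_u = max(int(abs(shift[1])) + 1, 2)
    core_v = slice(m_v, a.shape[0] - m_v) if a.shape[0] > 2 * m_v + 2 else slice(None)
    core_u = slice(m_u, a.shape[1] - m_u)
    diff = a[core_v, core_u] - b_shift[core_v, core_u]
    return float(np.mean(diff ** 2))


def estimate_distortion_center(
    first_proj: np.ndarray,
    last_proj_180: np.ndarray,
    k1: float = 0.0,
    k2: float = 0.0,
    search_radius_px: float = 30.0,
    coarse_step_px: float = 5.0,
) -> tuple[tuple[float, float], float]:
    """Estimate the radial-distortion centre from a 0/180-degree frame pair.

    In parallel-beam geometry the 180-degree check projection is the mirror
    image of the 0-degree projection, so after undistorting both with the
    known coefficients the flipped pair should match; the centre is found
    by coarse-to-fine grid search minimising their aligned mean squared
    difference.  Returns ``((x_c, y_c), residual_mismatch)``.

    With ``k1 = k2 = 0`` every candidate scores identically and the frame
    centre is returned (the tie-break rule; ties during search also break
    towards the frame centre).
    """
    first = np.asarray(first_proj, dtype=float)
    last = np.asarray(last_proj_180, dtype=float)
    if first.shape != last.shape:
        raise ValueError("frame shapes differ")
    if np.ptp(first) == 0 or np.ptp(last) == 0:
        raise DegenerateInputError("featureless (constant) frame")
    n_v, n_u = first.shape
    c0 = ((n_u - 1) / 2.0, (n_v - 1) / 2.0)
    if k1 == 0.0 and k2 == 0.0:
        return c0, _align_and_score(first, last[:, ::-1])

    def score(cx: float, cy: float) -> float:
        m = DistortionModel((cx, cy), k1, k2)
        u1 = undistort(first, m)
        u2 = undistort(last, m)[:, ::-1]
        # infinitesimal centre-distance penalty implements the tie-break
        return _align_and_score(u1, u2) + 1e-12 * ((cx - c0[0]) ** 2 + (cy - c0[1]) ** 2)

    def grid_search(cx0, cy0, radius, step):
        offs = np.arange(-radius, radius + step / 2, step)
        best = (float("inf"), cx0, cy0)
        for oy in offs:
            for ox in offs:
                s = score(cx0 + ox, cy0 + oy)
                if s < best[0]:
                    best = (s, cx0 + ox, cy0 + oy)
        return best

    best = grid_search(c0[0], c0[1], search_radius_px, coarse_step_px)
    step = coarse_step_px
    while step > 0.5:
        fine = step / 4.0
        best = grid_search(best[1], best[2], step, fine)
        step = fine
    return (best[1], best[2]), best[0]


def suppress_rings(sinogram: np.ndarray, smoothing_window_px: int = 31) -> np.ndarray:
    """Remove angle-invariant detector-column bias from a sinogram.

    Each detector column's mean over angles estimates the fixed-pattern
    gain bias; the sharp part of that profile (raw minus a
    ``smoothing_window_px`` moving average) is subtracted from every row,
    leaving genuine wide structures untouched and preserving the global
    mean.  Rows are angles, columns detector positions.
    """
    sino = np.asarray(sinogram, dtype=float)
    if sino.ndim != 2:
        raise ValueError("sinogram must be 2-D (n_angles, n_u)")
    n_u = sino.shape[1]
    if smoothing_window_px < 1 or smoothing_window_px % 2 == 0:
        raise ValueError("smoothing_window_px must be an odd integer >= 1")
    if smoothing_window_px >= n_u:
        raise ValueError(
            f"smoothing window ({smoothing_window_px}) must be smaller than "
            f"the detector width ({n_u})"
        )
    col = sino.mean(axis=0)
    smooth = ndimage.uniform_filter1d(col, size=smoothing_window_px, mode="nearest")
    bias = col - smooth
    out = sino - bias[None, :]
    out += sino.mean() - out.mean()
    return out


def correct_scan(
    pset: ProjectionSet,
    remove_zingers_flag: bool = True,
    zinger_sigma: float = 8.0,
    distortion: DistortionModel | None | str = "auto",
    estimate_center: bool = True,
) -> tuple[np.ndarray, CorrectionReport]:
    """Frame-level correction chain: zingers -> flat/dark -> undistort.

    Returns transmission frames of shape ``(n_frames, n_v, n_u)`` (the
    180-degree check frame, if present, is corrected too but flagged in the
    geometry) and a :class:`CorrectionReport`.  ``distortion="auto"`` takes
    the coefficients from the injection provenance and, when a check frame
    exists and ``estimate_center`` is set, re-estimates the centre from the
    0/180-degree pair; ``None`` disables the stage.
    """
    stages: list[str] = []
    frames = pset.frames.astype(float)
    flat_mean = pset.flats.mean(axis=0)
    dark_mean = pset.darks.mean(axis=0)

    counts: list[int] = []
    if remove_zingers_flag:
        cleaned = np.empty_like(frames)
        for i in range(frames.shape[0]):
            cleaned[i], n = remove_zingers(frames[i], threshold_sigma=zinger_sigma)
            counts.append(n)
        frames = cleaned
        stages.append("zingers")

    trans = np.empty_like(frames)
    for i in range(frames.shape[0]):
        trans[i] = flat_dark_correct(frames[i], flat_mean, dark_mean)
    stages.append("flat_dark")

    model: DistortionModel | None
    if distortion == "auto":
        info = pset.provenance.get("distortion")
        model = None if info is None else DistortionModel(
            tuple(info["center_xy"]), info["k1"], info["k2"]
        )
    else:
        model = distortion  # type: ignore[assignment]

    center = None
    mismatch = None
    if model is not None and not model.is_identity:
        if estimate_center and pset.geometry.extra_check_projection \
                and trans.shape[1] >= 8:
            center, mismatch = estimate_distortion_center(
                trans[0], trans[-1], model.k1, model.k2
            )
            model = DistortionModel(center, model.k1, model.k2)
        else:
            center = model.center_xy
        for i in range(trans.shape[0]):
            trans[i] = undistort(trans[i], model)
        stages.append("undistort")

    assert tuple(stages) == tuple(s for s in CHAIN_ORDER if s in stages), \
        "correction stages ran out of order"
    report = CorrectionReport(
        zingers_removed=counts,
        distortion_center_px=center,
        residual_mismatch=mismatch,
        rings_suppressed=False,
        stages=tuple(stages),
    )
    return trans, report
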