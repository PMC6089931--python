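"""Image-quality metrics and acquisition-parameter optimisation studies.

Two scalar metrics drive every optimisation in this package:

* :func:`psnr` — peak signal-to-noise ratio in dB between a reference
  ("true") reconstruction and a degraded one, defined as
  ``10*log10(max(t)**2 / sum((t - n)**2))``.  Note the denominator is the
  *summed* squared error, not the mean — this reproduces the convention the
  optimisation procedure was defined with; the conventional MSE-normalised
  form is available behind ``normalised=True`` but is never the default.
* :func:`rms_contrast` — the sample standard deviation (n-1 denominator) of
  pixel values over a region of interest of an individually min-max
  normalised slice.

On top of these sit the studies: single-scan iterative downsampling over
evenly spaced projection subsets (:func:`downsampling_study`), the
propagation-distance screen (:func:`sweep_propagation_distance`), the
Paganin delta/beta screen (:func:`sweep_delta_beta`), histogram peak
separation for threshold selection (:func:`histogram_peaks`) and plain
grey-level threshold segmentation (:func:`threshold_segment`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .forward import ArtefactConfig, ProjectionSet, ScanGeometry, simulate_scan
from .phantom import Phantom
from .recon import RetrievalParams, reconstruct_scan

__all__ = [
    "ROI",
    "QualityCurve",
    "HistogramPeaks",
    "psnr",
    "rms_contrast",
    "normalize_slice",
    "downsampling_study",
    "saturation_fraction",
    "histogram_peaks",
    "sweep_delta_beta",
    "sweep_propagation_distance",
    "threshold_segment",
]


@dataclass(frozen=True)
class ROI:
    """Rectangular pixel bounds on a slice (0-based, half-open)."""

    x0: int
    x1: int
    y0: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("ROI bounds must be non-empty half-open ranges")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI bounds must be non-negative")
        if (self.x1 - self.x0) * (self.y1 - self.y0) < 2:
            raise ValueError("ROI must contain at least 2 pixels")

    @property
    def n_x(self) -> int:
        return self.x1 - self.x0

    @property
    def n_y(self) -> int:
        return self.y1 - self.y0

    def extract(self, image: np.ndarray) -> np.ndarray:
        if self.x1 > image.shape[1] or self.y1 > image.shape[0]:
            raise ValueError("ROI exceeds image bounds")
        return image[self.y0:self.y1, self.x0:self.x1]

    @classmethod
    def centered(cls, shape: tuple[int, int], size: int) -> "ROI":
        """Square ROI of ``size`` pixels centred in an image of ``shape``."""
        cy, cx = shape[0] // 2, shape[1] // 2
        h = size // 2
        return cls(cx - h, cx - h + size, cy - h, cy - h + size)


@dataclass
class QualityCurve:
    """Metric values indexed by the swept acquisition parameter."""

    parameter_name: str
    parameter_values: np.ndarray
    rms_contrast: np.ndarray
    psnr_db: np.ndarray | None = None
    extras: dict = field(default_factory=dict)
    reference_id: str = ""

    def __post_init__(self) -> None:
        self.parameter_values = np.asarray(self.parameter_values, dtype=float)
        self.rms_contrast = np.asarray(self.rms_contrast, dtype=float)
        n = self.parameter_values.size
        if self.rms_contrast.size != n:
            raise ValueError("metric length differs from parameter length")
        if self.psnr_db is not None:
            self.psnr_db = np.asarray(self.psnr_db, dtype=float)
            if self.psnr_db.size != n:
                raise ValueError("metric length differs from parameter length")
        for k, v in self.extras.items():
            if np.asarray(v).size != n:
                raise ValueError(f"extra metric {k!r} length differs")

    def to_dataframe(self) -> pd.DataFrame:
        data = {self.parameter_name: self.parameter_values,
                "rms_contrast": self.rms_contrast}
        if self.psnr_db is not None:
            data["psnr_db"] = self.psnr_db
        for k, v in self.extras.items():
            data[k] = np.asarray(v)
        return pd.DataFrame(data)

    def plot(self, ax=None, logx: bool | None = None):
        """Plot every metric of the curve against the swept parameter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_dataframe().set_index(self.parameter_name)
        for col in df.columns:
            series = df[col] / np.nanmax(np.abs(df[col])) if df[col].abs().max() else df[col]
            ax.plot(df.index, series, marker="o", label=col)
        if logx if logx is not None else self.parameter_name == "delta_beta":
            ax.set_xscale("log")
        ax.set_xlabel(self.parameter_name)
        ax.set_ylabel("metric (scaled to max 1)")
        ax.legend()
        return ax


@dataclass(frozen=True)
class HistogramPeaks:
    """Two-mode histogram decomposition of a slice."""

    background_peak: float
    sample_peak: float
    cutoff: float
    unimodal: bool


# ---------------------------------------------------------------------------
# metrics

def psnr(t_image: np.ndarray, n_image: np.ndarray, normalised: bool = False) -> float:
    """Peak signal-to-noise ratio of ``n_image`` against reference ``t_image``.

    Default: ``10*log10(max(t)**2 / SSE)`` with the raw summed squared
    error.  ``normalised=True`` divides the SSE by the pixel count (the
    textbook MSE form).  Identical images return ``inf`` (the saturated
    sentinel).
    """
    t = np.asarray(t_image, dtype=float)
    n = np.asarray(n_image, dtype=float)
    if t.shape != n.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {n.shape}")
    sse = float(np.sum((t - n) ** 2))
    if sse == 0.0:
        return math.inf
    if normalised:
        sse /= t.size
    peak = float(np.max(t))
    return 10.0 * math.log10(peak * peak / sse)


def rms_contrast(roi_pixels: np.ndarray) -> float:
    """Sample standard deviation of pixel values over a region of interest.

    ``sqrt(sum((p - mean)**2) / (N - 1))`` — the RMS contrast of a region,
    computed with the n-1 denominator.
    """
    p = np.asarray(roi_pixels, dtype=float)
    if p.size < 2:
        raise ValueError("RMS contrast needs at least 2 pixels")
    return float(np.std(p, ddof=1))


def normalize_slice(image: np.ndarray) -> np.ndarray:
    """Min-max rescale a slice to [0, 1]; constant slices are an error."""
    a = np.asarray(image, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        raise ValueError("cannot normalise a constant slice")
    return (a - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# studies

def _roi_metrics(slice_img: np.ndarray, roi: ROI) -> float:
    """RMS contrast of the ROI crop of an individually normalised slice."""
    return rms_contrast(roi.extract(normalize_slice(slice_img)))


def downsampling_study(
    pset: ProjectionSet,
    subset_sizes,
    recon_params: RetrievalParams | None,
    roi: ROI,
    slice_row: int = 0,
    **recon_kw,
) -> QualityCurve:
    """Single-scan iterative downsampling study.

    Reconstructs the full-projection reference ``t(x, y)``, then each
    evenly spaced subset reconstruction ``n(x, y)`` on the same slice.
    PSNR is measured against the reference on the ROI crop of the raw
    slices; RMS contrast on the ROI crop of each individually normalised
    slice.  ``subset_sizes`` must each divide the full projection count.
    """
    sizes = sorted(set(int(s) for s in subset_sizes), reverse=True)
    trans_kw = dict(recon_kw)
    full = reconstruct_scan(pset, recon_params, n_subset=None,
                            slice_rows=slice_row, **trans_kw)
    t_slice = full.slices[0]
    t_roi = roi.extract(t_slice)

    psnr_vals = []
    rms_vals = []
    for s in sizes:
        tomo = reconstruct_scan(pset, recon_params, n_subset=s,
                                slice_rows=slice_row, **trans_kw)
        n_slice = tomo.slices[0]
        psnr_vals.append(psnr(t_roi, roi.extract(n_slice)))
        rms_vals.append(_roi_metrics(n_slice, roi))

    order = np.argsort(sizes)  # return ascending in parameter
    sizes_arr = np.asarray(sizes, dtype=float)[order]
    return QualityCurve(
        parameter_name="n_projections",
        parameter_values=sizes_arr,
        rms_contrast=np.asarray(rms_vals)[order],
        psnr_db=np.asarray(psnr_vals)[order],
        reference_id=f"full_{pset.geometry.n_angles}_projections",
    )


def saturation_fraction(curve: QualityCurve, at_value: float,
                        metric: str = "psnr_db") -> float:
    """Fraction of a curve's dynamic range reached at a parameter value.

    Baseline is the metric at the smallest parameter; the ceiling is the
    metric at the largest parameter with a finite value.  Returns
    ``(m(at) - baseline) / (ceiling - baseline)``.
    """
    if curve.parameter_values.size < 2:
        raise ValueError("curve needs at least 2 points")
    if metric == "psnr_db":
        vals = curve.psnr_db
    elif metric == "rms_contrast":
        vals = curve.rms_contrast
    else:
        vals = curve.extras.get(metric)
    if vals is None:
        raise ValueError(f"curve has no metric {metric!r}")
    order = np.argsort(curve.parameter_values)
    p = curve.parameter_values[order]
    v = np.asarray(vals)[order]
    matches = np.nonzero(np.isclose(p, at_value))[0]
    if matches.size == 0:
        raise ValueError(f"parameter value {at_value} not in curve")
    baseline = v[0]
    finite = np.isfinite(v)
    ceiling = v[finite][-1]
    return float((v[matches[0]] - baseline) / (ceiling - baseline))


def histogram_peaks(tomogram_slice: np.ndarray, n_bins: int = 256) -> HistogramPeaks:
    """Locate background and sample modes of a slice grey-level histogram.

    The histogram is smoothed with a moving average of window
    ``n_bins // 32`` before peak picking; the two most prominent local
    maxima are returned in ascending grey order (ties break towards the
    lower grey level) and the cutoff is the histogram minimum between
    them.  A histogram without two clear modes is flagged ``unimodal`` with
    NaN cutoff — no guess is made.
    """
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    a = np.asarray(tomogram_slice, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError("slice contains non-finite values")
    hist, edges = np.histogram(a, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    window = max(3, n_bins // 32)
    smoothed = ndimage.uniform_filter1d(hist.astype(float), size=window,
                                        mode="nearest")
    # a mode must rise above both a fraction of the tallest peak and the
    # Poisson counting noise of the histogram itself
    prominence = max(0.05 * smoothed.max(), 3.0 * math.sqrt(smoothed.max()))
    peaks, props = signal.find_peaks(smoothed, prominence=prominence)
    if peaks.size < 2:
        grey = centers[peaks[0]] if peaks.size else float("nan")
        return HistogramPeaks(grey, grey, float("nan"), True)
    # two most prominent, stable order => ties resolve to lower grey
    top2 = peaks[np.argsort(-props["prominences"], kind="stable")[:2]]
    lo_bin, hi_bin = sorted(map(int, top2))
    between = smoothed[lo_bin:hi_bin + 1]
    cutoff = centers[lo_bin + int(np.argmin(between))]
    return HistogramPeaks(float(centers[lo_bin]), float(centers[hi_bin]),
                          float(cutoff), False)


def sweep_delta_beta(
    pset: ProjectionSet,
    ratios,
    roi: ROI,
    base_params: RetrievalParams,
    n_subset: int | None = None,
    slice_row: int = 0,
    **recon_kw,
) -> QualityCurve:
    """RMS-contrast screen over Paganin delta/beta ratios on one scan."""
    ratios = [float(r) for r in ratios]
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be >= 0")
    rms_vals = []
    for r in ratios:
        params = replace(base_params, delta_beta_ratio=r)
        tomo = reconstruct_scan(pset, params, n_subset=n_subset,
                                slice_rows=slice_row, **recon_kw)
        rms_vals.append(_roi_metrics(tomo.slices[0], roi))
    return QualityCurve(
        parameter_name="delta_beta",
        parameter_values=np.asarray(ratios),
        rms_contrast=np.asarray(rms_vals),
        reference_id="delta_beta_sweep",
    )


def sweep_propagation_distance(
    phantom: Phantom,
    geometry_template: ScanGeometry,
    pd_list_mm=(20.0, 40.0, 80.0, 160.0, 320.0),
    roi: ROI | None = None,
    seed: int = 0,
    artefacts: ArtefactConfig | None = None,
    slice_row: int = 0,
) -> QualityCurve:
    """Propagation-distance screen on a simulated phantom.

    Simulates and reconstructs the same phantom (common seed, no Paganin
    filtering, so fringes stay visible) at each propagation distance and
    reports RMS contrast plus a fringe-overshoot score: the mean absolute
    excursion of reconstructed attenuation beyond the phantom's true
    material range, evaluated inside the reconstruction circle.  By
    default the screen is noise-free so both trends reflect the physics,
    not photon statistics.
    """
    pd_list = [float(p) for p in pd_list_mm]
    if any(p < 0 for p in pd_list):
        raise ValueError("propagation distances must be >= 0")
    art = artefacts or ArtefactConfig(photon_noise=False, flat_gradient=0.0)
    energy = geometry_template.beam.energy_kev
    mu_true = phantom.mu_map(energy)[slice_row if phantom.n_slices > 1 else 0]
    mu_lo, mu_hi = float(mu_true.min()), float(mu_true.max())
    g = phantom.grid_px
    yy, xx = np.mgrid[0:g, 0:g]
    c = (g - 1) / 2.0
    in_circle = np.hypot(yy - c, xx - c) < (g / 2.0 - 2)
    roi = roi or ROI.centered((g, g), int(0.55 * g))

    rms_vals, overshoot_vals = [], []
    for pd_mm in pd_list:
        geom = replace(geometry_template, propagation_distance_mm=pd_mm)
        pset = simulate_scan(phantom, geom, art, seed=seed)
        tomo = reconstruct_scan(pset, params=None, slice_rows=slice_row,
                                suppress_rings_flag=False)
        sl = tomo.slices[0]
        # slices of this sweep share physical units (1/m), so contrast is
        # compared on the raw ROI; min-max normalisation would let the
        # growing fringe extremes mask the very contrast gain being measured
        rms_vals.append(rms_contrast(roi.extract(sl)))
        over = np.clip(sl - mu_hi, 0, None) + np.clip(mu_lo - sl, 0, None)
        overshoot_vals.append(float(np.mean(over[in_circle])))
    return QualityCurve(
        parameter_name="PD_mm",
        parameter_values=np.asarray(pd_list),
        rms_contrast=np.asarray(rms_vals),
        extras={"edge_overshoot": np.asarray(overshoot_vals)},
        reference_id="pd_sweep",
    )


def threshold_segment(
    tomogram_slice: np.ndarray,
    mask: np.ndarray,
    cutoff: float,
    polarity: str = "darker",
    voxel_um: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Grey-level threshold segmentation within a mask.

    Returns the binary map of mask pixels on the chosen side of ``cutoff``
    (``darker``: value < cutoff; ``brighter``: value > cutoff) and the
    segmented area in square micrometres.
    """
    sl = np.asarray(tomogram_slice, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if m.shape != sl.shape:
        raise ValueError("mask shape differs from slice shape")
    if not m.any():
        raise ValueError("mask is empty")
    if polarity == "darker":
        binary = m & (sl < cutoff)
    elif polarity == "brighter":
        binary = m & (sl > cutoff)
    else:
        raise ValueError("polarity must be 'darker' or 'brighter'")
    area_um2 = float(binary.sum()) * voxel_um * voxel_um
    return binary, area_um2
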