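"""File formats, run configuration and the end-to-end pipeline driver.

Projection sets live either in a single HDF5 file with a minimal
NXtomo-inspired layout::

    /entry/data    (n_frames, n_v, n_u)  raw counts
    /entry/flats   (n_flats,  n_v, n_u)
    /entry/darks   (n_darks,  n_v, n_u)
    /entry/angles  (n_frames,)           degrees
    /entry attrs: provenance (JSON), energy_kev, pd_mm, pixel_um,
                  extra_check_projection

or in a directory of zero-padded numbered TIFFs (``proj_00000.tif``,
``flat_000.tif``, ``dark_000.tif``) with one ``metadata.json`` sidecar.
Both dialects load to identical in-memory :class:`ProjectionSet` objects
and loading enforces the shape/count invariants.

Tomograms are written as TIFF stacks, either float32 (lossless) or uint16
with the quantisation (min, max) recorded in a JSON sidecar alongside the
provenance.

:class:`RunConfig` (a flat YAML mapping) fully determines a pipeline run:
every random stage's seed is explicit, so identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .forward import (ArtefactConfig, DistortionModel, ProjectionSet,
                      ScanGeometry, simulate_scan)
from .phantom import make_cord_phantom, make_wire_phantom
from .planning import BeamSpec, DetectorSpec, kev_to_wavelength
from .quality import ROI, downsampling_study
from .recon import RetrievalParams, Tomogram, reconstruct_scan

__all__ = [
    "FormatError",
    "RunConfig",
    "write_projection_set",
    "read_projection_set",
    "write_tomogram",
    "read_tomogram",
    "run_pipeline",
]


class FormatError(ValueError):
    """A file violates the on-disk layout contract."""


def _geometry_from_meta(meta: dict, n_v: int, n_u: int) -> ScanGeometry:
    return ScanGeometry(
        beam=BeamSpec(float(meta["energy_kev"])),
        det=DetectorSpec(int(n_u), int(n_v), float(meta["pixel_um"])),
        propagation_distance_mm=float(meta["pd_mm"]),
        n_angles=int(meta["n_angles"]),
        extra_check_projection=bool(meta["extra_check_projection"]),
    )


def write_projection_set(pset: ProjectionSet, path) -> None:
    """Write a projection set to HDF5 (suffix .h5/.hdf5) or a TIFF directory."""
    path = Path(path)
    geom = pset.geometry
    meta = {
        "energy_kev": geom.beam.energy_kev,
        "pixel_um": geom.det.effective_pixel_um,
        "pd_mm": geom.propagation_distance_mm,
        "n_angles": geom.n_angles,
        "extra_check_projection": geom.extra_check_projection,
    }
    if path.suffix in (".h5", ".hdf5", ".nxs"):
        with h5py.File(path, "w") as f:
            e = f.create_group("entry")
            e.create_dataset("data", data=pset.frames)
            e.create_dataset("flats", data=pset.flats)
            e.create_dataset("darks", data=pset.darks)
            e.create_dataset("angles", data=geom.frame_angles_deg)
            e.attrs["provenance"] = json.dumps(pset.provenance)
            for k, v in meta.items():
                e.attrs[k] = v
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(pset.frames):
            tifffile.imwrite(path / f"proj_{i:05d}.tif", frame.astype(np.float32))
        for i, frame in enumerate(pset.flats):
            tifffile.imwrite(path / f"flat_{i:03d}.tif", frame.astype(np.float32))
        for i, frame in enumerate(pset.darks):
            tifffile.imwrite(path / f"dark_{i:03d}.tif", frame.astype(np.float32))
        sidecar = dict(meta)
        sidecar["angles_deg"] = [float(a) for a in geom.frame_angles_deg]
        sidecar["provenance"] = pset.provenance
        (path / "metadata.json").write_text(json.dumps(sidecar, indent=1))


def read_projection_set(path) -> ProjectionSet:
    """Load a projection set from either on-disk dialect, validating invariants."""
    path = Path(path)
    if path.is_dir():
        sidecar_path = path / "metadata.json"
        if not sidecar_path.exists():
            raise FormatError("TIFF directory lacks metadata.json sidecar")
        meta = json.loads(sidecar_path.read_text())
        projs = sorted(path.glob("proj_*.tif"))
        if not projs:
            raise FormatError("TIFF directory contains no proj_*.tif frames")
        frames = np.stack([tifffile.imread(p) for p in projs]).astype(float)
        flats = np.stack([tifffile.imread(p) for p in sorted(path.glob("flat_*.tif"))])
        darks = np.stack([tifffile.imread(p) for p in sorted(path.glob("dark_*.tif"))])
        angles = np.asarray(meta["angles_deg"], dtype=float)
        provenance = meta.get("provenance", {})
    else:
        with h5py.File(path, "r") as f:
            if "entry" not in f:
                raise FormatError("missing /entry group")
            e = f["entry"]
            for name in ("data", "flats", "darks", "angles"):
                if name not in e:
                    raise FormatError(f"missing dataset /entry/{name}")
            frames = e["data"][()].astype(float)
            flats = e["flats"][()].astype(float)
            darks = e["darks"][()].astype(float)
            angles = e["angles"][()]
            provenance = json.loads(e.attrs.get("provenance", "{}"))
            meta = {k: e.attrs[k] for k in
                    ("energy_kev", "pixel_um", "pd_mm", "n_angles",
                     "extra_check_projection")}
    if frames.ndim != 3:
        raise FormatError("projection frames must form a 3-D stack")
    if frames.shape[0] != len(angles):
        raise FormatError(
            f"frame count ({frames.shape[0]}) does not match angle count "
            f"({len(angles)})"
        )
    geom = _geometry_from_meta(meta, frames.shape[1], frames.shape[2])
    try:
        return ProjectionSet(frames, flats, darks, geom, provenance)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_tomogram(tomo: Tomogram, path, bit_depth: str = "float32") -> None:
    """Write a tomogram TIFF stack plus a JSON provenance sidecar.

    ``uint16`` export linearly quantises against the data (min, max), which
    the sidecar records for dequantisation.
    """
    path = Path(path)
    sidecar = {"voxel_um": tomo.voxel_um, "bit_depth": bit_depth,
               "provenance": tomo.provenance}
    if bit_depth == "float32":
        tifffile.imwrite(path, tomo.slices.astype(np.float32))
    elif bit_depth == "uint16":
        lo = float(tomo.slices.min())
        hi = float(tomo.slices.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        q = np.round((tomo.slices - lo) * scale).astype(np.uint16)
        tifffile.imwrite(path, q)
        sidecar["quantisation"] = {"min": lo, "max": hi}
    else:
        raise ValueError("bit_depth must be 'float32' or 'uint16'")
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_tomogram(path) -> Tomogram:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    data = tifffile.imread(path).astype(float)
    if sidecar.get("bit_depth") == "uint16":
        q = sidecar["quantisation"]
        data = q["min"] + data * (q["max"] - q["min"]) / 65535.0
    return Tomogram(data, float(sidecar["voxel_um"]), sidecar.get("provenance", {}))


# ---------------------------------------------------------------------------
# configuration-driven pipeline

@dataclass
class RunConfig:
    """Flat, fully explicit description of one simulate->score run."""

    # phantom
    phantom_kind: str = "cord"
    grid_px: int = 256
    voxel_um: float = 1.625
    embedding: str = "wax"
    stain_contrast: float = 0.3
    n_vessels: int = 20
    n_somata: int = 8
    phantom_seed: int = 1

    # geometry
    energy_kev: float = 25.0
    pd_mm: float = 160.0
    n_projections: int = 720
    extra_check_projection: bool = True

    # artefacts
    photon_noise: bool = True
    zinger_rate: float = 0.0
    ring_defect_density: float = 0.0
    distortion_k1: float = 0.0
    distortion_k2: float = 0.0
    scan_seed: int = 2

    # corrections / retrieval / recon
    corrections: bool = True
    suppress_rings: bool = True
    delta_beta: float = 0.0
    retrieval_pixel_um: float = 1.6125
    filter_window: str = "ramp"

    # study
    subset_sizes: tuple[int, ...] = ()
    roi_fraction: float = 0.55

    # output
    out_dir: str = "phasetomo_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "subset_sizes" in raw and raw["subset_sizes"] is not None:
            raw["subset_sizes"] = tuple(int(s) for s in raw["subset_sizes"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["subset_sizes"] = list(self.subset_sizes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute simulate -> correct -> reconstruct (-> study) per config.

    Returns a manifest dict (also written to ``out_dir/manifest.json``)
    listing every output file with its SHA-256 checksum, the config echo
    and stage summaries.  Identical configs produce identical checksums.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log(f"[phasetomo] run -> {out}")

    if cfg.phantom_kind == "cord":
        phantom = make_cord_phantom(
            grid_px=cfg.grid_px, voxel_um=cfg.voxel_um, embedding=cfg.embedding,
            stain_contrast=cfg.stain_contrast, n_vessels=cfg.n_vessels,
            n_somata=cfg.n_somata, seed=cfg.phantom_seed,
        )
    elif cfg.phantom_kind == "wire":
        phantom = make_wire_phantom(
            grid_px=cfg.grid_px, voxel_um=cfg.voxel_um, embedding=cfg.embedding,
            seed=cfg.phantom_seed,
        )
    else:
        raise ValueError(f"unknown phantom_kind {cfg.phantom_kind!r}")
    log(f"[phasetomo] phantom: {cfg.phantom_kind} {cfg.grid_px}px seed={cfg.phantom_seed}")

    geom = ScanGeometry(
        beam=BeamSpec(cfg.energy_kev),
        det=DetectorSpec(cfg.grid_px, phantom.n_slices, cfg.voxel_um),
        propagation_distance_mm=cfg.pd_mm,
        n_angles=cfg.n_projections,
        extra_check_projection=cfg.extra_check_projection,
    )
    distortion = None
    if cfg.distortion_k1 or cfg.distortion_k2:
        c = ((cfg.grid_px - 1) / 2.0, (phantom.n_slices - 1) / 2.0)
        distortion = DistortionModel(c, cfg.distortion_k1, cfg.distortion_k2)
    art = ArtefactConfig(
        photon_noise=cfg.photon_noise, zinger_rate=cfg.zinger_rate,
        ring_defect_density=cfg.ring_defect_density, distortion=distortion,
    )
    pset = simulate_scan(phantom, geom, art, seed=cfg.scan_seed)
    scan_path = out / "scan.h5"
    write_projection_set(pset, scan_path)
    log(f"[phasetomo] simulated {pset.n_frames} frames -> {scan_path}")

    params = None
    if cfg.delta_beta > 0:
        params = RetrievalParams(
            delta_beta_ratio=cfg.delta_beta, pd_m=cfg.pd_mm * 1e-3,
            wavelength_m=kev_to_wavelength(cfg.energy_kev),
            pixel_m=cfg.retrieval_pixel_um * 1e-6,
        )
    tomo = reconstruct_scan(
        pset, params, corrections=cfg.corrections,
        suppress_rings_flag=cfg.suppress_rings, filter_window=cfg.filter_window,
    )
    tomo_path = out / "tomogram.tif"
    write_tomogram(tomo, tomo_path)
    log(f"[phasetomo] reconstructed {tomo.slices.shape} -> {tomo_path}")

    files = [scan_path, tomo_path, Path(str(tomo_path) + ".json")]
    if cfg.subset_sizes:
        roi = ROI.centered((cfg.grid_px, cfg.grid_px),
                           int(cfg.roi_fraction * cfg.grid_px))
        curve = downsampling_study(pset, cfg.subset_sizes, params, roi,
                                   suppress_rings_flag=cfg.suppress_rings)
        curve_path = out / "projection_curve.csv"
        curve.to_dataframe().to_csv(curve_path, index=False)
        files.append(curve_path)
        log(f"[phasetomo] downsampling study ({len(cfg.subset_sizes)} subsets) "
            f"-> {curve_path}")

    cfg_path = out / "config.yaml"
    cfg.to_yaml(cfg_path)
    files.append(cfg_path)
    manifest = {
        "config": asdict(cfg),
        "tomogram_provenance": tomo.provenance,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log(f"[phasetomo] manifest -> {out / 'manifest.json'}")
    return manifest
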