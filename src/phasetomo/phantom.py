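"""Seeded digital phantoms for soft-tissue micro-CT simulation.

Two phantom families are provided, both returned as paired per-voxel maps of
the X-ray refractive index ``n = 1 - delta + i*beta``:

* :func:`make_cord_phantom` — a cylindrical spinal-cord sample inside an
  embedding cylinder: a white-matter rim, a mirror-symmetric grey-matter
  "butterfly" whose absorption is raised by a contrast stain, dark vessels
  of a few pixels diameter, and sparse brighter cell bodies confined to the
  grey matter.
* :func:`make_wire_phantom` — a plastic-insulated wire with several drawn
  copper strands, the standard sample used to compare embedding media and
  to calibrate projection numbers.

Structures are rasterised with area-weighted (1-pixel feathered) edges so
sub-pixel diameters are meaningful; the label map assigns each voxel the
material covering more than half of it, so every *labelled* voxel carries
its material's (delta, beta) exactly.

Material (delta, beta) values at 25 keV are plausible soft-tissue/wax
numbers chosen so that a ~3 mm path of wax absorbs ~30% of the beam; they
are configuration defaults, not ground truth, and every maker accepts an
override table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

from .planning import kev_to_wavelength

__all__ = [
    "Material",
    "Phantom",
    "LABELS",
    "material_table",
    "make_cord_phantom",
    "make_wire_phantom",
    "save_phantom",
    "load_phantom",
]


@dataclass(frozen=True)
class Material:
    """A material's refractive-index decrement and absorption index."""

    name: str
    delta: float
    beta: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.beta < 0:
            raise ValueError(f"material {self.name}: delta and beta must be >= 0")


#: Integer codes used in :attr:`Phantom.labels`.
LABELS = {
    "air": 0,
    "embedding": 1,
    "white_matter": 2,
    "grey_matter": 3,
    "vessel": 4,
    "soma": 5,
    "insulation": 6,
    "copper": 7,
}

# Defaults at 25 keV.  Absorption indices for the embedding media are set so
# a 3 mm path of wax transmits ~70% (Beer-Lambert with mu = 4*pi*beta/lambda)
# and agar absorbs ~10% more than wax/epoxy; soft tissue sits slightly above
# the media, stained grey matter above that, and copper far above everything.
_BASE_MATERIALS_25KEV = {
    "air": Material("air", 0.0, 0.0),
    "wax": Material("wax", 4.2e-7, 4.69e-10),
    "epoxy": Material("epoxy", 4.5e-7, 5.00e-10),
    "agar": Material("agar", 4.8e-7, 6.72e-10),
    "tissue": Material("tissue", 5.0e-7, 7.5e-10),
    "vessel": Material("vessel", 4.2e-7, 4.70e-10),
    "soma": Material("soma", 5.5e-7, 1.05e-9),
    "insulation": Material("insulation", 6.0e-7, 1.20e-9),
    "copper": Material("copper", 2.7e-6, 1.80e-8),
}


def material_table(
    energy_kev: float = 25.0, overrides: dict[str, Material] | None = None
) -> dict[str, Material]:
    """Material lookup table at a given photon energy.

    The table is defined at 25 keV; other energies are approximated by the
    photoelectric-dominated scalings ``delta ~ 1/E**2`` and ``beta ~ 1/E**3``
    (adequate for planning-level work on light materials, crude for copper).
    ``overrides`` replaces or adds entries verbatim after scaling.
    """
    if not energy_kev > 0:
        raise ValueError("energy_kev must be positive")
    sd = (25.0 / energy_kev) ** 2
    sb = (25.0 / energy_kev) ** 3
    table = {
        k: Material(m.name, m.delta * sd, m.beta * sb)
        for k, m in _BASE_MATERIALS_25KEV.items()
    }
    if overrides:
        table.update(overrides)
    return table


@dataclass
class Phantom:
    """Ground-truth object: per-voxel delta/beta maps plus provenance.

    ``delta``, ``beta`` and ``labels`` always have shape
    ``(n_slices, n, n)``; a 2-D phantom is the ``n_slices = 1`` case.
    ``truth`` records every inserted structure (kind, per-slice centres,
    diameter, label) so downstream tests can score recovery against it.
    """

    delta: np.ndarray
    beta: np.ndarray
    labels: np.ndarray
    voxel_um: float
    truth: list[dict] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta = _as3d(self.delta)
        self.beta = _as3d(self.beta)
        self.labels = _as3d(self.labels)
        if not (self.delta.shape == self.beta.shape == self.labels.shape):
            raise ValueError("delta, beta and labels must have identical shapes")
        if not self.voxel_um > 0:
            raise ValueError("voxel_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.delta.shape[0]

    @property
    def grid_px(self) -> int:
        return self.delta.shape[-1]

    def slice2d(self, i: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(delta, beta, labels) of one slice."""
        return self.delta[i], self.beta[i], self.labels[i]

    def mu_map(self, energy_kev: float = 25.0) -> np.ndarray:
        """Linear attenuation coefficient map in 1/m: ``mu = 4*pi*beta/lambda``."""
        lam = kev_to_wavelength(energy_kev)
        return 4.0 * math.pi * self.beta / lam


def _as3d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim == 2:
        return a[None]
    if a.ndim == 3:
        return a
    raise ValueError("phantom maps must be 2-D or 3-D")


# ---------------------------------------------------------------------------
# rasterisation helpers

def _grid(g: int) -> tuple[np.ndarray, np.ndarray]:
    c = (g - 1) / 2.0
    y, x = np.mgrid[0:g, 0:g]
    return y - c, x - c


def _disc_cov(dy: np.ndarray, dx: np.ndarray, cy: float, cx: float, radius: float) -> np.ndarray:
    """Area-weighted coverage of a disc: 1 inside, 0 outside, feathered edge."""
    r = np.hypot(dy - cy, dx - cx)
    return np.clip(radius - r + 0.5, 0.0, 1.0)


def _paint(delta: np.ndarray, beta: np.ndarray, labels: np.ndarray,
           cov: np.ndarray, mat: Material, label_id: int) -> None:
    delta *= 1.0 - cov
    delta += cov * mat.delta
    beta *= 1.0 - cov
    beta += cov * mat.beta
    labels[cov > 0.5] = label_id


def _butterfly_radius(theta: np.ndarray, r_cord: float) -> np.ndarray:
    """Radial extent of the grey-matter butterfly.

    ``theta`` is measured from the dorsal direction; the profile is even in
    ``theta`` (mirror-symmetric about the mid-sagittal axis) with lateral
    wings and slightly larger ventral horns.
    """
    return r_cord * (0.30 + 0.36 * np.sin(theta) ** 2 + 0.10 * np.cos(theta))


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    radii_px: Sequence[float],
    r_max_fn,
    existing: list[tuple[float, float, float]],
    clearance: float = 3.0,
    max_tries: int = 200000,
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping disc centres (cy, cx, radius).

    ``r_max_fn(theta)`` bounds the centre's distance from the origin for a
    disc of the given radius; discs keep ``clearance`` px between rims, both
    among themselves and against ``existing``.
    """
    placed: list[tuple[float, float, float]] = []
    tries = 0
    i = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} structures of radii {list(radii_px)}; "
                "phantom too crowded"
            )
        rad = radii_px[i % len(radii_px)]
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r_lim = r_max_fn(theta, rad)
        if r_lim <= 0:
            continue
        r = r_lim * math.sqrt(rng.uniform())
        cy, cx = -r * math.cos(theta), r * math.sin(theta)
        ok = True
        for (oy, ox, orad) in placed + existing:
            if math.hypot(cy - oy, cx - ox) < rad + orad + clearance:
                ok = False
                break
        if ok:
            placed.append((cy, cx, rad))
            i += 1
    return placed


# ---------------------------------------------------------------------------
# phantom makers

def make_cord_phantom(
    grid_px: int = 512,
    voxel_um: float = 1.625,
    embedding: str = "wax",
    stain_contrast: float = 0.3,
    vessel_diameters_px: Sequence[float] = (2, 3, 4, 6, 8),
    n_vessels: int = 20,
    n_somata: int = 12,
    seed: int = 0,
    n_slices: int = 1,
    soma_diameter_px: float = 15.0,
    materials: dict[str, Material] | None = None,
) -> Phantom:
    """Spinal-cord-in-embedding phantom.

    Concentric layout on an ``grid_px`` square: an embedding cylinder
    (radius 0.485 * grid) around a cord disc (radius 0.293 * grid) holding a
    white-matter annulus and a grey-matter butterfly whose absorption index
    exceeds white matter by the factor ``1 + stain_contrast`` (the
    contrast-stain dial; 0 reproduces an unstained sample).  Vessels are
    dark discs (lower beta than parenchyma) at seeded random positions in
    the cord; somata are brighter ~15 px discs confined to the grey matter.
    With ``n_slices > 1`` vessels become gently tilted tubes and somata
    spheres, giving a stack of correlated slices.

    Every inserted structure is recorded in ``Phantom.truth``.
    """
    if grid_px < 64:
        raise ValueError("grid_px must be >= 64")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if stain_contrast < 0:
        raise ValueError("stain_contrast must be >= 0")
    if any(d < 1 for d in vessel_diameters_px):
        raise ValueError("vessel diameters must be >= 1 px")
    mats = material_table(overrides=materials)
    if embedding not in mats:
        raise KeyError(f"unknown embedding material {embedding!r}")

    r_embed = 0.485 * grid_px
    r_cord = 0.293 * grid_px
    if max(vessel_diameters_px) / 2.0 >= r_cord:
        raise ValueError("vessel diameter exceeds cord radius")
    if soma_diameter_px / 2.0 >= 0.4 * r_cord and n_somata > 0:
        raise ValueError("soma diameter too large for the grey matter")

    white = mats["tissue"]
    grey = Material("grey_matter", white.delta, white.beta * (1.0 + stain_contrast))
    rng = np.random.default_rng(seed)
    dy, dx = _grid(grid_px)
    theta = np.arctan2(dx, -dy)  # 0 at dorsal (top), even-symmetric profile
    r_grey_profile = _butterfly_radius(theta, r_cord)

    # vessel centres anywhere in the cord; somata centres inside the butterfly
    vessel_radii = [vessel_diameters_px[i % len(vessel_diameters_px)] / 2.0
                    for i in range(n_vessels)]
    vessels = _sample_positions(
        rng, n_vessels, vessel_radii,
        r_max_fn=lambda th, rad: r_cord - rad - 3.0,
        existing=[],
    )
    soma_r = soma_diameter_px / 2.0
    somata = _sample_positions(
        rng, n_somata, [soma_r],
        r_max_fn=lambda th, rad: min(
            float(_butterfly_radius(np.asarray(th), r_cord)) - rad - 1.0,
            r_cord - rad - 3.0,
        ),
        existing=vessels,
        clearance=1.0,
    )

    # per-structure axial behaviour for 3-D stacks
    z_mid = (n_slices - 1) / 2.0
    vessel_slopes = rng.uniform(-0.3, 0.3, size=(n_vessels, 2)) if n_slices > 1 \
        else np.zeros((n_vessels, 2))
    soma_z = rng.uniform(0, n_slices - 1, size=n_somata) if n_slices > 1 \
        else np.zeros(n_somata)

    delta = np.zeros((n_slices, grid_px, grid_px))
    beta = np.zeros_like(delta)
    labels = np.zeros(delta.shape, dtype=np.uint8)

    cov_embed = _disc_cov(dy, dx, 0, 0, r_embed)
    cov_cord = _disc_cov(dy, dx, 0, 0, r_cord)
    r_pix = np.hypot(dy, dx)
    cov_grey = np.clip(r_grey_profile - r_pix + 0.5, 0.0, 1.0)

    truth: list[dict] = []
    for z in range(n_slices):
        d2, b2, l2 = delta[z], beta[z], labels[z]
        _paint(d2, b2, l2, cov_embed, mats[embedding], LABELS["embedding"])
        _paint(d2, b2, l2, cov_cord, white, LABELS["white_matter"])
        _paint(d2, b2, l2, cov_grey, grey, LABELS["grey_matter"])
        for i, (cy, cx, rad) in enumerate(vessels):
            oy = cy + vessel_slopes[i, 0] * (z - z_mid)
            ox = cx + vessel_slopes[i, 1] * (z - z_mid)
            _paint(d2, b2, l2, _disc_cov(dy, dx, oy, ox, rad),
                   mats["vessel"], LABELS["vessel"])
        for j, (cy, cx, rad) in enumerate(somata):
            dz = z - soma_z[j]
            if abs(dz) >= rad:
                continue
            rz = math.sqrt(rad * rad - dz * dz)
            _paint(d2, b2, l2, _disc_cov(dy, dx, cy, cx, rz),
                   mats["soma"], LABELS["soma"])

    c = (grid_px - 1) / 2.0
    for i, (cy, cx, rad) in enumerate(vessels):
        truth.append({"kind": "vessel", "center_yx": (cy + c, cx + c),
                      "diameter_px": 2 * rad, "label": LABELS["vessel"],
                      "slope_yx_px_per_slice": vessel_slopes[i].tolist()})
    for j, (cy, cx, rad) in enumerate(somata):
        truth.append({"kind": "soma", "center_yx": (cy + c, cx + c),
                      "diameter_px": 2 * rad, "label": LABELS["soma"],
                      "z_center": float(soma_z[j])})

    params = dict(grid_px=grid_px, voxel_um=voxel_um, embedding=embedding,
                  stain_contrast=stain_contrast, n_vessels=n_vessels,
                  n_somata=n_somata, seed=seed, n_slices=n_slices,
                  kind="cord", r_embed_px=r_embed, r_cord_px=r_cord)
    return Phantom(delta, beta, labels, voxel_um, truth, params)


def make_wire_phantom(
    grid_px: int = 512,
    voxel_um: float = 1.625,
    embedding: str = "wax",
    n_wire_pieces: int = 7,
    seed: int = 0,
    n_slices: int = 1,
    materials: dict[str, Material] | None = None,
) -> Phantom:
    """Wire-in-insulation standard sample.

    A solid plastic-insulation disc inside the embedding cylinder, holding
    ``n_wire_pieces`` (default 7) drawn copper strands as highly absorbing
    discs.  Used to exercise the projection-number study without tissue.
    """
    if grid_px < 64:
        raise ValueError("grid_px must be >= 64")
    if n_wire_pieces < 1:
        raise ValueError("n_wire_pieces must be >= 1")
    mats = material_table(overrides=materials)
    if embedding not in mats:
        raise KeyError(f"unknown embedding material {embedding!r}")

    r_embed = 0.485 * grid_px
    r_insul = 0.18 * grid_px
    r_cu = max(1.5, 0.014 * grid_px)
    rng = np.random.default_rng(seed)

    strands = _sample_positions(
        rng, n_wire_pieces, [r_cu],
        r_max_fn=lambda th, rad: 0.6 * r_insul,
        existing=[], clearance=2.0,
    )

    dy, dx = _grid(grid_px)
    delta = np.zeros((n_slices, grid_px, grid_px))
    beta = np.zeros_like(delta)
    labels = np.zeros(delta.shape, dtype=np.uint8)
    cov_embed = _disc_cov(dy, dx, 0, 0, r_embed)
    cov_insul = _disc_cov(dy, dx, 0, 0, r_insul)
    for z in range(n_slices):
        d2, b2, l2 = delta[z], beta[z], labels[z]
        _paint(d2, b2, l2, cov_embed, mats[embedding], LABELS["embedding"])
        _paint(d2, b2, l2, cov_insul, mats["insulation"], LABELS["insulation"])
        for (cy, cx, rad) in strands:
            _paint(d2, b2, l2, _disc_cov(dy, dx, cy, cx, rad),
                   mats["copper"], LABELS["copper"])

    c = (grid_px - 1) / 2.0
    truth = [{"kind": "copper", "center_yx": (cy + c, cx + c),
              "diameter_px": 2 * rad, "label": LABELS["copper"]}
             for (cy, cx, rad) in strands]
    params = dict(grid_px=grid_px, voxel_um=voxel_um, embedding=embedding,
                  n_wire_pieces=n_wire_pieces, seed=seed, n_slices=n_slices,
                  kind="wire", r_embed_px=r_embed, r_insul_px=r_insul)
    return Phantom(delta, beta, labels, voxel_um, truth, params)


# ---------------------------------------------------------------------------
# persistence

def save_phantom(phantom: Phantom, path) -> None:
    """Write a phantom to an HDF5 group (datasets delta/beta/labels)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("phantom")
        g.create_dataset("delta", data=phantom.delta)
        g.create_dataset("beta", data=phantom.beta)
        g.create_dataset("labels", data=phantom.labels)
        g.attrs["voxel_um"] = phantom.voxel_um
        g.attrs["truth"] = json.dumps(phantom.truth)
        g.attrs["params"] = json.dumps(phantom.params)


def load_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        g = f["phantom"]
        return Phantom(
            delta=g["delta"][()],
            beta=g["beta"][()],
            labels=g["labels"][()],
            voxel_um=float(g.attrs["voxel_um"]),
            truth=json.loads(g.attrs["truth"]),
            params=json.loads(g.attrs["params"]),
        )
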