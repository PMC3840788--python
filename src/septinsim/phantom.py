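"""Synthetic-data generation: render lattices into density volumes and
projections, and draw labelled 2D particle mixtures.

Subunits and cross-bridges are rendered as isotropic Gaussian blobs of
unit and scaled integrated mass respectively; the blobs stand in for
fitted atomic structures and are always band-limited downstream, so no
atomic detail is modelled.  All generators are pure functions of their
arguments including the seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .models import Lattice

__all__ = [
    "GridParams",
    "DensityVolume",
    "ParticleLabel",
    "ParticleSet",
    "DEFAULT_PIXEL_SIZE",
    "DEFAULT_SUBUNIT_SIGMA",
    "DEFAULT_BRIDGE_SIGMA",
    "BRIDGE_BASE_MASS",
    "render_volume",
    "render_projection",
    "generate_particle_mixture",
    "low_pass",
    "bin_image",
]

#: Post-binning pixel size of the acquisition this pipeline emulates (Å).
DEFAULT_PIXEL_SIZE = 7.3

#: Blob width so that the subunit FWHM matches the 4 nm subunit diameter.
DEFAULT_SUBUNIT_SIGMA = 40.0 / 2.3548  # Å

#: Bridge blob width: FWHM spans the 2-subunit bridge footprint (8 nm).
DEFAULT_BRIDGE_SIGMA = 80.0 / 2.3548  # Å

#: Integrated bridge mass in subunit-mass units before mass_scale; a
#: cross-bridge holds many ligand copies and far outweighs one subunit.
BRIDGE_BASE_MASS = 8.0

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class GridParams:
    """Sampling grid of a density volume: shape is (nz, ny, nx) voxels."""

    shape: tuple[int, int, int]
    voxel_size: float  # Å
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError("shape must be three components, each >= 8")

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) in Å."""
        return tuple(s * self.voxel_size for s in self.shape)


@dataclass
class DensityVolume:
    """3D scalar field on a grid; values are density in mass / Å^3."""

    grid: GridParams
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} != grid {self.grid.shape}"
            )

    @property
    def voxel_size(self) -> float:
        return self.grid.voxel_size

    def integral(self) -> float:
        """Total mass: voxel sum times voxel volume."""
        return float(self.values.sum()) * self.grid.voxel_size**3


class ParticleLabel(str, enum.Enum):
    OCTAMER_CAPPED = "octamer_capped"
    HEXAMER = "hexamer"


@dataclass
class ParticleSet:
    """2D particle images with generation-time ground-truth labels."""

    images: np.ndarray  # (n, h, w)
    labels: list[ParticleLabel]
    pixel_size: float
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have the same length")

    def __len__(self) -> int:
        return len(self.labels)

    def label_fraction(self, label: ParticleLabel) -> float:
        return sum(l is label for l in self.labels) / len(self.labels)


def _splat_gaussians(
    values: np.ndarray,
    centres: np.ndarray,
    sigma: float,
    masses: np.ndarray,
    voxel_size: float,
) -> None:
    """Accumulate normalised 3D Gaussians (density units) in place.

    ``centres`` are (n, 3) voxel coordinates in (z, y, x) order.  Each
    blob is evaluated separably on a +-4.5 sigma window so the rendered
    integral matches the analytic mass to well under 0.1%.
    """
    if len(centres) == 0:
        return
    nz, ny, nx = values.shape
    s_vox = sigma / voxel_size
    half = int(np.ceil(4.5 * s_vox)) + 1
    norm = (2.0 * np.pi) ** -1.5 / sigma**3
    for (cz, cy, cx), mass in zip(centres, masses):
        zlo, zhi = max(0, int(cz) - half), min(nz, int(cz) + half + 1)
        ylo, yhi = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
        xlo, xhi = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
        if zlo >= zhi or ylo >= yhi or xlo >= xhi:
            continue
        gz = np.exp(-0.5 * ((np.arange(zlo, zhi) - cz) / s_vox) ** 2)
        gy = np.exp(-0.5 * ((np.arange(ylo, yhi) - cy) / s_vox) ** 2)
        gx = np.exp(-0.5 * ((np.arange(xlo, xhi) - cx) / s_vox) ** 2)
        blob = mass * norm * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
        values[zlo:zhi, ylo:yhi, xlo:xhi] += blob


def _splat_spheres(
    values: np.ndarray,
    centres: np.ndarray,
    radius: float,
    masses: np.ndarray,
    voxel_size: float,
) -> None:
    """Accumulate uniform balls (one-voxel antialiased edge) in place.

    Stand-in for compact barrel-shaped densities: unlike a Gaussian, a
    ball keeps a flat top and a steep edge after band-limiting, which
    matters for thresholded-extent measurements.
    """
    if len(centres) == 0:
        return
    nz, ny, nx = values.shape
    r_vox = radius / voxel_size
    half = int(np.ceil(r_vox)) + 2
    for (cz, cy, cx), mass in zip(centres, masses):
        zlo, zhi = max(0, int(cz) - half), min(nz, int(cz) + half + 1)
        ylo, yhi = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
        xlo, xhi = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
        if zlo >= zhi or ylo >= yhi or xlo >= xhi:
            continue
        zz = np.arange(zlo, zhi)[:, None, None] - cz
        yy = np.arange(ylo, yhi)[None, :, None] - cy
        xx = np.arange(xlo, xhi)[None, None, :] - cx
        r = np.sqrt(zz * zz + yy * yy + xx * xx)
        cover = np.clip(r_vox - r + 0.5, 0.0, 1.0)
        total = cover.sum() * voxel_size**3
        values[zlo:zhi, ylo:yhi, xlo:xhi] += mass * cover / total


def _lattice_voxel_coords(
    lattice: Lattice, grid: GridParams
) -> tuple[np.ndarray, np.ndarray]:
    """Subunit and bridge centres in voxel coordinates, lattice centred."""
    sub_nm = np.array([s.position for s in lattice.subunits], dtype=float)
    br_nm = lattice.bridge_positions()
    pts = [p for p in (sub_nm, br_nm) if len(p)]
    if not pts:
        return np.empty((0, 3)), np.empty((0, 3))
    allpts = np.vstack(pts)
    centre_nm = (allpts.min(axis=0) + allpts.max(axis=0)) / 2.0

    def to_vox(p_nm: np.ndarray) -> np.ndarray:
        if not len(p_nm):
            return np.empty((0, 3))
        # (x, y, z) nm -> (z, y, x) voxels, centred on the grid centre
        rel = (p_nm - centre_nm) * 10.0 / grid.voxel_size
        grid_centre = (np.array(grid.shape)[::-1] - 1) / 2.0  # (x, y, z)
        return (rel + grid_centre)[:, ::-1]

    return to_vox(sub_nm), to_vox(br_nm)


def render_volume(
    lattice: Lattice,
    grid: GridParams,
    subunit_sigma: float = DEFAULT_SUBUNIT_SIGMA,
    bridge_sigma: float = DEFAULT_BRIDGE_SIGMA,
    bridge_base_mass: float = BRIDGE_BASE_MASS,
    which: str = "all",
    bridge_shape: str = "gaussian",
) -> DensityVolume:
    """Render a lattice as a sum of blobs, centred in the grid.

    Each subunit contributes an isotropic Gaussian of unit integrated
    mass; each bridge contributes ``bridge_base_mass * bridge.mass_scale``
    as a Gaussian of width ``bridge_sigma`` or, with
    ``bridge_shape="sphere"``, as a uniform ball whose diameter equals
    the Gaussian's FWHM (a closer stand-in for a compact barrel-shaped
    cross-bridge).  ``which`` selects ``"all"``, ``"subunits"`` or
    ``"bridges"``.  Raises if the lattice (blob tails included) exceeds
    the grid.
    """
    if which not in ("all", "subunits", "bridges"):
        raise ValueError(f"unknown component selector: {which!r}")
    if bridge_shape not in ("gaussian", "sphere"):
        raise ValueError(f"unknown bridge_shape: {bridge_shape!r}")
    values = np.zeros(grid.shape, dtype=np.float64)
    sub_vox, br_vox = _lattice_voxel_coords(lattice, grid)

    for pts, sigma in ((sub_vox, subunit_sigma), (br_vox, bridge_sigma)):
        if len(pts):
            pad = 4.5 * sigma / grid.voxel_size
            lo = pts.min(axis=0) - pad
            hi = pts.max(axis=0) + pad
            if (lo < -0.5).any() or (hi > np.array(grid.shape) - 0.5).any():
                raise ValueError(
                    "lattice exceeds grid bounds: voxel extent "
                    f"[{lo.round(1)}, {hi.round(1)}] vs shape {grid.shape}"
                )

    if which in ("all", "subunits") and len(sub_vox):
        _splat_gaussians(
            values, sub_vox, subunit_sigma,
            np.ones(len(sub_vox)), grid.voxel_size,
        )
    if which in ("all", "bridges") and len(br_vox):
        masses = np.array(
            [bridge_base_mass * b.mass_scale for b in lattice.bridges]
        )
        if bridge_shape == "sphere":
            radius = bridge_sigma * _FWHM / 2.0
            _splat_spheres(values, br_vox, radius, masses, grid.voxel_size)
        else:
            _splat_gaussians(values, br_vox, bridge_sigma, masses,
                             grid.voxel_size)
    return DensityVolume(grid, values)


_VIEW_AXIS = {"side": 0, "top": 2}  # axis of (z, y, x) to integrate over


def render_projection(
    lattice: Lattice,
    grid: GridParams,
    view: str = "side",
    **render_kw,
) -> np.ndarray:
    """Noise-free line-integral projection of the rendered lattice.

    ``side`` integrates along the beam (z), showing the railroad pattern
    (filaments along x, spaced in y); ``top`` integrates along the
    filament axis (x), showing filament cross-sections.  Pixel values
    carry the voxel_size path-length factor so the image sum equals the
    volume sum times voxel_size.
    """
    if view not in _VIEW_AXIS:
        raise ValueError(f"unknown view: {view!r}")
    vol = render_volume(lattice, grid, **render_kw)
    return vol.values.sum(axis=_VIEW_AXIS[view]) * grid.voxel_size


def _render_rod_image(
    shape: tuple[int, int],
    n_subunits: int,
    capped: bool,
    angle_rad: float,
    pixel_size: float,
    subunit_spacing: float,
    subunit_sigma: float,
    cap_mass: float,
) -> np.ndarray:
    """A 2D rod of Gaussian subunits, optionally end-capped, rotated."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    d_px = subunit_spacing / pixel_size
    s_px = subunit_sigma / pixel_size
    offs = (np.arange(n_subunits) - (n_subunits - 1) / 2.0) * d_px
    masses = [1.0] * n_subunits
    if capped:
        end = (n_subunits - 1) / 2.0 + 1.0
        offs = np.concatenate([offs, [-end * d_px, end * d_px]])
        masses += [cap_mass, cap_mass]
    ux, uy = np.cos(angle_rad), np.sin(angle_rad)
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros(shape, dtype=np.float64)
    for off, mass in zip(offs, masses):
        px, py = cx + off * ux, cy + off * uy
        img += mass * np.exp(
            -((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * s_px**2)
        )
    return img


def generate_particle_mixture(
    n: int,
    fraction_octamer: float,
    snr: float = 5.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    subunit_spacing: float = 40.0,
    subunit_sigma: float = 14.0,
    cap_mass: float = 1.3,
) -> ParticleSet:
    """Draw a labelled mixture of capped octamer and hexamer particles.

    Each particle is an 8-subunit rod with extra terminal ligand blobs
    (``octamer_capped``) or a bare 6-subunit rod (``hexamer``),
    uniformly rotated in-plane, with additive white Gaussian noise of
    variance = per-image signal variance / ``snr``.  Labels are i.i.d.
    Bernoulli(``fraction_octamer``) ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= fraction_octamer <= 1.0:
        raise ValueError("fraction_octamer must be in [0, 1]")
    if not (snr > 0):
        raise ValueError("snr must be positive (may be inf)")
    rng = np.random.default_rng(seed)
    images = np.empty((n, *shape), dtype=np.float32)
    labels: list[ParticleLabel] = []
    for i in range(n):
        is_oct = rng.random() < fraction_octamer
        angle = rng.uniform(0.0, 2.0 * np.pi)
        img = _render_rod_image(
            shape, 8 if is_oct else 6, is_oct, angle, pixel_size,
            subunit_spacing, subunit_sigma, cap_mass,
        )
        if np.isfinite(snr):
            noise_sd = np.sqrt(img.var() / snr)
            img = img + rng.normal(0.0, noise_sd, size=shape)
        images[i] = img
        labels.append(
            ParticleLabel.OCTAMER_CAPPED if is_oct else ParticleLabel.HEXAMER
        )
    return ParticleSet(
        images, labels, pixel_size, seed,
        meta=dict(
            n=n, fraction_octamer=fraction_octamer, snr=snr,
            subunit_spacing=subunit_spacing, subunit_sigma=subunit_sigma,
            cap_mass=cap_mass,
        ),
    )


def _gaussian_transfer(shape, voxel_size, resolution) -> np.ndarray:
    """Radial Gaussian low-pass with half amplitude at 1/resolution."""
    k2 = np.zeros(shape)
    for ax, npts in enumerate(shape):
        k = np.fft.fftfreq(npts, d=voxel_size)
        sh = [1] * len(shape)
        sh[ax] = npts
        k2 = k2 + (k.reshape(sh)) ** 2
    kc2 = (1.0 / resolution) ** 2
    # exp(-ln2 * (k/kc)^2) == 0.5 at k = kc
    return np.exp(-np.log(2.0) * k2 / kc2)


def low_pass(data, resolution: float, voxel_size: float | None = None):
    """Gaussian low-pass to a target resolution (half amplitude at the
    cutoff frequency 1/resolution); preserves the mean exactly.

    Accepts a DensityVolume (voxel size taken from its grid) or a bare
    2D/3D array with ``voxel_size`` given explicitly.
    """
    if isinstance(data, DensityVolume):
        out = low_pass(data.values, resolution, data.grid.voxel_size)
        return DensityVolume(data.grid, out)
    if voxel_size is None:
        raise ValueError("voxel_size required for bare arrays")
    if resolution <= 2.0 * voxel_size:
        raise ValueError(
            f"resolution {resolution} Å is below the Nyquist limit "
            f"{2 * voxel_size} Å"
        )
    arr = np.asarray(data, dtype=np.float64)
    transfer = _gaussian_transfer(arr.shape, voxel_size, resolution)
    out = np.fft.ifftn(np.fft.fftn(arr) * transfer).real
    return out.astype(np.float32)


def bin_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping factor x factor block means (mean-preserving)."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    image = np.asarray(image)
    h, w = image.shape[-2:]
    if h % factor or w % factor:
        raise ValueError(
            f"image dimensions {(h, w)} not divisible by factor {factor}"
        )
    shape = image.shape[:-2] + (h // factor, factor, w // factor, factor)
    return image.reshape(shape).mean(axis=(-3, -1))
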