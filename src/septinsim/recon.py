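"""Weighted back-projection reconstruction and missing-wedge bookkeeping.

The back-projection is the exact geometric adjoint of the projector in
:mod:`septinsim.tiltsim`: each (ramp-weighted) image is replicated
along the beam axis and rotated back about the tilt axis by the
negative tilt angle, so projector and reconstructor share one rotation
convention by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DensityVolume, GridParams
from .tiltsim import TiltSeries, rotate_about_tilt_axis

__all__ = [
    "ReconParams",
    "ramp_filter_profile",
    "weight_projections",
    "wbp",
    "missing_wedge_occupancy",
]


@dataclass(frozen=True)
class ReconParams:
    """Reconstruction controls.

    weighting "ramp" applies a |k| filter along the axis perpendicular
    to the tilt axis, apodized by a raised-cosine rolloff over the top
    ``rolloff_fraction`` of frequencies; "none" back-projects raw
    images.
    """

    output_shape: tuple[int, int, int] | None = None
    weighting: str = "ramp"
    rolloff_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.weighting not in ("ramp", "none"):
            raise ValueError(f"unknown weighting: {self.weighting!r}")
        if not 0.0 < self.rolloff_fraction <= 1.0:
            raise ValueError("rolloff_fraction must be in (0, 1]")


def ramp_filter_profile(n: int, rolloff_fraction: float = 0.05) -> np.ndarray:
    """|k| ramp with raised-cosine rolloff, on np.fft.fftfreq ordering.

    Even in k (real filter output for real input) and exactly zero at
    DC.
    """
    k = np.abs(np.fft.fftfreq(n))
    kmax = k.max()
    ramp = k.copy()
    edge = kmax * (1.0 - rolloff_fraction)
    hi = k > edge
    if rolloff_fraction > 0 and hi.any():
        t = (k[hi] - edge) / (kmax - edge)
        ramp[hi] = k[hi] * 0.5 * (1.0 + np.cos(np.pi * t * 0.5))
    return ramp


def weight_projections(stack: TiltSeries,
                       params: ReconParams | None = None) -> TiltSeries:
    """Ramp-filter each image along x (perpendicular to the y tilt axis)."""
    params = params or ReconParams()
    if len(stack) == 0:
        raise ValueError("empty tilt series")
    if params.weighting == "none":
        return stack
    nx = stack.images.shape[2]
    # zero-pad to avoid circular-convolution wraparound of the ramp
    npad = int(2 ** np.ceil(np.log2(max(2 * nx, 16))))
    ramp = ramp_filter_profile(npad, params.rolloff_fraction)
    padded = np.zeros(stack.images.shape[:2] + (npad,), dtype=np.float64)
    padded[:, :, :nx] = stack.images
    ft = np.fft.fft(padded, axis=2)
    weighted = np.fft.ifft(ft * ramp[None, None, :], axis=2).real[:, :, :nx]
    # the ramp zeroes DC on the padded support; restore exact zero mean
    # on the cropped images (a pure DC shift, irrelevant to WBP)
    weighted -= weighted.mean(axis=(1, 2), keepdims=True)
    return TiltSeries(
        weighted.astype(np.float32), stack.angles, stack.pixel_size,
        stack.geometry, stack.optics, stack.snr, stack.seed,
        meta={**stack.meta, "weighted": params.weighting},
    )


def wbp(stack: TiltSeries, params: ReconParams | None = None) -> DensityVolume:
    """Weighted back-projection of a tilt series into a volume.

    Each weighted image is smeared along the beam (z) and rotated back
    by the negative tilt angle about the y axis; the sum over angles is
    scaled by the angular increment (radians) / (2 * pixel_size) so
    that a fully sampled, ramp-weighted series reconstructs densities
    on the scale of the original volume.  Linear in the input stack.
    """
    params = params or ReconParams()
    if len(stack) == 0:
        raise ValueError("empty tilt series")
    n_angles, ny, nx = stack.images.shape
    shape = params.output_shape or (nx, ny, nx)
    if shape[1] != ny or shape[2] != nx:
        raise ValueError(
            f"output_shape {shape} incompatible with image size {(ny, nx)}"
        )
    weighted = weight_projections(stack, params)
    out = np.zeros(shape, dtype=np.float64)
    nz = shape[0]
    for angle, img in zip(weighted.angles, weighted.images):
        slab = np.broadcast_to(
            img[None, :, :], (nz, ny, nx)
        ).astype(np.float64)
        out += rotate_about_tilt_axis(slab, -angle)
    if len(stack.angles) > 1:
        dtheta = np.deg2rad(np.diff(stack.angles).mean())
    else:
        dtheta = np.pi
    out *= dtheta / (2.0 * stack.pixel_size**2)
    grid = GridParams(shape, stack.pixel_size)
    return DensityVolume(grid, out)


def missing_wedge_occupancy(tilt_half_range: float) -> float:
    """Fraction of the kx-kz Fourier plane sampled by single-axis
    tilting to ±tilt_half_range degrees: half_range / 90."""
    if not 0.0 < tilt_half_range <= 90.0:
        raise ValueError("tilt half-range must be in (0, 90]")
    return tilt_half_range / 90.0
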