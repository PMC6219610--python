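"""Plane-wave delay-and-sum beamforming and coherent compounding.

Images are reconstructed from tilted plane-wave channel data on a fixed
Cartesian grid (depth positive downward, pixel (0, 0) at the shallow-left
corner) and the angled images are averaged coherently (pre-detection) to
form one compounded frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArrayGeometry",
    "ChannelData",
    "ImagingGrid",
    "AngledImage",
    "das_beamform",
    "coherent_compound",
    "compound_frame_rate",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Linear transducer array: element layout and channel sampling.

    The element count and pitch of the probe used in the original
    experiments are not published; the defaults are generic linear-array
    values and fully configurable.
    """

    n_elements: int = 128
    pitch: float = 3.0e-4            # m
    sampling_frequency: float = 25.6e6   # Hz, channel-data rate

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be positive")
        if self.pitch <= 0 or self.sampling_frequency <= 0:
            raise ValueError("pitch and sampling frequency must be positive")

    @property
    def element_positions(self) -> np.ndarray:
        """Lateral element coordinates (m), centred on the array axis."""
        n = self.n_elements
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch

    @property
    def aperture(self) -> float:
        return (self.n_elements - 1) * self.pitch


@dataclass
class ChannelData:
    """Raw per-element traces of one plane-wave transmission."""

    data: np.ndarray                 # (n_elements, n_samples), real RF
    sampling_frequency: float        # Hz
    angle: float                     # transmit tilt, degrees
    t0: float = 0.0                  # time of transmit at array centre, s

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.sampling_frequency <= 0:
            raise ValueError("sampling frequency must be positive")

    @property
    def n_elements(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ImagingGrid:
    """Reconstruction grid in metres. Depth (z) increases downward."""

    z: np.ndarray                    # (nz,) depths, m
    x: np.ndarray                    # (nx,) lateral positions, m

    @classmethod
    def regular(cls, nz: int, nx: int, dz: float, dx: float,
                z0: float = 0.0, x_center: float = 0.0) -> "ImagingGrid":
        z = z0 + np.arange(nz) * dz
        x = x_center + (np.arange(nx) - (nx - 1) / 2.0) * dx
        return cls(z=z, x=x)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.z), len(self.x)


@dataclass
class AngledImage:
    """Complex image reconstructed from a single plane-wave angle."""

    image: np.ndarray                # (nz, nx), complex
    angle: float                     # degrees
    grid: ImagingGrid

    def __post_init__(self) -> None:
        if self.image.shape != self.grid.shape:
            raise ValueError("image shape does not match grid")


def _analytic(data: np.ndarray) -> np.ndarray:
    from scipy.signal import hilbert
    return hilbert(data, axis=-1)


def das_beamform(channels: ChannelData, geometry: ArrayGeometry,
                 grid: ImagingGrid, apodization: str = "rect",
                 speed_of_sound: float = 1540.0) -> AngledImage:
    """Delay-and-sum reconstruction of one tilted plane-wave transmission.

    For each pixel (z, x) and element at x_e, the two-way delay is

        tau = (z cos(theta) + x sin(theta) + sqrt(z^2 + (x - x_e)^2)) / c

    with the transmit delay referenced to the array centre.  Channel
    traces are converted to their analytic signal and sampled at ``tau``
    by linear interpolation; delays beyond the record contribute zero.
    ``apodization`` is ``rect`` (none) or ``hann`` across the aperture.
    """
    theta = np.deg2rad(channels.angle)
    c = speed_of_sound
    analytic = _analytic(channels.data)
    fs = channels.sampling_frequency
    zz, xx = np.meshgrid(grid.z, grid.x, indexing="ij")
    tx_delay = (zz * np.cos(theta) + xx * np.sin(theta)) / c

    if apodization == "hann":
        apod = np.hanning(geometry.n_elements)
    elif apodization == "rect":
        apod = np.ones(geometry.n_elements)
    else:
        raise ValueError(f"unknown apodization {apodization!r}")

    out = np.zeros(grid.shape, dtype=complex)
    n = channels.n_samples
    sample_idx = np.arange(n)
    for e, xe in enumerate(geometry.element_positions):
        if e >= channels.n_elements:
            break
        rx_delay = np.sqrt(zz ** 2 + (xx - xe) ** 2) / c
        s = ((tx_delay + rx_delay) - channels.t0) * fs
        flat = s.ravel()
        re = np.interp(flat, sample_idx, analytic[e].real, left=0.0, right=0.0)
        im = np.interp(flat, sample_idx, analytic[e].imag, left=0.0, right=0.0)
        out += apod[e] * (re + 1j * im).reshape(grid.shape)
    return AngledImage(image=out, angle=channels.angle, grid=grid)


def coherent_compound(images: list[AngledImage] | list[np.ndarray]) -> np.ndarray:
    """Pixel-wise complex mean over the angled images (pre-detection).

    Compounding N copies of one image returns that image; phase-opposed
    inputs cancel.  All images must share the grid shape.
    """
    if not images:
        raise ValueError("no images to compound")
    arrays = [im.image if isinstance(im, AngledImage) else np.asarray(im)
              for im in images]
    shape = arrays[0].shape
    for a in arrays:
        if a.shape != shape:
            raise ValueError("mismatched image shapes")
    return np.mean(arrays, axis=0)


def compound_frame_rate(config) -> float:
    """Compounded frame rate: PRF divided by the number of tilt angles."""
    if config.n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    return config.pulse_repetition_frequency / config.n_angles
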