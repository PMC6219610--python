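"""Power-Doppler and relative cerebral-blood-volume mapping.

After clutter filtering, the per-pixel time-averaged signal energy
("power Doppler") is proportional to the cerebral blood volume sampled in
that pixel; normalizing to the mean power of a baseline window yields
relative CBV in percent (0 % = unchanged, +150 % = 2.5x baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import AcquisitionConfig, IQBlock

__all__ = ["ParametricMap", "BaselineReference", "power_doppler",
           "relative_cbv", "max_unaliased_velocity_span"]

_KINDS = ("power", "relative_cbv", "resistivity")
_UNITS = {"power": "", "relative_cbv": "%", "resistivity": ""}


@dataclass
class ParametricMap:
    """2-D parametric map with a kind tag, units and timestamp.

    Undefined pixels (e.g. below the baseline noise floor) are NaN and
    excluded from regional statistics.  Power maps are nonnegative
    everywhere; resistivity maps lie in [0, 1] where defined.
    """

    values: np.ndarray
    kind: str
    timestamp: float = 0.0          # s relative to CPR
    units: str = ""
    pixel_pitch_axial: float = 1.2e-4
    pixel_pitch_lateral: float = 3.0e-4

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("map must be 2-D")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not self.units:
            self.units = _UNITS[self.kind]
        defined = self.values[np.isfinite(self.values)]
        if self.kind == "power" and defined.size and defined.min() < 0:
            raise ValueError("power map must be nonnegative")
        if self.kind == "resistivity" and defined.size and (
                defined.min() < -1e-9 or defined.max() > 1 + 1e-9):
            raise ValueError("resistivity must lie in [0, 1]")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def time_min(self) -> float:
        return self.timestamp / 60.0


def power_doppler(block: IQBlock) -> ParametricMap:
    """Mean |signal|^2 over frames, per pixel.

    The block should already be clutter filtered; on unfiltered data the
    result is dominated by tissue.
    """
    if block.data.size == 0:
        raise ValueError("empty block")
    power = np.mean(np.abs(block.data.astype(np.complex128)) ** 2, axis=2)
    return ParametricMap(values=power, kind="power", timestamp=block.t0,
                         pixel_pitch_axial=block.pixel_pitch_axial,
                         pixel_pitch_lateral=block.pixel_pitch_lateral)


@dataclass
class BaselineReference:
    """Per-pixel mean power over the baseline window.

    Pixels whose baseline power falls below the noise floor are masked
    (NaN) and stay undefined in every relative map derived from this
    reference.  ``noise_floor='auto'`` estimates the floor as
    3x the median baseline power, which separates vessel pixels from the
    noise-only background whenever vessels are a minority of the slice.
    """

    mean_power: np.ndarray
    window_min: tuple[float, float] = (-23.0, -13.0)
    noise_floor: float = 0.0
    n_blocks: int = 0

    @classmethod
    def from_maps(cls, maps: list[ParametricMap],
                  window_min: tuple[float, float] = (-23.0, -13.0),
                  noise_floor: float | str = "auto") -> "BaselineReference":
        """Average the power maps falling inside the baseline window."""
        lo, hi = window_min
        if hi <= lo:
            raise ValueError("baseline window inverted")
        sel = [m for m in maps if m.kind == "power"
               and lo <= m.time_min <= hi]
        if not sel:
            raise ValueError("no power maps inside the baseline window")
        mean = np.mean([m.values for m in sel], axis=0)
        if noise_floor == "auto":
            noise_floor = 3.0 * float(np.median(mean))
        mean = np.where(mean > max(noise_floor, 0.0), mean, np.nan)
        if not np.isfinite(mean).any():
            warnings.warn("every pixel fell below the noise floor",
                          stacklevel=2)
        return cls(mean_power=mean, window_min=(lo, hi),
                   noise_floor=float(noise_floor), n_blocks=len(sel))

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.mean_power) & (self.mean_power > 0)


def relative_cbv(power_map: ParametricMap,
                 ref: BaselineReference) -> ParametricMap:
    """Percent change of power versus the baseline reference.

    ``100 * (P - P0) / P0`` per pixel; pixels undefined in the reference
    (zero, negative or below the noise floor) are NaN.
    """
    if power_map.kind != "power":
        raise ValueError("relative_cbv expects a power map")
    if power_map.values.shape != ref.mean_power.shape:
        raise ValueError("map and reference shapes differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = 100.0 * (power_map.values - ref.mean_power) / ref.mean_power
    rel[~ref.valid] = np.nan
    return ParametricMap(values=rel, kind="relative_cbv",
                         timestamp=power_map.timestamp,
                         pixel_pitch_axial=power_map.pixel_pitch_axial,
                         pixel_pitch_lateral=power_map.pixel_pitch_lateral)


def max_unaliased_velocity_span(config: AcquisitionConfig) -> float:
    """Full (peak-to-peak) axial velocity span free of aliasing, m/s.

    ``c * fs / (2 * f0)``: at the published 2 kHz compounded rate and
    6.4 MHz carrier this is 0.24 m/s, i.e. blood flows below 24 cm/s are
    sampled unambiguously.
    """
    return (config.sound_speed * config.frame_rate
            / (2.0 * config.center_frequency))
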