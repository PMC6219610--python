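"""Synthetic ultrafast-ultrasound data with known hemodynamic ground truth.

This module generates every input the analysis pipeline consumes:

* complex IQ blocks (depth x lateral x frame cubes) containing strong,
  slowly moving tissue clutter, weak pulsatile blood echoes and white
  noise, synthesized directly in image space;
* raw plane-wave channel data from point scatterers, for beamforming
  tests;
* full multi-subject experiments following the cardiac-arrest /
  resuscitation protocol (10 min baseline, 13 min asphyxia, CPR at t = 0,
  follow-up to 67 min), with group-specific cerebral-blood-volume
  templates (Sham plateau, Control hyperemia, TLV-mitigated hyperemia),
  paired mean-arterial-pressure traces and protocol event markers.

The Doppler phase convention is the two-way pulsed-Doppler one: a
scatterer moving axially at v advances the pixel phase by
4*pi*f0*v*dt/c per frame, i.e. a Doppler frequency of 2*f0*v/c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy.ndimage import gaussian_filter

from .beamforming import ArrayGeometry, ChannelData
from .regional_stats import RegionSet, RegionTimeSeries, default_region_set

__all__ = [
    "AcquisitionConfig",
    "IQBlock",
    "HemodynamicTemplate",
    "ScattererField",
    "VesselLayout",
    "ExperimentSeries",
    "SyntheticSubject",
    "pulsatile_velocity",
    "simulate_iq_block",
    "simulate_rf_plane_wave",
    "make_experiment",
    "simulate_region_series",
    "build_vessel_layout",
    "tissue_background",
    "field_for_time",
]


# --------------------------------------------------------------------------
# acquisition configuration and the IQ block container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and geometry of the ultrafast acquisition.

    Defaults follow the published sequence: a 6.4 MHz linear array firing
    4 tilted plane waves (-3, -1, 1, 3 degrees) at an 8 kHz pulse
    repetition frequency, compounded to a 2 kHz frame rate; 1000 frames
    (0.5 s) per Doppler block, one block every 10 s.
    """

    center_frequency: float = 6.4e6        # Hz
    sound_speed: float = 1540.0            # m/s
    pulse_repetition_frequency: float = 8000.0  # Hz
    n_angles: int = 4
    tilt_angles: tuple[float, ...] = (-3.0, -1.0, 1.0, 3.0)
    frames_per_block: int = 1000
    block_interval: float = 10.0           # s
    pixel_pitch_axial: float = 1.2e-4      # m
    pixel_pitch_lateral: float = 3.0e-4    # m
    grid_shape: tuple[int, int] = (64, 64)  # (depth, lateral)

    def __post_init__(self) -> None:
        for name in ("center_frequency", "sound_speed",
                     "pulse_repetition_frequency", "pixel_pitch_axial",
                     "pixel_pitch_lateral", "block_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_angles < 1 or self.frames_per_block < 1:
            raise ValueError("n_angles and frames_per_block must be >= 1")
        if len(self.tilt_angles) != self.n_angles:
            raise ValueError("len(tilt_angles) must equal n_angles")
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be two positive counts")

    @property
    def frame_rate(self) -> float:
        """Compounded frame rate fs = PRF / n_angles (Hz)."""
        return self.pulse_repetition_frequency / self.n_angles

    @property
    def block_duration(self) -> float:
        return self.frames_per_block / self.frame_rate

    @property
    def n_pixels(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @classmethod
    def desk_scale(cls, frames_per_block: int = 200,
                   grid_shape: tuple[int, int] = (64, 64),
                   block_interval: float = 30.0) -> "AcquisitionConfig":
        """Reduced configuration for desk-scale runs and tests.

        Smaller blocks and a coarser block cadence keep end-to-end
        simulations tractable while leaving the Doppler physics (frame
        rate, carrier, velocities) identical to the full sequence.
        """
        return cls(frames_per_block=frames_per_block, grid_shape=grid_shape,
                   block_interval=block_interval)


@dataclass
class IQBlock:
    """One compounded Doppler ensemble: depth x lateral x frame, complex."""

    data: np.ndarray
    frame_rate: float              # Hz
    t0: float                      # s, block start relative to CPR
    pixel_pitch_axial: float = 1.2e-4
    pixel_pitch_lateral: float = 3.0e-4
    aliased: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("IQ data must be (depth, lateral, frame)")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, relative to CPR."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate


def max_axial_velocity(config: AcquisitionConfig) -> float:
    """Largest one-sided axial speed sampled without aliasing (m/s)."""
    return config.sound_speed * config.frame_rate / (4 * config.center_frequency)


# --------------------------------------------------------------------------
# cardiac-cycle velocity waveform
# --------------------------------------------------------------------------

_SYSTOLIC_FRACTION = 0.4   # fraction of the cardiac cycle taken by systole


def pulsatile_velocity(t, heart_rate: float, v_systolic: float,
                       v_diastolic: float):
    """Axial blood speed over the cardiac cycle (m/s).

    Raised-cosine systolic pulse on a diastolic baseline: the speed sits
    at ``v_diastolic`` through diastole and rises smoothly to
    ``v_systolic`` at mid-systole.  Periodic with period 1/heart_rate;
    the maximum over one period is ``v_systolic`` and the minimum
    ``v_diastolic``, so the prescribed resistivity index is
    1 - v_diastolic / v_systolic.
    """
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    if v_diastolic < 0 or v_systolic < v_diastolic:
        raise ValueError("require v_systolic >= v_diastolic >= 0")
    t = np.asarray(t, dtype=float)
    phase = np.mod(t * heart_rate, 1.0)
    v = np.full(phase.shape, float(v_diastolic))
    s = phase < _SYSTOLIC_FRACTION
    v[s] += (v_systolic - v_diastolic) * 0.5 * (
        1.0 - np.cos(2 * np.pi * phase[s] / _SYSTOLIC_FRACTION))
    return v if v.shape else float(v)


# --------------------------------------------------------------------------
# vessel layout and scatterer fields
# --------------------------------------------------------------------------

_NAMED_REGIONS = ("hippocampus", "thalamus", "cortex")


@dataclass
class VesselLayout:
    """Vessel pixels on the grid with their anatomical labels.

    ``region_names`` lists the labels (named regions plus ``background``
    for vessels outside every named mask); ``region_index`` holds, per
    vessel pixel, an index into that list.
    """

    grid_shape: tuple[int, int]
    pixel_index: np.ndarray        # flat indices of vessel pixels
    region_index: np.ndarray       # per-pixel index into region_names
    region_names: tuple[str, ...]

    @property
    def n_vessels(self) -> int:
        return self.pixel_index.size

    def counts_by_region(self) -> dict[str, int]:
        return {name: int(np.sum(self.region_index == i))
                for i, name in enumerate(self.region_names)}

    def vessel_mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool).ravel()
        m[self.pixel_index] = True
        return m.reshape(self.grid_shape)


def build_vessel_layout(regions: RegionSet, fraction: float = 0.35,
                        seed: int | Generator | None = 0) -> VesselLayout:
    """Randomly place vessel pixels in every region at a given density.

    Each pixel of the slice is a vessel with probability ``fraction``;
    vessels are labelled with the first named region containing them
    (hippocampus, thalamus, cortex, in that order) or ``background``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    shape = regions.grid_shape
    vessel = rng.random(shape) < fraction
    flat_idx = np.flatnonzero(vessel)
    names = tuple(n for n in _NAMED_REGIONS if n in regions) + ("background",)
    label = np.full(shape, len(names) - 1, dtype=np.int32)
    for i, name in reversed(list(enumerate(names[:-1]))):
        label[regions[name]] = i
    return VesselLayout(grid_shape=shape, pixel_index=flat_idx,
                        region_index=label.ravel()[flat_idx],
                        region_names=names)


def region_weights(regions: RegionSet) -> dict[str, float]:
    """Expected fraction of vessel pixels carried by each label.

    Uses the same priority labelling as :func:`build_vessel_layout`; with
    a spatially uniform vessel fraction the weights equal the area
    fractions, independent of the vessel density.
    """
    shape = regions.grid_shape
    names = tuple(n for n in _NAMED_REGIONS if n in regions) + ("background",)
    label = np.full(shape, len(names) - 1, dtype=np.int32)
    for i, name in reversed(list(enumerate(names[:-1]))):
        label[regions[name]] = i
    total = label.size
    return {name: float(np.sum(label == i)) / total
            for i, name in enumerate(names)}


@dataclass
class TissueMotion:
    """Slow (< 5 Hz, sub-mm/s) tissue displacement driving the clutter.

    A spatially uniform sinusoid (amplitude ``d1_amp`` metres) plus a
    spatially weighted steady drift (``drift_rate`` metres/second).  The
    shared sinusoid keeps the bulk clutter in a single singular
    component whatever its excursion; the weighted drift always varies
    within a block, so the clutter reliably occupies a second component
    well above the blood level instead of collapsing to rank one.
    """

    d1_amp: float = 5.7e-6
    d1_freq: float = 1.7       # Hz
    d1_phase: float = 0.0
    drift_rate: float = 5.7e-5  # m/s, weighted by the per-pixel motion map

    def displacements(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Shared and weighted displacement traces over the block."""
        d1 = self.d1_amp * np.sin(2 * np.pi * self.d1_freq * t + self.d1_phase)
        d2 = self.drift_rate * (t - t[0])
        return d1, d2


@dataclass
class ScattererField:
    """Image-space scatterer description of one acquisition instant.

    Tissue is a per-pixel complex reflectivity undergoing the shared
    :class:`TissueMotion`; blood occupies the vessel pixels of a
    :class:`VesselLayout` with an expected scatterer count per pixel
    (already scaled by the local CBV multiplier) and a pulsatile axial
    velocity.  Blood echoes are ``blood_amp / tissue`` dB below tissue by
    construction of the amplitudes.
    """

    grid_shape: tuple[int, int]
    tissue_amp: np.ndarray             # (nz, nx), >= 0
    tissue_phase: np.ndarray           # (nz, nx), rad
    motion: TissueMotion
    motion_weight: np.ndarray          # (nz, nx) in [0, 1], second-mode map
    vessel_pixels: np.ndarray          # flat indices
    vessel_counts: np.ndarray          # expected scatterers per vessel pixel
    blood_amp: float = 1.0
    heart_rate: float = 4.2            # Hz
    v_systolic: float = 0.10           # m/s
    v_diastolic: float = 0.04          # m/s
    velocity_jitter_sd: float = 0.05   # per-scatterer multiplicative SD
    noise_sd: float = 0.39             # complex noise SD per sample

    def __post_init__(self) -> None:
        mean_tissue = float(np.mean(self.tissue_amp))
        if mean_tissue > 0 and self.blood_amp >= mean_tissue:
            # tissue-free fields are allowed for blood-only diagnostics
            raise ValueError("blood amplitude must be below tissue amplitude")
        if self.v_diastolic < 0 or self.v_systolic < self.v_diastolic:
            raise ValueError("require v_systolic >= v_diastolic >= 0")
        if self.vessel_pixels.shape != self.vessel_counts.shape:
            raise ValueError("vessel pixel/count arrays must align")


def tissue_background(config: AcquisitionConfig,
                      rng: Generator,
                      mean_amp: float = 90.0,
                      motion: TissueMotion | None = None) -> dict:
    """Draw the tissue reflectivity, phase and motion-weight fields.

    The amplitude field is a smoothed log-normal-like texture around
    ``mean_amp``; with unit blood scatterer amplitude and ~8 scatterers
    per vessel pixel this places tissue about 30 dB above blood in power.
    """
    shape = config.grid_shape
    g = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    g = g / (np.std(g) + 1e-12)
    amp = mean_amp * np.clip(1.0 + 0.3 * g, 0.2, None)
    phase = rng.uniform(0, 2 * np.pi, size=shape)
    # second-mode weight: rough enough that its spatial variation (and
    # hence the second clutter component) is well above the blood level
    w = gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    w = np.clip(0.5 + 0.3 * w / (np.std(w) + 1e-12), 0.0, 1.0)
    if motion is None:
        motion = TissueMotion(d1_phase=rng.uniform(0, 2 * np.pi))
    return {"tissue_amp": amp, "tissue_phase": phase, "motion": motion,
            "motion_weight": w}


# --------------------------------------------------------------------------
# IQ block synthesis
# --------------------------------------------------------------------------

def simulate_iq_block(field: ScattererField, config: AcquisitionConfig,
                      t0: float = 0.0,
                      seed: int | Generator | None = None,
                      allow_aliasing: bool = False,
                      dtype=np.complex128) -> IQBlock:
    """Synthesize one IQ block directly in image space.

    Tissue contributes ``A(p) exp(i psi(p)) exp(i k (d1(t) + w(p) d2(t)))``
    with k = 4 pi f0 / c; each blood scatterer contributes a complex
    exponential whose phase advances by ``k v dt`` per frame along the
    prescribed pulsatile velocity (with a per-scatterer multiplicative
    velocity jitter and a random initial phase), plus complex white
    noise.  Reproducible for a fixed seed.
    """
    if field.grid_shape != config.grid_shape:
        raise ValueError("field and config grids differ")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    nz, nx = config.grid_shape
    nt = config.frames_per_block
    fs = config.frame_rate
    k = 4 * np.pi * config.center_frequency / config.sound_speed
    t = t0 + np.arange(nt) / fs

    aliased = False
    vmax = max_axial_velocity(config)
    v_extreme = field.v_systolic * (1 + 4 * field.velocity_jitter_sd)
    if v_extreme > vmax:
        aliased = True
        if not allow_aliasing:
            warnings.warn(
                f"peak blood speed {v_extreme:.3f} m/s exceeds the "
                f"unaliased limit {vmax:.3f} m/s", stacklevel=2)

    # tissue clutter: shared motion, small spatially weighted second mode
    rdt = np.float32 if np.dtype(dtype) == np.complex64 else np.float64
    d1, d2 = field.motion.displacements(t)
    phase = (field.tissue_phase[..., None]
             + k * (d1[None, None, :]
                    + field.motion_weight[..., None] * d2[None, None, :]))
    phase = phase.astype(rdt)
    block = np.empty((nz, nx, nt), dtype=dtype)
    # in-place sin/cos on the real/imag views: much faster than complex exp
    np.cos(phase, out=block.real)
    np.sin(phase, out=block.imag)
    block *= field.tissue_amp[..., None].astype(rdt)

    # blood: Poisson number of scatterers per vessel pixel
    counts = rng.poisson(field.vessel_counts)
    n_scat = int(counts.sum())
    if n_scat:
        pix = np.repeat(field.vessel_pixels, counts)   # sorted by pixel
        v = pulsatile_velocity(t, field.heart_rate, field.v_systolic,
                               field.v_diastolic)
        cum = (k / fs) * np.cumsum(v)
        jit = np.clip(1.0 + field.velocity_jitter_sd
                      * rng.standard_normal(n_scat), 0.05, None)
        phi0 = rng.uniform(0, 2 * np.pi, size=n_scat)
        # build the phase matrix in the working precision with in-place
        # ops; float64 intermediates dominate the runtime otherwise
        theta = np.multiply(jit.astype(rdt)[:, None], cum.astype(rdt)[None, :])
        theta += phi0.astype(rdt)[:, None]
        contrib = np.empty(theta.shape, dtype=dtype)
        np.cos(theta, out=contrib.real)
        np.sin(theta, out=contrib.imag)
        if field.blood_amp != 1.0:
            contrib *= rdt(field.blood_amp)
        # per-pixel accumulation: scatterers are grouped by pixel already
        uniq, starts = np.unique(pix, return_index=True)
        summed = np.add.reduceat(contrib, starts, axis=0)
        flat = block.reshape(-1, nt)
        flat[uniq] += summed.astype(dtype)

    if field.noise_sd > 0:
        scale = rdt(field.noise_sd / np.sqrt(2.0))
        block.real += scale * rng.standard_normal((nz, nx, nt), dtype=rdt)
        block.imag += scale * rng.standard_normal((nz, nx, nt), dtype=rdt)

    return IQBlock(data=block, frame_rate=fs, t0=t0,
                   pixel_pitch_axial=config.pixel_pitch_axial,
                   pixel_pitch_lateral=config.pixel_pitch_lateral,
                   aliased=aliased)


# --------------------------------------------------------------------------
# raw channel data for beamforming tests
# --------------------------------------------------------------------------

def simulate_rf_plane_wave(point_scatterers: Sequence[tuple[float, float, float]],
                           config: AcquisitionConfig,
                           geometry: ArrayGeometry,
                           angle: float,
                           noise_sd: float = 0.0,
                           seed: int | Generator | None = None) -> ChannelData:
    """Channel data for one tilted plane-wave transmit over point targets.

    ``point_scatterers`` is a sequence of (x, z, amplitude) triples in
    metres.  Each element trace receives, per scatterer, a 3-cycle
    Hann-windowed pulse centred at the two-way delay

        tau = (z cos(theta) + x sin(theta) + sqrt(z^2 + (x - xe)^2)) / c

    (transmit delay referenced to the array centre).  Scatterers outside
    the imaging field of view are excluded with a warning.
    """
    c = config.sound_speed
    f0 = config.center_frequency
    fs = geometry.sampling_frequency
    theta = np.deg2rad(angle)
    zmax = config.grid_shape[0] * config.pixel_pitch_axial
    xhalf = max(config.grid_shape[1] * config.pixel_pitch_lateral / 2,
                geometry.aperture / 2) * 1.5

    kept = []
    for (x, z, amp) in point_scatterers:
        if z <= 0 or z > zmax * 1.5 or abs(x) > xhalf:
            warnings.warn(f"scatterer at (x={x}, z={z}) outside the field "
                          "of view; excluded", stacklevel=2)
            continue
        kept.append((x, z, amp))

    # pulse centred on zero lag so a scatterer's echo peaks exactly at tau
    half = 1.5 / f0
    tp = np.arange(-half, half, 1.0 / fs)
    pulse = np.sin(2 * np.pi * f0 * tp) * np.hanning(tp.size)

    duration = 2 * zmax * 1.6 / c + 4 * half
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    data = np.zeros((geometry.n_elements, n))
    for e, xe in enumerate(geometry.element_positions):
        for (x, z, amp) in kept:
            tau = (z * np.cos(theta) + x * np.sin(theta)
                   + np.hypot(z, x - xe)) / c
            data[e] += amp * np.interp(t - tau, tp, pulse, left=0.0, right=0.0)
    if noise_sd > 0:
        rng = seed if isinstance(seed, Generator) else default_rng(seed)
        data += noise_sd * rng.standard_normal(data.shape)
    return ChannelData(data=data, sampling_frequency=fs, angle=angle)


# --------------------------------------------------------------------------
# hemodynamic templates
# --------------------------------------------------------------------------

def _interp(knots: np.ndarray, values: np.ndarray, t) -> np.ndarray | float:
    return np.interp(t, knots, values)


@dataclass
class HemodynamicTemplate:
    """Group-level ground-truth time courses of the protocol.

    Relative-CBV curves are piecewise linear in percent versus minutes
    relative to CPR start (baseline anchored at 0 %); each anatomical
    label (cortex, hippocampus, thalamus, background) carries its own
    curve and the whole-slice curve is their vessel-area-weighted mean.
    MAP (mmHg), systolic velocity and resistivity-index knots share the
    timeline.  Per-subject variation is a multiplicative Gaussian factor
    on the post-CPR hyperemic lobe (one shared factor per subject plus a
    region-specific one), with SDs set to reproduce the reported
    group-level dispersions.
    """

    group: str
    knots: np.ndarray                     # min relative to CPR
    region_values: dict[str, np.ndarray]  # % at knots, per label
    weights: dict[str, float]             # vessel-area weight per label
    map_knots: np.ndarray
    map_values: np.ndarray                # mmHg
    vsys_values: np.ndarray               # m/s at knots
    ri_values: np.ndarray                 # prescribed RI at knots
    heart_rate: float = 4.2               # Hz (~250 bpm rabbit)
    shared_sd: float = 0.15               # subject factor SD, shared
    subject_sd: dict[str, float] = field(default_factory=dict)  # specific
    map_noise_sd: float = 4.0             # mmHg, block-to-block
    map_gain: float = 0.0                 # mmHg per % CBV, post-CPR coupling
    map_clip: tuple[float, float] | None = (60.0, 90.0)
    map_clip_from: float = 2.0            # min; clip applies at t >= this
    artifact_window: tuple[float, float] | None = (23.0, 26.0)
    imaging_interval_s: float = 10.0
    baseline_window: tuple[float, float] = (-23.0, -13.0)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.map_knots = np.asarray(self.map_knots, dtype=float)
        self.map_values = np.asarray(self.map_values, dtype=float)
        self.vsys_values = np.asarray(self.vsys_values, dtype=float)
        self.ri_values = np.asarray(self.ri_values, dtype=float)
        for name, v in self.region_values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.knots.shape:
                raise ValueError(f"curve {name!r} does not match knots")
            self.region_values[name] = v
        missing = set(self.weights) ^ set(self.region_values)
        if missing:
            raise ValueError(f"weights/curves label mismatch: {missing}")

    # -- time span and events ---------------------------------------------
    @property
    def time_span(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def events(self) -> dict[str, tuple[float, float]]:
        t0, t1 = self.time_span
        if self.group == "sham":
            return {"baseline": self.baseline_window,
                    "map_sweep": (self.baseline_window[1], t1)}
        ev = {"baseline": (-23.0, -13.0), "asphyxia": (-13.0, 0.0),
              "cpr": (0.0, 2.0)}
        if self.group == "tlv":
            ev["tlv"] = (1.0, 31.0)
        return ev

    # -- ground-truth curves ----------------------------------------------
    def relative_cbv(self, region: str, t,
                     factors: Mapping[str, float] | None = None):
        """Relative CBV (%) of one label at time t (min)."""
        v = self.region_values[region]
        if factors is not None:
            v = self._scaled_values(region, factors)
        return _interp(self.knots, v, t)

    def _scaled_values(self, region: str,
                       factors: Mapping[str, float]) -> np.ndarray:
        v = self.region_values[region].copy()
        lobe = (self.knots > 0) & (v > 0)
        v[lobe] *= factors.get(region, 1.0)
        return v

    def whole_slice_cbv(self, t, factors: Mapping[str, float] | None = None,
                        weights: Mapping[str, float] | None = None):
        """Vessel-area-weighted whole-slice relative CBV (%)."""
        w = dict(weights) if weights is not None else self.weights
        total = sum(w.values())
        out = None
        for name in self.region_values:
            c = self.relative_cbv(name, t, factors)
            term = (w.get(name, 0.0) / total) * np.asarray(c, dtype=float)
            out = term if out is None else out + term
        return out if np.ndim(t) else float(out)

    def density_multiplier(self, region: str, t,
                           factors: Mapping[str, float] | None = None):
        """Blood scatterer density multiplier 1 + CBV(t)/100 (floor 0.05)."""
        return np.clip(1.0 + np.asarray(
            self.relative_cbv(region, t, factors)) / 100.0, 0.05, None)

    def map_at(self, t, factors: Mapping[str, float] | None = None):
        """Mean arterial pressure (mmHg) at time t, before block noise."""
        t = np.asarray(t, dtype=float)
        m = _interp(self.map_knots, self.map_values, t)
        if self.map_gain:
            cbv = np.asarray(self.whole_slice_cbv(t, factors), dtype=float)
            m = m + self.map_gain * np.where(t >= self.map_clip_from,
                                             np.clip(cbv, 0.0, None), 0.0)
        return m

    def velocity_at(self, t) -> tuple[float, float]:
        """(v_systolic, v_diastolic) in m/s at time t (min)."""
        vs = float(_interp(self.knots, self.vsys_values, t))
        ri = float(_interp(self.knots, self.ri_values, t))
        return vs, vs * (1.0 - ri)

    def in_artifact_window(self, t) -> np.ndarray | bool:
        if self.artifact_window is None:
            return np.zeros(np.shape(t), dtype=bool) if np.ndim(t) else False
        a, b = self.artifact_window
        return (np.asarray(t) >= a) & (np.asarray(t) <= b)

    def draw_subject_factors(self, rng: Generator) -> dict[str, float]:
        shared = max(0.1, 1.0 + self.shared_sd * rng.standard_normal())
        return {name: shared * max(0.1, 1.0 + self.subject_sd.get(name, 0.0)
                                   * rng.standard_normal())
                for name in self.region_values}

    # -- shipped group templates ------------------------------------------
    @classmethod
    def control(cls, grid_shape: tuple[int, int] = (64, 64)
                ) -> "HemodynamicTemplate":
        """Untreated cardiac-arrest group: severe transient hyperemia.

        Whole-slice relative CBV peaks at +150 % ten minutes after CPR
        (2.5x the baseline blood volume), the hippocampus at +210 %, the
        thalamus at about +127 %; resistivity drops at the hyperemic
        peak.  MAP recovers to the 60-90 mmHg band after resuscitation.
        """
        return _arrest_template(
            cls, group="control", grid_shape=grid_shape,
            peaks={"cortex": 150.0, "hippocampus": 210.0,
                   "thalamus": 126.6}, whole_peak=150.0,
            subject_sd={"cortex": 0.60, "hippocampus": 0.32,
                        "thalamus": 0.65, "background": 0.15},
            shared_sd=0.15,
            map_post=77.0, map_noise_sd=4.0, map_gain=0.0,
            ri_post=(0.40, 0.35, 0.42, 0.50, 0.55))

    @classmethod
    def tlv(cls, grid_shape: tuple[int, int] = (64, 64)
            ) -> "HemodynamicTemplate":
        """Rapid-cooling group: mitigated hyperemia, preserved resistivity.

        Region curves stay pointwise below the Control curves through the
        7-37 min window; MAP runs lower (low 60s to 70s mmHg) and is
        pressure-passively coupled to CBV, giving the steep linear
        CBV-vs-MAP relationship seen post cooling.
        """
        return _arrest_template(
            cls, group="tlv", grid_shape=grid_shape,
            peaks={"cortex": 45.0, "hippocampus": 67.0, "thalamus": 30.0},
            whole_peak=43.0,
            subject_sd={"cortex": 0.60, "hippocampus": 0.35,
                        "thalamus": 0.65, "background": 0.25},
            shared_sd=0.30,
            map_post=60.0, map_noise_sd=1.5, map_gain=0.40,
            ri_post=(0.55, 0.58, 0.60, 0.60, 0.60))

    @classmethod
    def sham(cls, grid_shape: tuple[int, int] = (64, 64)
             ) -> "HemodynamicTemplate":
        """No-arrest group: MAP sweep under intact autoregulation.

        A 4 min baseline is followed by a 6 min manipulation driving MAP
        from about 40 to 140 mmHg; CBV follows the classical
        autoregulation curve (steep collapse below ~60 mmHg, a gentle
        plateau through the physiological range, force-mediated dilation
        above ~105 mmHg), so whole-brain CBV stays within a few tens of
        percent.  Times are minutes from the start of the sham session.
        """
        regions = default_region_set(grid_shape)
        weights = region_weights(regions)
        map_knots = np.array([0.0, 4.0, 5.0, 6.0, 7.0, 8.5, 10.0])
        map_values = np.array([72.0, 72.0, 55.0, 42.0, 80.0, 115.0, 138.0])
        knots = np.linspace(0.0, 10.0, 41)
        mp = np.interp(knots, map_knots, map_values)
        cbv = _autoregulation_response(mp)
        region_values = {name: cbv.copy() for name in weights}
        return cls(group="sham", knots=knots, region_values=region_values,
                   weights=weights, map_knots=map_knots,
                   map_values=map_values,
                   vsys_values=np.full_like(knots, 0.10),
                   ri_values=np.full_like(knots, 0.60),
                   shared_sd=0.20,
                   subject_sd={name: 0.10 for name in weights},
                   map_noise_sd=3.0, map_gain=0.0, map_clip=None,
                   artifact_window=None, imaging_interval_s=6.0,
                   baseline_window=(0.0, 4.0))


def _autoregulation_response(map_mmhg: np.ndarray) -> np.ndarray:
    """Relative CBV (%) of an intact autoregulation curve, 0 % at 72 mmHg."""
    m = np.asarray(map_mmhg, dtype=float)
    lo, hi, slope = 60.0, 105.0, 0.10
    out = slope * (np.clip(m, lo, hi) - 72.0)
    out = out + 0.8 * np.clip(m - lo, None, 0.0)      # arterial collapse
    out = out + 0.3 * np.clip(m - hi, 0.0, None)      # forced dilation
    return out


# protocol knots shared by the two arrest groups (min relative to CPR)
_ARREST_KNOTS = np.array([-23.0, -13.0, -8.0, -4.0, 0.0,
                          5.0, 10.0, 20.0, 30.0, 37.0, 50.0, 67.0])
# hyperemic lobe shape, as a fraction of the regional peak
_LOBE_SHAPE = {5.0: 0.25, 10.0: 1.0, 20.0: 0.58, 30.0: 0.35, 37.0: 0.20}
# arrest-phase and late-tail values shared across regions (absolute %)
_ARREST_VALUES = {-23.0: 0.0, -13.0: 0.0, -8.0: 0.0, -4.0: -60.0, 0.0: -80.0}
_TAIL_VALUES = {50.0: -5.0, 67.0: -10.0}


def _arrest_template(cls, group: str, grid_shape: tuple[int, int],
                     peaks: dict[str, float], whole_peak: float,
                     subject_sd: dict[str, float], shared_sd: float,
                     map_post: float, map_noise_sd: float, map_gain: float,
                     ri_post: tuple[float, ...]) -> "HemodynamicTemplate":
    regions = default_region_set(grid_shape)
    weights = region_weights(regions)
    named = {k: v for k, v in peaks.items()}
    # solve the background-vessel peak so the weighted whole-slice curve
    # peaks exactly at whole_peak
    w_bg = weights["background"]
    named["background"] = (whole_peak - sum(weights[r] * named[r]
                                            for r in peaks)) / w_bg
    if named["background"] <= 0:
        raise ValueError("inconsistent regional peaks")
    region_values = {}
    for name, peak in named.items():
        vals = []
        for t in _ARREST_KNOTS:
            if t in _ARREST_VALUES:
                vals.append(_ARREST_VALUES[t])
            elif t in _LOBE_SHAPE:
                vals.append(_LOBE_SHAPE[t] * peak)
            else:
                vals.append(_TAIL_VALUES[t])
        region_values[name] = np.array(vals)
    map_knots = np.array([-23.0, -13.0, -11.0, -8.0, -4.0, 0.0, 2.0, 67.0])
    map_values = np.array([70.0, 70.0, 105.0, 60.0, 15.0, 12.0,
                           map_post, map_post])
    vsys = np.array([0.10, 0.10, 0.10, 0.03, 0.02,
                     0.09, 0.085, 0.09, 0.095, 0.10, 0.10, 0.10])
    ri = np.array([0.60, 0.60, 0.60, 0.30, 0.20,
                   *ri_post, 0.60, 0.60])
    return cls(group=group, knots=_ARREST_KNOTS, region_values=region_values,
               weights=weights, map_knots=map_knots, map_values=map_values,
               vsys_values=vsys, ri_values=ri, shared_sd=shared_sd,
               subject_sd=subject_sd, map_noise_sd=map_noise_sd,
               map_gain=map_gain)


# --------------------------------------------------------------------------
# full experiments
# --------------------------------------------------------------------------

# elevated-noise factors inside the chest-compression artifact window
_ARTIFACT_NOISE_FACTOR = 5.0
_ARTIFACT_MOTION_FACTOR = 10.0


def field_for_time(template: HemodynamicTemplate, layout: VesselLayout,
                   config: AcquisitionConfig, t_min: float,
                   factors: Mapping[str, float] | None,
                   rng: Generator,
                   base_count: float = 8.0, blood_amp: float = 1.0,
                   tissue_amp: float = 90.0, noise_sd: float = 0.39,
                   velocity_jitter_sd: float = 0.05) -> ScattererField:
    """Scatterer field realizing the template state at one instant."""
    background = tissue_background(config, rng, mean_amp=tissue_amp)
    mult = np.empty(len(layout.region_names))
    for i, name in enumerate(layout.region_names):
        mult[i] = template.density_multiplier(name, t_min, factors)
    counts = base_count * mult[layout.region_index]
    vs, vd = template.velocity_at(t_min)
    motion = background["motion"]
    if template.in_artifact_window(t_min):
        noise_sd = noise_sd * _ARTIFACT_NOISE_FACTOR
        motion = replace(motion,
                         drift_rate=motion.drift_rate * _ARTIFACT_MOTION_FACTOR)
    return ScattererField(
        grid_shape=config.grid_shape,
        tissue_amp=background["tissue_amp"],
        tissue_phase=background["tissue_phase"],
        motion=motion, motion_weight=background["motion_weight"],
        vessel_pixels=layout.pixel_index, vessel_counts=counts,
        blood_amp=blood_amp, heart_rate=template.heart_rate,
        v_systolic=vs, v_diastolic=vd,
        velocity_jitter_sd=velocity_jitter_sd, noise_sd=noise_sd)


@dataclass
class ExperimentSeries:
    """One synthetic subject: lazily synthesized IQ blocks plus metadata.

    Blocks are generated on demand (:meth:`iter_blocks`) from per-block
    seeds so a 90-minute series never has to reside in memory; the
    realized (subject-perturbed) template curves are stored as ground
    truth alongside the MAP samples and protocol events.
    """

    subject: str
    group: str
    config: AcquisitionConfig
    template: HemodynamicTemplate
    layout: VesselLayout
    factors: dict[str, float]
    block_times_min: np.ndarray
    block_seeds: np.ndarray
    artifact: np.ndarray
    map_values: np.ndarray            # mmHg at block times
    events: dict[str, tuple[float, float]]
    field_kwargs: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return self.block_times_min.size

    def ground_truth_cbv(self, region: str, t):
        """Realized relative CBV (%) of this subject at time t (min)."""
        if region == "whole_slice":
            weights = {k: float(v) for k, v in
                       self.layout.counts_by_region().items()}
            return self.template.whole_slice_cbv(t, self.factors, weights)
        return self.template.relative_cbv(region, t, self.factors)

    def block(self, i: int, dtype=np.complex64) -> IQBlock:
        t_min = float(self.block_times_min[i])
        rng = default_rng(int(self.block_seeds[i]))
        f = field_for_time(self.template, self.layout, self.config, t_min,
                           self.factors, rng, **self.field_kwargs)
        return simulate_iq_block(f, self.config, t0=t_min * 60.0, seed=rng,
                                 dtype=dtype)

    def iter_blocks(self, dtype=np.complex64) -> Iterator[tuple[int, IQBlock]]:
        for i in range(self.n_blocks):
            yield i, self.block(i, dtype=dtype)


def make_experiment(template: HemodynamicTemplate,
                    config: AcquisitionConfig,
                    n_subjects: int = 5,
                    seed: int | SeedSequence = 0,
                    interval_s: float | None = None,
                    vessel_fraction: float = 0.35,
                    **field_kwargs) -> list[ExperimentSeries]:
    """Simulate a cohort of subjects following one group template.

    One block is acquired every ``interval_s`` seconds (defaulting to the
    template's imaging cadence) over the protocol span.  Each subject
    receives its own vessel layout, subject-level amplitude factors and
    per-block seeds, all derived deterministically from ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    interval = interval_s if interval_s is not None \
        else template.imaging_interval_s
    t0, t1 = template.time_span
    times = np.arange(t0 * 60.0, t1 * 60.0 + 1e-9, interval) / 60.0

    series = []
    for sub_idx, sub_ss in enumerate(ss.spawn(n_subjects)):
        child = sub_ss.spawn(3)
        rng = default_rng(child[0])
        layout = build_vessel_layout(default_region_set(config.grid_shape),
                                     fraction=vessel_fraction,
                                     seed=default_rng(child[1]))
        factors = template.draw_subject_factors(rng)
        block_seeds = child[2].generate_state(times.size, dtype=np.uint32)
        map_vals = np.asarray(template.map_at(times, factors), dtype=float)
        map_vals = map_vals + template.map_noise_sd * rng.standard_normal(
            times.size)
        if template.map_clip is not None:
            post = times >= template.map_clip_from
            map_vals[post] = np.clip(map_vals[post], *template.map_clip)
        series.append(ExperimentSeries(
            subject=f"{template.group}_{sub_idx:02d}", group=template.group,
            config=config, template=template, layout=layout, factors=factors,
            block_times_min=times, block_seeds=block_seeds,
            artifact=np.asarray(template.in_artifact_window(times)),
            map_values=map_vals, events=template.events(),
            field_kwargs=dict(field_kwargs)))
    return series


# --------------------------------------------------------------------------
# fast template-level series (no IQ synthesis)
# --------------------------------------------------------------------------

@dataclass
class SyntheticSubject:
    """Template-level subject realization without IQ synthesis.

    Used for statistical calibration and autoregulation studies where
    only the regional time series and MAP matter; the measurement-noise
    model (iid Gaussian on each spatially averaged sample, scaled with
    the instantaneous blood volume) emulates the residual speckle noise
    of the full pipeline.
    """

    subject: str
    group: str
    series: dict[str, RegionTimeSeries]
    map_times: np.ndarray             # min
    map_values: np.ndarray            # mmHg
    factors: dict[str, float]

    def cloud_samples(self, window: tuple[float, float] = (7.0, 37.0),
                      region: str = "whole_slice"
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Paired (relative CBV %, MAP mmHg) samples within a window."""
        s = self.series[region]
        keep = ((s.times >= window[0]) & (s.times <= window[1])
                & ~s.artifact & np.isfinite(s.values))
        tsel = s.times[keep]
        return s.values[keep], np.interp(tsel, self.map_times, self.map_values)


def simulate_region_series(template: HemodynamicTemplate,
                           n_subjects: int = 5,
                           seed: int | SeedSequence = 0,
                           interval_s: float | None = None,
                           noise_sd: float = 4.0,
                           regions: Sequence[str] = ("whole_slice", "cortex",
                                                     "hippocampus",
                                                     "thalamus")
                           ) -> list[SyntheticSubject]:
    """Sample subject region time series directly from the template."""
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    interval = interval_s if interval_s is not None \
        else template.imaging_interval_s
    t0, t1 = template.time_span
    times = np.arange(t0 * 60.0, t1 * 60.0 + 1e-9, interval) / 60.0
    artifact = np.asarray(template.in_artifact_window(times))

    subjects = []
    for sub_idx, sub_ss in enumerate(ss.spawn(n_subjects)):
        rng = default_rng(sub_ss)
        factors = template.draw_subject_factors(rng)
        series: dict[str, RegionTimeSeries] = {}
        for region in regions:
            if region == "whole_slice":
                truth = np.asarray(template.whole_slice_cbv(times, factors))
            else:
                truth = np.asarray(template.relative_cbv(region, times,
                                                         factors))
            scale = 1.0 + np.clip(truth, 0.0, None) / 100.0
            noise = noise_sd * scale * rng.standard_normal(times.size)
            noise[artifact] *= _ARTIFACT_NOISE_FACTOR
            series[region] = RegionTimeSeries(
                region=region, times=times, values=truth + noise,
                subject=f"{template.group}_{sub_idx:02d}", artifact=artifact)
        map_vals = np.asarray(template.map_at(times, factors), dtype=float)
        map_vals = map_vals + template.map_noise_sd * rng.standard_normal(
            times.size)
        if template.map_clip is not None:
            post = times >= template.map_clip_from
            map_vals[post] = np.clip(map_vals[post], *template.map_clip)
        subjects.append(SyntheticSubject(
            subject=f"{template.group}_{sub_idx:02d}", group=template.group,
            series=series, map_times=times, map_values=map_vals,
            factors=factors))
    return subjects
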