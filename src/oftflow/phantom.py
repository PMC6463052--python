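"""Synthetic non-gated 4-D image + Doppler datasets of a beating tube.

The phantom emulates the acquisition used for the embryonic outflow
tract (OFT): one longitudinal b-mode sequence along the tube plus a
stack of cross-sectional sequences at fixed axial increments, 200
frames each at 140 frames/s, every sequence starting at an unknown
random cardiac phase (no gating).  Paired per-pixel "vertical" velocity
planes emulate Doppler imaging: they hold the beam-axis projection
(cos of the beam tilt) of the axial blood velocity, zero outside the
lumen.

Wall motion model
-----------------
The lumen radius at normalized axial position s in [0, 1] and cardiac
phase phi in [0, 1) is

    R(s, phi) = R0(s) * [1 + a * sin(2*pi*(phi - s / w))]
                      * [1 - d * bump(s) * g(phi)]

a traveling contraction wave (amplitude ``a``, speed ``w`` tube lengths
per cycle, giving the inlet->outlet phase lag seen in area-motion
plots) modulated by a cushion-like constriction of depth ``d`` at a
fixed axial location that approaches closure once per cycle.  ``bump``
is a Gaussian in s and ``g`` a smooth periodic pulse peaking at the
closure phase.

Flow model
----------
Blood velocity is quasi-Poiseuille: axial, parabolic with no-slip at
R(s, phi), with local flow rate from mass conservation in the deforming
tube,

    Q(s, phi) = Q_in(phi) - (1/T) * d/dphi [ volume upstream of s ],

the upstream-volume derivative taken analytically.  Wall-motion-induced
radial velocity components are neglected (they are O(wall speed), much
smaller than axial speeds except near closure).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .sync import BModeSequence, DopplerSequence

RadiusProfile = Callable[[np.ndarray], np.ndarray]


def _default_profile(base_radius_mm: float) -> RadiusProfile:
    """Smoothly varying baseline radius: mild mid-tube bulge."""

    def profile(s: np.ndarray) -> np.ndarray:
        return base_radius_mm * (1.0 + 0.15 * np.sin(np.pi * np.asarray(s)))

    return profile


@dataclass
class PhantomConfig:
    """Parameters of the beating-tube phantom.

    Geometric quantities are in mm, times in ms, velocities in mm/s.
    ``wave_speed`` is in tube lengths per cardiac cycle; the traveling
    wave's inlet->outlet phase lag is 1/wave_speed cycles.
    ``cushion_depth`` = 0 means no constriction, 1 full closure at the
    cushion center.  ``beam_tilt_deg`` is the angle between the tube
    axis and the imaging beam; Doppler planes hold
    cos(beam_tilt_deg) * axial velocity.
    """

    base_radius_mm: float = 0.16
    base_radius_profile: RadiusProfile | None = None
    pulsation_amplitude: float = 0.25
    wave_speed: float = 2.0
    cushion_depth: float = 0.85
    cushion_center: float = 0.65
    cushion_width: float = 0.12
    cushion_phase: float = 0.75
    period_ms: float = 410.0
    fps: float = 140.0
    frames_per_sequence: int = 200
    slice_spacing_um: float = 20.0
    n_slices: int = 21
    beam_tilt_deg: float = 45.0
    pixel_size_um: float = 10.0
    image_depth_px: int = 64
    image_width_px: int = 64
    wall_thickness_mm: float = 0.04
    speckle_noise_sd: float = 0.03
    peak_inlet_velocity_mm_s: float = 80.0
    flow_bias: float = 0.25
    phase_offset_seed: int | None = None

    # rendering intensities
    lumen_intensity: float = 0.05
    wall_intensity: float = 1.0
    background_intensity: float = 0.30

    def __post_init__(self) -> None:
        if self.period_ms <= 0:
            raise ValueError("period_ms must be positive")
        if self.fps * self.period_ms / 1000.0 < 2:
            raise ValueError("fewer than two frames per cardiac cycle")
        if not 0 <= self.pulsation_amplitude < 1:
            raise ValueError("pulsation_amplitude must be in [0, 1)")
        if not 0 <= self.cushion_depth <= 1:
            raise ValueError("cushion_depth must be in [0, 1]")
        s = np.linspace(0.0, 1.0, 101)
        if np.any(self.radius_profile(s) <= 0):
            raise ValueError("radius profile must be strictly positive")

    @property
    def radius_profile(self) -> RadiusProfile:
        return self.base_radius_profile or _default_profile(self.base_radius_mm)

    @property
    def tube_length_mm(self) -> float:
        return (self.n_slices - 1) * self.slice_spacing_um / 1000.0

    @property
    def period_s(self) -> float:
        return self.period_ms / 1000.0

    @property
    def frames_per_cycle(self) -> float:
        return self.fps * self.period_ms / 1000.0

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0

    @property
    def doppler_scale(self) -> float:
        """Beam-axis projection factor cos(beam_tilt_deg)."""
        return float(np.cos(np.radians(self.beam_tilt_deg)))


class PhantomKinematics:
    """Analytic wall radius, its phase derivative, and the flow field."""

    def __init__(self, config: PhantomConfig):
        self.config = config

    # -- wall -------------------------------------------------------------
    def _factors(self, s, phi):
        c = self.config
        s = np.asarray(s, dtype=float)
        phi = np.asarray(phi, dtype=float)
        r0 = c.radius_profile(s)
        wave_arg = 2.0 * np.pi * (phi - s / c.wave_speed)
        F = 1.0 + c.pulsation_amplitude * np.sin(wave_arg)
        dF = 2.0 * np.pi * c.pulsation_amplitude * np.cos(wave_arg)
        bump = np.exp(-0.5 * ((s - c.cushion_center) / c.cushion_width) ** 2)
        h = 0.5 * (1.0 + np.cos(2.0 * np.pi * (phi - c.cushion_phase)))
        g = h**3
        dg = 3.0 * h**2 * (-np.pi * np.sin(2.0 * np.pi * (phi - c.cushion_phase)))
        G = 1.0 - c.cushion_depth * bump * g
        dG = -c.cushion_depth * bump * dg
        return r0, F, dF, G, dG

    def radius(self, s, phi):
        """Lumen radius R(s, phi) in mm (broadcasts over inputs)."""
        r0, F, _, G, _ = self._factors(s, phi)
        return r0 * F * G

    def dradius_dphi(self, s, phi):
        r0, F, dF, G, dG = self._factors(s, phi)
        return r0 * (dF * G + F * dG)

    def darea_dphi(self, s, phi):
        """d(pi R^2)/dphi in mm^2 per cycle."""
        return 2.0 * np.pi * self.radius(s, phi) * self.dradius_dphi(s, phi)

    # -- flow -------------------------------------------------------------
    def mean_inlet_velocity(self, phi):
        """Cross-section mean axial velocity at the inlet (mm/s)."""
        c = self.config
        phi = np.asarray(phi, dtype=float)
        wave = (np.sin(2.0 * np.pi * phi) + c.flow_bias) / (1.0 + c.flow_bias)
        return 0.5 * c.peak_inlet_velocity_mm_s * wave

    def inlet_flow_rate(self, phi):
        """Q at s=0 in mm^3/s."""
        area = np.pi * self.radius(0.0, phi) ** 2
        return area * self.mean_inlet_velocity(phi)

    def flow_rate(self, s, phi, n_quad: int = 129):
        """Local flow rate Q(s, phi) from mass conservation (mm^3/s).

        Subtracts (1/T) * d/dphi of the lumen volume upstream of s,
        with the phase derivative taken analytically under the
        integral (trapezoid quadrature on ``n_quad`` axial points).
        """
        c = self.config
        s = np.atleast_1d(np.asarray(s, dtype=float))
        phi = np.asarray(phi, dtype=float)
        z = np.linspace(0.0, 1.0, n_quad)
        dA = self.darea_dphi(z[:, None], phi[None, ...].reshape(1, -1))
        from scipy.integrate import cumulative_trapezoid

        cum = cumulative_trapezoid(dA, z * c.tube_length_mm, axis=0, initial=0.0)
        # interpolate the cumulative integral at the requested s
        out = np.empty(s.shape + np.shape(phi))
        flat = cum.reshape(n_quad, -1)
        for j in range(flat.shape[1]):
            out.reshape(s.size, -1)[:, j] = np.interp(s, z, flat[:, j])
        qin = self.inlet_flow_rate(phi)
        res = qin - out.reshape(s.shape + np.shape(phi)) / c.period_s
        return res if res.shape else float(res)

    def axial_velocity(self, s, rho, phi, q=None, r_min: float = 1e-4):
        """Parabolic axial velocity at radius rho (mm), mm/s.

        Zero outside the lumen and wherever the tube is (nearly)
        closed (R < r_min).
        """
        s = np.asarray(s, dtype=float)
        rho = np.asarray(rho, dtype=float)
        R = self.radius(s, phi)
        if q is None:
            q = self.flow_rate(np.atleast_1d(s).ravel(), phi)
            q = np.asarray(q).reshape(np.shape(s) or (1,))
            q = q if np.shape(s) else q[0]
        R_safe = np.maximum(R, r_min)
        v = 2.0 * np.asarray(q) / (np.pi * R_safe**2) * (1.0 - (rho / R_safe) ** 2)
        open_mask = (R >= r_min) & (rho < R)
        return np.where(open_mask, v, 0.0)

    def lumen_volume(self, phi, n_quad: int = 257):
        """Total lumen volume (mm^3) at phase phi."""
        z = np.linspace(0.0, 1.0, n_quad)
        area = np.pi * self.radius(z, phi) ** 2
        return float(np.trapezoid(area, z * self.config.tube_length_mm))


@dataclass
class GroundTruth:
    """Everything the synthesis knew: oracle for synchronization and CFD."""

    period_ms: float
    slice_phase_offsets: np.ndarray  # per cross-sectional slice, in [0, 1)
    longitudinal_phase_offset: float
    kinematics: PhantomKinematics
    config: PhantomConfig

    def radius_field(self, s, phi):
        return self.kinematics.radius(s, phi)

    def velocity_field(self, s, rho, phi):
        return self.kinematics.axial_velocity(s, rho, phi)

    def flow_rate_waveform(self, phi, s=0.0):
        return self.kinematics.flow_rate(np.atleast_1d(s), phi)


@dataclass
class PhantomDataset:
    """Synthetic acquisition: longitudinal + cross-sectional sequences."""

    longitudinal: BModeSequence
    longitudinal_doppler: DopplerSequence
    cross_sections: list[tuple[BModeSequence, DopplerSequence]]
    truth: GroundTruth

    @property
    def cross_images(self) -> list[BModeSequence]:
        return [b for b, _ in self.cross_sections]

    @property
    def cross_doppler(self) -> list[DopplerSequence]:
        return [d for _, d in self.cross_sections]


def _soft_band(dist: np.ndarray, lo, hi, edge: float) -> np.ndarray:
    """Smooth indicator of lo <= dist <= hi with transition width ``edge``."""
    rise = 1.0 / (1.0 + np.exp(-(dist - lo) / edge))
    fall = 1.0 / (1.0 + np.exp(-(hi - dist) / edge))
    return rise * fall


def _render_cross_frames(
    kin: PhantomKinematics, s: float, phases: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-sectional image + Doppler frames for one slice.

    The wall appears as a bright annulus of configured thickness around
    a dark lumen on a mid-grey background, with sub-pixel smooth edges
    and additive Gaussian speckle.
    """
    c = kin.config
    pix = c.pixel_size_mm
    rows = (np.arange(c.image_depth_px) - (c.image_depth_px - 1) / 2.0) * pix
    cols = (np.arange(c.image_width_px) - (c.image_width_px - 1) / 2.0) * pix
    dist = np.sqrt(rows[:, None] ** 2 + cols[None, :] ** 2)
    R = kin.radius(s, phases)[:, None, None]
    edge = 0.6 * pix
    inside = 1.0 / (1.0 + np.exp(-(R - dist[None]) / edge))
    band = _soft_band(dist[None], R, R + c.wall_thickness_mm, edge)
    img = (
        c.background_intensity * (1.0 - inside - band).clip(0.0, 1.0)
        + c.lumen_intensity * inside
        + c.wall_intensity * band
    )
    if c.speckle_noise_sd > 0:
        img = img + rng.normal(0.0, c.speckle_noise_sd, img.shape)
    q = np.asarray(kin.flow_rate(np.atleast_1d(s), phases)).ravel()
    R_flat = R[:, 0, 0]
    r_min = 1e-4
    R_safe = np.maximum(R_flat, r_min)[:, None, None]
    v = (
        2.0
        * q[:, None, None]
        / (np.pi * R_safe**2)
        * (1.0 - (dist[None] / R_safe) ** 2)
    )
    open_mask = (R >= r_min) & (dist[None] < R)
    dop = np.where(open_mask, v * c.doppler_scale, 0.0)
    return img, dop


def _render_longitudinal_frames(
    kin: PhantomKinematics, phases: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Longitudinal image + Doppler frames.

    Columns sample the slice positions (one column per cross-sectional
    slice, so longitudinal column k corresponds to slice k exactly);
    depth uses the configured pixel size.  The wall appears as two
    bright bands at +-R about the tube center line.
    """
    c = kin.config
    pix = c.pixel_size_mm
    rows = (np.arange(c.image_depth_px) - (c.image_depth_px - 1) / 2.0) * pix
    s = np.linspace(0.0, 1.0, c.n_slices)
    R = kin.radius(s[None, :], phases[:, None])  # (t, n_slices)
    dd = np.abs(rows)[None, :, None]  # (1, depth, 1)
    Rb = R[:, None, :]
    edge = 0.6 * pix
    inside = 1.0 / (1.0 + np.exp(-(Rb - dd) / edge))
    band = _soft_band(dd, Rb, Rb + c.wall_thickness_mm, edge)
    img = (
        c.background_intensity * (1.0 - inside - band).clip(0.0, 1.0)
        + c.lumen_intensity * inside
        + c.wall_intensity * band
    )
    if c.speckle_noise_sd > 0:
        img = img + rng.normal(0.0, c.speckle_noise_sd, img.shape)
    q = np.stack([np.asarray(kin.flow_rate(s, p)).ravel() for p in phases])
    r_min = 1e-4
    R_safe = np.maximum(Rb, r_min)
    v = 2.0 * q[:, None, :] / (np.pi * R_safe**2) * (1.0 - (dd / R_safe) ** 2)
    open_mask = (Rb >= r_min) & (dd < Rb)
    dop = np.where(open_mask, v * c.doppler_scale, 0.0)
    return img, dop


def generate_phantom(config: PhantomConfig, seed: int) -> PhantomDataset:
    """Generate a seeded, fully reproducible phantom acquisition.

    Per-slice starting phases (and the longitudinal one) are drawn
    uniformly on [0, 1) from the seeded RNG, emulating the absence of
    gating, and recorded in the ground truth.
    """
    kin = PhantomKinematics(config)
    offset_seed = (
        config.phase_offset_seed if config.phase_offset_seed is not None else seed
    )
    offset_rng = np.random.default_rng(offset_seed)
    long_offset = float(offset_rng.uniform())
    slice_offsets = offset_rng.uniform(size=config.n_slices)
    noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0C]))

    t = np.arange(config.frames_per_sequence) / config.fps  # seconds
    phase_of = lambda offset: np.mod(offset + t / config.period_s, 1.0)

    img, dop = _render_longitudinal_frames(kin, phase_of(long_offset), noise_rng)
    longitudinal = BModeSequence(frames=img, fps=config.fps)
    longitudinal_doppler = DopplerSequence(frames=dop, fps=config.fps)

    s_positions = np.linspace(0.0, 1.0, config.n_slices)
    cross: list[tuple[BModeSequence, DopplerSequence]] = []
    for k, s in enumerate(s_positions):
        ci, cd = _render_cross_frames(kin, float(s), phase_of(slice_offsets[k]), noise_rng)
        cross.append(
            (
                BModeSequence(frames=ci, fps=config.fps),
                DopplerSequence(frames=cd, fps=config.fps),
            )
        )

    truth = GroundTruth(
        period_ms=config.period_ms,
        slice_phase_offsets=slice_offsets,
        longitudinal_phase_offset=long_offset,
        kinematics=kin,
        config=config,
    )
    return PhantomDataset(
        longitudinal=longitudinal,
        longitudinal_doppler=longitudinal_doppler,
        cross_sections=cross,
        truth=truth,
    )


def analytic_flow(config: PhantomConfig, phase: float) -> Callable:
    """Velocity-field sampler at one cardiac phase.

    Returns ``sampler(s, rho) -> axial velocity (mm/s)`` with a
    quasi-Poiseuille profile and local flow rate from mass
    conservation; zero in closed regions.
    """
    if not 0.0 <= phase < 1.0:
        raise ValueError("phase must be in [0, 1)")
    kin = PhantomKinematics(config)

    def sampler(s, rho):
        return kin.axial_velocity(s, rho, phase)

    return sampler


# ---------------------------------------------------------------------------
# stage presets
# ---------------------------------------------------------------------------

#: Plausibility anchors for chick outflow-tract looping stages (HH14-HH18):
#: cardiac period, tube length and radius scale follow the reported stage
#: means; pulsation amplitudes keep peak velocities in the measured
#: 35-90 mm/s band.  These are not reproductions of any individual embryo.
STAGE_PRESETS: dict[str, dict] = {
    "HH14": dict(period_ms=486.0, length_mm=0.54, base_radius_mm=0.12, peak=43.0),
    "HH15": dict(period_ms=507.0, length_mm=0.59, base_radius_mm=0.13, peak=35.0),
    "HH16": dict(period_ms=408.0, length_mm=0.73, base_radius_mm=0.15, peak=82.0),
    "HH17": dict(period_ms=410.0, length_mm=0.78, base_radius_mm=0.17, peak=90.0),
    "HH18": dict(period_ms=400.0, length_mm=0.69, base_radius_mm=0.16, peak=62.0),
}


def stage_preset(stage: str, **overrides) -> PhantomConfig:
    """PhantomConfig for a developmental-stage preset (HH14..HH18)."""
    if stage not in STAGE_PRESETS:
        raise KeyError(f"unknown stage {stage!r}; choose from {sorted(STAGE_PRESETS)}")
    p = STAGE_PRESETS[stage]
    n_slices = int(round(p["length_mm"] * 1000.0 / 20.0)) + 1
    cfg = PhantomConfig(
        period_ms=p["period_ms"],
        base_radius_mm=p["base_radius_mm"],
        peak_inlet_velocity_mm_s=p["peak"],
        n_slices=n_slices,
    )
    return replace(cfg, **overrides) if overrides else cfg
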