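"""Synthetic labeled gait cohorts: skeleton walks plus plantar-pressure series.

The walker is a stylized sinusoidal kinematic model, not a biomechanically
validated one; its purpose is controllable class structure.  Sarcopenic
parameter priors shift toward shorter/uneven strides, reduced joint range
of motion, slower speed, reduced forefoot pressure and a more staggered
footprint, with the shift scaled by a configurable effect size.  Grip
strength is drawn per class and sex so that the grip-strength labeling
rule reproduces the intended class.

Conventions match the capture setup: x left, y up, z walking/depth
direction, 30 fps, 32 raw joints per frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .cohort_labeling import (
    HGS_CUTOFF_KG,
    CohortTable,
    Label,
    ParticipantRecord,
    Sex,
    label_awgs,
)
from .footpressure_processing import PressureSeries
from .skeleton_processing import RAW32_JOINT_NAMES, SkeletonSequence

__all__ = [
    "GaitParams",
    "CohortSpec",
    "GaitSample",
    "simulate_walk",
    "synthesize_pressure",
    "generate_cohort",
    "draw_gait_params",
    "draw_hgs",
]

_J = {name: i for i, name in enumerate(RAW32_JOINT_NAMES)}


@dataclass(frozen=True)
class GaitParams:
    """Per-participant gait generation parameters (SI units)."""

    speed_mps: float
    stride_m: float
    cadence_spm: float           # steps per minute
    rom_scale: float = 1.0       # joint range-of-motion multiplier, (0, 1.5]
    asymmetry: float = 0.0       # left/right phase unevenness, >= 0
    trunk_length_m: float = 0.52
    noise_sd_m: float = 0.004
    forefoot_factor: float = 1.0  # [0, 1]
    stagger: float = 0.0          # lateral footprint irregularity, >= 0

    #: relative tolerance for the speed ~ stride x cycle-rate consistency check
    _SPEED_RTOL = 0.10

    def __post_init__(self) -> None:
        for name in ("speed_mps", "stride_m", "cadence_spm", "trunk_length_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.rom_scale <= 1.5):
            raise ValueError("rom_scale must lie in (0, 1.5]")
        if self.asymmetry < 0 or self.stagger < 0 or self.noise_sd_m < 0:
            raise ValueError("asymmetry, stagger and noise_sd_m must be >= 0")
        if not (0 <= self.forefoot_factor <= 1):
            raise ValueError("forefoot_factor must lie in [0, 1]")
        implied = self.stride_m * self.cycle_rate_hz
        if abs(self.speed_mps - implied) > self._SPEED_RTOL * implied:
            raise ValueError(
                f"speed {self.speed_mps:.3f} m/s inconsistent with stride x "
                f"cycle rate = {implied:.3f} m/s (tolerance {self._SPEED_RTOL:.0%})")

    @property
    def cycle_rate_hz(self) -> float:
        """Gait cycles (= 2 steps) per second."""
        return self.cadence_spm / 60.0 / 2.0

    @classmethod
    def from_stride_cadence(cls, stride_m: float, cadence_spm: float, **kw) -> "GaitParams":
        """Construct with speed set exactly consistent with stride and cadence."""
        speed = stride_m * cadence_spm / 120.0
        return cls(speed_mps=speed, stride_m=stride_m, cadence_spm=cadence_spm, **kw)


def _smooth_phase_jitter(rng: np.random.Generator, t: np.ndarray,
                         cycle_rate: float, amplitude: float) -> np.ndarray:
    """Per-cycle random phase offsets, linearly interpolated over time."""
    if amplitude == 0:
        return np.zeros_like(t)
    n_cycles = int(np.ceil(t[-1] * cycle_rate)) + 2
    knots = rng.normal(0.0, amplitude, size=n_cycles)
    return np.interp(t * cycle_rate, np.arange(n_cycles), knots)


def simulate_walk(
    params: GaitParams,
    duration_s: float,
    fps: float = 30.0,
    seed: int | np.random.Generator = 0,
) -> SkeletonSequence:
    """Generate a raw 32-joint walking sequence.

    The pelvis advances along z at the configured speed; hip and knee
    angles follow sinusoids at the cadence frequency with amplitude scaled
    by ``rom_scale``; the right side is phase-offset by half a cycle plus
    smooth jitter proportional to ``asymmetry``; arms counter-swing.  The
    sacrum-to-shoulder-center distance equals ``trunk_length_m`` exactly
    before noise.  Gaussian noise of sd ``noise_sd_m`` is added to every
    coordinate.
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    if duration_s * params.cycle_rate_hz < 1.0:
        raise ValueError("duration must cover at least one gait cycle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    L = params.trunk_length_m
    rom = params.rom_scale
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    omega = 2 * np.pi * params.cycle_rate_hz

    thigh, shank = 0.85 * L, 0.80 * L
    hip_half = 0.20 * L
    sh_half = 0.35 * L
    upper_arm, forearm = 0.55 * L, 0.45 * L

    # hip swing amplitude consistent with the stride length
    a_hip = np.arcsin(np.clip(params.stride_m / 2.0 / (thigh + shank), 0.0, 0.95))
    a_knee = 0.8 * rom

    jit = _smooth_phase_jitter(rng, t, params.cycle_rate_hz, 0.15 * params.asymmetry)
    phase = {"left": omega * t, "right": omega * t + np.pi + jit}

    coords = np.zeros((n, 32, 3))

    # pelvis / sacrum: lateral sway (period = full cycle), vertical bounce
    # and forward surge (period = half cycle, so a half-cycle shift maps the
    # pelvis onto itself up to the forward offset)
    pelvis_y = thigh + shank
    pelvis = np.stack([
        0.05 * L * rom * np.sin(omega * t),
        pelvis_y + 0.03 * L * rom * np.cos(2 * omega * t),
        params.speed_mps * t + 0.01 * L * rom * np.sin(2 * omega * t),
    ], axis=1)
    coords[:, _J["pelvis"]] = pelvis

    # trunk: unit direction with a slight periodic sagittal lean
    lean = 0.04 + 0.04 * rom * np.sin(2 * omega * t)
    trunk_u = np.stack([np.zeros(n), np.cos(lean), np.sin(lean)], axis=1)
    chest = pelvis + L * trunk_u
    coords[:, _J["spine_chest"]] = chest
    coords[:, _J["spine_navel"]] = pelvis + 0.5 * L * trunk_u
    neck = pelvis + 1.15 * L * trunk_u
    coords[:, _J["neck"]] = neck
    head = pelvis + 1.32 * L * trunk_u
    coords[:, _J["head"]] = head

    for side, sgn in (("left", +1.0), ("right", -1.0)):
        ph = phase[side]
        # --- leg ---
        hip = pelvis + np.array([sgn * hip_half, -0.05 * L, 0.0])
        th = a_hip * rom * np.sin(ph)                    # hip flexion angle
        kn = a_knee * (1 - np.cos(ph)) / 2.0             # knee flexion >= 0
        knee = hip + thigh * np.stack(
            [np.zeros(n), -np.cos(th), np.sin(th)], axis=1)
        sh_ang = th - kn
        ankle = knee + shank * np.stack(
            [np.zeros(n), -np.cos(sh_ang), np.sin(sh_ang)], axis=1)
        foot = ankle + 0.28 * L * np.stack(
            [np.zeros(n), -0.25 * np.ones(n), 0.97 * np.ones(n)], axis=1)
        coords[:, _J[f"hip_{side}"]] = hip
        coords[:, _J[f"knee_{side}"]] = knee
        coords[:, _J[f"ankle_{side}"]] = ankle
        coords[:, _J[f"foot_{side}"]] = foot

        # --- arm: counter-swing (opposite phase to the same-side leg) ---
        shoulder = chest + np.array([sgn * sh_half, 0.05 * L, 0.0])
        arm_ph = ph + np.pi
        aa = 0.30 * rom * np.sin(arm_ph)
        elbow = shoulder + upper_arm * np.stack(
            [np.zeros(n), -np.cos(aa), np.sin(aa)], axis=1)
        fa = aa + 0.35  # constant elbow flexion
        wrist = elbow + forearm * np.stack(
            [np.zeros(n), -np.cos(fa), np.sin(fa)], axis=1)
        hand_dir = np.stack([np.zeros(n), -np.sin(fa), np.cos(fa)], axis=1)
        coords[:, _J[f"shoulder_{side}"]] = shoulder
        coords[:, _J[f"clavicle_{side}"]] = 0.5 * (neck + shoulder)
        coords[:, _J[f"elbow_{side}"]] = elbow
        coords[:, _J[f"wrist_{side}"]] = wrist
        coords[:, _J[f"hand_{side}"]] = wrist + 0.12 * L * hand_dir
        coords[:, _J[f"handtip_{side}"]] = wrist + 0.22 * L * hand_dir
        coords[:, _J[f"thumb_{side}"]] = (
            wrist + 0.10 * L * hand_dir + np.array([sgn * -0.05 * L, 0, 0]))

    # face landmarks (dropped by joint selection, but present in raw data)
    fwd = np.array([0.0, 0.0, 1.0])
    coords[:, _J["nose"]] = head + 0.10 * L * fwd - np.array([0, 0.02 * L, 0])
    for side, sgn in (("left", +1.0), ("right", -1.0)):
        coords[:, _J[f"eye_{side}"]] = (
            head + 0.09 * L * fwd + np.array([sgn * 0.04 * L, 0.01 * L, 0]))
        coords[:, _J[f"ear_{side}"]] = head + np.array([sgn * 0.08 * L, 0, 0])

    if params.noise_sd_m > 0:
        coords = coords + rng.normal(0.0, params.noise_sd_m, size=coords.shape)

    return SkeletonSequence(coords=coords, fps=fps, joint_set="raw32")


def synthesize_pressure(
    params: GaitParams,
    duration_s: float,
    grid: tuple[int, int] = (64, 192),
    seed: int | np.random.Generator = 0,
    fps: float = 30.0,
    grid_spacing_mm: float = 10.0,
) -> PressureSeries:
    """Generate a plantar-pressure frame series over a rectangular plate.

    Footprints are placed alternately left/right along the walkway (the W
    axis) at half-stride spacing with lateral jitter proportional to
    ``stagger``.  Each footprint is a heel blob plus a forefoot blob (2-D
    Gaussians); the forefoot amplitude is multiplied by
    ``forefoot_factor``.  Blobs are active during their stance window with
    a smooth loading envelope.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    h, w = grid
    sp = grid_spacing_mm / 1000.0  # meters per cell
    heel_sigma = 0.030
    fore_offset = 0.15
    fore_sigma_x, fore_sigma_z = 0.035, 0.025
    if h * sp < 0.30 or w * sp < fore_offset + 6 * heel_sigma:
        raise ValueError(f"grid {grid} at {grid_spacing_mm} mm is too small "
                         "for a footprint")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    step_len = params.stride_m / 2.0
    step_period = 60.0 / params.cadence_spm
    stance = 0.65 * 2 * step_period  # stance lasts ~65% of the gait cycle
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps

    n_steps = int(duration_s / step_period) + 2
    center_x = h * sp / 2.0
    foot_sep = 0.11  # half distance between left and right foot lines

    # footprint centers (meters): x lateral (H axis), z along walkway (W axis)
    steps = []
    for k in range(n_steps):
        side = +1.0 if k % 2 == 0 else -1.0  # left, right, left, ...
        z_k = 0.08 + k * step_len + rng.normal(0.0, 0.02 * params.stagger)
        x_k = center_x + side * foot_sep + rng.normal(0.0, 0.03 * params.stagger)
        if not (0.05 < z_k < w * sp - fore_offset - 0.05):
            continue
        steps.append((x_k, z_k, k * step_period))

    xs = (np.arange(h) + 0.5) * sp
    zs = (np.arange(w) + 0.5) * sp
    gx = xs[:, None]
    gz = zs[None, :]
    frames = np.zeros((n_frames, h, w))
    for x_k, z_k, t_k in steps:
        heel = np.exp(-(((gx - x_k) ** 2) / (2 * heel_sigma ** 2)
                        + ((gz - z_k) ** 2) / (2 * heel_sigma ** 2)))
        fore = params.forefoot_factor * 0.9 * np.exp(
            -(((gx - x_k) ** 2) / (2 * fore_sigma_x ** 2)
              + ((gz - z_k - fore_offset) ** 2) / (2 * fore_sigma_z ** 2)))
        print_img = heel + fore
        active = (t >= t_k) & (t < t_k + stance)
        if not active.any():
            continue
        envelope = np.sin(np.pi * (t[active] - t_k) / stance)
        frames[active] += envelope[:, None, None] * print_img[None]

    return PressureSeries(frames=frames, grid_spacing_mm=grid_spacing_mm)


# ---------------------------------------------------------------------------
# cohort-level generation


#: Normal-class prior means; sarcopenia deltas are scaled by the effect size.
_NORMAL_PRIOR = {
    "stride_m": 1.30, "cadence_spm": 112.0, "rom_scale": 1.0,
    "asymmetry": 0.05, "trunk_length_m": 0.52, "noise_sd_m": 0.004,
    "forefoot_factor": 0.95, "stagger": 0.05,
}
_SARCOPENIA_DELTA = {
    "stride_m": -0.38, "cadence_spm": -16.0, "rom_scale": -0.35,
    "asymmetry": +0.30, "forefoot_factor": -0.50, "stagger": +0.35,
}
_PRIOR_SD = {
    "stride_m": 0.05, "cadence_spm": 4.0, "rom_scale": 0.04,
    "asymmetry": 0.02, "trunk_length_m": 0.03, "noise_sd_m": 0.0,
    "forefoot_factor": 0.03, "stagger": 0.02,
}
_PARAM_BOUNDS = {
    "stride_m": (0.4, 2.0), "cadence_spm": (60.0, 160.0),
    "rom_scale": (0.2, 1.5), "asymmetry": (0.0, 2.0),
    "trunk_length_m": (0.40, 0.65), "noise_sd_m": (0.0, 0.05),
    "forefoot_factor": (0.0, 1.0), "stagger": (0.0, 2.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``sequences_per_participant`` defaults to 20 (10 round trips, each
    recorded in 2 walking directions).  ``effect_size`` scales the
    class-prior separation: 0 makes the classes indistinguishable, 1 is
    the strong default.  Defaults for sex ratio and age bands mirror the
    study cohort composition and never enter any algorithm.
    """

    n_participants: int = 100
    sarcopenia_fraction: float = 0.2
    sequences_per_participant: int = 20
    round_trips: int = 10
    directions: int = 2
    effect_size: float = 1.0
    male_fraction: float = 0.23
    borderline_fraction: float = 0.0
    duration_s: float = 3.0
    fps: float = 30.0
    pressure_grid: tuple[int, int] = (64, 192)
    grid_spacing_mm: float = 10.0
    include_pressure: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sarcopenia_fraction <= 1):
            raise ValueError("sarcopenia_fraction must lie in [0, 1]")
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.sequences_per_participant != self.round_trips * self.directions:
            raise ValueError(
                f"sequences_per_participant ({self.sequences_per_participant}) "
                f"must equal round_trips x directions "
                f"({self.round_trips} x {self.directions})")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class GaitSample:
    """One walking sequence: skeleton plus (optionally) its pressure series."""

    participant_id: str
    sequence_id: str
    direction: int  # +1 away from camera, -1 toward it
    label: Label
    skeleton: SkeletonSequence
    pressure: PressureSeries | None


def draw_hgs(rng: np.random.Generator, sex: Sex, label: Label,
             borderline_fraction: float = 0.0) -> float:
    """Grip strength consistent with the intended class for this sex."""
    cut = HGS_CUTOFF_KG[sex]
    if borderline_fraction and rng.random() < borderline_fraction:
        off = rng.uniform(0.01, 0.5)
        return cut - off if label == Label.SARCOPENIA else cut + off
    if label == Label.SARCOPENIA:
        mu, sd = (20.0, 3.0) if sex == Sex.MALE else (13.5, 2.5)
        lo, hi = 0.0, np.nextafter(cut, 0.0)
    else:
        mu, sd = (38.0, 5.0) if sex == Sex.MALE else (26.0, 4.0)
        lo, hi = cut, 80.0
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return float(round(v, 1))
    return float((lo + min(hi, mu + sd)) / 2)  # pragma: no cover


def draw_gait_params(rng: np.random.Generator, label: Label,
                     effect_size: float = 1.0) -> GaitParams:
    """Draw per-participant gait parameters from the class prior."""
    vals = {}
    for key, mean in _NORMAL_PRIOR.items():
        mu = mean + effect_size * _SARCOPENIA_DELTA.get(key, 0.0) * (
            1.0 if label == Label.SARCOPENIA else 0.0)
        v = rng.normal(mu, _PRIOR_SD[key]) if _PRIOR_SD[key] else mu
        lo, hi = _PARAM_BOUNDS[key]
        vals[key] = float(np.clip(v, lo, hi))
    return GaitParams.from_stride_cadence(
        stride_m=vals.pop("stride_m"), cadence_spm=vals.pop("cadence_spm"), **vals)


_AGE_BANDS = ((30, 39, 18), (40, 59, 21), (60, 69, 28), (70, 85, 33))


def _draw_age(rng: np.random.Generator) -> int:
    weights = np.array([b[2] for b in _AGE_BANDS], dtype=float)
    lo, hi, _ = _AGE_BANDS[rng.choice(len(_AGE_BANDS), p=weights / weights.sum())]
    return int(rng.integers(lo, hi + 1))


def _participant_rng(seed: int, p_idx: int, s_idx: int = -1) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, p_idx, s_idx + 1)))


def build_cohort_table(spec: CohortSpec) -> tuple[CohortTable, dict[str, GaitParams]]:
    """Participant records (labeled) plus each participant's gait parameters."""
    n_sar = int(round(spec.sarcopenia_fraction * spec.n_participants))
    n_male = int(round(spec.male_fraction * spec.n_participants))
    records, params_by_id = [], {}
    for p_idx in range(spec.n_participants):
        rng = _participant_rng(spec.seed, p_idx)
        pid = f"P{p_idx:03d}"
        label = Label.SARCOPENIA if p_idx < n_sar else Label.NORMAL
        # interleave sexes across both classes deterministically
        sex = Sex.MALE if (p_idx * n_male) % spec.n_participants < n_male else Sex.FEMALE
        hgs = draw_hgs(rng, sex, label, spec.borderline_fraction)
        assert label_awgs(sex, hgs) == label
        records.append(ParticipantRecord(
            participant_id=pid, sex=sex, age_years=_draw_age(rng),
            hgs_kg=hgs, label=label))
        params_by_id[pid] = draw_gait_params(rng, label, spec.effect_size)
    return CohortTable(records), params_by_id


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, Iterator[GaitSample]]:
    """Build the cohort table and a lazy stream of its gait samples.

    Every participant yields ``round_trips x directions`` sequences; with
    the default 100-participant spec that is 100 x 10 x 2 = 2,000.  The
    stream is fully determined by ``spec.seed``.
    """
    cohort, params_by_id = build_cohort_table(spec)

    def _iter() -> Iterator[GaitSample]:
        for p_idx, rec in enumerate(cohort):
            gp = params_by_id[rec.participant_id]
            s_idx = 0
            for trip in range(spec.round_trips):
                for direction in (+1, -1)[: spec.directions]:
                    rng = _participant_rng(spec.seed, p_idx, s_idx)
                    skel = simulate_walk(gp, spec.duration_s, spec.fps, rng)
                    if direction < 0:
                        # walk back toward the camera: reflect the z axis
                        zmax = spec.duration_s * gp.speed_mps
                        skel.coords[:, :, 2] = zmax - skel.coords[:, :, 2]
                    pressure = None
                    if spec.include_pressure:
                        pressure = synthesize_pressure(
                            gp, spec.duration_s, spec.pressure_grid, rng,
                            spec.fps, spec.grid_spacing_mm)
                        pressure.participant_id = rec.participant_id
                    sid = f"{rec.participant_id}_t{trip:02d}_d{0 if direction > 0 else 1}"
                    skel.participant_id = rec.participant_id
                    skel.sequence_id = sid
                    if pressure is not None:
                        pressure.sequence_id = sid
                    yield GaitSample(
                        participant_id=rec.participant_id, sequence_id=sid,
                        direction=direction, label=rec.label,
                        skeleton=skel, pressure=pressure)
                    s_idx += 1

    return cohort, _iter()
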