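"""Synthetic inputs with known ground truth: whisker phantoms, vibrometer
recordings, and multi-subject study tables.

Three generators emulate the three kinds of data the analysis consumes:

* :func:`generate_phantom` builds a voxelized whisker shaft (30 um isotropic
  by default) as a tapered elliptical tube lying flat on a virtual slide,
  either *smooth* (sea-lion-like: constant shape, principal axis rotated off
  the slide plane) or *undulated* (true-seal-like: the maximum semi-axis
  swings sinusoidally with crests and troughs while the cross-sectional
  area follows only the smooth taper).  The exact per-slice area, caliper
  widths and theta are returned alongside the volume.
* :func:`generate_recording` composes a velocity time series (default 6 s at
  1200 Hz) from deterministic shedding tones, a low-frequency sting-mount
  artifact (spectral mode 15 Hz, no energy above 50 Hz, peak amplitude
  0.005 m/s), and white noise.
* :func:`generate_study_table` draws per-subject species x angle measurement
  tables whose cell means/SE default to the study's pooled group values,
  with a shared random subject effect so the table has a true
  repeated-measures structure.

All randomness flows from the explicit ``seed`` carried by each spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import VibrationRecording, averaged_fft

__all__ = [
    "WhiskerSpec",
    "SignalSpec",
    "StudyDesign",
    "Phantom",
    "GroundTruthProfile",
    "SpecError",
    "generate_phantom",
    "generate_recording",
    "generate_study_table",
    "default_study_design",
    "SPECIES",
    "FREQ_MEAN",
    "FREQ_SE",
    "VEL_MEAN",
    "VEL_SE",
]


class SpecError(ValueError):
    """A generator spec violates its invariants or is unresolvable."""


# --------------------------------------------------------------------------
# whisker phantoms
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WhiskerSpec:
    """Parametric description of a whisker shaft phantom.

    The shaft is an elliptical tube: cross-sectional area tapers from
    ``base_area`` to ``tip_area_ratio * base_area`` following
    ``A(u) = A0 * (1 - (1 - tip_area_ratio) * u) ** taper_exponent`` with
    ``u = s / length``, and eccentricity ramps linearly from base to tip.
    For the undulated archetype the maximum semi-axis is additionally
    modulated as ``a(s) = a0(s) * (1 + alpha * sin(2*pi*s/lambda))`` with the
    minimum semi-axis taking up the slack so the area keeps to the taper.

    theta (principal-axis angle from the slide plane) is
    ``theta_offset + theta_amplitude * sin(2*pi*theta_cycles*s/length)``:
    constant 0 for the undulated archetype, offset ~15 deg and slowly varying
    for the smooth archetype, matching the reported off-axis rotation of
    sea-lion whiskers.
    """

    species_archetype: str = "undulated"  # "smooth" | "undulated"
    length: float = 65.0  # mm
    base_area: float = 0.6  # mm^2
    taper_exponent: float = 1.5
    tip_area_ratio: float = 0.15
    undulation_wavelength: float = 2.0  # mm (undulated only; not paper-reported)
    undulation_relative_amplitude: float = 0.15  # alpha (undulated only)
    base_eccentricity: float = 0.72
    tip_eccentricity: float = 0.85
    theta_offset: float = 0.0  # degrees
    theta_amplitude: float = 0.0  # degrees
    theta_cycles: float = 1.0
    curvature_radius: float = 400.0  # mm, gentle bow in the slide plane
    voxel_size: float = 30.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_archetype not in ("smooth", "undulated"):
            raise SpecError(f"unknown archetype {self.species_archetype!r}")
        if self.length <= 0 or self.base_area <= 0 or self.voxel_size <= 0:
            raise SpecError("length, base_area and voxel_size must be positive")
        for e in (self.base_eccentricity, self.tip_eccentricity):
            if not 0.0 <= e < 1.0:
                raise SpecError(f"eccentricity {e} outside [0, 1)")
        if not 0.0 <= self.undulation_relative_amplitude <= 0.5:
            raise SpecError("undulation_relative_amplitude outside [0, 0.5]")
        if not 0.0 < self.tip_area_ratio <= 1.0:
            raise SpecError("tip_area_ratio must be in (0, 1]")
        if self.curvature_radius <= self.length:
            raise SpecError("curvature_radius must exceed the whisker length")

    @property
    def alpha(self) -> float:
        return (
            self.undulation_relative_amplitude
            if self.species_archetype == "undulated"
            else 0.0
        )


def smooth_archetype(**overrides) -> WhiskerSpec:
    """Sea-lion-like spec: no undulation, principal axis rotated off-slide."""
    defaults = dict(
        species_archetype="smooth",
        base_eccentricity=0.70,
        tip_eccentricity=0.85,
        theta_offset=15.0,
        theta_amplitude=12.0,
        theta_cycles=1.5,
    )
    defaults.update(overrides)
    return WhiskerSpec(**defaults)


def undulated_archetype(**overrides) -> WhiskerSpec:
    """True-seal-like spec: sinusoidal caliper undulation, theta constant 0."""
    defaults = dict(species_archetype="undulated")
    defaults.update(overrides)
    return WhiskerSpec(**defaults)


@dataclass
class GroundTruthProfile:
    """Exact per-slice geometry of a phantom, on the voxel-slice arc grid."""

    arc_mm: np.ndarray
    area_mm2: np.ndarray
    max_caliper_mm: np.ndarray
    min_caliper_mm: np.ndarray
    theta_deg: np.ndarray
    orientation_undefined: np.ndarray  # bool per slice (circular sections)


@dataclass
class Phantom:
    volume: np.ndarray  # (z, y, x) uint8, 0 background / 255 whisker
    voxel_size_um: float
    truth: GroundTruthProfile
    spec: WhiskerSpec


def _analytic_geometry(spec: WhiskerSpec, s: np.ndarray):
    """Semi-axes a, b (mm) and theta (deg) at arc positions ``s`` (mm)."""
    u = s / spec.length
    area = spec.base_area * (1.0 - (1.0 - spec.tip_area_ratio) * u) ** spec.taper_exponent
    ecc = spec.base_eccentricity + (spec.tip_eccentricity - spec.base_eccentricity) * u
    q = np.sqrt(1.0 - ecc**2)  # b/a before undulation
    a0 = np.sqrt(area / (np.pi * q))
    if spec.alpha > 0:
        mod = 1.0 + spec.alpha * np.sin(2.0 * np.pi * s / spec.undulation_wavelength)
        a = a0 * mod
        b = area / (np.pi * a)
        if np.any(b > a):
            raise SpecError(
                "undulation troughs would invert the principal axis "
                "(need (1 - alpha)^2 >= sqrt(1 - e^2) everywhere); "
                "reduce the amplitude or raise the eccentricity"
            )
    else:
        a = a0
        b = q * a0
    theta = spec.theta_offset + spec.theta_amplitude * np.sin(
        2.0 * np.pi * spec.theta_cycles * u
    )
    return area, a, b, theta


def generate_phantom(spec: WhiskerSpec) -> Phantom:
    """Voxelize a whisker phantom and return it with its exact profile.

    The shaft is extruded along the slice (z) axis with a gentle circular bow
    in the slide (x-z) plane; each axial slice carries the designed
    cross-section, so the ground truth applies directly to axial slices
    (the bow's slopes are kept shallow enough that axial and
    centerline-perpendicular sections coincide to well under a voxel).
    """
    dz = spec.voxel_size / 1000.0  # mm
    n_slices = int(round(spec.length / dz))
    s = (np.arange(n_slices) + 0.5) * dz
    area, a, b, theta = _analytic_geometry(spec, s)

    if np.any(2.0 * np.minimum(a, b) < 3.0 * dz):
        raise SpecError(
            f"whisker thinner than 3 voxels ({3 * spec.voxel_size:g} um) near the tip; "
            "unresolvable geometry at this voxel size"
        )

    # bow in the slide plane: circular-arc sagitta, zero at the midpoint
    R = spec.curvature_radius
    zc = s - spec.length / 2.0
    x_bow = R - np.sqrt(R**2 - zc**2)

    a_max = float(a.max())
    margin = 3.0 * dz
    nx = int(math.ceil((x_bow.max() + 2.0 * a_max + 2.0 * margin) / dz))
    ny = int(math.ceil((2.0 * a_max + 2.0 * margin) / dz))
    y_mid = ny * dz / 2.0

    vol = np.zeros((n_slices, ny, nx), dtype=np.uint8)
    xs = (np.arange(nx) + 0.5) * dz
    ys = (np.arange(ny) + 0.5) * dz
    X, Y = np.meshgrid(xs, ys)
    for i in range(n_slices):
        cx = x_bow[i] + a_max + margin
        th = math.radians(theta[i])
        dx, dy = X - cx, Y - y_mid
        xr = dx * math.cos(th) + dy * math.sin(th)
        yr = -dx * math.sin(th) + dy * math.cos(th)
        vol[i] = ((xr / a[i]) ** 2 + (yr / b[i]) ** 2 <= 1.0) * np.uint8(255)

    circular = np.isclose(a, b, rtol=1e-9)
    truth = GroundTruthProfile(
        arc_mm=s,
        area_mm2=np.pi * a * b,
        max_caliper_mm=2.0 * a,
        min_caliper_mm=2.0 * b,
        theta_deg=np.where(circular, 0.0, theta),
        orientation_undefined=circular,
    )
    return Phantom(volume=vol, voxel_size_um=spec.voxel_size, truth=truth, spec=spec)


# --------------------------------------------------------------------------
# vibrometer recordings
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalSpec:
    """Composition of a synthetic vibrometer recording."""

    sample_rate: float = 1200.0  # Hz
    duration: float = 6.0  # s
    tone_frequency: float = 200.0  # Hz
    tone_amplitude: float = 0.1  # m/s
    harmonic_amplitudes: tuple[float, ...] = ()
    sting_peak_frequency: float = 15.0  # Hz
    sting_band_limit: float = 50.0  # Hz
    sting_amplitude: float = 0.005  # m/s, averaged-spectrum peak
    sting_bandwidth: float = 6.0  # Hz, spectral envelope sigma
    noise_floor: float = 0.0  # m/s white-noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tone_frequency >= self.sample_rate / 2.0:
            raise SpecError("tone frequency at or above Nyquist")
        amps = (self.tone_amplitude, self.sting_amplitude, self.noise_floor) + tuple(
            self.harmonic_amplitudes
        )
        if any(a < 0 for a in amps):
            raise SpecError("amplitudes must be non-negative")
        if not self.sting_peak_frequency < self.sting_band_limit:
            raise SpecError("sting peak frequency must lie below its band limit")


def sting_preset(seed: int = 0, **overrides) -> SignalSpec:
    """Sting-mount-only fixture: the rig artifact with no whisker tone."""
    defaults = dict(tone_amplitude=0.0, noise_floor=0.0, seed=seed)
    defaults.update(overrides)
    return SignalSpec(**defaults)


def _sting_series(spec: SignalSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise with spectral mode at the sting peak frequency.

    White Gaussian noise is shaped in the frequency domain by a Gaussian
    envelope centered on ``sting_peak_frequency``, zeroed at DC and hard-
    zeroed above ``sting_band_limit``, then scaled so the realized 240-point
    averaged-spectrum peak equals ``sting_amplitude``.
    """
    if spec.sting_amplitude == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    env = np.exp(-0.5 * ((freqs - spec.sting_peak_frequency) / spec.sting_bandwidth) ** 2)
    env[freqs == 0] = 0.0
    env[freqs > spec.sting_band_limit] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * env, n=n)
    # normalize the realized averaged-FFT peak to the configured amplitude
    nfft = min(240, n)
    probe = averaged_fft(
        VibrationRecording(samples=x, sample_rate=spec.sample_rate), nfft=nfft
    )
    peak = probe.amplitude[1:].max()
    return x * (spec.sting_amplitude / peak) if peak > 0 else x


def generate_recording(spec: SignalSpec) -> VibrationRecording:
    """Synthesize a velocity recording: tone(s) + sting artifact + white noise."""
    n = int(round(spec.sample_rate * spec.duration))
    t = np.arange(n) / spec.sample_rate
    rng = np.random.default_rng(spec.seed)
    x = spec.tone_amplitude * np.sin(2.0 * np.pi * spec.tone_frequency * t)
    for k, amp in enumerate(spec.harmonic_amplitudes, start=2):
        x += amp * np.sin(2.0 * np.pi * k * spec.tone_frequency * t)
    x += _sting_series(spec, n, rng)
    if spec.noise_floor > 0:
        x += spec.noise_floor * rng.standard_normal(n)
    return VibrationRecording(samples=x, sample_rate=spec.sample_rate)


# --------------------------------------------------------------------------
# study tables
# --------------------------------------------------------------------------

SPECIES = ("california_sea_lion", "elephant_seal", "harbor_seal")
ANGLES = (0, 45, 90)

# Pooled group values for peak frequency (Hz): mean and SE per species x angle.
FREQ_MEAN = {
    ("california_sea_lion", 0): 204.4,
    ("california_sea_lion", 45): 156.7,
    ("california_sea_lion", 90): 112.5,
    ("elephant_seal", 0): 151.3,
    ("elephant_seal", 45): 140.0,
    ("elephant_seal", 90): 121.3,
    ("harbor_seal", 0): 202.8,
    ("harbor_seal", 45): 157.2,
    ("harbor_seal", 90): 95.0,
}
FREQ_SE = {
    ("california_sea_lion", 0): 9.4,
    ("california_sea_lion", 45): 13.4,
    ("california_sea_lion", 90): 4.6,
    ("elephant_seal", 0): 5.9,
    ("elephant_seal", 45): 7.3,
    ("elephant_seal", 90): 5.2,
    ("harbor_seal", 0): 7.3,
    ("harbor_seal", 45): 17.6,
    ("harbor_seal", 90): 4.3,
}
# Pooled group values for peak velocity (m/s).
VEL_MEAN = {
    ("california_sea_lion", 0): 0.0087,
    ("california_sea_lion", 45): 0.0426,
    ("california_sea_lion", 90): 0.1099,
    ("elephant_seal", 0): 0.0029,
    ("elephant_seal", 45): 0.0559,
    ("elephant_seal", 90): 0.1745,
    ("harbor_seal", 0): 0.0069,
    ("harbor_seal", 45): 0.0484,
    ("harbor_seal", 90): 0.1192,
}
VEL_SE = {
    ("california_sea_lion", 0): 0.0029,
    ("california_sea_lion", 45): 0.0142,
    ("california_sea_lion", 90): 0.0172,
    ("elephant_seal", 0): 0.0010,
    ("elephant_seal", 45): 0.0280,
    ("elephant_seal", 90): 0.0226,
    ("harbor_seal", 0): 0.0038,
    ("harbor_seal", 45): 0.0167,
    ("harbor_seal", 90): 0.0175,
}
# Complete-case subject counts used for the group statistics.
DEFAULT_COUNTS = {"california_sea_lion": 8, "elephant_seal": 8, "harbor_seal": 6}
# Sample lengths (cm): species means and SDs of the flume samples.
LENGTH_MEAN_CM = {"california_sea_lion": 7.7, "elephant_seal": 8.19, "harbor_seal": 7.35}
LENGTH_SD_CM = {"california_sea_lion": 0.4, "elephant_seal": 0.5, "harbor_seal": 0.4}
# Between-subject SDs from the reported ANOVA variance components
# ((MS_subjects - MS_residual) / n_angles).
DEFAULT_SUBJECT_SD = {"peak_freq_hz": 14.0, "peak_vel_m_s": 0.0139}


@dataclass
class StudyDesign:
    """Species x angle cell design for the study-table generator.

    ``freq_se``/``vel_se`` are standard errors of the cell means at the
    reference counts ``se_reference_n``; the generator converts them to
    between-subject SDs (``SE * sqrt(n_ref)``) so the cell spread stays put
    when ``n_subjects`` is scaled up.  ``subject_sd`` adds a per-subject
    offset shared across that subject's angles (the repeated-measures
    structure).
    """

    n_subjects: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    angles: tuple = ANGLES
    freq_mean: dict = field(default_factory=lambda: dict(FREQ_MEAN))
    freq_se: dict = field(default_factory=lambda: dict(FREQ_SE))
    vel_mean: dict = field(default_factory=lambda: dict(VEL_MEAN))
    vel_se: dict = field(default_factory=lambda: dict(VEL_SE))
    se_reference_n: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    subject_sd: dict = field(default_factory=lambda: dict(DEFAULT_SUBJECT_SD))
    length_mean_cm: dict = field(default_factory=lambda: dict(LENGTH_MEAN_CM))
    length_sd_cm: dict = field(default_factory=lambda: dict(LENGTH_SD_CM))
    seed: int = 0

    @property
    def species(self) -> tuple:
        return tuple(self.n_subjects)

    def __post_init__(self) -> None:
        for sp, n in self.n_subjects.items():
            if n < 2:
                raise SpecError(f"need >= 2 subjects per species, got {n} for {sp}")
            for a in self.angles:
                for table in (self.freq_mean, self.freq_se, self.vel_mean, self.vel_se):
                    if (sp, a) not in table:
                        raise SpecError(f"missing cell value for ({sp}, {a})")
        if any(v < 0 for v in self.freq_se.values()) or any(
            v < 0 for v in self.vel_se.values()
        ):
            raise SpecError("standard errors must be non-negative")


def default_study_design(seed: int = 0) -> StudyDesign:
    """The study's design: pooled cell means/SE, n = 8/8/6, angles 0/45/90."""
    return StudyDesign(seed=seed)


def generate_study_table(design: StudyDesign) -> pd.DataFrame:
    """Draw a per-subject measurement table from the cell design.

    Every subject appears at every angle.  Per variable:
    ``value = cell_mean + subject_effect + residual`` with
    ``subject_effect ~ N(0, subject_sd)`` shared across the subject's angles
    and ``residual ~ N(0, SE * sqrt(n_ref))`` independent per angle.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for sp in design.species:
        n_ref = design.se_reference_n.get(sp, design.n_subjects[sp])
        for j in range(design.n_subjects[sp]):
            sid = f"{sp}_{j + 1:03d}"
            length = rng.normal(design.length_mean_cm[sp], design.length_sd_cm[sp])
            eff_f = rng.normal(0.0, design.subject_sd["peak_freq_hz"])
            eff_v = rng.normal(0.0, design.subject_sd["peak_vel_m_s"])
            for a in design.angles:
                f = (
                    design.freq_mean[(sp, a)]
                    + eff_f
                    + rng.normal(0.0, design.freq_se[(sp, a)] * math.sqrt(n_ref))
                )
                v = (
                    design.vel_mean[(sp, a)]
                    + eff_v
                    + rng.normal(0.0, design.vel_se[(sp, a)] * math.sqrt(n_ref))
                )
                rows.append(
                    dict(
                        subject_id=sid,
                        species=sp,
                        angle_deg=a,
                        peak_freq_hz=f,
                        peak_vel_m_s=v,
                        length_cm=length,
                    )
                )
    return pd.DataFrame(rows)
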