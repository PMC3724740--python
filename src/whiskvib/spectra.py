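"""Averaged-FFT analysis of laser-vibrometer velocity recordings.

The recording convention follows the study setup: point velocity on the
whisker shaft digitized at 1200 Hz for 6 s.  The spectral stage splits the
record into consecutive non-overlapping segments (default 240 samples,
i.e. 5 Hz resolution at 1200 Hz), computes a single-sided amplitude spectrum
per segment with a rectangular window, and averages amplitudes across
segments.  An on-bin sinusoid of amplitude A reads A at its bin.

Peak extraction takes the arg-max over bins, always excluding DC and
optionally excluding a frequency band (e.g. 0-50 Hz to reject the sting-mount
artifact).  A simple RMS-based dropout filter flags low-energy segments so
records with signal dropouts can be averaged over fewer segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VibrationRecording",
    "Spectrum",
    "PeakResult",
    "UnusableRecordingError",
    "averaged_fft",
    "peak_pick",
    "segment_quality_filter",
]


class UnusableRecordingError(ValueError):
    """Every segment of the recording failed the quality filter."""


@dataclass
class VibrationRecording:
    """A single-axis velocity time series (m/s) sampled uniformly."""

    samples: np.ndarray
    sample_rate: float  # Hz
    angle_deg: float | None = None
    subject_id: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class Spectrum:
    """Single-sided amplitude spectrum averaged over FFT segments."""

    frequencies: np.ndarray  # Hz, bin centers
    amplitude: np.ndarray  # m/s
    resolution: float  # Hz
    n_segments_averaged: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.frequencies.shape != self.amplitude.shape:
            raise ValueError("frequency and amplitude arrays must align")


@dataclass(frozen=True)
class PeakResult:
    peak_frequency: float  # Hz (a bin center)
    peak_velocity: float  # m/s
    excluded_band: tuple[float, float] | None = None


def averaged_fft(
    recording: VibrationRecording,
    nfft: int = 240,
    segment_indices: list[int] | None = None,
    window: str = "rectangular",
) -> Spectrum:
    """Average single-sided amplitude spectra over non-overlapping segments.

    Parameters
    ----------
    recording
        The velocity time series.
    nfft
        Segment length in samples; bin spacing is ``sample_rate / nfft``.
        The trailing remainder shorter than one segment is discarded.
    segment_indices
        Optional subset of segment indices to average (e.g. the usable list
        from :func:`segment_quality_filter`).  Default: all segments.
    window
        ``"rectangular"`` (default) or ``"hann"``.  The amplitude scaling is
        corrected for the window's coherent gain so an on-bin tone of
        amplitude A still reads A.
    """
    x = recording.samples
    if x.size < nfft:
        raise ValueError(
            f"recording of {x.size} samples is shorter than one {nfft}-sample segment"
        )
    n_total = x.size // nfft
    segs = x[: n_total * nfft].reshape(n_total, nfft)
    if segment_indices is not None:
        if len(segment_indices) == 0:
            raise UnusableRecordingError("no usable segments to average")
        segs = segs[np.asarray(segment_indices, dtype=int)]

    if window == "rectangular":
        w = np.ones(nfft)
    elif window == "hann":
        w = np.hanning(nfft)
    else:
        raise ValueError(f"unknown window {window!r}")
    gain = w.sum()  # coherent gain * nfft

    spec = np.abs(np.fft.rfft(segs * w, axis=1)) * (2.0 / gain)
    # DC (and Nyquist for even nfft) are not mirrored, so undo the doubling
    spec[:, 0] /= 2.0
    if nfft % 2 == 0:
        spec[:, -1] /= 2.0
    amp = spec.mean(axis=0)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / recording.sample_rate)
    return Spectrum(
        frequencies=freqs,
        amplitude=amp,
        resolution=recording.sample_rate / nfft,
        n_segments_averaged=segs.shape[0],
    )


def peak_pick(
    spectrum: Spectrum, exclude_band: tuple[float, float] | None = None
) -> PeakResult:
    """Arg-max of the averaged amplitude spectrum outside DC and any excluded band.

    Ties break toward the lower frequency.
    """
    if spectrum.frequencies.size == 0:
        raise ValueError("empty spectrum")
    mask = spectrum.frequencies > 0  # DC is never a vibration
    if exclude_band is not None:
        lo, hi = exclude_band
        mask &= ~((spectrum.frequencies >= lo) & (spectrum.frequencies <= hi))
    if not mask.any():
        raise ValueError("all frequency bins excluded from peak picking")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(spectrum.amplitude[idx])]  # argmax -> first max = lowest f
    return PeakResult(
        peak_frequency=float(spectrum.frequencies[best]),
        peak_velocity=float(spectrum.amplitude[best]),
        excluded_band=exclude_band,
    )


def segment_quality_filter(
    recording: VibrationRecording,
    dropout_threshold: float = 0.2,
    nfft: int = 240,
) -> tuple[list[int], list[int]]:
    """Flag dropout segments whose RMS falls below a fraction of the median RMS.

    Returns ``(usable, flagged)`` segment index lists.  Raises
    :class:`UnusableRecordingError` when nothing is usable (mirroring records
    dropped from the study for poor signal quality).
    """
    x = recording.samples
    if x.size < nfft:
        raise ValueError("recording shorter than one segment")
    n = x.size // nfft
    rms = np.sqrt(np.mean(x[: n * nfft].reshape(n, nfft) ** 2, axis=1))
    cutoff = dropout_threshold * np.median(rms)
    ok = rms > cutoff if cutoff > 0 else rms > 0
    usable = np.flatnonzero(ok).tolist()
    flagged = np.flatnonzero(~ok).tolist()
    if not usable:
        raise UnusableRecordingError(
            f"all {n} segments below the RMS dropout threshold"
        )
    return usable, flagged
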