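"""Gauge-voltage calibration and amplitude spectra of tracing vibrations.

A strain-gauge tactile sensor tracing a textured surface records a
voltage proportional to the vertical deflection of its leaf spring.  The
processing chain here is: (1) convert volts to micrometres of vertical
displacement with the sensor's linear calibration, (2) turn the
displacement trace into a single-sided, Hamming-windowed amplitude
spectrum whose peak bins report time-domain sinusoid amplitudes, and
(3) express amplitudes in dB re 1 um so they can be compared directly
with the dB-valued mechanoreceptor thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CAL_SLOPE",
    "CAL_INTERCEPT",
    "VibrationTrace",
    "SampleMetadata",
    "AmplitudeSpectrum",
    "strain_to_displacement",
    "compute_spectrum",
    "spectrum_to_db",
    "db_to_amplitude",
]

# Linear strain-gauge calibration d = CAL_SLOPE * V + CAL_INTERCEPT,
# d in micrometres, V in volts.
CAL_SLOPE = -1409.4
CAL_INTERCEPT = 710.35

#: dB value assigned to zero amplitude (log of zero is undefined).
DB_FLOOR = -120.0

DEFAULT_NFFT = 32768  # 2**15; covers a 3 s trace at 10 kHz with zero padding


@dataclass(frozen=True)
class VibrationTrace:
    """A sampled vibration time series in volts or micrometres."""

    sample_id: str
    repetition: int
    sampling_rate: float  # Hz
    values: np.ndarray
    unit: str = "volt"  # "volt" | "micrometer"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.values.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.unit not in ("volt", "micrometer"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.repetition < 1:
            raise ValueError("repetition must be >= 1")

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample physical measurements consumed as model inputs."""

    sample_id: str
    mu_prime: float  # dynamic friction coefficient, dimensionless
    ra_um: float | None = None  # arithmetic average roughness
    wa_um: float | None = None  # arithmetic average waviness
    normal_force_n: float | None = None

    def __post_init__(self) -> None:
        if self.mu_prime <= 0:
            raise ValueError("mu_prime must be positive")


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """Single-sided amplitude spectrum: um peak per bin vs Hz."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    window: str
    n_fft: int
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, float))
        if self.frequencies.shape != self.amplitudes.shape:
            raise ValueError("frequencies and amplitudes must align")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def df(self) -> float:
        """Bin spacing in Hz."""
        return float(self.frequencies[1] - self.frequencies[0])

    def to_db(self, ref: float = 1.0, floor: float = DB_FLOOR) -> np.ndarray:
        return spectrum_to_db(self, ref=ref, floor=floor)


def strain_to_displacement(trace: VibrationTrace) -> VibrationTrace:
    """Convert a voltage trace to vertical displacement in micrometres.

    Applies the sensor calibration d = -1409.4 V + 710.35 elementwise.
    A trace already in micrometres is returned unchanged with a warning.
    """
    if trace.unit == "micrometer":
        warnings.warn("trace already in micrometres; returning unchanged")
        return trace
    d = CAL_SLOPE * trace.values + CAL_INTERCEPT
    return replace(trace, values=d, unit="micrometer")


def compute_spectrum(
    trace: VibrationTrace,
    n_fft: int = DEFAULT_NFFT,
    *,
    mode: str = "center",
) -> AmplitudeSpectrum:
    """Mean-removed, Hamming-windowed single-sided amplitude spectrum.

    The trace is reduced to ``n_fft`` samples (``mode='center'`` keeps
    the central steady-state block, ``'head'`` the first block) or
    zero-padded if shorter; the mean is removed before windowing so the
    static preload of the calibration does not leak into bin 0.  The
    amplitude scaling divides by the window's coherent gain (its mean),
    so a pure sinusoid centred on a bin reports its time-domain amplitude.
    """
    if trace.unit != "micrometer":
        raise ValueError("compute_spectrum expects a displacement trace (micrometres)")
    if n_fft < 2:
        raise ValueError("n_fft must be >= 2")
    x = trace.values
    if x.size > n_fft:
        if mode == "center":
            start = (x.size - n_fft) // 2
        elif mode == "head":
            start = 0
        else:
            raise ValueError(f"unknown truncation mode {mode!r}")
        x = x[start : start + n_fft]
    x = x - x.mean()
    window = np.hamming(x.size)
    spec = np.fft.rfft(x * window, n=n_fft)
    # 2/sum(w) so that a bin-centred sinusoid of amplitude A reports A;
    # sum over the actual (possibly shorter) window, zero padding adds
    # no energy.
    amps = 2.0 * np.abs(spec) / window.sum()
    amps[0] /= 2.0  # DC is not mirrored
    if n_fft % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not mirrored either
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / trace.sampling_rate)
    return AmplitudeSpectrum(
        frequencies=freqs,
        amplitudes=amps,
        window="hamming",
        n_fft=n_fft,
        source_id=f"{trace.sample_id}:{trace.repetition}",
    )


def spectrum_to_db(
    spec: AmplitudeSpectrum, ref: float = 1.0, floor: float = DB_FLOOR
) -> np.ndarray:
    """20 log10(amplitude / ref); zero amplitudes map to ``floor``."""
    if ref <= 0:
        raise ValueError("reference amplitude must be positive")
    amps = spec.amplitudes
    out = np.full_like(amps, floor)
    nz = amps > 0
    out[nz] = 20.0 * np.log10(amps[nz] / ref)
    return np.maximum(out, floor)


def db_to_amplitude(db: np.ndarray | float, ref: float = 1.0) -> np.ndarray | float:
    """Inverse of :func:`spectrum_to_db` above the floor."""
    return ref * 10.0 ** (np.asarray(db, float) / 20.0)
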