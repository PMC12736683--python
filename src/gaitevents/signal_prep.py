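"""Shared resampling, filtering and differentiation primitives.

Every detector in this package consumes :class:`UniformSignal` objects and the
small set of operators below.  Conventions that matter for event *timing*:

* All Butterworth filtering is zero-phase (forward-backward, ``sosfiltfilt``)
  so that filtered extrema keep their locations; the quoted filter order is
  the per-pass design order, so effective attenuation order doubles.
* ``derivative`` is a central finite difference (one-sided at the ends), so a
  linear trend is differentiated exactly.
* ``cwt_gaussian_derivative`` is a single-scale continuous wavelet transform
  with a first-derivative-of-Gaussian wavelet, implemented as direct
  convolution with a sampled kernel.  The sign convention is chosen so that
  the output is positively proportional to a smoothed time derivative of the
  input (a rising step yields a single positive lobe).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import convolve1d as _nd_convolve1d
from scipy.ndimage import median_filter as _nd_median

from .errors import ParameterError, SignalTooShortError

__all__ = [
    "UniformSignal",
    "resample_to",
    "butter_lowpass",
    "median_filter",
    "derivative",
    "trapezoid_integrate",
    "cwt_gaussian_derivative",
    "gaussian_derivative_kernel",
]


@dataclass(frozen=True)
class UniformSignal:
    """A uniformly sampled real-valued channel.

    Sample ``k`` is located at time ``t0 + k / fs`` seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ParameterError("UniformSignal expects a 1-D sample array")
        if self.samples.size < 2:
            raise SignalTooShortError(
                f"signal {self.label!r} needs >= 2 samples, got {self.samples.size}"
            )

    def __len__(self) -> int:
        return self.samples.size

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return (self.samples.size - 1) / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "UniformSignal":
        return replace(self, samples=np.asarray(samples, dtype=float),
                       label=self.label if label is None else label)


def resample_to(signal: UniformSignal, fs_target: float,
                method: str = "linear_interpolation") -> UniformSignal:
    """Resample to ``fs_target``.

    ``linear_interpolation`` (for upsampling marker data) evaluates a linear
    interpolant on the new grid; ``polyphase`` (for downsampling IMU data)
    uses anti-aliased rational-ratio polyphase resampling.  ``t0`` is
    preserved and the duration changes by less than one output sample.
    """
    if fs_target <= 0:
        raise ParameterError("fs_target must be positive")
    if method not in ("linear_interpolation", "polyphase"):
        raise ParameterError(f"unknown resampling method {method!r}")
    if signal.samples.size < 2:
        raise SignalTooShortError("resampling needs at least 2 samples")
    if fs_target == signal.fs:
        return replace(signal)

    if method == "linear_interpolation":
        n_out = int(np.floor(signal.duration * fs_target)) + 1
        t_new = np.arange(n_out) / fs_target
        t_old = np.arange(signal.samples.size) / signal.fs
        out = np.interp(t_new, t_old, signal.samples)
        return UniformSignal(out, fs_target, signal.t0, signal.label)

    ratio = Fraction(fs_target / signal.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    # high-beta Kaiser window keeps the passband flat (DC ripple < 1e-5)
    out = sps.resample_poly(signal.samples, up, down, padtype="line",
                            window=("kaiser", 12.0))
    return UniformSignal(out, signal.fs * up / down, signal.t0, signal.label)


def butter_lowpass(signal: UniformSignal, cutoff: float, order: int = 4,
                   zero_phase: bool = True) -> UniformSignal:
    """Butterworth low-pass filter; ``zero_phase`` applies it forward-backward."""
    nyq = signal.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq} Hz)")
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    sos = sps.butter(order, cutoff, btype="low", fs=signal.fs, output="sos")
    if zero_phase:
        out = sps.sosfiltfilt(sos, signal.samples)
    else:
        out = sps.sosfilt(sos, signal.samples)
    return signal.with_samples(out)


def median_filter(signal: UniformSignal, order: int) -> UniformSignal:
    """Running median of odd window length ``order``; edges by reflection."""
    if order % 2 == 0 or order < 3:
        raise ParameterError(f"median filter order must be odd and >= 3, got {order}")
    out = _nd_median(signal.samples, size=order, mode="reflect")
    return signal.with_samples(out)


def derivative(signal: UniformSignal) -> UniformSignal:
    """First time derivative: central differences, one-sided at the ends."""
    if signal.samples.size < 3:
        raise SignalTooShortError("derivative needs at least 3 samples")
    out = np.gradient(signal.samples) * signal.fs
    return signal.with_samples(out, label=f"d({signal.label})/dt")


def trapezoid_integrate(signal: UniformSignal) -> UniformSignal:
    """Cumulative trapezoidal integral starting at 0.  No detrending and no
    drift correction is applied."""
    out = cumulative_trapezoid(signal.samples, dx=1.0 / signal.fs, initial=0.0)
    return signal.with_samples(out, label=f"int({signal.label})")


def gaussian_derivative_kernel(scale: float, truncate: float = 5.0) -> np.ndarray:
    """Sampled first-derivative-of-Gaussian wavelet kernel at ``scale`` samples.

    The kernel is ``h[m] = (-m / a) * exp(-m^2 / (2 a^2)) / (a^2 sqrt(2 pi))``
    for ``|m| <= truncate * a``; convolving a signal with it approximates the
    derivative per sample of the Gaussian-smoothed signal (positive for a
    rising input).
    """
    if scale < 1:
        raise ParameterError("wavelet scale must be >= 1 sample")
    half = int(np.ceil(truncate * scale))
    m = np.arange(-half, half + 1, dtype=float)
    h = (-m / scale) * np.exp(-(m ** 2) / (2.0 * scale ** 2))
    h /= scale ** 2 * np.sqrt(2.0 * np.pi)
    return h


def cwt_gaussian_derivative(signal: UniformSignal, scale: float) -> UniformSignal:
    """Single-scale CWT with a first-derivative-of-Gaussian ('gaus1') wavelet.

    Acts as a smoothing derivative operator: for a slowly varying input the
    output approximates ``dx/dt`` (units per second), with the Gaussian
    standard deviation equal to ``scale`` samples.  Output length equals the
    input length (reflect-padded convolution, so edges within ``5 * scale``
    samples of each end see a mirrored extension rather than zeros).
    """
    if scale < 1:
        raise ParameterError("wavelet scale must be >= 1 sample")
    if signal.samples.size < 10 * scale:
        raise ParameterError(
            f"signal of {signal.samples.size} samples is too short for "
            f"scale {scale} (needs >= {int(10 * scale)})")
    h = gaussian_derivative_kernel(scale)
    out = _nd_convolve1d(signal.samples, h, mode="reflect") * signal.fs
    return signal.with_samples(out, label=f"cwt({signal.label})")
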