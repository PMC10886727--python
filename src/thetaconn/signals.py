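"""Shared spectral-domain signal primitives.

All epochs in this package are short (2.5 s), so band-limiting is done by
multiplying the real FFT of each epoch by a real, non-negative gain curve and
inverting.  This is a zero-phase filter applied circularly; it has no group
delay and no start-up transient, which matters because a time-domain FIR with
comparable stopband attenuation would be longer than the epoch itself.
"""

from __future__ import annotations

import numpy as np

__all__ = ["band_gain", "shaped_gaussian", "rotate_phase", "analytic_signal"]


def band_gain(
    n_samples: int,
    fs: float,
    lo: float,
    hi: float,
    transition: float = 2.0,
) -> np.ndarray:
    """Real rFFT gain curve: exactly 1 on [lo, hi], raised-cosine rolloff to
    exactly 0 at lo - transition and hi + transition.

    Parameters
    ----------
    n_samples : epoch length in samples.
    fs : sampling rate in Hz.
    lo, hi : passband edges in Hz.
    transition : transition-band width in Hz on each side.

    Returns
    -------
    Gain per rFFT bin, shape (n_samples // 2 + 1,).
    """
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band ({lo}, {hi}) Hz must lie inside (0, fs/2) = (0, {fs / 2})")
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    ramp_lo = 0.5 * (1 - np.cos(np.pi * (freqs - (lo - transition)) / transition))
    ramp_hi = 0.5 * (1 + np.cos(np.pi * (freqs - hi) / transition))
    g = np.where(freqs < lo - transition, 0.0, np.where(freqs < lo, ramp_lo, 1.0))
    g = np.where(freqs > hi + transition, 0.0, np.where(freqs > hi, ramp_hi, g))
    return g


def apply_gain(data: np.ndarray, gain: np.ndarray) -> np.ndarray:
    """Apply an rFFT gain curve along the last axis (zero-phase, circular)."""
    n = data.shape[-1]
    return np.fft.irfft(np.fft.rfft(data, axis=-1) * gain, n=n, axis=-1)


def _gain_variance(gain: np.ndarray, n: int) -> float:
    # Expected variance of irfft(rfft(white) * gain) for unit-variance white input.
    g2 = gain**2
    if n % 2 == 0:
        return float((2 * g2[1:-1].sum() + g2[0] + g2[-1]) / n)
    return float((2 * g2[1:].sum() + g2[0]) / n)


def shaped_gaussian(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    gain: np.ndarray,
) -> np.ndarray:
    """Zero-mean Gaussian process with power spectrum |gain|^2, unit RMS.

    The normalisation uses the analytic expected variance (not the sample
    variance) so the output remains an exactly Gaussian process; this is what
    makes phase-randomised surrogates distributionally exchangeable with the
    generated data.
    """
    n = shape[-1]
    out = apply_gain(rng.standard_normal(shape), gain)
    var = _gain_variance(gain, n)
    if var <= 0:
        raise ValueError("gain curve is identically zero")
    return out / np.sqrt(var)


def pink_gain(n_samples: int, fs: float, exponent: float = 1.0) -> np.ndarray:
    """rFFT gain with 1/f^(exponent/2) amplitude rolloff (zero DC)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    g = np.zeros_like(freqs)
    g[1:] = freqs[1:] ** (-exponent / 2.0)
    return g


def analytic_signal(data: np.ndarray) -> np.ndarray:
    """FFT analytic signal along the last axis (negative frequencies zeroed)."""
    from scipy.signal import hilbert

    return hilbert(data, axis=-1)


def rotate_phase(data: np.ndarray, lag: float) -> np.ndarray:
    """Delay every spectral component of a real signal by `lag` radians.

    Implemented as Re(analytic(x) * exp(-i*lag)); for a narrowband signal this
    shifts the instantaneous phase by exactly `lag` at constant envelope.
    """
    return np.real(analytic_signal(data) * np.exp(-1j * lag))
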