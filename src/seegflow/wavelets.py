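"""Continuous wavelet transforms used across the pipeline.

Two analytic families are provided:

* generalized Morse wavelet (symmetry parameter gamma = 3, time-bandwidth
  product P^2 = beta*gamma = 60, i.e. beta = 20), evaluated directly from its
  closed-form frequency-domain expression
  ``psi_hat(w) = a * w**beta * exp(-w**gamma)`` on ``w > 0`` — the default
  throughout, with ten voices per octave when a dyadic grid is requested;
* complex Morlet, delegated to :mod:`pywt`, as an alternative estimator for
  the gamma-power time course.

Both return complex coefficients so magnitude and power are taken by the
caller.
"""

from __future__ import annotations

import numpy as np
import pywt

MORSE_GAMMA = 3.0
MORSE_BETA = 20.0  # time-bandwidth product 60 with gamma = 3


def morse_peak_omega(gamma: float = MORSE_GAMMA, beta: float = MORSE_BETA) -> float:
    """Angular frequency at which the Morse wavelet magnitude peaks."""
    return (beta / gamma) ** (1.0 / gamma)


def dyadic_frequencies(fs: float, f_min: float, voices_per_octave: int = 10,
                       f_max: float | None = None) -> np.ndarray:
    """Descending geometric frequency grid with the given voices/octave.

    Spans from just below ``f_max`` (default 0.85 * Nyquist, keeping the
    wavelet pass-band inside the sampled spectrum) down to above ``f_min``.
    """
    if f_max is None:
        f_max = 0.85 * fs / 2.0
    n_octaves = np.log2(f_max / f_min)
    k = np.arange(0, int(np.floor(n_octaves * voices_per_octave)) + 1)
    return f_max / 2.0 ** (k / voices_per_octave)


def _morse_filters(n: int, fs: float, freqs: np.ndarray,
                   gamma: float = MORSE_GAMMA,
                   beta: float = MORSE_BETA) -> np.ndarray:
    """Frequency-domain Morse filters, one row per requested peak frequency."""
    omega = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)
    wp = morse_peak_omega(gamma, beta)
    filters = np.zeros((len(freqs), n))
    pos = omega > 0
    # peak-normalized: psi_hat(omega_peak) = 2 (analytic convention)
    log_norm = np.log(2.0) - (beta / gamma) * (np.log(beta / gamma) - 1.0)
    for i, f in enumerate(np.asarray(freqs, dtype=float)):
        w = omega[pos] * (wp / (2.0 * np.pi * f))
        filters[i, pos] = np.exp(log_norm + beta * np.log(w) - w ** gamma)
    return filters


def cwt_morse(x: np.ndarray, fs: float, freqs: np.ndarray,
              gamma: float = MORSE_GAMMA, beta: float = MORSE_BETA) -> np.ndarray:
    """Morse CWT of ``x`` along its last axis.

    Returns a complex array of shape ``(len(freqs),) + x.shape``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    filt = _morse_filters(n, fs, freqs, gamma, beta)
    xf = np.fft.fft(x, axis=-1)
    # broadcast filters over leading axes of x
    shape = (len(freqs),) + (1,) * (x.ndim - 1) + (n,)
    return np.fft.ifft(xf[None] * filt.reshape(shape), axis=-1)


def cwt_morlet(x: np.ndarray, fs: float, freqs: np.ndarray,
               wavelet: str = "cmor1.5-1.0") -> np.ndarray:
    """Complex-Morlet CWT of ``x`` along its last axis (via pywt)."""
    x = np.asarray(x, dtype=float)
    scales = pywt.frequency2scale(wavelet, np.asarray(freqs, dtype=float) / fs)
    coeffs, _ = pywt.cwt(x, scales, wavelet, axis=-1)
    return coeffs


def cwt(x: np.ndarray, fs: float, freqs: np.ndarray,
        family: str = "morse") -> np.ndarray:
    """Dispatch on wavelet family ('morse' or 'morlet')."""
    if family == "morse":
        return cwt_morse(x, fs, freqs)
    if family == "morlet":
        return cwt_morlet(x, fs, freqs)
    raise ValueError(f"unknown wavelet family: {family!r}")
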