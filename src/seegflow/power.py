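"""Broadband-gamma power, lead classification, and threshold latencies.

Gamma power (50-150 Hz) is estimated per trial from a complex wavelet
decomposition at the ten 10-Hz sub-band centers (55, 65, ..., 145 Hz),
averaged across sub-bands, and averaged within non-overlapping 25 ms bins.
The trial-averaged time course per lead is z-scored against the 1 s
pre-onset baseline; responsive/selective leads and threshold-crossing
latency/duration are derived from the z traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PipelineConfig
from .core import TrialTensor
from .wavelets import cwt


@dataclass
class PowerTensor:
    """Binned gamma-power time courses.

    ``values`` is (lead, trial, bin) for raw power or (lead, bin) for
    baseline-z-scored trial averages; ``bin_times_ms`` are bin centers
    relative to static onset.
    """

    values: np.ndarray
    bin_times_ms: np.ndarray
    bin_ms: float
    band_hz: tuple
    kind: str = "raw"


@dataclass
class LeadClassification:
    responsive: bool
    selective: bool
    latency_ms: float
    duration_ms: float
    sep_peak_gender: float
    sep_peak_action: float
    vep_peak_gender: float


def band_center_frequencies(band_hz=(50.0, 150.0), width_hz=10.0) -> np.ndarray:
    """Centers of the adjacent sub-bands covering ``band_hz``."""
    lo, hi = band_hz
    return np.arange(lo + width_hz / 2.0, hi, width_hz)


def gamma_power_timecourse(tensor: TrialTensor,
                           cfg: PipelineConfig | None = None) -> PowerTensor:
    """Per-trial binned gamma power (raw, pre-z).

    Wavelet power is computed at the ten sub-band center frequencies with
    the configured family ('morse' default, 'morlet' optional), averaged
    over sub-bands, then averaged within non-overlapping 25 ms bins.
    Masked (lead, trial) combinations come out as NaN.
    """
    cfg = cfg or PipelineConfig()
    freqs = band_center_frequencies(cfg.gamma_band_hz)
    bin_len = int(round(cfg.power_bin_ms * tensor.fs / 1000.0))
    n_bins = tensor.n_samples // bin_len
    out = np.full((tensor.n_leads, tensor.n_trials, n_bins), np.nan)
    valid = tensor.valid_combination()
    chunk = 16
    for lead in range(tensor.n_leads):
        idx = np.flatnonzero(valid[lead])
        for start in range(0, idx.size, chunk):
            sel = idx[start:start + chunk]
            traces = tensor.data[lead, sel, :]
            traces = traces - traces.mean(axis=-1, keepdims=True)
            coeffs = cwt(traces, tensor.fs, freqs,
                         family=cfg.power_wavelet)
            power = (np.abs(coeffs) ** 2).mean(axis=0)  # (trial, time)
            binned = power[:, : n_bins * bin_len].reshape(
                len(sel), n_bins, bin_len
            ).mean(axis=-1)
            out[lead, sel, :] = binned
    centers = (np.arange(n_bins) + 0.5) * bin_len
    times = (centers - tensor.onset_index) * 1000.0 / tensor.fs
    return PowerTensor(values=out, bin_times_ms=times,
                       bin_ms=cfg.power_bin_ms, band_hz=cfg.gamma_band_hz)


def zscore_vs_baseline(power: PowerTensor,
                       baseline_window_s: tuple = (-1.0, 0.0),
                       trials: np.ndarray | None = None) -> PowerTensor:
    """Baseline-z-score the trial-averaged power time course per lead.

    ``trials`` optionally restricts the average (e.g. to one task).  A lead
    whose baseline SD is zero raises ``ValueError``.
    """
    vals = power.values
    if vals.ndim != 3:
        raise ValueError("expected raw (lead, trial, bin) power")
    if trials is not None:
        vals = vals[:, np.asarray(trials), :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_tc = np.nanmean(vals, axis=1)  # (lead, bin)
    t = power.bin_times_ms
    base = (t >= baseline_window_s[0] * 1000.0) & (t < baseline_window_s[1] * 1000.0)
    if not base.any():
        raise ValueError("baseline window outside the data")
    mu = mean_tc[:, base].mean(axis=1, keepdims=True)
    sd = mean_tc[:, base].std(axis=1, keepdims=True)
    # a dead or constant-power channel has no usable baseline spread
    degenerate = (sd == 0) | (sd < 1e-9 * np.abs(mu)) | (np.abs(mu) < 1e-30)
    if degenerate.any():
        bad = np.flatnonzero(degenerate[:, 0])
        raise ValueError(
            f"zero or degenerate baseline SD for lead(s) {bad.tolist()}"
        )
    return PowerTensor(values=(mean_tc - mu) / sd, bin_times_ms=t,
                       bin_ms=power.bin_ms, band_hz=power.band_hz, kind="z")


def latency_duration(z: np.ndarray, times_ms: np.ndarray,
                     threshold: float) -> tuple[float, float]:
    """First post-onset up-crossing of ``threshold`` and time to the next
    down-crossing, linearly interpolated between bins.

    Returns ``(nan, nan)`` when the trace never crosses.
    """
    z = np.asarray(z, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    latency = np.nan
    up_idx = None
    for i in range(1, len(z)):
        if z[i - 1] < threshold <= z[i]:
            frac = (threshold - z[i - 1]) / (z[i] - z[i - 1])
            t_cross = t[i - 1] + frac * (t[i] - t[i - 1])
            if t_cross >= 0:
                latency = t_cross
                up_idx = i
                break
    if up_idx is None:
        return (np.nan, np.nan)
    duration = np.nan
    for j in range(up_idx, len(z) - 1):
        if z[j] >= threshold > z[j + 1]:
            frac = (z[j] - threshold) / (z[j] - z[j + 1])
            duration = t[j] + frac * (t[j + 1] - t[j]) - latency
            break
    return (float(latency), float(duration))


def classify_lead(z_gender: np.ndarray,
                  z_action: np.ndarray | None,
                  times_ms: np.ndarray,
                  cfg: PipelineConfig | None = None,
                  video_epoch_ms: tuple | None = None) -> LeadClassification:
    """Responsive / selective classification of one lead.

    Responsive: gender-task z exceeds 3 during the static epoch (any bin).
    Selective: additionally the action-task static-epoch z stays at or below
    3 (task specificity) and the gender-task video-epoch z stays at or below
    3 (epoch specificity).  With the action task missing, only
    responsiveness is assessed (with a warning).
    """
    cfg = cfg or PipelineConfig()
    t = np.asarray(times_ms)
    sep = (t >= cfg.static_epoch_ms[0]) & (t < cfg.static_epoch_ms[1])
    if video_epoch_ms is None:
        video_epoch_ms = (cfg.static_epoch_ms[1] + 300.0, t.max())
    vep = (t >= video_epoch_ms[0]) & (t <= video_epoch_ms[1])

    sep_g = float(np.nanmax(z_gender[sep]))
    vep_g = float(np.nanmax(z_gender[vep])) if vep.any() else np.nan
    responsive = sep_g > cfg.responsive_z
    if z_action is None:
        warnings.warn("action task missing: selectivity not assessed")
        sep_a = np.nan
        selective = False
    else:
        sep_a = float(np.nanmax(z_action[sep]))
        selective = (responsive and sep_a <= cfg.responsive_z
                     and vep_g <= cfg.responsive_z)
    lat, dur = latency_duration(z_gender, t, threshold=2.0)
    return LeadClassification(
        responsive=bool(responsive), selective=bool(selective),
        latency_ms=lat, duration_ms=dur, sep_peak_gender=sep_g,
        sep_peak_action=sep_a, vep_peak_gender=vep_g,
    )


def gc_power_correlation(strengths: np.ndarray,
                         source_power: np.ndarray,
                         target_power: np.ndarray) -> dict:
    """Pearson correlation of connection strength C with source peak power,
    target peak power, and their product; NaN under zero variance."""
    C = np.asarray(strengths, dtype=float)
    if C.size < 3:
        raise ValueError("need >= 3 pairs")
    out = {}
    for name, x in (("source", np.asarray(source_power, float)),
                    ("target", np.asarray(target_power, float)),
                    ("product",
                     np.asarray(source_power, float) * np.asarray(target_power, float))):
        if np.std(x) == 0 or np.std(C) == 0:
            out[name] = np.nan
        else:
            out[name] = float(stats.pearsonr(C, x)[0])
    return out
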