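"""Pipeline configuration.

Every tunable parameter of the analysis chain lives here with an explicit
default, and the resolved configuration is serialized alongside every stage
output so that a result can always be traced back to the exact parameter set
that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline.

    Attributes
    ----------
    bivariate_reject_percentile : float
        Percentile of the bivariate-Gaussian reference used to threshold
        robust Mahalanobis distances in the feature-vector screen.  At 97.5
        the distance threshold is 2.7162.  Plausible per-dataset range 90-99.
    wavelet_low_cutoff_hz : float
        Blobs whose centroid frequency falls below this value never count as
        high-frequency transient outliers.
    wavelet_blob_percentile : float
        Pooled max-intensity percentile above which the largest-area blob of
        a (trial, lead) flags that combination.
    trial_reject_lead_threshold : int
        A trial tagged by a trial-based screen (coherent events, amplitude)
        is removed only if it contains more than this many feature-vector
        outlier leads.  Range 5-10.
    glitch_threshold_factor : float
        Scaled-MAD multiple for the glitch (coherent jump) screen.
    flatness_winlen, flatness_winstep, flatness_replen : int
        Window length / step (samples) and repetition count for the
        out-of-range (flat signal) screen.
    gc_window_samples : int
        Sliding-window length in samples at the base sampling rate (100
        samples = 100 ms at 1 kHz).
    gc_offset_samples : int
        Step between successive window starts.
    gc_lags : int
        VAR model order (number of lags); with sample spacing ns the maximum
        modelled delay is ``gc_lags * ns`` base samples.
    ns_factors : tuple of int
        Sample-spacing settings; 1/2/4 give maximum delays 4/8/16 ms at
        1 kHz with 4 lags.
    n_bootstrap, n_surrogate : int
        Number of trial-resampled / trial-permuted recomputations.
    strong_z, medium_z : float
        z thresholds for strong connections (typing, via-leads) and for the
        conditioning screen.
    strength_window_s : tuple
        Response interval, seconds after static onset, over which the signed
        strength C is taken.
    baseline_window_s : tuple
        Baseline interval relative to onset used for z-scoring GC traces.
    gamma_band_hz : tuple
        Broadband-gamma range, analysed as ten adjacent 10-Hz sub-bands.
    power_bin_ms : float
        Non-overlapping binning of the gamma-power time course.
    power_wavelet : str
        'morlet' (default; the short-support estimator behind the latency
        and classification analysis) or 'morse' (the long time-bandwidth
        family used in artifact screening).
    responsive_z : float
        z threshold on the static-epoch gamma response defining a
        responsive lead.
    static_epoch_ms : tuple
        Static epoch (SEp) relative to onset, ms.
    onset_search_window_ms : tuple
        Region in which the 50 %-of-peak onset estimator looks for the peak.
    min_common_trials : int
        Pairs with fewer common valid trials than this are skipped.
    """

    bivariate_reject_percentile: float = 97.5
    wavelet_low_cutoff_hz: float = 10.0
    wavelet_blob_percentile: float = 95.0
    trial_reject_lead_threshold: int = 5
    glitch_threshold_factor: float = 5.0
    flatness_winlen: int = 100
    flatness_winstep: int = 50
    flatness_replen: int = 3
    gc_window_samples: int = 100
    gc_offset_samples: int = 10
    gc_lags: int = 4
    ns_factors: tuple = (1, 2, 4)
    n_bootstrap: int = 20
    n_surrogate: int = 20
    strong_z: float = 5.0
    medium_z: float = 3.0
    strength_window_s: tuple = (0.1, 0.4)
    baseline_window_s: tuple = (-0.9, 0.0)
    gamma_band_hz: tuple = (50.0, 150.0)
    power_bin_ms: float = 25.0
    power_wavelet: str = "morlet"
    responsive_z: float = 3.0
    static_epoch_ms: tuple = (75.0, 275.0)
    onset_search_window_ms: tuple = (50.0, 500.0)
    min_common_trials: int = 12
    min_trials_mcd: int = 10
    amplitude_outlier_mad: float = 3.0
    welch_nperseg: int = 256
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.bivariate_reject_percentile < 100:
            raise ValueError("bivariate_reject_percentile must be in (0, 100)")
        if self.gc_lags < 1:
            raise ValueError("gc_lags must be >= 1")
        if self.gc_window_samples <= self.gc_lags * max(self.ns_factors):
            raise ValueError("gc_window_samples too short for the lag order")
        for name in ("ns_factors", "strength_window_s", "baseline_window_s",
                     "gamma_band_hz", "static_epoch_ms",
                     "onset_search_window_ms"):
            setattr(self, name, tuple(getattr(self, name)))

    def max_delay_ms(self, ns_factor: int, fs: float = 1000.0) -> float:
        """Maximum modelled causal delay for a sample-spacing setting."""
        return self.gc_lags * ns_factor * 1000.0 / fs

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)
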