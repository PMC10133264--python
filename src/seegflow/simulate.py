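"""Synthetic trial-tensor generator with known ground truth.

Emulates the statistical structure the analysis chain assumes: a stationary
1 s pre-onset baseline, brief task-gated broadband-gamma bursts shortly
after static onset, and directed lead-to-lead couplings realized as gated
vector-autoregressive (VAR) terms

    x_target[t] += gain * x_source[t - lag]

active only inside a window relative to onset and only for trials of the
gated task.  Because the couplings are genuine VAR terms, the Granger engine's
model class matches the generator in the ideal case and closed-form oracles
stay valid.  Every non-noise structure placed in the tensor is recorded in a
:class:`GroundTruth` object, making recovery tests possible.

Artifacts of each class the rejection pipeline targets can be injected with
exact placement records: single-combination amplitude outliers, narrow-band
gamma blobs, coherent cross-lead transients (interictal-like), coherent
glitch steps, and flat (saturated) segments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import TrialTensor

TASKS = ("gender", "action")
STATIC_DURATIONS_MS = (283.0, 458.0, 583.0, 733.0, 883.0)

ARTIFACT_KINDS = ("amplitude_outlier", "gamma_blob", "interictal_coherent",
                  "glitch", "flat_segment")


@dataclass
class CouplingSpec:
    """A directed causal influence between two leads.

    ``lag_ms`` must be an integer number of samples at the simulation
    sampling rate.  ``gain`` is the unitless VAR coefficient.  The coupling
    is applied only inside ``window_s`` (seconds relative to onset) and, if
    ``task_gate`` is set, only on trials of that task.
    """

    source: int
    target: int
    lag_ms: float
    gain: float
    task_gate: str | None = "gender"
    window_s: tuple = (0.1, 0.4)


@dataclass
class BurstSpec:
    """A broadband-gamma response burst on one lead.

    The burst is 50-150 Hz band-limited Gaussian noise (unit variance)
    multiplied by a raised-cosine envelope of the stated onset/duration and
    scaled by ``amplitude`` (in units of the background noise SD).
    """

    lead: int
    onset_ms: float = 170.0
    duration_ms: float = 120.0
    amplitude: float = 1.0
    task_gate: str | None = "gender"
    band_hz: tuple = (50.0, 150.0)


@dataclass
class ArtifactSpec:
    """One injectable artifact.  Unset placement fields are drawn at random
    (within bounds) at injection time; the resolved placement is recorded in
    the returned ground truth."""

    kind: str
    trial: int | None = None
    lead: int | None = None
    start_ms: float | None = None   # relative to static onset
    duration_ms: float = 200.0
    amplitude: float = 10.0         # scale factor / multiples of trace SD
    freq_hz: float = 80.0           # gamma_blob center frequency
    lead_fraction: float = 0.8      # interictal_coherent: fraction of leads

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind: {self.kind!r}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow the recorded regime the pipeline targets: 1 kHz
    sampling, 1 s baseline + 1 s post-onset segments, two tasks with equal
    trial counts, white unit-variance lead noise, and task-specific bursts
    ~170 ms after onset lasting ~120 ms.
    """

    n_leads: int = 6
    n_trials_per_task: int = 40
    fs: float = 1000.0
    baseline_s: float = 1.0
    post_onset_s: float = 1.0
    noise_sd: float = 1.0
    pink_fraction: float = 0.0      # optional 1/f noise admixture (0..1)
    couplings: list = field(default_factory=list)
    bursts: list = field(default_factory=list)


@dataclass
class GroundTruth:
    """Complete record of injected structure, the recovery-test oracle."""

    couplings: list = field(default_factory=list)
    artifacts: list = field(default_factory=list)
    response_onset_ms: dict = field(default_factory=dict)
    response_duration_ms: dict = field(default_factory=dict)
    rng_seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "couplings": [dataclasses.asdict(c) for c in self.couplings],
            "artifacts": [dataclasses.asdict(a) for a in self.artifacts],
            "response_onset_ms": dict(self.response_onset_ms),
            "response_duration_ms": dict(self.response_duration_ms),
            "rng_seed": self.rng_seed,
        }


def _bandlimited_noise(rng, n, fs, band):
    """Unit-variance Gaussian noise band-passed to ``band`` (Hz)."""
    lo, hi = band
    hi = min(hi, 0.499 * fs)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _raised_cosine(n):
    """Hann-shaped envelope of length n (smooth rise and fall)."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def _make_trial_labels(cfg: SimConfig, rng) -> "pd.DataFrame":
    import pandas as pd

    n = cfg.n_trials_per_task
    tasks, truncation, static, rt = [], [], [], []
    for i in range(2 * n):
        tasks.append(TASKS[i % 2])
        truncation.append("full" if (i // 2) % 2 == 0 else "truncated")
        static.append(STATIC_DURATIONS_MS[i % len(STATIC_DURATIONS_MS)])
        rt.append(static[-1] + rng.uniform(550.0, 950.0))
    return pd.DataFrame(
        {"task": tasks, "truncation": truncation,
         "static_duration_ms": static, "response_time_ms": rt}
    )


def simulate_dataset(cfg: SimConfig, seed: int) -> tuple[TrialTensor, GroundTruth]:
    """Generate one synthetic dataset; deterministic given ``seed``.

    Raises ``ValueError`` if any coupling lag is not an integer number of
    samples at ``cfg.fs`` (the caller must choose representable lags).
    """
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    n_base = int(round(cfg.baseline_s * fs))
    n_post = int(round(cfg.post_onset_s * fs))
    n_samp = n_base + n_post
    n_trials = 2 * cfg.n_trials_per_task
    shape = (cfg.n_leads, n_trials, n_samp)

    for c in cfg.couplings:
        lag = c.lag_ms * fs / 1000.0
        if abs(lag - round(lag)) > 1e-9:
            raise ValueError(
                f"coupling lag {c.lag_ms} ms is not an integer number of "
                f"samples at fs={fs}"
            )

    labels = _make_trial_labels(cfg, rng)
    x = rng.standard_normal(shape) * cfg.noise_sd
    if cfg.pink_fraction > 0:
        # 1/f admixture shaped in the frequency domain
        freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
        gain = np.zeros_like(freqs)
        gain[1:] = 1.0 / np.sqrt(freqs[1:])
        pink = np.fft.irfft(
            np.fft.rfft(rng.standard_normal(shape), axis=-1) * gain, n_samp,
            axis=-1,
        )
        pink *= cfg.noise_sd / pink.std()
        x = (1 - cfg.pink_fraction) * x + cfg.pink_fraction * pink

    gt = GroundTruth(rng_seed=seed)

    # -- bursts --------------------------------------------------------
    for b in cfg.bursts:
        n_dur = int(round(b.duration_ms * fs / 1000.0))
        i0 = n_base + int(round(b.onset_ms * fs / 1000.0))
        env = _raised_cosine(n_dur)
        sel = np.flatnonzero(
            (labels["task"] == b.task_gate) if b.task_gate else
            np.ones(n_trials, bool)
        )
        for tr in sel:
            carrier = _bandlimited_noise(rng, n_dur, fs, b.band_hz)
            x[b.lead, tr, i0:i0 + n_dur] += (
                b.amplitude * cfg.noise_sd * env * carrier
            )
        gt.response_onset_ms[int(b.lead)] = float(b.onset_ms)
        gt.response_duration_ms[int(b.lead)] = float(b.duration_ms)
    gt.couplings = list(cfg.couplings)

    # -- gated VAR couplings, applied in time order --------------------
    if cfg.couplings:
        active = []
        for c in cfg.couplings:
            lag = int(round(c.lag_ms * fs / 1000.0))
            t0 = n_base + int(round(c.window_s[0] * fs))
            t1 = n_base + int(round(c.window_s[1] * fs))
            sel = np.flatnonzero(
                (labels["task"] == c.task_gate) if c.task_gate else
                np.ones(n_trials, bool)
            )
            active.append((c, lag, t0, t1, sel))
        tmin = min(a[2] for a in active)
        tmax = max(a[3] for a in active)
        for t in range(max(tmin, 0), min(tmax, n_samp)):
            for c, lag, t0, t1, sel in active:
                if t0 <= t < t1 and t - lag >= 0:
                    x[c.target, sel, t] += c.gain * x[c.source, sel, t - lag]

    tensor = TrialTensor(
        data=x, fs=fs, onset_index=n_base, trial_labels=labels
    )
    return tensor, gt


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(tensor: TrialTensor, specs: list[ArtifactSpec],
                     seed: int) -> tuple[TrialTensor, GroundTruth]:
    """Return a modified copy of ``tensor`` plus the exact placement record.

    Raises ``ValueError`` if a flat segment and a glitch would overlap on the
    same sample of the same trial (the classes must remain separable for
    testing).
    """
    rng = np.random.default_rng(seed)
    out = tensor.copy()
    fs = out.fs
    n_leads, n_trials, n_samp = out.data.shape
    gt = GroundTruth(rng_seed=seed)
    glitch_samples: dict[int, set] = {}
    flat_ranges: dict[int, list] = {}

    for spec in specs:
        s = dataclasses.replace(spec)
        if s.trial is None:
            s.trial = int(rng.integers(n_trials))
        if s.lead is None and s.kind in ("amplitude_outlier", "gamma_blob",
                                         "flat_segment"):
            s.lead = int(rng.integers(n_leads))
        n_dur = int(round(s.duration_ms * fs / 1000.0))
        if s.start_ms is None:
            lo = -tensor.onset_index
            hi = (n_samp - tensor.onset_index - n_dur - 1)
            s.start_ms = float(rng.integers(lo, max(hi, lo + 1))) * 1000.0 / fs
        i0 = tensor.onset_index + int(round(s.start_ms * fs / 1000.0))
        i0 = int(np.clip(i0, 0, n_samp - 1))
        i1 = min(i0 + n_dur, n_samp)

        if s.kind == "amplitude_outlier":
            out.data[s.lead, s.trial, :] *= s.amplitude
        elif s.kind == "gamma_blob":
            trace_sd = out.data[s.lead, s.trial, :].std()
            n_b = i1 - i0
            carrier = _bandlimited_noise(
                rng, n_b, fs, (s.freq_hz - 10.0, s.freq_hz + 10.0)
            )
            out.data[s.lead, s.trial, i0:i1] += (
                s.amplitude * trace_sd * _raised_cosine(n_b) * carrier
            )
        elif s.kind == "interictal_coherent":
            n_aff = max(2, int(round(s.lead_fraction * n_leads)))
            leads = rng.choice(n_leads, size=n_aff, replace=False)
            n_b = i1 - i0
            waveform = _bandlimited_noise(rng, n_b, fs, (4.0, 15.0))
            waveform *= _raised_cosine(n_b)
            sd = np.median(out.data[:, s.trial, :].std(axis=-1))
            for ld in np.sort(leads):
                out.data[ld, s.trial, i0:i1] += (
                    s.amplitude * sd * rng.uniform(0.7, 1.3) * waveform
                )
            s.lead = None
        elif s.kind == "glitch":
            if any(lo <= i0 < hi
                   for lo, hi in flat_ranges.get(s.trial, [])):
                raise ValueError(
                    "glitch overlaps a flat segment on the same sample"
                )
            sd = np.median(out.data[:, s.trial, :].std(axis=-1))
            out.data[:, s.trial, i0:] += s.amplitude * sd
            glitch_samples.setdefault(s.trial, set()).add(i0)
        elif s.kind == "flat_segment":
            if any(i0 <= g < i1 for g in glitch_samples.get(s.trial, set())):
                raise ValueError(
                    "flat segment overlaps a glitch on the same sample"
                )
            out.data[s.lead, s.trial, i0:i1] = out.data[s.lead, s.trial, i0]
            flat_ranges.setdefault(s.trial, []).append((i0, i1))
        gt.artifacts.append(s)

    return out, gt
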