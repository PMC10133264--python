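"""Ground-truth recovery experiments on synthetic data.

Each function builds a synthetic dataset under the package's default study
conditions, runs the relevant part of the analysis chain, and measures
recovery against the generator's ground truth.  The functions return raw
measurements; judgements (thresholds, tolerances) belong to the caller.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import granger, power, rejection, timing
from .config import PipelineConfig
from .simulate import (ArtifactSpec, BurstSpec, CouplingSpec, SimConfig,
                       inject_artifacts, simulate_dataset)


def _gender_trials(tensor):
    return np.flatnonzero(tensor.trial_labels["task"] == "gender")


def surrogate_false_positive_rate(seed: int,
                                  cfg: PipelineConfig | None = None) -> dict:
    """Fraction of windows with surrogate z > 3 on an uncoupled lead pair
    (both directions pooled)."""
    cfg = cfg or PipelineConfig()
    tensor, _ = simulate_dataset(SimConfig(n_leads=2, n_trials_per_task=20),
                                 seed)
    trials = granger.select_pair_trials(tensor, (0, 1),
                                        cfg.min_common_trials)
    fw, bw = granger.pairwise_ugc(tensor, (0, 1), 1, cfg, trials)
    granger.surrogate_normalize(tensor, (fw, bw), 1, cfg,
                                np.random.default_rng(seed), trials)
    z = np.concatenate([fw.surrogate_z, bw.surrogate_z])
    return {"rate": float(np.nanmean(z > 3.0)), "n_windows": int(z.size)}


def delay_recovery(seed: int, cfg: PipelineConfig | None = None) -> dict:
    """Strengths for a short-lag (2 ms) and a long-lag (12 ms) coupling.

    Returns forward/reverse C at NS1 for the 2 ms coupling and the
    (C_ns1, C_ns4) pair plus type for the 12 ms coupling.
    """
    cfg = cfg or PipelineConfig()
    out = {}
    for label, lag in (("short", 2.0), ("long", 12.0)):
        sim = SimConfig(n_leads=2, n_trials_per_task=20,
                        couplings=[CouplingSpec(0, 1, lag, 0.4)])
        tensor, _ = simulate_dataset(sim, seed)
        trials = granger.select_pair_trials(
            tensor, (0, 1), cfg.min_common_trials,
            trials=_gender_trials(tensor))
        C = {}
        for direction, pair in (("fw", (0, 1)), ("bw", (1, 0))):
            for ns in (1, 4):
                fw, _ = granger.pairwise_ugc(tensor, pair, ns, cfg, trials)
                granger.baseline_zscore_gc(fw, tensor, cfg)
                C[(direction, ns)] = granger.connection_strength(
                    fw.baseline_z, fw.times_ms, cfg.strength_window_s,
                    fw.window_len_ms)
        out[label] = {
            "C_ns1_fw": C[("fw", 1)], "C_ns1_bw": C[("bw", 1)],
            "C_ns4_fw": C[("fw", 4)], "C_ns4_bw": C[("bw", 4)],
            "type_fw": granger.classify_connection(
                C[("fw", 1)], C[("fw", 4)], cfg.strong_z),
        }
    return out


def conditioning_recovery(seed: int,
                          cfg: PipelineConfig | None = None) -> dict:
    """Common-driver motif: Z drives X (2 ms) and Y (4 ms), no X->Y link.

    Measures the spurious unconditioned X->Y peak z, the conditioned peak z
    given the driver and given an independent lead, and the screen's output
    over both candidates.
    """
    cfg = cfg or PipelineConfig()
    sim = SimConfig(n_leads=4, n_trials_per_task=20, couplings=[
        CouplingSpec(2, 0, 2.0, 0.9), CouplingSpec(2, 1, 4.0, 0.9)])
    tensor, _ = simulate_dataset(sim, seed)
    trials = granger.select_pair_trials(tensor, (0, 1),
                                        cfg.min_common_trials,
                                        trials=_gender_trials(tensor))
    fw, _ = granger.pairwise_ugc(tensor, (0, 1), 1, cfg, trials)
    granger.baseline_zscore_gc(fw, tensor, cfg)
    sel = granger._response_window_mask(fw, cfg)
    idx = np.flatnonzero(sel)[np.nanargmax(fw.baseline_z[sel])]
    rng = np.random.default_rng(seed)
    cond_driver = granger.conditioned_gc(tensor, (0, 1), 2, 1, cfg, rng,
                                         trials=trials)
    cond_indep = granger.conditioned_gc(tensor, (0, 1), 3, 1, cfg, rng,
                                        trials=trials)
    screen = granger.conditioning_screen(tensor, (0, 1), [2, 3], cfg,
                                         np.random.default_rng(seed),
                                         trials=trials)
    return {
        "spurious_peak_z": granger.peak_response_z(fw, cfg),
        "z_given_driver": float(cond_driver.baseline_z[idx]),
        "z_given_independent": float(cond_indep.baseline_z[idx]),
        "screen": screen,
        "driver": 2,
    }


_ARTIFACT_PLAN = [
    ArtifactSpec("amplitude_outlier", trial=1, lead=0, amplitude=10.0),
    ArtifactSpec("amplitude_outlier", trial=9, lead=2, amplitude=10.0),
    ArtifactSpec("amplitude_outlier", trial=15, lead=4, amplitude=10.0),
    ArtifactSpec("gamma_blob", trial=4, lead=1, start_ms=-300.0,
                 amplitude=10.0, freq_hz=80.0, duration_ms=200.0),
    ArtifactSpec("gamma_blob", trial=20, lead=3, start_ms=-100.0,
                 amplitude=10.0, freq_hz=80.0, duration_ms=200.0),
    ArtifactSpec("gamma_blob", trial=33, lead=5, start_ms=100.0,
                 amplitude=10.0, freq_hz=80.0, duration_ms=200.0),
    ArtifactSpec("interictal_coherent", trial=7, start_ms=-400.0,
                 amplitude=8.0, duration_ms=300.0, lead_fraction=0.8),
    ArtifactSpec("interictal_coherent", trial=26, start_ms=200.0,
                 amplitude=8.0, duration_ms=300.0, lead_fraction=0.8),
    ArtifactSpec("glitch", trial=12, start_ms=-200.0, amplitude=50.0),
    ArtifactSpec("flat_segment", trial=18, lead=0, start_ms=-600.0,
                 duration_ms=500.0),
    ArtifactSpec("flat_segment", trial=31, lead=5, start_ms=0.0,
                 duration_ms=500.0),
]


def artifact_recovery(seed: int, cfg: PipelineConfig | None = None) -> dict:
    """Per-class detection sensitivity for injected artifacts plus the
    clean-data (lead, trial) false-positive fraction of the combined mask."""
    cfg = cfg or PipelineConfig()
    clean, _ = simulate_dataset(SimConfig(n_leads=6, n_trials_per_task=20),
                                seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, clean_mask, _ = rejection.reject(clean, cfg,
                                            np.random.default_rng(seed))
    fp = float(clean_mask.combined.mean())

    dirty, gt = inject_artifacts(clean, _ARTIFACT_PLAN, seed)
    det = rejection.detrend_tensor(dirty)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fv = rejection.feature_vector_outliers(
            det, cfg.bivariate_reject_percentile, cfg)
        wav = rejection.wavelet_blob_outliers(
            det, cfg.wavelet_low_cutoff_hz, cfg.wavelet_blob_percentile)
        ied = rejection.interictal_trial_detector(
            det, rng=np.random.default_rng(seed))
        gli = rejection.glitch_detector(det, cfg.glitch_threshold_factor)
        fla = rejection.flatness_detector(
            dirty, cfg.flatness_winlen, cfg.flatness_winstep,
            cfg.flatness_replen)

    hits = {k: [] for k in ("amplitude_outlier", "gamma_blob",
                            "interictal_coherent", "glitch", "flat_segment")}
    for a in gt.artifacts:
        if a.kind == "amplitude_outlier":
            hits[a.kind].append(bool(fv[a.lead, a.trial]))
        elif a.kind == "gamma_blob":
            hits[a.kind].append(bool(wav[a.lead, a.trial]))
        elif a.kind == "interictal_coherent":
            hits[a.kind].append(a.trial in ied)
        elif a.kind == "glitch":
            hits[a.kind].append(a.trial in gli)
        elif a.kind == "flat_segment":
            hits[a.kind].append(bool(fla[a.lead, a.trial]))
    out = {f"sensitivity_{k}": float(np.mean(v)) for k, v in hits.items()}
    out["n_injected"] = {k: len(v) for k, v in hits.items()}
    out["clean_false_positive_fraction"] = fp
    return out


def latency_recovery(seed: int, onset_a_ms: float = 150.0,
                     onset_b_ms: float = 190.0,
                     cfg: PipelineConfig | None = None):
    """Recover a known onset difference between two responsive leads from
    single-trial gamma-power traces via the bootstrap onset comparison."""
    cfg = cfg or PipelineConfig()
    sim = SimConfig(n_leads=2, n_trials_per_task=30, bursts=[
        BurstSpec(lead=0, onset_ms=onset_a_ms, duration_ms=120.0,
                  amplitude=4.0),
        BurstSpec(lead=1, onset_ms=onset_b_ms, duration_ms=120.0,
                  amplitude=4.0),
    ])
    tensor, _ = simulate_dataset(sim, seed)
    p = power.gamma_power_timecourse(tensor, cfg)
    g = _gender_trials(tensor)
    # per-trial traces z-scored against each trial's own baseline spread
    base = p.bin_times_ms < 0
    traces = []
    for lead in (0, 1):
        tr = p.values[lead, g, :]
        mu = tr[:, base].mean(axis=1, keepdims=True)
        sd = tr[:, base].std(axis=1, keepdims=True)
        traces.append((tr - mu) / sd)
    return timing.onset_difference_bootstrap(
        traces[0], traces[1], p.bin_times_ms, n_boot=100, seed=seed,
        search_window_ms=cfg.onset_search_window_ms, peak_z_min=None)
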