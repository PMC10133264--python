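"""Multi-pronged trial/lead artifact rejection.

Granger causality is computed on single-trial traces, so it is far more
sensitive to artifacts than trial-averaged power.  Six complementary screens
are applied, each targeting an artifact class visible in intracranial
recordings:

1. feature-vector outliers — per lead, a robust (minimum covariance
   determinant) Mahalanobis screen on [log high-gamma power, log SD] of each
   trial; the threshold is the bivariate-Gaussian reference distance for a
   chosen percentile (2.7162 at 97.5 %);
2. wavelet blobs — transient high-frequency oscillatory events found as the
   largest-area connected component in a binarized Morse scalogram, flagged
   when its centroid frequency and pooled max intensity are both high;
3. putative interictal events — trials whose cross-lead maximum-correlation
   histogram is an outlier cluster under earth-mover distance + fuzzy
   c-means;
4. trial amplitude outliers — robust dispersion rule on the per-trial peak
   absolute value across all leads;
5. glitches — coherent one-sample jumps across leads;
6. out-of-range (flat) segments — extended runs of near-constant signal.

Trial-based screens (3, 4) only remove a whole trial when it also contains
more than a configurable number of feature-vector outlier leads; glitch
trials are removed unconditionally.  All (trial, lead)-based flags are
combined by set union.

All screens except flatness run on linearly detrended traces; flatness uses
the raw data because detrending perturbs exact constancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from sklearn.covariance import MinCovDet

from .config import PipelineConfig
from .core import TrialTensor
from .wavelets import cwt_morse, dyadic_frequencies

_MAD_SCALE = 1.4826  # scaled MAD: consistent with SD under a Gaussian


@dataclass
class BlobFeature:
    """Largest-area connected component of one binarized scalogram."""

    lead: int
    trial: int
    area: int
    centroid_freq_hz: float
    centroid_time_ms: float
    bounding_box: tuple
    mean_intensity: float
    max_intensity: float


@dataclass
class RejectionMask:
    """Per-criterion and combined rejection state.

    ``per_criterion`` maps criterion name to a boolean (lead, trial) mask
    for combination-based screens, or to a set of trial indices for
    trial-based screens.  ``combined`` is the union over kept trials plus
    all leads of removed trials.
    """

    per_criterion: dict
    removed_trials: set
    combined: np.ndarray


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def detrend_trial(series: np.ndarray) -> np.ndarray:
    """Residual of the least-squares line fit to a single trace."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("trace must have at least 2 samples")
    return signal.detrend(series, type="linear")


def detrend_tensor(tensor: TrialTensor) -> TrialTensor:
    """Linearly detrend every (lead, trial) trace (masked traces left as-is)."""
    out = tensor.copy()
    out.data = signal.detrend(out.data, axis=-1, type="linear")
    invalid = ~tensor.valid_combination()
    out.data[invalid] = tensor.data[invalid]
    return out


# ---------------------------------------------------------------------------
# 1. feature-vector outliers
# ---------------------------------------------------------------------------

def mahalanobis_threshold(percentile: float) -> float:
    """Bivariate-Gaussian Mahalanobis distance below which ``percentile`` %
    of samples lie (sqrt of the chi-square quantile with 2 d.f.); 2.7162 at
    97.5 %."""
    return float(np.sqrt(stats.chi2.ppf(percentile / 100.0, df=2)))


def feature_vector_outliers(tensor: TrialTensor,
                            percentile: float = 97.5,
                            cfg: PipelineConfig | None = None) -> np.ndarray:
    """Robust bivariate outlier screen, per lead.

    For each lead the per-trial feature vector is [log band power summed
    over 50-150 Hz (Welch), log SD over time]; components below 1e-42 are
    dropped before the logs.  Center/covariance are estimated by minimum
    covariance determinant and trials beyond the reference distance for
    ``percentile`` are flagged.  Leads with fewer valid trials than the
    robust-estimator minimum are skipped with a warning.
    """
    cfg = cfg or PipelineConfig()
    thr = mahalanobis_threshold(percentile)
    valid = tensor.valid_combination()
    flags = np.zeros((tensor.n_leads, tensor.n_trials), dtype=bool)
    lo, hi = cfg.gamma_band_hz
    nperseg = min(cfg.welch_nperseg, tensor.n_samples)
    for lead in range(tensor.n_leads):
        idx = np.flatnonzero(valid[lead])
        if idx.size < cfg.min_trials_mcd:
            warnings.warn(
                f"lead {lead}: only {idx.size} valid trials, "
                "feature-vector screen skipped"
            )
            continue
        traces = tensor.data[lead, idx, :]
        freqs, psd = signal.welch(traces, fs=tensor.fs, nperseg=nperseg,
                                  axis=-1)
        band = (freqs >= lo) & (freqs <= hi)
        power = psd[:, band].sum(axis=-1)
        sd = traces.std(axis=-1)
        usable = (power >= 1e-42) & (sd >= 1e-42)
        if usable.sum() < cfg.min_trials_mcd:
            warnings.warn(f"lead {lead}: too few usable trials for MCD")
            continue
        X = np.column_stack([np.log(power[usable]), np.log(sd[usable])])
        try:
            # support 0.9: efficient at modest per-lead trial counts while
            # tolerating the ~10 % contamination artifacts produce
            mcd = MinCovDet(support_fraction=0.9,
                            random_state=cfg.rng_seed).fit(X)
        except Exception as exc:  # singular feature cloud
            warnings.warn(f"lead {lead}: MCD failed ({exc}); screen skipped")
            continue
        d2 = mcd.mahalanobis(X)
        # finite-sample calibration: robust distances of clean bivariate
        # Gaussian data should have median chi2_{0.5}(2); rescale so the
        # nominal percentile keeps its meaning at small trial counts
        med = np.median(d2)
        if med > 0:
            d2 = d2 * (stats.chi2.ppf(0.5, df=2) / med)
        flags[lead, idx[usable]] = np.sqrt(d2) > thr
    return flags


# ---------------------------------------------------------------------------
# 2. wavelet blobs
# ---------------------------------------------------------------------------

def _largest_blob(image: np.ndarray, freqs: np.ndarray, fs: float,
                  downsample: int, lead: int, trial: int) -> BlobFeature | None:
    """Binarize a scalogram at its 95th intensity percentile, fill holes,
    label 8-connected components and return the largest-area blob."""
    from skimage import measure

    thresh = np.percentile(image, 95.0)
    binary = image > thresh
    if not binary.any():
        return None
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    props = measure.regionprops(labels, intensity_image=image)
    best = max(props, key=lambda p: p.area)
    row, col = best.centroid
    # frequency axis is geometric; interpolate at the (fractional) row index
    logf = np.log(freqs)
    cfreq = float(np.exp(np.interp(row, np.arange(len(freqs)), logf)))
    return BlobFeature(
        lead=lead, trial=trial, area=int(best.area),
        centroid_freq_hz=cfreq,
        centroid_time_ms=float(col * downsample * 1000.0 / fs),
        bounding_box=tuple(best.bbox),
        mean_intensity=float(best.intensity_mean),
        max_intensity=float(best.intensity_max),
    )


def wavelet_blob_outliers(tensor: TrialTensor,
                          low_cutoff_hz: float = 10.0,
                          blob_percentile: float = 95.0,
                          return_blobs: bool = False):
    """Flag (lead, trial) combinations carrying a strong high-frequency
    transient.

    Per combination: Morse CWT magnitude (frequencies above 10 Hz, ten
    voices per octave), time downsampled by 10, binarized at the image's
    95th percentile; the largest-area blob is kept.  Largest blobs are
    pooled across all combinations, and a combination is flagged when its
    blob has centroid frequency above ``low_cutoff_hz`` AND max intensity
    strictly above the pooled ``blob_percentile``.
    """
    down = 10
    freqs = dyadic_frequencies(tensor.fs, f_min=10.0)
    valid = tensor.valid_combination()
    blobs: list[BlobFeature] = []
    chunk = 16
    for lead in range(tensor.n_leads):
        idx = np.flatnonzero(valid[lead])
        for start in range(0, idx.size, chunk):
            sel = idx[start:start + chunk]
            coeffs = cwt_morse(tensor.data[lead, sel, :], tensor.fs, freqs)
            mag = np.abs(coeffs)[:, :, ::down]  # (freq, trial, time)
            for j, trial in enumerate(sel):
                blob = _largest_blob(mag[:, j, :], freqs, tensor.fs, down,
                                     lead, int(trial))
                if blob is not None:
                    blobs.append(blob)
    flags = np.zeros((tensor.n_leads, tensor.n_trials), dtype=bool)
    if blobs:
        intensities = np.array([b.max_intensity for b in blobs])
        cutoff = np.percentile(intensities, blob_percentile)
        for b in blobs:
            if b.centroid_freq_hz > low_cutoff_hz and b.max_intensity > cutoff:
                flags[b.lead, b.trial] = True
    if return_blobs:
        return flags, blobs
    return flags


# ---------------------------------------------------------------------------
# 3. putative interictal events
# ---------------------------------------------------------------------------

def _fuzzy_cmeans(X: np.ndarray, rng, c: int = 2, m: float = 2.0,
                  n_iter: int = 300, tol: float = 1e-7) -> np.ndarray:
    """Standard fuzzy c-means; returns the (n, c) membership matrix."""
    n = X.shape[0]
    u = rng.dirichlet(np.ones(c), size=n)
    for _ in range(n_iter):
        um = u ** m
        centers = (um.T @ X) / (um.sum(axis=0)[:, None] + 1e-30)
        d = np.linalg.norm(X[:, None, :] - centers[None], axis=2) + 1e-12
        inv = d ** (-2.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(u_new - u).max() < tol:
            return u_new
        u = u_new
    return u


def interictal_trial_detector(tensor: TrialTensor,
                              win_len: int = 400,
                              win_step: int = 50,
                              xcorr_lags: int = 150,
                              n_bins: int = 20,
                              rng=None) -> set:
    """Detect trials carrying coherent cross-lead transients.

    Per trial: leads are z-scored; over sliding windows the maximum absolute
    normalized cross-correlation (lags within +/- ``xcorr_lags`` samples) is
    taken per lead pair, keeping the max across windows.  Each trial is then
    summarized by a 20-bin histogram of its pairwise maxima, trials are
    compared by the earth-mover (optimal transport) distance between
    histograms, and the distance matrix is split into two fuzzy clusters.
    The smaller cluster, when well separated, is returned as the outlier
    set; exchangeable data triggers the degeneracy guard and an empty set.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_leads, n_trials, n_samp = tensor.data.shape
    if n_trials < 3 or n_leads < 2:
        raise ValueError("need >= 3 trials and >= 2 leads")
    win_len = min(win_len, n_samp)
    pairs = [(i, j) for i in range(n_leads) for j in range(i + 1, n_leads)]
    nfft = int(2 ** np.ceil(np.log2(2 * win_len)))
    lag_idx = np.concatenate(
        [np.arange(0, xcorr_lags + 1), np.arange(nfft - xcorr_lags, nfft)]
    )
    starts = list(range(0, n_samp - win_len + 1, win_step)) or [0]

    maxcorr = np.zeros((n_trials, len(pairs)))
    valid = tensor.valid_combination()
    for tr in range(n_trials):
        z = tensor.data[:, tr, :].copy()
        sd = z.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=-1, keepdims=True)) / sd
        for w0 in starts:
            seg = z[:, w0:w0 + win_len]
            norms = np.linalg.norm(seg, axis=-1)
            norms[norms == 0] = 1.0
            F = np.fft.rfft(seg, n=nfft, axis=-1)
            for k, (i, j) in enumerate(pairs):
                if not (valid[i, tr] and valid[j, tr]):
                    continue
                cc = np.fft.irfft(F[i] * np.conj(F[j]), n=nfft)
                val = np.abs(cc[lag_idx]).max() / (norms[i] * norms[j])
                if val > maxcorr[tr, k]:
                    maxcorr[tr, k] = val

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = np.array([
        np.histogram(maxcorr[tr], bins=edges)[0].astype(float)
        for tr in range(n_trials)
    ])
    hists /= hists.sum(axis=1, keepdims=True) + 1e-30

    D = np.zeros((n_trials, n_trials))
    for a in range(n_trials):
        for b in range(a + 1, n_trials):
            D[a, b] = D[b, a] = stats.wasserstein_distance(
                centers, centers, u_weights=hists[a] + 1e-12,
                v_weights=hists[b] + 1e-12,
            )

    u = _fuzzy_cmeans(D, rng)
    hard = u.argmax(axis=1)
    sizes = np.bincount(hard, minlength=2)
    small = int(np.argmin(sizes))
    # degeneracy guards: no confident cluster, or "outlier" cluster too big
    if u.max(axis=0).min() < 0.6 or sizes[small] > 0.4 * n_trials:
        warnings.warn("interictal screen: no coherent-event cluster found")
        return set()
    return set(int(t) for t in np.flatnonzero(hard == small))


# ---------------------------------------------------------------------------
# 4. trial amplitude outliers
# ---------------------------------------------------------------------------

def _mad_outliers(values: np.ndarray, factor: float = 3.0) -> np.ndarray:
    """Boolean flags by the median +/- factor * scaled-MAD dispersion rule."""
    med = np.median(values)
    mad = _MAD_SCALE * np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros(len(values), dtype=bool)
    return np.abs(values - med) > factor * mad


def trial_amplitude_outliers(tensor: TrialTensor,
                             mad_factor: float = 3.0) -> set:
    """Trials whose peak |value| across all leads and time is a robust
    dispersion outlier."""
    if tensor.n_trials < 3:
        raise ValueError("need >= 3 trials")
    data = np.where(tensor.mask, 0.0, np.abs(tensor.data))
    stat = data.max(axis=(0, 2))
    return set(int(t) for t in np.flatnonzero(_mad_outliers(stat, mad_factor)))


# ---------------------------------------------------------------------------
# 5. glitches
# ---------------------------------------------------------------------------

def glitch_detector(tensor: TrialTensor, threshold_factor: float = 3.0) -> set:
    """Trials with a coherent one-sample jump across leads.

    Per trial the mean across leads of |x[t] - x[t-1]| is formed; the peak
    local maximum of that series per trial is screened by the scaled-MAD
    rule at ``threshold_factor``.
    """
    if tensor.n_samples < 2:
        raise ValueError("need >= 2 samples")
    diffs = np.abs(np.diff(tensor.data, axis=-1))
    diffs = np.where(tensor.mask[:, :, 1:], np.nan, diffs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(diffs, axis=0)  # (trial, time-1)
    m = np.nan_to_num(m)
    interior = m[:, 1:-1]
    is_peak = (interior >= m[:, :-2]) & (interior >= m[:, 2:])
    peaks = np.where(is_peak, interior, 0.0).max(axis=1)
    return set(int(t) for t in
               np.flatnonzero(_mad_outliers(peaks, threshold_factor)))


# ---------------------------------------------------------------------------
# 6. out-of-range (flat) measurements
# ---------------------------------------------------------------------------

def flatness_detector(tensor: TrialTensor, winlen: int = 100,
                      winstep: int = 50, replen: int = 3) -> np.ndarray:
    """Flag (lead, trial) combinations containing extended flat signal.

    Samples where the successive difference is below 1e-10 are labelled;
    length-``winlen`` windows stepped by ``winstep`` that are entirely
    labelled are counted, and combinations with more than ``replen`` such
    windows are flagged.
    """
    if winlen > tensor.n_samples:
        raise ValueError("winlen exceeds trace length")
    flat = np.abs(np.diff(tensor.data, axis=-1)) < 1e-10
    csum = np.concatenate(
        [np.zeros(flat.shape[:2] + (1,)), np.cumsum(flat, axis=-1)], axis=-1
    )
    starts = np.arange(0, flat.shape[-1] - winlen + 1, winstep)
    if starts.size == 0:
        return np.zeros((tensor.n_leads, tensor.n_trials), dtype=bool)
    counts = (csum[:, :, starts + winlen] - csum[:, :, starts]) == winlen
    return counts.sum(axis=-1) > replen


# ---------------------------------------------------------------------------
# combination and reporting
# ---------------------------------------------------------------------------

def combine_rejections(per_criterion: dict, lead_threshold: int = 5,
                       n_leads: int | None = None,
                       n_trials: int | None = None) -> RejectionMask:
    """Combine all screens into one RejectionMask.

    Trial candidates from the interictal and amplitude screens are removed
    as whole trials only when the trial contains more than ``lead_threshold``
    feature-vector outlier leads; glitch-flagged trials are removed
    unconditionally.  The combined mask is the union of removed trials (all
    leads) with the combination-based masks.
    """
    fv = np.asarray(per_criterion["feature_vector"], dtype=bool)
    wav = np.asarray(per_criterion["wavelet"], dtype=bool)
    flat = np.asarray(per_criterion["flatness"], dtype=bool)
    if not (fv.shape == wav.shape == flat.shape):
        raise ValueError("criterion mask shapes disagree")
    if n_leads is None:
        n_leads, n_trials = fv.shape
    if fv.shape != (n_leads, n_trials):
        raise ValueError("criterion masks do not match tensor shape")

    candidates = set(per_criterion.get("interictal", set())) | set(
        per_criterion.get("amplitude", set())
    )
    removed = {t for t in candidates if fv[:, t].sum() > lead_threshold}
    removed |= set(per_criterion.get("glitch", set()))

    combined = fv | wav | flat
    for t in removed:
        combined[:, t] = True
    return RejectionMask(per_criterion=dict(per_criterion),
                         removed_trials=removed, combined=combined)


def rejection_report(mask: RejectionMask, tensor: TrialTensor) -> pd.DataFrame:
    """One-row summary mirroring the global-performance table layout:
    lead count, total lead-trials, rejected lead-trials (union, counted
    once), fraction, median and min remaining trials per lead."""
    n_leads, n_trials = mask.combined.shape
    rejected = int(mask.combined.sum())
    remaining = (~mask.combined).sum(axis=1)
    return pd.DataFrame(
        {
            "n_leads": [n_leads],
            "total_lead_trials": [n_leads * n_trials],
            "rejected_lead_trials": [rejected],
            "fraction_rejected": [rejected / (n_leads * n_trials)],
            "median_trials_per_lead": [float(np.median(remaining))],
            "min_trials_per_lead": [int(remaining.min())],
        }
    )


def reject(tensor: TrialTensor, cfg: PipelineConfig | None = None,
           rng=None) -> tuple[TrialTensor, RejectionMask, pd.DataFrame]:
    """Run the full rejection chain and return (masked tensor, mask, report).

    Detrends once, applies every screen to the detrended data (flatness to
    the raw data), combines, and applies the combined mask to a copy of the
    input tensor.
    """
    cfg = cfg or PipelineConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    det = detrend_tensor(tensor)
    per = {
        "feature_vector": feature_vector_outliers(
            det, cfg.bivariate_reject_percentile, cfg
        ),
        "wavelet": wavelet_blob_outliers(
            det, cfg.wavelet_low_cutoff_hz, cfg.wavelet_blob_percentile
        ),
        "flatness": flatness_detector(
            tensor, cfg.flatness_winlen, cfg.flatness_winstep,
            cfg.flatness_replen
        ),
        "interictal": interictal_trial_detector(det, rng=rng),
        "amplitude": trial_amplitude_outliers(det, cfg.amplitude_outlier_mad),
        "glitch": glitch_detector(det, cfg.glitch_threshold_factor),
    }
    mask = combine_rejections(per, cfg.trial_reject_lead_threshold,
                              tensor.n_leads, tensor.n_trials)
    masked = tensor.with_mask(mask.combined)
    return masked, mask, rejection_report(mask, tensor)
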