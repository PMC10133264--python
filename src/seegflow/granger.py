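"""Time-resolved pairwise and conditional Granger causality.

The engine slides a short window (100 samples at the 1 kHz base rate,
stepped by 10) across the trial-aligned traces of an ordered lead pair and,
within each window, fits vector-autoregressive (VAR) models of order 4 by
ordinary least squares with trials pooled as independent realizations.  The
time-domain Granger causality from source x to target y is

    F(x -> y) = ln( var_reduced(y) / var_full(y) )

where the reduced model omits the source's lagged terms.  Because the
reduced regressor set is nested in the full one on identical rows, F is
non-negative by construction.

Longer causal delays are probed by decimating the window by a sample-spacing
factor ns in {1, 2, 4}: with 4 lags the maximum modelled delay is 4*ns ms at
1 kHz (the NS1/NS2/NS4 settings, 4/8/16 ms).

Three run modes operate on every pair: a point estimate over all common
trials; 20 bootstrap runs (trials resampled with replacement) giving a
per-window mean/SD; and 20 surrogate runs in which each lead's trial order
is permuted independently, destroying any trial-locked coupling — the
surrogate mean/SD turn the raw F into a surrogate z.  Task-phasic effects
are isolated by z-scoring the raw trace against the pre-onset baseline
windows; the signed strength C summarizes the baseline-z extreme inside the
0.1-0.4 s response interval and drives the D/M/A/N connection typing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .core import TrialTensor

CONNECTION_TYPES = ("D", "M", "A", "N", "opposite", "weak")


@dataclass
class GCTrace:
    """Windowed directed GC time course for one ordered lead pair."""

    source: int
    target: int
    ns_factor: int
    window_starts: np.ndarray          # base-rate start sample of each window
    times_ms: np.ndarray               # window centers relative to onset
    f: np.ndarray                      # raw time-domain GC per window
    window_len_ms: float = 100.0
    surrogate_z: np.ndarray | None = None
    surrogate_mean: np.ndarray | None = None
    surrogate_sd: np.ndarray | None = None
    bootstrap_mean: np.ndarray | None = None
    bootstrap_sd: np.ndarray | None = None
    baseline_z: np.ndarray | None = None
    freq_hz: np.ndarray | None = None
    f_freq: np.ndarray | None = None   # (n_windows, n_freqs)
    cond_lead: int | None = None


@dataclass
class ConnectionSummary:
    source: int
    target: int
    C_ns1: float
    C_ns4: float
    type: str
    is_via: bool | None = None


# ---------------------------------------------------------------------------
# trial selection
# ---------------------------------------------------------------------------

def select_pair_trials(tensor: TrialTensor, pair: tuple,
                       min_common: int = 12,
                       trials: np.ndarray | None = None) -> np.ndarray | None:
    """Trials unmasked in every lead of ``pair`` (greedy, per-pair).

    Returns ``None`` with a warning when fewer than ``min_common`` common
    trials remain.
    """
    valid = tensor.valid_combination()
    ok = np.ones(tensor.n_trials, dtype=bool)
    for lead in pair:
        ok &= valid[lead]
    if trials is not None:
        sub = np.zeros(tensor.n_trials, dtype=bool)
        sub[np.asarray(trials)] = True
        ok &= sub
    idx = np.flatnonzero(ok)
    if idx.size < min_common:
        warnings.warn(
            f"pair {pair}: only {idx.size} common trials (< {min_common}), "
            "skipped"
        )
        return None
    return idx


# ---------------------------------------------------------------------------
# windowed VAR fitting
# ---------------------------------------------------------------------------

def _solve_ols(G: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Solve the normal equations with a ridge fallback for ill-conditioned
    regressor matrices."""
    p = G.shape[0]
    if np.linalg.cond(G) > 1e10:
        G = G + 1e-8 * (np.trace(G) / p) * np.eye(p)
    return np.linalg.solve(G, c)


def fit_var_window(window_data: np.ndarray, order: int = 4,
                   ns_factor: int = 1) -> dict:
    """OLS VAR fit on one window of multi-lead, multi-trial data.

    Parameters
    ----------
    window_data : ndarray, shape (n_leads, n_trials, win_samples)
        Base-rate samples; the window is decimated by ``ns_factor`` (simple
        sample skipping) before fitting, and each lead is demeaned over the
        pooled window.
    order : int
        VAR lag order (>= 1).

    Returns a dict with the coefficient matrix ``coefs`` (n_leads x
    n_leads*order, row = target), the full-model residual covariance
    ``sigma_full``, per-target reduced residual variances
    ``reduced_var[(target, excluded_source)]``, and ``n_obs``.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    d = np.asarray(window_data, dtype=float)[:, :, ::ns_factor]
    L, T, m = d.shape
    if m <= order:
        raise ValueError("window too short for the requested order")
    d = d - d.mean(axis=(1, 2), keepdims=True)
    n = m - order
    N = T * n
    Y = d[:, :, order:].reshape(L, N)
    cols = np.empty((L * order, N))
    for lead in range(L):
        for k in range(1, order + 1):
            cols[lead * order + k - 1] = d[lead, :, order - k:m - k].reshape(N)
    G = cols @ cols.T
    C = cols @ Y.T                      # (p, L)
    beta = _solve_ols(G, C)
    sigma_full = (Y @ Y.T - C.T @ beta) / N
    yy = np.einsum("ln,ln->l", Y, Y)

    reduced_var = {}
    for tgt in range(L):
        for src in range(L):
            if src == tgt:
                continue
            keep = np.concatenate([
                np.arange(l * order, (l + 1) * order)
                for l in range(L) if l != src
            ])
            br = _solve_ols(G[np.ix_(keep, keep)], C[keep, tgt])
            reduced_var[(tgt, src)] = (yy[tgt] - C[keep, tgt] @ br) / N
    return {
        "coefs": beta.T,
        "sigma_full": sigma_full,
        "reduced_var": reduced_var,
        "n_obs": N,
    }


def gc_from_fit(fit: dict, source: int, target: int) -> float:
    """Time-domain GC for one direction from a fitted window."""
    num = fit["reduced_var"][(target, source)]
    den = fit["sigma_full"][target, target]
    if den <= 0 or num <= 0:
        return np.nan
    return float(np.log(num / den))


def spectral_gc(fit: dict, source: int, target: int, fs_eff: float,
                n_freqs: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """Parametric frequency-domain GC from a fitted bivariate/trivariate VAR.

    Evaluated at ``n_freqs`` equally spaced frequencies from 0 to the
    effective Nyquist (fs_eff / 2) via the fitted transfer function.  Used
    as a diagnostic only.
    """
    A = fit["coefs"]
    L = A.shape[0]
    order = A.shape[1] // L
    Sigma = fit["sigma_full"]
    freqs = np.linspace(0.0, fs_eff / 2.0, n_freqs)
    out = np.zeros(n_freqs)
    s, t = source, target
    # partial covariance of the source innovation given the target's
    cond_var = Sigma[s, s] - Sigma[s, t] ** 2 / Sigma[t, t]
    for i, f in enumerate(freqs):
        Af = np.eye(L, dtype=complex)
        for k in range(1, order + 1):
            Af -= A[:, (k - 1)::order] * np.exp(-2j * np.pi * f * k / fs_eff)
        H = np.linalg.inv(Af)
        S = H @ Sigma @ H.conj().T
        s_tt = S[t, t].real
        denom = s_tt - cond_var * np.abs(H[t, s]) ** 2
        out[i] = np.log(s_tt / max(denom, 1e-300))
    return freqs, out


# ---------------------------------------------------------------------------
# windowed time courses
# ---------------------------------------------------------------------------

def window_starts(n_samples: int, cfg: PipelineConfig) -> np.ndarray:
    return np.arange(0, n_samples - cfg.gc_window_samples + 1,
                     cfg.gc_offset_samples)


def _gc_timecourse(stack: np.ndarray, ns_factor: int, cfg: PipelineConfig,
                   directions: list[tuple], compute_freq: bool = False,
                   fs: float = 1000.0):
    """Raw GC time course for the given (source, target) index pairs over a
    (n_leads, n_trials, n_samples) stack of trial-matched traces."""
    starts = window_starts(stack.shape[-1], cfg)
    W = cfg.gc_window_samples
    out = {d: np.empty(len(starts)) for d in directions}
    freq_out = {d: [] for d in directions} if compute_freq else None
    freqs = None
    for wi, w0 in enumerate(starts):
        fit = fit_var_window(stack[:, :, w0:w0 + W], cfg.gc_lags, ns_factor)
        for d in directions:
            out[d][wi] = gc_from_fit(fit, d[0], d[1])
            if compute_freq:
                freqs, g = spectral_gc(fit, d[0], d[1], fs / ns_factor)
                freq_out[d].append(g)
    return starts, out, freqs, freq_out


def _times_ms(starts: np.ndarray, tensor: TrialTensor,
              cfg: PipelineConfig) -> np.ndarray:
    centers = starts + cfg.gc_window_samples / 2.0
    return (centers - tensor.onset_index) * 1000.0 / tensor.fs


def pairwise_ugc(tensor: TrialTensor, pair: tuple, ns_factor: int = 1,
                 cfg: PipelineConfig | None = None,
                 trials: np.ndarray | None = None,
                 compute_freq: bool = False) -> tuple[GCTrace, GCTrace]:
    """Raw unconditioned GC time courses for both directions of ``pair``.

    Returns ``(forward, backward)`` traces where forward runs from
    ``pair[0]`` to ``pair[1]``.
    """
    cfg = cfg or PipelineConfig()
    if trials is None:
        trials = select_pair_trials(tensor, pair, cfg.min_common_trials)
        if trials is None:
            raise ValueError(f"pair {pair}: too few common trials")
    stack = tensor.data[list(pair)][:, trials, :]
    dirs = [(0, 1), (1, 0)]
    starts, out, freqs, fout = _gc_timecourse(
        stack, ns_factor, cfg, dirs, compute_freq, tensor.fs
    )
    times = _times_ms(starts, tensor, cfg)
    wlen = cfg.gc_window_samples * 1000.0 / tensor.fs
    fw = GCTrace(source=pair[0], target=pair[1], ns_factor=ns_factor,
                 window_starts=starts, times_ms=times, f=out[(0, 1)],
                 window_len_ms=wlen)
    bw = GCTrace(source=pair[1], target=pair[0], ns_factor=ns_factor,
                 window_starts=starts, times_ms=times, f=out[(1, 0)],
                 window_len_ms=wlen)
    if compute_freq:
        fw.freq_hz, fw.f_freq = freqs, np.array(fout[(0, 1)])
        bw.freq_hz, bw.f_freq = freqs, np.array(fout[(1, 0)])
    return fw, bw


def surrogate_normalize(tensor: TrialTensor, traces: tuple, ns_factor: int,
                        cfg: PipelineConfig, rng,
                        trials: np.ndarray) -> tuple[GCTrace, GCTrace]:
    """Fill ``surrogate_z`` on a (forward, backward) pair of raw traces.

    Each surrogate run pairs the two leads' trials in independently permuted
    orders, destroying trial-locked coupling while preserving each lead's
    marginal statistics.  z = (F - surrogate mean) / surrogate SD per
    window; windows with zero surrogate SD come out NaN.
    """
    if cfg.n_surrogate < 2:
        raise ValueError("need >= 2 surrogate runs")
    fw, bw = traces
    pair = (fw.source, fw.target)
    n_win = len(fw.f)
    surr = {d: np.empty((cfg.n_surrogate, n_win)) for d in [(0, 1), (1, 0)]}
    for r in range(cfg.n_surrogate):
        p1 = rng.permutation(trials)
        p2 = rng.permutation(trials)
        stack = np.stack([tensor.data[pair[0], p1, :],
                          tensor.data[pair[1], p2, :]])
        _, out, _, _ = _gc_timecourse(stack, ns_factor, cfg,
                                      [(0, 1), (1, 0)], fs=tensor.fs)
        surr[(0, 1)][r] = out[(0, 1)]
        surr[(1, 0)][r] = out[(1, 0)]
    for trace, d in ((fw, (0, 1)), (bw, (1, 0))):
        mean = surr[d].mean(axis=0)
        sd = surr[d].std(axis=0, ddof=1)
        z = np.where(sd > 0, (trace.f - mean) / np.where(sd > 0, sd, 1.0),
                     np.nan)
        trace.surrogate_mean, trace.surrogate_sd, trace.surrogate_z = mean, sd, z
    return fw, bw


def bootstrap_gc(tensor: TrialTensor, pair: tuple, ns_factor: int,
                 cfg: PipelineConfig, rng,
                 trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mean and SD of the GC over trial-resampled recomputations
    (sampling with replacement), for the forward direction then backward.

    Returns arrays of shape (2, n_windows): [forward, backward] means and
    SDs stacked."""
    boots_fw, boots_bw = [], []
    for _ in range(cfg.n_bootstrap):
        res = rng.choice(trials, size=len(trials), replace=True)
        fw, bw = pairwise_ugc(tensor, pair, ns_factor, cfg, trials=res)
        boots_fw.append(fw.f)
        boots_bw.append(bw.f)
    boots = np.array([boots_fw, boots_bw])
    return boots.mean(axis=1), boots.std(axis=1, ddof=1)


def baseline_zscore_gc(trace: GCTrace, tensor: TrialTensor,
                       cfg: PipelineConfig | None = None) -> GCTrace:
    """z-score the raw GC trace against windows wholly inside the baseline
    period (default -900 to 0 ms relative to onset)."""
    cfg = cfg or PipelineConfig()
    lo = tensor.onset_index + cfg.baseline_window_s[0] * tensor.fs
    hi = tensor.onset_index + cfg.baseline_window_s[1] * tensor.fs
    starts = trace.window_starts
    base = (starts >= lo) & (starts + cfg.gc_window_samples <= hi)
    if not base.any():
        raise ValueError("no windows inside the baseline period")
    mu = trace.f[base].mean()
    sd = trace.f[base].std()
    if sd == 0:
        trace.baseline_z = np.full_like(trace.f, np.nan)
    else:
        trace.baseline_z = (trace.f - mu) / sd
    return trace


# ---------------------------------------------------------------------------
# strength and typing
# ---------------------------------------------------------------------------

def connection_strength(baseline_z: np.ndarray, times_ms: np.ndarray,
                        response_window_s: tuple = (0.1, 0.4),
                        window_len_ms: float = 0.0) -> float:
    """Signed strength C: the baseline-z extreme in the response interval.

    Both extremes positive -> max; both negative -> min; mixed signs with
    |max - min| < 3 -> their mean, otherwise the extreme of larger absolute
    value (signed).

    When ``window_len_ms`` is given, only windows lying wholly inside the
    response interval contribute (same convention as the baseline windows).
    """
    t = np.asarray(times_ms)
    margin = window_len_ms / 2.0
    sel = ((t >= response_window_s[0] * 1000.0 + margin)
           & (t <= response_window_s[1] * 1000.0 - margin))
    if not sel.any():
        raise ValueError("response window not covered by the trace")
    vals = np.asarray(baseline_z)[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan
    mx, mn = float(vals.max()), float(vals.min())
    if mx > 0 and mn > 0:
        return mx
    if mx < 0 and mn < 0:
        return mn
    if abs(mx - mn) < 3.0:
        return 0.5 * (mx + mn)
    return mx if abs(mx) >= abs(mn) else mn


def classify_connection(C_ns1: float, C_ns4: float,
                        strong_z: float = 5.0) -> str:
    """D/M/A/N typing of a connection from its short- and long-delay
    strengths ('exceeds' is strict; ties fall to the weaker category)."""
    s = strong_z
    if (C_ns1 > s and C_ns4 < -s) or (C_ns1 < -s and C_ns4 > s):
        return "opposite"
    if C_ns1 > s and C_ns4 > s:
        return "M"
    if C_ns1 > s:
        return "D"
    if C_ns4 > s and -s <= C_ns1 <= s:
        return "A"
    if C_ns4 < -s and C_ns1 < s:
        return "N"
    return "weak"


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def conditioned_gc(tensor: TrialTensor, pair: tuple, cond_lead: int,
                   ns_factor: int = 1, cfg: PipelineConfig | None = None,
                   rng=None, trials: np.ndarray | None = None,
                   normalize: bool = True) -> GCTrace:
    """Conditional GC source -> target given ``cond_lead`` (3-lead VAR),
    surrogate- and baseline-normalized like the unconditioned trace."""
    cfg = cfg or PipelineConfig()
    if cond_lead in pair:
        raise ValueError("conditioning lead must not belong to the pair")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    leads = (pair[0], pair[1], cond_lead)
    if trials is None:
        trials = select_pair_trials(tensor, leads, cfg.min_common_trials)
        if trials is None:
            raise ValueError(f"leads {leads}: too few common trials")
    stack = tensor.data[list(leads)][:, trials, :]
    starts, out, _, _ = _gc_timecourse(stack, ns_factor, cfg, [(0, 1)],
                                       fs=tensor.fs)
    trace = GCTrace(source=pair[0], target=pair[1], ns_factor=ns_factor,
                    window_starts=starts,
                    times_ms=_times_ms(starts, tensor, cfg),
                    f=out[(0, 1)], cond_lead=cond_lead,
                    window_len_ms=cfg.gc_window_samples * 1000.0 / tensor.fs)
    if normalize:
        surr = np.empty((cfg.n_surrogate, len(starts)))
        for r in range(cfg.n_surrogate):
            perms = [rng.permutation(trials) for _ in range(3)]
            s = np.stack([tensor.data[leads[i], perms[i], :]
                          for i in range(3)])
            _, o, _, _ = _gc_timecourse(s, ns_factor, cfg, [(0, 1)],
                                        fs=tensor.fs)
            surr[r] = o[(0, 1)]
        mean, sd = surr.mean(axis=0), surr.std(axis=0, ddof=1)
        trace.surrogate_mean, trace.surrogate_sd = mean, sd
        trace.surrogate_z = np.where(
            sd > 0, (trace.f - mean) / np.where(sd > 0, sd, 1.0), np.nan
        )
        baseline_zscore_gc(trace, tensor, cfg)
    return trace


def peak_response_z(trace: GCTrace, cfg: PipelineConfig,
                    which: str = "baseline_z") -> float:
    """Peak z over windows wholly inside the response interval (used by the
    conditioning screen)."""
    z = getattr(trace, which)
    vals = z[_response_window_mask(trace, cfg)]
    vals = vals[np.isfinite(vals)]
    return float(vals.max()) if vals.size else np.nan


def _response_window_mask(trace: GCTrace, cfg: PipelineConfig) -> np.ndarray:
    margin = trace.window_len_ms / 2.0
    t = trace.times_ms
    return ((t >= cfg.strength_window_s[0] * 1000.0 + margin)
            & (t <= cfg.strength_window_s[1] * 1000.0 - margin))


def conditioning_screen(tensor: TrialTensor, pair: tuple,
                        candidates, cfg: PipelineConfig | None = None,
                        rng=None, ns_factor: int = 1,
                        trials: np.ndarray | None = None) -> set:
    """Leads whose conditioning drops the pair's response z below the
    medium threshold (default 3): the most influential common inputs.

    The conditioned z is read at the window where the pair's unconditioned
    baseline-z peaks inside the response interval — the screen asks whether
    THAT connection peak survives conditioning, so the comparison is made at
    the same window rather than over a fresh maximum.
    """
    cfg = cfg or PipelineConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    if trials is None:
        trials = select_pair_trials(tensor, pair, cfg.min_common_trials)
        if trials is None:
            raise ValueError(f"pair {pair}: too few common trials")
    fw, _ = pairwise_ugc(tensor, pair, ns_factor, cfg, trials)
    baseline_zscore_gc(fw, tensor, cfg)
    sel = _response_window_mask(fw, cfg)
    idx = np.flatnonzero(sel)[np.nanargmax(fw.baseline_z[sel])]

    influential = set()
    for cand in candidates:
        if cand in pair:
            continue
        trace = conditioned_gc(tensor, pair, cand, ns_factor, cfg, rng,
                               trials=trials)
        if trace.baseline_z[idx] < cfg.medium_z:
            influential.add(int(cand))
    return influential


def via_lead_classification(c_source_to_lead: float, c_lead_to_target: float,
                            strong_z: float = 5.0) -> bool:
    """True iff the outside lead is strongly connected from the source and
    to the target (both strengths > strong_z)."""
    return bool(c_source_to_lead > strong_z and c_lead_to_target > strong_z)


def region_average_gc(traces: list) -> GCTrace:
    """Pointwise mean of GC traces sharing windows and delay setting (e.g.
    one outside lead against the several leads of one region)."""
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0]
    for tr in traces[1:]:
        if tr.ns_factor != t0.ns_factor or len(tr.f) != len(t0.f):
            raise ValueError("traces are not aligned")
    out = GCTrace(source=t0.source, target=t0.target, ns_factor=t0.ns_factor,
                  window_starts=t0.window_starts.copy(),
                  times_ms=t0.times_ms.copy(),
                  f=np.mean([tr.f for tr in traces], axis=0),
                  window_len_ms=t0.window_len_ms)
    for attr in ("surrogate_z", "baseline_z"):
        vals = [getattr(tr, attr) for tr in traces]
        if all(v is not None for v in vals):
            setattr(out, attr, np.mean(vals, axis=0))
    return out


# ---------------------------------------------------------------------------
# convenience: full characterization of one ordered pair
# ---------------------------------------------------------------------------

def analyze_connection(tensor: TrialTensor, source: int, target: int,
                       cfg: PipelineConfig | None = None, rng=None,
                       trials: np.ndarray | None = None,
                       with_surrogate: bool = True) -> ConnectionSummary:
    """Strength at NS1 and NS4 plus connection type for one ordered pair."""
    cfg = cfg or PipelineConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    if trials is None:
        trials = select_pair_trials(tensor, (source, target),
                                    cfg.min_common_trials)
        if trials is None:
            raise ValueError("too few common trials")
    C = {}
    for ns in (1, 4):
        fw, bw = pairwise_ugc(tensor, (source, target), ns, cfg, trials)
        if with_surrogate:
            surrogate_normalize(tensor, (fw, bw), ns, cfg, rng, trials)
        baseline_zscore_gc(fw, tensor, cfg)
        C[ns] = connection_strength(fw.baseline_z, fw.times_ms,
                                    cfg.strength_window_s, fw.window_len_ms)
    ctype = classify_connection(C[1], C[4], cfg.strong_z)
    return ConnectionSummary(source=source, target=target, C_ns1=C[1],
                             C_ns4=C[4], type=ctype)
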