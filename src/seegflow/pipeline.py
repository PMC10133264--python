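"""End-to-end orchestration: simulate/load -> reject -> power -> granger ->
timing, with every stage output and the resolved configuration written to an
output directory as tab-separated text."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import granger, power, rejection, simulate, timing
from .config import PipelineConfig
from .core import TrialTensor, write_trial_tensor

log = logging.getLogger("seegflow")

_FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def build_sim_config(raw: dict) -> simulate.SimConfig:
    """SimConfig from a plain dict (e.g. the 'simulate' section of a YAML
    config), with couplings/bursts given as lists of dicts."""
    raw = dict(raw)
    couplings = [simulate.CouplingSpec(**c) for c in raw.pop("couplings", [])]
    bursts = [simulate.BurstSpec(**b) for b in raw.pop("bursts", [])]
    for spec in couplings:
        spec.window_s = tuple(spec.window_s)
    return simulate.SimConfig(couplings=couplings, bursts=bursts, **raw)


def _task_trials(tensor: TrialTensor, task: str) -> np.ndarray:
    return np.flatnonzero(tensor.trial_labels["task"] == task)


def run_pipeline(config: dict, outdir, seed: int,
                 tensor: TrialTensor | None = None) -> Path:
    """Execute the full chain and return the output directory.

    ``config`` is a dict with optional sections:

    * ``pipeline`` — PipelineConfig fields;
    * ``simulate`` — SimConfig fields (used when no tensor is passed);
    * ``pairs`` — list of [source, target] lead indices for the GC stage
      (default: all ordered pairs);
    * ``conditioning`` — bool, run the conditioning screen on strong pairs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_dict(dict(config.get("pipeline", {}),
                                        rng_seed=seed))
    rng = np.random.default_rng(seed)

    if tensor is None:
        if "simulate" not in config:
            raise ValueError("config needs a 'simulate' section or a tensor")
        sim_cfg = build_sim_config(config["simulate"])
        tensor, gt = simulate.simulate_dataset(sim_cfg, seed)
        write_trial_tensor(outdir / "tensor.h5", tensor)
        (outdir / "ground_truth.yaml").write_text(
            yaml.safe_dump(gt.to_dict(), sort_keys=True)
        )
    cfg.to_yaml(outdir / "config_resolved.yaml")

    # -- rejection -----------------------------------------------------
    try:
        masked, mask, report = rejection.reject(tensor, cfg, rng)
        _write(report, outdir / "rejection_report.tsv")
        per = pd.DataFrame({
            name: [int(np.asarray(list(v)).size) if isinstance(v, set)
                   else int(np.asarray(v).sum())]
            for name, v in mask.per_criterion.items()
        })
        per["removed_trials"] = [len(mask.removed_trials)]
        _write(per, outdir / "rejection_counts.tsv")
    except Exception as exc:
        raise StageError("reject", exc)

    # -- power ---------------------------------------------------------
    try:
        ptens = power.gamma_power_timecourse(masked, cfg)
        z_by_task = {}
        for task in ("gender", "action"):
            tr = _task_trials(masked, task)
            if tr.size:
                z_by_task[task] = power.zscore_vs_baseline(ptens, trials=tr)
        rows, ztab = [], {"time_ms": ptens.bin_times_ms}
        zg = z_by_task.get("gender")
        za = z_by_task.get("action")
        for lead in range(masked.n_leads):
            cls = power.classify_lead(
                zg.values[lead],
                za.values[lead] if za is not None else None,
                ptens.bin_times_ms, cfg,
            )
            rows.append({
                "lead_id": masked.lead_ids[lead],
                "responsive": cls.responsive, "selective": cls.selective,
                "latency_ms": cls.latency_ms, "duration_ms": cls.duration_ms,
            })
            ztab[f"z_gender_{masked.lead_ids[lead]}"] = zg.values[lead]
        _write(pd.DataFrame(rows), outdir / "lead_classification.tsv")
        _write(pd.DataFrame(ztab), outdir / "power_z.tsv")
    except Exception as exc:
        raise StageError("power", exc)

    # -- granger -------------------------------------------------------
    try:
        pairs = config.get("pairs")
        if pairs is None:
            pairs = [(i, j) for i in range(masked.n_leads)
                     for j in range(masked.n_leads) if i != j]
        pairs = [tuple(p) for p in pairs]
        gc_task = config.get("gc_task", "gender")
        task_idx = _task_trials(masked, gc_task)
        summaries, traces_ns1 = [], {}
        for src, tgt in pairs:
            trials = granger.select_pair_trials(masked, (src, tgt),
                                                cfg.min_common_trials,
                                                trials=task_idx)
            if trials is None:
                continue
            C = {}
            for ns in (1, 4):
                fw, bw = granger.pairwise_ugc(masked, (src, tgt), ns, cfg,
                                              trials)
                granger.surrogate_normalize(masked, (fw, bw), ns, cfg, rng,
                                            trials)
                granger.baseline_zscore_gc(fw, masked, cfg)
                granger.baseline_zscore_gc(bw, masked, cfg)
                C[ns] = granger.connection_strength(
                    fw.baseline_z, fw.times_ms, cfg.strength_window_s,
                    fw.window_len_ms,
                )
                tab = pd.DataFrame({
                    "window_center_ms": fw.times_ms,
                    "F_fw": fw.f, "F_bw": bw.f,
                    "zsurr_fw": fw.surrogate_z, "zsurr_bw": bw.surrogate_z,
                    "zbase_fw": fw.baseline_z, "zbase_bw": bw.baseline_z,
                })
                _write(tab, outdir / f"gc_{src}to{tgt}_ns{ns}.tsv")
                if ns == 1:
                    traces_ns1[(src, tgt)] = fw
            summaries.append({
                "source": src, "target": tgt, "C_ns1": C[1], "C_ns4": C[4],
                "type": granger.classify_connection(C[1], C[4], cfg.strong_z),
            })
        summary_df = pd.DataFrame(summaries)
        _write(summary_df, outdir / "connections.tsv")

        if config.get("conditioning") and len(summaries):
            rows = []
            for s in summaries:
                if s["C_ns1"] <= cfg.strong_z:
                    continue
                pair = (s["source"], s["target"])
                cands = [l for l in range(masked.n_leads) if l not in pair]
                before = granger.peak_response_z(traces_ns1[pair], cfg)
                hits = granger.conditioning_screen(
                    masked, pair, cands, cfg, rng,
                    trials=granger.select_pair_trials(
                        masked, pair, cfg.min_common_trials, trials=task_idx
                    ),
                )
                rows.append({"source": pair[0], "target": pair[1],
                             "peak_z_unconditioned": before,
                             "influential_leads":
                                 ",".join(map(str, sorted(hits)))})
            _write(pd.DataFrame(rows), outdir / "conditioning.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("granger", exc)

    # -- timing --------------------------------------------------------
    try:
        rows = []
        for lead in range(masked.n_leads):
            est = timing.onset_latency_50pct(
                zg.values[lead], ptens.bin_times_ms,
                cfg.onset_search_window_ms, peak_z_min=None,
            )
            rows.append({"kind": "power", "id": masked.lead_ids[lead],
                         "onset_ms": est.onset_ms, "peak": est.peak_z,
                         "included": est.included})
        for (src, tgt), fw in traces_ns1.items():
            est = timing.onset_latency_50pct(
                fw.baseline_z, fw.times_ms, cfg.onset_search_window_ms,
                peak_z_min=cfg.medium_z,
            )
            rows.append({"kind": "gc_ns1", "id": f"{src}to{tgt}",
                         "onset_ms": est.onset_ms, "peak": est.peak_z,
                         "included": est.included})
        _write(pd.DataFrame(rows), outdir / "onset_latencies.tsv")
    except Exception as exc:
        raise StageError("timing", exc)

    log.info("pipeline complete: %s", outdir)
    return outdir
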