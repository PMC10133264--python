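"""Directed connectivity at two delays: strength C and connection typing.

Two couplings are injected: 0->1 at 2 ms lag (visible to the short-delay
NS1 setting, max 4 ms) and 2->3 at 12 ms lag (visible only to the
long-delay NS4 setting, max 16 ms).  Each ordered pair gets a signed
strength C per delay setting — the baseline-z extreme of its GC trace in
the 0.1-0.4 s response window — and a type: D (strong only at short
delay), M (both), A (only long), N (suppressed at long delay).
"""

import numpy as np

import seegflow as sf
from seegflow import CouplingSpec, SimConfig, simulate_dataset

cfg = sf.PipelineConfig()
sim = SimConfig(n_leads=4, n_trials_per_task=40, couplings=[
    CouplingSpec(source=0, target=1, lag_ms=2.0, gain=0.4),
    CouplingSpec(source=2, target=3, lag_ms=12.0, gain=0.4),
])
tensor, _ = simulate_dataset(sim, seed=7)
gender = np.flatnonzero(tensor.trial_labels["task"] == "gender")

print(f"{'pair':>8s} {'C_ns1':>8s} {'C_ns4':>8s}  type")
for src, tgt in [(0, 1), (1, 0), (2, 3), (3, 2)]:
    trials = sf.select_pair_trials(tensor, (src, tgt),
                                   cfg.min_common_trials, trials=gender)
    summary = sf.analyze_connection(tensor, src, tgt, cfg,
                                    np.random.default_rng(7), trials,
                                    with_surrogate=False)
    print(f"{src}->{tgt:>5d} {summary.C_ns1:8.1f} {summary.C_ns4:8.1f}  "
          f"{summary.type}")
# Expected: 0->1 types D (strong C_ns1, weak C_ns4), 2->3 types A (the
# 12 ms influence falls outside the 4 ms NS1 horizon but inside NS4's
# 16 ms), and both reverse directions stay weak — the engine recovers
# direction and delay class of the injected couplings.
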