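"""Which response starts first?  Bootstrap onset comparison.

Two leads carry bursts whose onsets differ by 40 ms.  Single-trial gamma
power traces are bootstrap-resampled (100 draws); each bootstrap mean
curve yields a 50 %-of-peak onset, and the difference of the bootstrap
means with its pooled SD gives the significance flag.
"""

import numpy as np

import seegflow as sf
from seegflow import BurstSpec, SimConfig, simulate_dataset

cfg = sf.PipelineConfig()
sim = SimConfig(n_leads=2, n_trials_per_task=30, bursts=[
    BurstSpec(lead=0, onset_ms=150.0, duration_ms=120.0, amplitude=4.0),
    BurstSpec(lead=1, onset_ms=190.0, duration_ms=120.0, amplitude=4.0),
])
tensor, _ = simulate_dataset(sim, seed=9)
p = sf.gamma_power_timecourse(tensor, cfg)
gender = np.flatnonzero(tensor.trial_labels["task"] == "gender")
base = p.bin_times_ms < 0
traces = []
for lead in (0, 1):
    tr = p.values[lead, gender, :]
    mu = tr[:, base].mean(axis=1, keepdims=True)
    sd = tr[:, base].std(axis=1, keepdims=True)
    traces.append((tr - mu) / sd)

cmp_ = sf.onset_difference_bootstrap(traces[0], traces[1], p.bin_times_ms,
                                     n_boot=100, seed=9, peak_z_min=None)
print(f"onset lead 0: {cmp_.onset_a_ms:6.1f} ms")
print(f"onset lead 1: {cmp_.onset_b_ms:6.1f} ms")
print(f"difference:   {cmp_.mean_diff_ms:+6.1f} ms "
      f"(pooled bootstrap SD {cmp_.sd_ms:.1f} ms), "
      f"significant: {cmp_.significant}")
# The estimated difference should sit near the injected -40 ms with the
# flag set: lead 0's response leads lead 1's.
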