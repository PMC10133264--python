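"""Broadband-gamma response characterization of a responsive lead.

Gamma power (50-150 Hz, ten 10-Hz sub-bands averaged, 25 ms bins) is
z-scored against the 1 s pre-onset baseline; a lead is 'responsive' when
its gender-task z exceeds 3 in the static epoch (75-275 ms after onset)
and 'selective' when the action task and the video epoch stay silent.
"""

import numpy as np

import seegflow as sf
from seegflow import BurstSpec, SimConfig, simulate_dataset

cfg = sf.PipelineConfig()
sim = SimConfig(n_leads=3, n_trials_per_task=40, bursts=[
    BurstSpec(lead=0, onset_ms=170.0, duration_ms=120.0, amplitude=1.0,
              task_gate="gender"),
])
tensor, _ = simulate_dataset(sim, seed=4)

p = sf.gamma_power_timecourse(tensor, cfg)
gender = np.flatnonzero(tensor.trial_labels["task"] == "gender")
action = np.flatnonzero(tensor.trial_labels["task"] == "action")
zg = sf.zscore_vs_baseline(p, trials=gender)
za = sf.zscore_vs_baseline(p, trials=action)

for lead in range(tensor.n_leads):
    cls = sf.classify_lead(zg.values[lead], za.values[lead],
                           p.bin_times_ms, cfg)
    print(f"lead {lead}: peak static-epoch z (gender) = "
          f"{cls.sep_peak_gender:5.2f}  responsive={cls.responsive}  "
          f"selective={cls.selective}  latency={cls.latency_ms:.0f} ms  "
          f"duration={cls.duration_ms:.0f} ms"
          if cls.responsive else
          f"lead {lead}: peak static-epoch z (gender) = "
          f"{cls.sep_peak_gender:5.2f}  responsive={cls.responsive}")
# Lead 0 carries the injected burst and should classify responsive and
# selective, with a threshold-crossing latency near the injected 170 ms;
# the silent leads stay below the 3 SD criterion.
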