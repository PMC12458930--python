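#!/usr/bin/env python
"""Force-trace and EMG quantification of myotonia.

Simulates paired tetanic force and EMG recordings for a myotonic and a
non-myotonic genotype, quantifies the mechanical after-contraction
(normalized-force impulse), the electrical run on the EMG envelope
(post-stimulus activity duration), and fits the force-frequency Boltzmann
sigmoid to a control and a right-shifted dataset.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from myorescue.physio import (
    fit_force_frequency,
    force_frequency_sigmoid,
    linear_envelope,
    myotonia_impulse,
    post_stimulus_activity,
    specific_force,
)
from myorescue.simulate import simulate_emg, simulate_force_trace

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for name, amp, run in (("myotonic", 0.35, 0.8), ("non_myotonic", 0.0, 0.0)):
    force = simulate_force_trace(myotonia_amp=amp, myotonia_tau_s=0.25, seed=5)
    impulse = myotonia_impulse(force, window_s=2.0)
    emg, _ = simulate_emg(run_duration_s=run, seed=5)
    env = linear_envelope(emg, cutoff_hz=10.0)
    duration, auc, flagged = post_stimulus_activity(emg, env)
    rows.append({"condition": name, "impulse_au_s": impulse.auc,
                 "emg_activity_duration_s": duration, "emg_activity_auc": auc,
                 "flagged": flagged})

summary = pd.DataFrame(rows)
summary.to_csv(OUT / "myotonia_quantification.tsv", sep="\t", index=False)
print("myotonia quantification:")
print(summary.round(4).to_string(index=False))

# force-frequency: control vs right-shifted (frequency-insensitive) muscle
freqs = np.array([1, 10, 20, 30, 40, 50, 60, 80, 100, 120, 150, 200], float)
rng = np.random.default_rng(5)
ff_rows = []
for name, f_half in (("control", 38.0), ("myotonic", 55.0)):
    y = force_frequency_sigmoid(freqs, 0.05, 1.0, f_half, 8.0) + rng.normal(0, 0.02, freqs.shape)
    fit = fit_force_frequency(freqs, y / y.max())
    ff_rows.append({"condition": name, "f_half_true_hz": f_half,
                    "f_half_fit_hz": fit.f_half, "k_f_hz": fit.k_f})
ff = pd.DataFrame(ff_rows)
ff.to_csv(OUT / "force_frequency_fits.tsv", sep="\t", index=False)
print("\nforce-frequency Boltzmann fits:")
print(ff.round(2).to_string(index=False))

sf = specific_force(peak_mn=150.0, mass_mg=9.0, lo_mm=12.0)
print(f"\nexample soleus specific force (150 mN peak, 9 mg, Lo 12 mm, "
      f"fiber ratio 0.71): {sf:.1f} mN/mm^2")
print("the myotonic condition shows a positive impulse and a prolonged EMG "
      "envelope; the non-myotonic condition relaxes promptly.")
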