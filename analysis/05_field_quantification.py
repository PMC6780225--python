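#!/usr/bin/env python
"""Histology-field quantification: nucleus counts, FND-positive cells,
marker colocalization, and a two-group density comparison.

Emulates the sectioning readout: six random fields per section, DAPI nucleus
counting, perinuclear FND scoring, and Manders colocalization of the FND
channel with a chondrocyte-marker channel (with a block-scramble control).
Two groups are simulated at a 2:1 nucleus density (cell-seeded vs
scaffold-only graft), 8 sections per group.  Writes
results/field_counts.csv and results/colocalization.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fndtrace import (
    FieldQuant,
    FieldSpec,
    ImageField,
    colocalization,
    count_nuclei,
    detect_fnd_cells,
    scramble_blocks,
    simulate_field,
    summarize_fields,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

GROUPS = {"cells_plus_scaffold": 30, "scaffold_only": 15}
N_SECTIONS = 8
N_FIELDS = 6

rows = []
coloc_rows = []
for gi, (group, n_nuclei) in enumerate(GROUPS.items()):
    labeled = 0.5 if group == "cells_plus_scaffold" else 0.0
    for section in range(N_SECTIONS):
        quants = []
        for field_i in range(N_FIELDS):
            seed = int(np.random.SeedSequence([9, gi, section, field_i]).generate_state(1)[0] % 2**31)
            spec = FieldSpec(
                n_nuclei=n_nuclei,
                fnd_labeled_fraction=labeled,
                marker_positive_fraction=0.8 if labeled else 0.0,
                include_marker=True,
                seed=seed,
            )
            f = simulate_field(spec)
            n, label_map = count_nuclei(f)
            n_pos, _ = detect_fnd_cells(f, label_map)
            m1, m2 = colocalization(f, "fnd", "marker")
            quants.append(FieldQuant(f"s{section}f{field_i}", n, min(n_pos, n), m1, m2))
            if labeled and field_i == 0:
                scr = ImageField(
                    channels={
                        "fnd": f.channels["fnd"],
                        "marker": scramble_blocks(f.channels["marker"], 32, seed),
                    },
                    pixel_size_um=f.pixel_size_um,
                )
                m1s, _ = colocalization(scr, "fnd", "marker")
                coloc_rows.append(
                    {"group": group, "section": section, "m1_genuine": m1, "m1_scrambled": m1s}
                )
        s = summarize_fields(quants, n_fields=N_FIELDS)
        rows.append(
            {
                "group": group,
                "section": section,
                "nuclei_mean": s["n_nuclei_mean"],
                "nuclei_sem": s["n_nuclei_sem"],
                "fnd_positive_mean": s["n_fnd_positive_mean"],
                "fnd_positive_sem": s["n_fnd_positive_sem"],
            }
        )

df = pd.DataFrame(rows)
df.to_csv(RESULTS / "field_counts.csv", index=False)
gmeans = df.groupby("group")["nuclei_mean"].mean()
print(df.groupby("group")[["nuclei_mean", "fnd_positive_mean"]].mean()
      .to_string(float_format=lambda v: f"{v:.2f}"))
ratio = gmeans["cells_plus_scaffold"] / gmeans["scaffold_only"]
print(f"\ncell-seeded vs scaffold-only nucleus density ratio: {ratio:.2f} (ground truth 2.0)")

if coloc_rows:
    cdf = pd.DataFrame(coloc_rows)
    cdf.to_csv(RESULTS / "colocalization.csv", index=False)
    print(f"Manders M1 fnd->marker: {cdf.m1_genuine.mean():.3f} genuine vs "
          f"{cdf.m1_scrambled.mean():.3f} after block scrambling "
          "(spatial correspondence, not intensity coincidence)")
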