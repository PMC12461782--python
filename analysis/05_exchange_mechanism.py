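#!/usr/bin/env python
"""Water-ligand exchange mechanism of binding events.

Generates labeled binding-event distance traces (dissociative and
associative, with sub-residence spurious dips planted as negatives),
detects events with the 3.4 A / 20 ps rule, classifies each from the
water-departure ordering, and measures the leaving water's exit
direction relative to the entering amino group. Writes
results/mechanism_summary.csv and results/exit_angles.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import chelkin as ck

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 0

data = ck.synth_binding_trajectory(
    mechanism="mixed", n_events=20, n_spurious=5, noise_sigma=0.2, seed=SEED
)
events = ck.detect_binding_events(data.trajectory)
classified = [
    e for e in (ck.classify_mechanism(ev, data.trajectory) for ev in events)
    if e is not None
]
summary = ck.mechanism_summary(classified)
summary.to_csv(OUT / "mechanism_summary.csv", index=False)

truth = {e["nitrogen_index"]: e["label"] for e in data.events}
correct = sum(e.label == truth.get(e.nitrogen_index) for e in classified)
spurious_hits = sum(e.nitrogen_index >= 20 for e in events)
print(summary.to_string(index=False))
print(
    f"\nDetected {len(events)}/20 planted events ({spurious_hits} of 5 spurious dips "
    f"misdetected); classifier accuracy {100 * correct / len(classified):.0f}% "
    f"at 0.2 A distance noise."
)

geo_data = ck.synth_binding_trajectory(
    mechanism="dissociative", n_events=30, with_coords=True,
    exit_angle=90.0, exit_angle_sigma=10.0, seed=SEED + 1,
)
rows = []
for ev in ck.detect_binding_events(geo_data.trajectory):
    ev = ck.classify_mechanism(ev, geo_data.trajectory)
    geo = ck.leaving_water_geometry(ev, geo_data.trajectory)
    rows.append(
        {
            "event_time_ps": ev.time,
            "exit_angle_deg": geo.angles[-1],
            "exit_radius_A": float(np.linalg.norm(geo.xy[-1])),
        }
    )
df = pd.DataFrame(rows)
df.to_csv(OUT / "exit_angles.csv", index=False)
print(
    f"Leaving water exits at {df.exit_angle_deg.mean():.1f} +/- "
    f"{df.exit_angle_deg.std():.1f} deg to the entering amino group "
    f"(orthogonal departure)."
)
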