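"""Reconstruct integer selection counts from the printed percentages.

With n = 13 (TBI) and n = 11 (control) in the actor test, and the
audience per-scenario group sizes inferred exhaustively, every printed
percentage maps to a unique integer count.  Writes
results/reconstructed_counts.csv and results/action_counts.csv, and
prints the known internal inconsistencies of the source tables.
"""

from pathlib import Path

import pandas as pd

from moralagent.evaluation import KNOWN_DISCREPANCIES
from moralagent.respondents import (reconstruct_action_counts,
                                    reconstruct_counts)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

rows = []
for t in reconstruct_counts():
    for emotion, k in t.counts.items():
        rows.append({"scenario": t.scenario, "role": t.role,
                     "group": t.group, "n": t.n, "emotion": emotion,
                     "count": k, "predicted": emotion in t.predicted,
                     "provisional": t.provisional})
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "reconstructed_counts.csv", index=False)

sizes = (df[df.role != "protagonist"]
         .groupby(["scenario", "role", "group"])["n"].first())
print("inferred audience group sizes:")
print(sizes.to_string())

actions = reconstruct_action_counts()
actions.to_csv(RESULTS / "action_counts.csv", index=False)
print("\naction-choice counts:")
print(actions.to_string(index=False))

print("\nsource-table inconsistencies (recorded, not resolved):")
for note in KNOWN_DISCREPANCIES:
    print(" -", note)
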