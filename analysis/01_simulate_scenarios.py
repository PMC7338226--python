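"""Run the agent on all seven scenarios and check the prediction marks.

For each actor scenario the agent must pick the marked course of action
and end with the marked emotion set; for each audience scenario every
character's final emotions must equal the marks (other-character marks
are provisional transcriptions).  Writes results/scenario_predictions.csv
and per-character traces under results/traces/.
"""

from pathlib import Path

import pandas as pd

from moralagent.scenarios import all_scenario_ids, load_packaged, run_scenario

RESULTS = Path(__file__).resolve().parent.parent / "results"
TRACES = RESULTS / "traces"
TRACES.mkdir(parents=True, exist_ok=True)

rows = []
for sid in all_scenario_ids():
    scen = load_packaged(sid)
    traces = run_scenario(scen)
    plan = traces[scen.protagonist.id].selected_plan() \
        if scen.study == "actor" else ""
    for cid, trace in traces.items():
        expected = (scen.predicted_emotions.get(cid)
                    or scen.provisional_emotions.get(cid))
        if expected is None:
            continue
        got = trace.final_emotion_types()
        rows.append({
            "scenario": sid, "study": scen.study, "character": cid,
            "selected_plan": plan if cid == scen.protagonist.id else "",
            "predicted_plan": scen.predicted_plan or "",
            "emotions": "|".join(sorted(got)),
            "expected_emotions": "|".join(sorted(expected)),
            "provisional": cid in scen.provisional_emotions,
            "match": got == set(expected),
        })
        (TRACES / f"{sid}_{cid}.log").write_text(trace.to_log())

df = pd.DataFrame(rows)
df.to_csv(RESULTS / "scenario_predictions.csv", index=False)
print(df.to_string(index=False))
n_match = int(df["match"].sum())
print(f"\n{n_match}/{len(df)} character predictions reproduced; "
      f"plans: {sum(1 for r in rows if r['selected_plan'] and r['selected_plan'] == r['predicted_plan'])}"
      "/3 actor choices reproduced")
assert df["match"].all(), "a prediction mark failed to reproduce"
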