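# moralagent

A computational model of **moral emotions in story characters**, together
with the evaluation pipeline used to compare how well traumatic-brain-injured
(TBI) participants and neurologically intact controls anticipate a
character's morally-driven choices and feelings.

The package is aimed at researchers in computational affective science and
neuropsychological assessment who want a fully reproducible, scriptable
version of this paradigm: an agent whose deliberation is shaped by moral
values through *anticipated emotions*, a bank of narrative scenarios with
the model's predicted behavior/emotion marks, and the scoring machinery
(emotion scores, error scores, simple matching coefficients, nonparametric
group comparisons) that turns respondent selections into group statistics.

## The model

Characters are **belief–desire–intention (BDI)** agents extended with an
**OCC-style** (Ortony–Clore–Collins) appraisal component and explicit
**moral values**. A goal `g` carries an importance of success `IoS(g)` and
of failure `IoF(g)` plus adoption/success/failure conditions; a value `v`
carries a priority `pr(v)` and violation conditions. Each reasoning cycle
runs six phases: *Value Monitoring → Goal Formation → Emotional
Anticipatory Appraisal → Execution → Monitoring → Emotional Appraisal*.

Changes in goal and value status are appraised into variables
(desirability, undesirability, praiseworthiness, blameworthiness,
likelihood) with intensity

```
intensity = importance × probability-of-success × effort(plan length)
```

and affect derivation maps them to the 12-emotion answer set: joy,
distress, hope, fear, pride, shame, admiration, reproach, and the
compounds gratification (joy+pride), gratitude (joy+admiration), remorse
(distress+shame), anger (distress+reproach), which fire when an
event-based and a standard-based variable share a cause. Plans are ranked
by

```
utility(plan) = p·IoS − (1−p)·IoF + w·EER,
EER = Σ intensity(positive anticipated emotions) − Σ intensity(negative)
```

so a high-priority value deters the plans that would violate it through
the anticipated shame — the mechanism the actor scenarios probe.

Respondent agreement with the model is scored per participant (emotion
total score ETS, moral/non-moral splits MES/N-MES, error scores
ERTS/MERS/N-MERS, action total score ATS) and with the **Simple Matching
Coefficient** over the 12-emotion vector:

```
SMC = (M00 + M11) / (M00 + M01 + M10 + M11)
```

Only marginal selection percentages were published; because the group
sizes are small (n = 13 TBI, n = 11 control), every percentage maps back
to a unique integer count, and every published group mean is linear in
those counts — hence exactly recomputable. The package also generates
synthetic per-participant matrices with exact marginals for the
statistics that need individual rows.

## Worked example

```
$ moralagent simulate --scenario wallace
scenario wallace (actor); config 4763c8c8bddd
selected plan: giving_key (predicted: giving_key)
wallace: shame
```

Wallace's agent weighs betraying his loyalty (anticipated shame,
intensity 0.8 × 0.9 × 0.2 = 0.144) against the near-certain doom of his
family if he refuses; utility 1.48 for giving the key vs −0.78 for
refusing, so he complies — and the final appraisal of his own betrayal
yields exactly the predicted emotion, shame.

```
$ moralagent evaluate
Group score means:
          ATS   ETS   MES  N-MES   ERTS  MERS  N-MERS
TBI      2.15  3.38  2.15   1.23  11.31  8.00    3.31
control  1.82  2.45  1.36   1.09  10.27  7.64    2.64
```

These are the group means recomputed from the packaged marginal tables:
e.g. TBI participants matched on average 3.38 of the model's predicted
emotions over the three actor scenarios but committed 8.00 moral-emotion
errors, versus 7.64 for controls — the characteristic unselective pattern
of the clinical group. The output also flags the cells of the source
tables that are internally inconsistent (e.g. the printed control ATS of
2.00, which the printed percentages contradict).

`moralagent verify` runs every scenario end-to-end and every printed-mean
reproduction and exits non-zero on any failure. The numbered scripts
under `analysis/` walk the same pipeline as a narrative: simulate the
scenarios, reconstruct the counts, score the groups, and demonstrate the
group-comparison statistics on clearly-labeled synthetic data.

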