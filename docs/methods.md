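# Methods

## The agent model

Characters are BDI agents with an OCC-style emotional layer. The world is
a set of ground propositions `pred(arg, ...)`; goal and value conditions
are conjunctions of proposition patterns in which an uppercase-initial
term is a variable unified against the fact base (bindings shared across
the conjunction). There is deliberately no negation-as-failure and no
planner: the condition language is the smallest sufficient for the
packaged scenarios, and plans are authored in the scenario files with a
scalar probability of success, because deliberation *between* given
options — not plan synthesis — is what the model is about.

Each reasoning cycle runs six phases in fixed order:

1. **Value Monitoring** — a value is *at stake* iff one of its violation
   conditions holds; the flag always reflects the last monitoring.
2. **Goal Formation** — goals whose adoption conditions hold become
   active; every value at stake spawns a restoration goal that inherits
   the value's priority as both its importance of success and of failure
   (the model ties value importance to priority but prescribes no
   mapping; equality is the least-committal choice). A restoration goal
   succeeds when its value's violation conditions no longer hold —
   checked directly against the value rather than through the (negation-
   free) condition language. Achieved or failed goals are never
   re-activated.
3. **Emotional Anticipatory Appraisal** — each plan of each active goal
   is mentally simulated on a copy of the world; the resulting goal/value
   changes are appraised into anticipatory emotions, a likelihood
   variable equal to the plan's success probability adds hope (≥ θ_hope)
   or fear (≤ θ_fear), and the agent commits to the plan maximizing
   `p·IoS − (1−p)·IoF + w·EER`. Ties break lexicographically by plan id
   for reproducibility. A plan with an inapplicable step is evaluated
   with its probability treated as 0 and a warning recorded.
4. **Execution** — the chosen plan's outcome is scripted by the scenario
   (the default, for reproducibility) or sampled Bernoulli(p) behind an
   explicit seed. On success the steps' add/delete effects apply in
   sequence; on failure the plan's failure-branch effects apply. Deleting
   an absent fact is a logged no-op.
5. **Monitoring** — scripted exogenous events (other characters' actions,
   or non-intentional happenings) apply here; goal and value statuses are
   re-derived after *each* action or event so that every change carries
   the cause that produced it, which is what responsibility attribution
   and compound-emotion formation need.
6. **Emotional Appraisal** — the accumulated delta is appraised into the
   agent's actual emotions.

The cycle terminates when no active goals remain (and no scripted events
are pending) or at `max_cycles`, in which case the trace carries a
truncation flag. Traces are exportable as line-delimited JSON records
(one per phase) and as a human-readable log; identical inputs produce
byte-identical traces.

### Appraisal and affect derivation

Goal achievement/failure yields desirability/undesirability with
intensity `importance × p × effort`; value violation/restoration yields
blameworthiness/praiseworthiness with intensity `priority × p × effort`,
tagged *self* when the causing action's actor is the appraising agent and
*other* otherwise. Exogenous events use probability 1 and effort 1. The
effort factor is `min(1, plan length / L_ref)` with `L_ref = 5` by
default: the model states only that intensity grows multiplicatively with
effort measured as plan length, so a saturating linear ramp is the
simplest faithful form.

Affect derivation is a fixed rule table (joy/distress, pride/shame for
self-caused praise/blame, admiration/reproach for other-caused,
hope/fear from likelihood against θ_hope = 0.7 / θ_fear = 0.3). A
compound (gratification, gratitude, remorse, anger) fires when its
event-based and standard-based component variables share a cause and
agree in valence; its intensity is the mean of the components. Whether
the components are co-emitted alongside the compound is a configuration
flag, default co-emit: the published prediction marks require joy, pride
*and* gratification together in one actor scenario but gratification
*alone* in one audience scenario, so the flag is per-scenario and the
"Vicomte of Bragelonne" fixture selects suppression. All thresholds and
weights (θ_hope, θ_fear, L_ref, w) are surfaced in `AffectConfig`, not
hard-coded.

EER sums positive-valence anticipated intensities minus negative ones,
with compounds and (under co-emission) their components each counted as
felt — double-counting a fused emotion is a modeling choice, applied
consistently; the sign-flip invariance under valence mirroring holds
either way.

### Scenario fixtures

The seven scenario files encode the published narrative situations; the
original goal/value encodings were not published, so the numerics here
are authored to satisfy the ordinal constraints the narratives imply
(e.g. Wallace's family outweighs his loyalty; Anna's family duty
outweighs her career) and are constrained end-to-end: the engine must
reproduce the published prediction marks — selected plan and final
emotion set per character — exactly, which the test suite and `verify`
command enforce. Other-character marks in the audience test come from a
typographically corrupted source table; they are encoded with a
`provisional` flag, asserted against our own fixtures, and never used as
acceptance targets.

## Respondent data

Only marginal percentages of emotion/action selection were published.
With n = 13 (TBI) and n = 11 (control), `k = round(pct·n/100)` recovers a
unique count; each reconstruction must round-trip to the printed
one-decimal percentage within 0.06 (strict rounding gives ≤ 0.05; the
margin absorbs the source's occasionally inconsistent rounding, which
prints e.g. 0.769 as 0.76 but 0.818 as 0.82). Audience group sizes are
unprinted because participants could split sessions; they are inferred as
the smallest n ≤ 30 consistent with every non-zero percentage, giving
15/10 (Hamlet), 14/8 (Montecristo), 13/9 (Thérèse Raquin), 13/10
(Bragelonne) for TBI/control.

The synthetic generator emulates n respondents each ticking a subset of
the 12 emotions per scenario. `exact_marginal` mode places exactly k ones
per emotion on a seeded permutation of participants, so column sums are
exact and **any statistic linear in them is seed-invariant**;
`bernoulli` mode draws i.i.d. with p = k/n. What the synthetic data does
*not* model: within-participant correlation across emotions and
scenarios, which the published marginals cannot identify. Consequently,
reproduced group means and mean SMCs are exact, while dispersion
statistics (SDs, U statistics, correlations) computed on synthetic
matrices characterize only the synthetic joint distribution — they are
reported as synthetic and never compared against the source.

## Scoring

The moral partition is {admiration, reproach, gratification, gratitude,
pride, shame, anger, remorse}; non-moral is {joy, distress, fear, hope}.
(The source's prose lists a few labels — contempt, blame, sadness — that
are not in the 12-emotion answer set; this operational partition is the
one that reproduces every published moral/non-moral mean from the
marginals.) Match scores count selected∩predicted within the partition
class; error scores count commissions plus omissions. Selections of
*hope* are excluded from commissions by default (`hope_rule`): only this
rule reproduces the published non-moral error means (3.31 TBI, 2.64
control), and it is a documented, toggleable divergence from the prose
definition. ETS = MES + N-MES and ERTS = MERS + N-MERS hold identically
under a single error semantics.

The group-mean SMC has a closed form in the marginals: predicted emotions
contribute their selection count, non-predicted ones n − count, over
|subset|·n. This equals per-participant averaging for any joint
distribution with those marginals; the pipeline computes every table both
ways and requires agreement to 10⁻¹².

Mann–Whitney U is computed from midranks; the two-tailed p doubles the
smaller exact tail (capped at 1), using the exact distribution when the
pooled sample is tie-free, complete permutation enumeration under ties
while the arrangement count is tractable, and the tie-corrected normal
approximation beyond. Spearman's ρ uses average ranks, with complete
permutation enumeration of p up to n = 8, a seeded 20 000-resample Monte
Carlo permutation for n ≤ 10, and the t-approximation beyond — the
enumeration cutoff reflects that n! arrangements stop being worth exact
treatment well before the asymptotic p becomes accurate enough for these
sample sizes.

## Known source inconsistencies (recorded, not resolved)

* Control ATS prints 2.00; the printed percentages give 20/11 = 1.82.
* Control ERTS prints 10.2, a one-decimal truncation of 113/11 = 10.27.
* "At school!" all-emotion SMCs print 0.57/0.60; the marginals give
  0.60/0.63. "A difficult choice" control all-emotion SMC prints 0.65
  vs 0.67. The moral-only control global SMC prints 0.70 vs 0.68.

These cells are flagged in every report and excluded from verification;
all other published means and SMCs reproduce at printed precision (SMCs
within ±0.005 plus one unit in the second decimal, the source's
truncation-vs-rounding wobble).

## Limitations

* The fixtures' numeric priorities are sufficient, not unique: many
  parameterizations reproduce the same marks; conclusions should rest on
  the ordinal structure, which is documented per scenario file.
* Passing the end-to-end tests shows the model and fixtures jointly
  reproduce the published predictions, not that the model would predict
  fresh scenarios without authored encodings.
* The agent attributes responsibility only through the acting character
  of a cause; there is no deeper theory of mind, no natural-language
  layer, and no planner, all outside the model's scope.
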