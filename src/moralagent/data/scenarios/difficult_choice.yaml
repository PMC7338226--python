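# Actor scenario 3: Anna can stay to care for her gravely ill mother or
# leave to start her career abroad, which she had promised her partner.
# Staying fulfils the duty of care (joy) but forfeits the career dream
# (distress) and breaks the promise (shame, remorse).  The model predicts
# staying, with exactly that bittersweet mixture.
id: difficult_choice
study: actor
title: A difficult choice
narrative: >
  Anna's mother has fallen gravely ill just as Anna received the job
  offer abroad she had long hoped for -- and had promised her partner
  they would leave together.  Staying means giving up the offer and
  breaking the promise; leaving means abandoning her mother.  Family
  duty weighs most for Anna.
world:
  - ill(mother)
  - offer(job)
  - promised(partner)
max_cycles: 1
characters:
  - id: anna
    protagonist: true
    goals:
      - id: care_for_mother
        importance_of_success: 0.9
        importance_of_failure: 0.9
        adoption: [["ill(mother)"]]
        success: [["cared_for(mother)"]]
        failure: [["abandoned(mother)"]]
      - id: career_abroad
        importance_of_success: 0.6
        importance_of_failure: 0.3
        adoption: [["offer(job)"]]
        success: [["career_started(anna)"]]
        failure: [["refused(job)"]]
    values:
      - id: promise_keeping
        priority: 0.4
        violation: [["broken(promise)"]]
      - id: family_duty
        priority: 0.9
        violation: [["abandoned(mother)"]]
    plans:
      - id: staying
        goal: care_for_mother
        probability_of_success: 0.9
        steps:
          - id: stay
            actor: anna
            add: ["cared_for(mother)", "refused(job)", "broken(promise)"]
      - id: leaving
        goal: career_abroad
        probability_of_success: 0.9
        steps:
          - id: leave
            actor: anna
            add: ["career_started(anna)", "abandoned(mother)"]
script:
  cycles:
    - outcomes: {staying: true, leaving: true}
predictions:
  plan: staying
  emotions:
    anna: [distress, joy, shame, remorse]
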