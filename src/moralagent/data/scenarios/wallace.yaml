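# Actor scenario 1: a guard is coerced into handing over a key to protect
# his threatened family.  Complying betrays his loyalty to his lord;
# refusing almost certainly dooms the family.  The model predicts that he
# gives the key -- and that he feels shame for it.
id: wallace
study: actor
title: Wallace
narrative: >
  Wallace keeps the key to the stronghold.  His family is threatened:
  unless he hands the key to the besiegers, they will take revenge on
  them.  Giving the key betrays the trust placed in him; refusing it is
  near-certain doom for his family.  His loyalty matters to him, but his
  family's safety matters more.
world:
  - threatened(family)
max_cycles: 1
characters:
  - id: wallace
    protagonist: true
    goals:
      - id: save_family
        importance_of_success: 0.9
        importance_of_failure: 0.9
        adoption: [["threatened(family)"]]
        success: [["safe(family)"]]
        failure: [["doomed(family)"]]
    values:
      - id: loyalty
        priority: 0.8
        violation: [["gave_key(wallace)"]]
    plans:
      - id: giving_key
        goal: save_family
        probability_of_success: 0.9
        steps:
          - id: give_key
            actor: wallace
            add: ["gave_key(wallace)"]
      - id: refusing_key
        goal: save_family
        probability_of_success: 0.2
        steps:
          - id: refuse_key
            actor: wallace
            add: ["refused(wallace)", "doomed(family)"]
script:
  cycles:
    - outcomes: {giving_key: true, refusing_key: true}
predictions:
  plan: giving_key
  emotions:
    wallace: [shame]
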