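# Actor scenario 2: a kid humiliated by a bully can take revenge or walk
# away.  Revenge restores the kid's injured dignity and punishes the
# bully, but violates the (weakly held) norm against violence.  The model
# predicts revenge, felt as joy, pride and gratification mixed with shame.
id: at_school
study: actor
title: At school!
narrative: >
  A kid has been bullied and publicly humiliated at school.  Getting even
  would punish the bully and restore the kid's dignity, but it means
  hurting someone; letting it go means swallowing the humiliation.
  Dignity weighs more for the kid than the rule against violence.
world:
  - bullied(kid)
  - humiliated(kid)
max_cycles: 1
characters:
  - id: kid
    protagonist: true
    goals:
      - id: get_justice
        importance_of_success: 0.8
        importance_of_failure: 0.5
        adoption: [["bullied(kid)"]]
        success: [["punished(bully)"]]
        failure: [["resigned(kid)"]]
    values:
      - id: dignity
        priority: 0.7
        violation: [["humiliated(kid)"]]
      - id: nonviolence
        priority: 0.3
        violation: [["hurt(bully)"]]
    plans:
      - id: revenging
        goal: get_justice
        probability_of_success: 0.8
        steps:
          - id: take_revenge
            actor: kid
            add: ["punished(bully)", "hurt(bully)"]
            delete: ["humiliated(kid)"]
      - id: letting_go
        goal: get_justice
        probability_of_success: 0.9
        steps:
          - id: walk_away
            actor: kid
            add: ["resigned(kid)"]
script:
  cycles:
    - outcomes: {revenging: true, letting_go: true}
predictions:
  plan: revenging
  emotions:
    kid: [joy, pride, shame, gratification]
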