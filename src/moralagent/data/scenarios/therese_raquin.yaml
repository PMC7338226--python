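# Audience scenario: Therese Raquin.  Therese and her lover Laurent drown
# her husband Camille.  For each of them their own part in the murder
# violates a deeply held value (self-caused) and destroys the untroubled
# life they had: distress, shame, and their compound, remorse.
id: therese_raquin
study: audience
title: Therese Raquin
narrative: >
  Therese, trapped in a dull marriage to the sickly Camille, takes his
  friend Laurent as her lover.  During a boat outing Therese lets it
  happen and Laurent drowns Camille.  The murder stains them both and
  poisons the life they hoped to share.
world:
  - married(therese, camille)
  - alive(camille)
max_cycles: 1
characters:
  - id: therese
    protagonist: true
    goals:
      - id: peaceful_life
        importance_of_success: 0.6
        importance_of_failure: 0.8
        adoption: [["married(therese, camille)"]]
        failure: [["dead(camille)"]]
    values:
      - id: fidelity
        priority: 0.9
        violation: [["dead(camille)"]]
  - id: laurent
    goals:
      - id: carefree_life
        importance_of_success: 0.6
        importance_of_failure: 0.8
        adoption: [["alive(camille)"]]
        failure: [["complicit(laurent)"]]
    values:
      - id: loyalty
        priority: 0.8
        violation: [["complicit(laurent)"]]
script:
  cycles:
    - events:
        - id: drowning
          actor: therese
          add: ["dead(camille)"]
          delete: ["alive(camille)"]
        - id: complicity
          actor: laurent
          add: ["complicit(laurent)"]
predictions:
  emotions:
    therese: [remorse, distress, shame]
  provisional_emotions:
    laurent: [remorse, distress, shame]
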