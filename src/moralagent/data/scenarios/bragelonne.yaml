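# Audience scenario: The Vicomte of Bragelonne.  Athos petitions the king
# and secures a commission for his son Raoul, at once fulfilling his hopes
# for the boy and discharging his paternal duty: the published prediction
# is the fused compound alone -- gratification for Athos, gratitude for
# Raoul toward his father -- so this scenario suppresses the component
# emotions of a compound instead of co-emitting them.
id: bragelonne
study: audience
title: The Vicomte of Bragelonne
narrative: >
  Athos has yet to settle the future of his son Raoul.  He petitions the
  king and obtains for Raoul a commission in the royal service: his
  fatherly duty is discharged and Raoul's career is made.  Raoul owes his
  standing to his father's deed.
world:
  - unprovided(raoul)
max_cycles: 1
affect:
  co_emit_components: false
characters:
  - id: athos
    protagonist: true
    goals:
      - id: advance_son
        importance_of_success: 0.9
        importance_of_failure: 0.7
        adoption: [["unprovided(raoul)"]]
        success: [["commissioned(raoul)"]]
    values:
      - id: paternal_duty
        priority: 0.8
        violation: [["unprovided(raoul)"]]
  - id: raoul
    goals:
      - id: military_career
        importance_of_success: 0.8
        importance_of_failure: 0.6
        adoption: [["unprovided(raoul)"]]
        success: [["commissioned(raoul)"]]
    values:
      - id: family_standing
        priority: 0.7
        violation: [["unprovided(raoul)"]]
script:
  cycles:
    - events:
        - id: royal_petition
          actor: athos
          add: ["commissioned(raoul)"]
          delete: ["unprovided(raoul)"]
predictions:
  emotions:
    athos: [gratification]
  provisional_emotions:
    raoul: [gratitude]
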