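# Audience scenario: The Count of Montecristo.  Edmond, long ago betrayed
# and unjustly imprisoned, finally exposes Fernand.  His own act achieves
# his revenge and rights the standing injustice: joy and pride fused into
# gratification.  Fernand loses everything -- distress (other-character
# prediction, provisional).
id: montecristo
study: audience
title: The Count of Montecristo
narrative: >
  Edmond Dantes was betrayed by Fernand and unjustly imprisoned while
  Fernand rose to wealth and title.  Years later, as the Count of
  Montecristo, Edmond exposes Fernand's treachery before the world,
  ruining him and finally righting the old injustice.
world:
  - betrayed(edmond)
  - rich(fernand)
  - unpunished(fernand)
max_cycles: 1
characters:
  - id: edmond
    protagonist: true
    goals:
      - id: revenge
        importance_of_success: 0.9
        importance_of_failure: 0.8
        adoption: [["betrayed(edmond)"]]
        success: [["ruined(fernand)"]]
    values:
      - id: justice
        priority: 0.8
        violation: [["unpunished(fernand)"]]
  - id: fernand
    goals:
      - id: keep_status
        importance_of_success: 0.7
        importance_of_failure: 0.8
        adoption: [["rich(fernand)"]]
        failure: [["ruined(fernand)"]]
script:
  cycles:
    - events:
        - id: exposure
          actor: edmond
          add: ["ruined(fernand)"]
          delete: ["unpunished(fernand)"]
predictions:
  emotions:
    edmond: [joy, gratification, pride]
  provisional_emotions:
    fernand: [distress]
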