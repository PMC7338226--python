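# Audience scenario: Hamlet.  Gertrude's hasty remarriage to Claudius
# betrays the memory of the dead king: for Hamlet the event both defeats
# his wish to honor his father and violates his value of fidelity,
# other-caused -- distress, reproach and their compound, anger.  Ophelia,
# pressed by her father, deceives Hamlet; her own act violates her
# sincerity, felt as shame (other-character prediction, provisional).
id: hamlet
study: audience
title: Hamlet
narrative: >
  The old king is dead.  Barely a month later Queen Gertrude marries his
  brother Claudius; to Hamlet the wedding is a betrayal of his father's
  memory.  Meanwhile Ophelia, obeying her father, turns Hamlet away and
  returns his letters, deceiving the man who loves her.
world:
  - dead(king_hamlet)
  - loves(ophelia, hamlet)
max_cycles: 1
characters:
  - id: hamlet
    protagonist: true
    goals:
      - id: honor_father
        importance_of_success: 0.8
        importance_of_failure: 0.8
        adoption: [["dead(king_hamlet)"]]
        success: [["honored(king_hamlet)"]]
        failure: [["married(gertrude, claudius)"]]
    values:
      - id: fidelity
        priority: 0.9
        violation: [["married(gertrude, claudius)"]]
  - id: ophelia
    values:
      - id: sincerity
        priority: 0.8
        violation: [["deceived(hamlet)"]]
  - id: gertrude
script:
  cycles:
    - events:
        - id: hasty_wedding
          actor: gertrude
          add: ["married(gertrude, claudius)"]
        - id: returning_letters
          actor: ophelia
          add: ["deceived(hamlet)"]
predictions:
  emotions:
    hamlet: [reproach, anger, distress]
  provisional_emotions:
    ophelia: [shame]
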