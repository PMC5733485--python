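# Default CIB composite map: composite -> constituent 1-5 Likert scales,
# per infant age group. Scale membership differs by age; entries marked
# reversed are flipped (r -> 6 - r) before averaging. This file is the
# single source of truth for composite membership; edit or replace it to
# adopt a different reading.
"4m":
  Maternal sensitivity:
    - Acknowledgement
    - Imitation
    - Elaborating
    - Positive affect
    - Vocal appropriateness
    - Appropriate range of affect
    - Resourcefulness
    - Supportive presence
  Maternal intrusiveness:
    - Overriding
  Infant involvement:
    - Gaze/Joint attention
    - Positive affect (infant)
    - Alert
    - Vocalizations/Verbal output
    - Initiation
  Infant negativity:
    - Negative emotionality
  Dyadic reciprocity:
    - Dyadic reciprocity
    - Fluency
    - Adaptation-Regulation
  Dyadic negative states:
    - Constriction
  Parent-led:
    - Parent-led
  Child-led:
    - Child-led
"13m":
  Maternal sensitivity:
    - Acknowledgement
    - Elaborating
    - Positive affect
    - Vocal appropriateness
    - Appropriate range of affect
    - Resourcefulness
    - Supportive presence
  Maternal intrusiveness:
    - Overriding
  Maternal limit-setting:
    - Consistency of style
    - On-task persistence
    - Appropriate structure
  Infant involvement:
    - Gaze/Joint attention
    - Alert
    - Vocalizations/Verbal output
    - Initiation
    - {scale: Fatigue, reversed: true}
    - Competent use of environment
    - Creative symbolic play
  Infant negativity:
    - Negative emotionality
    - Labile affect
  Infant compliance:
    - Compliance to parent
    - On-task persistence
  Dyadic reciprocity:
    - Dyadic reciprocity
    - Fluency
    - Adaptation-Regulation
  Dyadic negative states:
    - Constriction
  Parent-led:
    - Parent-led
  Child-led:
    - Child-led
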