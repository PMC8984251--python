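# Two-center questionnaire catalog used by the synthetic cohort generator.
# The Tinnitus Questionnaire (TQ) is the only instrument administered at
# both centers; tinnitus distress and depressivity are the only shared
# topical categories.  Item counts are instrument-typical values; only the
# counts and the category/center structure matter for the analysis.
questionnaires:
  TQ:
    items: 52
    category: tinnitus_distress
    centers: [CHA, UHREG]
    score_range: [0, 84]
  TLQ:
    items: 12
    category: tinnitus_distress
    centers: [CHA]
  THI:
    items: 25
    category: tinnitus_distress
    centers: [UHREG]
  TFI:
    items: 25
    category: tinnitus_distress
    centers: [UHREG]
  TBF12:
    items: 12
    category: tinnitus_distress
    centers: [UHREG]
  CGI:
    items: 1
    category: tinnitus_distress
    centers: [UHREG]
  BI:
    items: 24
    category: physical_strain
    centers: [CHA]
  ADSL:
    items: 20
    category: depressivity
    centers: [CHA]
  BSF:
    items: 30
    category: depressivity
    centers: [CHA]
  MDI:
    items: 10
    category: depressivity
    centers: [UHREG]
  PSQ:
    items: 20
    category: stress
    centers: [CHA]
  SF8:
    items: 8
    category: quality_of_life
    centers: [CHA]
  SWOP:
    items: 9
    category: coping
    centers: [CHA]
  SOZK:
    items: 20
    category: sociodemographics
    centers: [CHA]
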