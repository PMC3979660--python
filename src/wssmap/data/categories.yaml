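# JMP-style response-category vocabulary for household water and sanitation
# modules. Categories are matched after lower-casing and whitespace
# collapsing. Survey-specific synonyms may be merged in at run time.
improved_water:
  - piped water into the dwelling
  - piped water to yard/plot/compound
  - public tap or standpipe
  - tubewell or borewell
  - protected dug well
  - protected spring
  - rainwater
improved_sanitation:
  - flush toilet
  - piped sewer system
  - septic tank
  - ventilated improved pit latrine (vip)
  - pit latrine with slab
  - composting toilet
open_defecation:
  - no facilities
  - bush
  - field
  - no facilities or bush or field
  - bush or field
# categories that are pit latrines of unstated construction; treated as
# unimproved unless slab status is known to be "with slab"
ambiguous_pit_latrine:
  - pit latrine
  - traditional pit latrine
  - pit latrine without slab/open pit
water_synonyms:
  piped into dwelling: piped water into the dwelling
  piped to yard/plot: piped water to yard/plot/compound
  public tap/standpipe: public tap or standpipe
  tube well or borehole: tubewell or borewell
sanitation_synonyms:
  piper sewer system: piped sewer system
  flush to piped sewer system: piped sewer system
  flush to septic tank: septic tank
  vip latrine: ventilated improved pit latrine (vip)
  ventilated improved pit latrine: ventilated improved pit latrine (vip)
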