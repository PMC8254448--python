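# Illustrative guideline table (synthetic stand-in).
#
# First/second-choice empiric regimens per RTI/UTI sub-indication, keyed by
# ATC level-5 code. The entries sketch the *shape* of a national empiric
# guideline (single agents, combinations for severe CAP, an oral-route
# constraint for nitrofurantoin, non-assessable 'other' codes); they are NOT
# the Dutch SWAB recommendations. Production audits must supply the current
# national table in this same layout.
#
# Agents used:
#   J01CA04 amoxicillin            J01CR02 amoxicillin-clavulanic acid
#   J01DD04 ceftriaxone            J01DC02 cefuroxime
#   J01MA02 ciprofloxacin          J01MA14 moxifloxacin
#   J01XE01 nitrofurantoin         J01XX01 fosfomycin
#   J01EA01 trimethoprim           J01AA02 doxycycline
#   J01CE01 benzylpenicillin       J01FA01 erythromycin
#   J01GB03 gentamicin             J01XD01 metronidazole (parenteral)

CAP:                      # severity not distinguished in the EMR
  assessable: true
  first_choice:
    - [J01CA04]
  second_choice:
    - [J01DD04]

CAP-m:
  assessable: true
  first_choice:
    - [J01CA04]
  second_choice:
    - [J01AA02]

CAP-s:
  assessable: true
  first_choice:
    - [J01DD04]
    - [J01DD04, J01FA01]
  second_choice:
    - [J01MA14]

HAP:
  assessable: true
  first_choice:
    - [J01DD04]
  second_choice:
    - [J01MA02]

COPD:
  assessable: true
  first_choice:
    - [J01CA04]
  second_choice:
    - [J01AA02]

aspiration-pneumonia:
  assessable: true
  first_choice:
    - [J01CE01, J01XD01]
  second_choice:
    - [J01CR02]

bronchitis:
  assessable: true
  first_choice:
    - [J01AA02]
  second_choice:
    - [J01CA04]

other-RTI:
  assessable: false
  first_choice: []
  second_choice: []

cystitis:
  assessable: true
  first_choice:
    - [J01XE01]
  second_choice:
    - [J01XX01]
    - [J01EA01]
  route_constraint:
    J01XE01: oral

complicated-UTI:
  assessable: true
  first_choice:
    - [J01DD04]
  second_choice:
    - [J01MA02]
    - [J01CA04, J01GB03]

chronic-prostatitis:
  assessable: true
  first_choice:
    - [J01MA02]
  second_choice:
    - [J01EA01]

other-UTI:
  assessable: false
  first_choice: []
  second_choice: []
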