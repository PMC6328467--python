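# Chain map and transmembrane-segment residue ranges for the gamma-secretase
# Cryo-EM structure 5FN2 (and its siblings 5FN3/5FN4/5FN5, which share the
# chain layout and numbering).
#
# CONVENTION, not data: no deposited annotation fixes the helix boundaries
# used in the original tilt/alignment protocols.  The ranges below follow
# standard topology annotation for PSEN1/PEN-2/APH-1a, trimmed to the
# membrane-spanning span; they are the package default and can be overridden
# by pointing any analysis at a different config file.
chains:
  A: NIC
  B: PS1
  C: APH1
  D: PEN2
frame_period: 1.0
segments:
  PS1-TMD1: {subunit: PS1, range: [82, 102]}
  PS1-TMD2: {subunit: PS1, range: [133, 153]}
  PS1-TMD3: {subunit: PS1, range: [164, 184]}
  PS1-TMD4: {subunit: PS1, range: [195, 215]}
  PS1-TMD5: {subunit: PS1, range: [221, 241]}
  PS1-TMD6: {subunit: PS1, range: [244, 264]}
  PS1-TMD7: {subunit: PS1, range: [381, 401]}
  PS1-TMD8: {subunit: PS1, range: [407, 427]}
  PS1-TMD9: {subunit: PS1, range: [433, 453]}
  PS1-LOOP2: {subunit: PS1, range: [265, 380]}
  APH1-TMD1: {subunit: APH1, range: [7, 27]}
  APH1-TMD2: {subunit: APH1, range: [36, 56]}
  APH1-TMD3: {subunit: APH1, range: [66, 86]}
  APH1-TMD4: {subunit: APH1, range: [96, 116]}
  APH1-TMD5: {subunit: APH1, range: [127, 147]}
  APH1-TMD6: {subunit: APH1, range: [161, 181]}
  APH1-TMD7: {subunit: APH1, range: [193, 213]}
  PEN2-H1: {subunit: PEN2, range: [17, 37]}
  PEN2-H2: {subunit: PEN2, range: [41, 61]}
  PEN2-H3: {subunit: PEN2, range: [63, 83]}
  NIC-TMD: {subunit: NIC, range: [670, 690]}
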