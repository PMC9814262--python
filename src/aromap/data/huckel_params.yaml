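# Editable Hückel parameter overrides (units of |beta|).
# Keys: "<element>,<pi electrons contributed>"; couplings "<key>-<key>".
# Values below restate the built-in Van Catledge defaults for the most
# common centers; edit and pass to HuckelParams.from_yaml to override.
onsite:
  "N,1": 0.51
  "N,2": 1.37
  "O,1": 0.97
  "O,2": 2.09
  "S,2": 1.11
  "F,2": 2.71
  "Cl,2": 1.48
coupling:
  "C,1-N,1": 1.02
  "C,1-N,2": 0.89
  "C,1-O,1": 1.06
  "C,1-O,2": 0.66
  "C,1-S,2": 0.69
  "C,1-F,2": 0.52
  "C,1-Cl,2": 0.62
ev_map:
  ip_slope: 2.2
  ip_offset: -7.0
  ea_slope: 2.2
  ea_offset: -1.7
  gap_slope: 2.0
  gap_offset: 0.8
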