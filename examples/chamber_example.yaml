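# Illustrative current-divider chamber (synthetic interpretation).
#
# Three stimulation sections of identical rectangular cross-section sit in
# series along the main channel; after s1 and s2 a bypass branch shunts part
# of the current back to the return reservoir, so the field steps down
# section by section.  The bypass resistances were solved so that a 43.5 uA
# input produces 4.7 / 2.7 / 1.0 mV/mm in s1 / s2 / s3 with sigma = 1.5 S/m.
# The real chamber's exact wiring is not published in full; treat this file
# as a schema example, not as ground-truth geometry.
#
# All units SI: metres, ohms, siemens per metre, amperes, farads, volts.

electrolyte:
  sigma: 1.5

source:
  from: anode
  to: cathode
  i_in: 43.5e-6

electrode:
  diameter: 15.0e-3
  capacitance: 54.333e-3     # with voltage_window: C * dV = 32.6 mC
  voltage_window: 0.6

edges:
  - {from: anode, to: n0, resistance: 200.0}
  - from: n0
    to: n1
    geometry: {length: 10.0e-3, width: 7.7127659574468075e-3, height: 0.8e-3, label: s1}
  - {from: n1, to: cathode, resistance: 2023.850574712644}
  - from: n1
    to: n2
    geometry: {length: 10.0e-3, width: 7.7127659574468075e-3, height: 0.8e-3, label: s2}
  - {from: n2, to: cathode, resistance: 664.9763353617308}
  - from: n2
    to: n3
    geometry: {length: 10.0e-3, width: 7.7127659574468075e-3, height: 0.8e-3, label: s3}
  - {from: n3, to: cathode, resistance: 50.0}
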