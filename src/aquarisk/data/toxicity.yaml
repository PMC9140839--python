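# Toxicity reference values (editable).
# rfd_* mg/(kg d); csf_* (mg/(kg d))^-1; csf omitted for non-carcinogens.
As:
  rfd_drinking: 0.0003
  rfd_dermal: 0.000123
  csf_drinking: 1.5
  csf_dermal: 3.66
Cd:
  rfd_drinking: 0.0005
  rfd_dermal: 0.000005
  csf_drinking: 0.38
  csf_dermal: 6.1
Cr:
  rfd_drinking: 0.003
  rfd_dermal: 0.00006
  csf_drinking: 41
  csf_dermal: 41
Ni:
  rfd_drinking: 0.02
  rfd_dermal: 0.02
Pb:
  rfd_drinking: 0.0014
  rfd_dermal: 0.0014
Cu:
  rfd_drinking: 0.005
  rfd_dermal: 0.005
Zn:
  rfd_drinking: 0.3
  rfd_dermal: 0.06
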