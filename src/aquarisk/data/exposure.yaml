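# Receptor exposure parameters (editable).
# BW kg | AT days | EF days/year | IR L/day | ABS_GI - | ED years
# KP cm/h | ET h/day | SA cm^2
adult:
  BW: 62.4
  AT: 10950
  EF: 350
  IR: 2.2
  ABS_GI: 1
  ED: 30
  KP: 0.001
  ET: 0.5
  SA: 16600
kid:
  BW: 20.08
  AT: 4380
  EF: 350
  IR: 1.0
  ABS_GI: 1
  ED: 12
  KP: 0.001
  ET: 0.5
  SA: 9500
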