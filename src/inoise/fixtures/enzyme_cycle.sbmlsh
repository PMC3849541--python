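@model = enzyme_cycle
  omega = 50
@compartments
  cell = 1
@species
  S = 0.20000000000000001
  E = 0.5
  C = 0.5
@parameters
  delta = 0.5
  E_total = 1
  k1 = 10
  km1 = 1
  k2 = 1
  k_in = 0.5
@reactions
@r = influx
   -> S
  0.5
@r = binding
  S + E <-> C
  10, 1
@r = catalysis
  C -> E
  1
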