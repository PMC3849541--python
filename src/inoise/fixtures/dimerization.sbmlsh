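@model = dimerization
  omega = 10
@compartments
  cell = 1
@species
  A = 0
@parameters
  k_in = 1
  k_dim = 1
@reactions
@r = influx
   -> A
  1
@r = dimerization
  2 A -> 
  1
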