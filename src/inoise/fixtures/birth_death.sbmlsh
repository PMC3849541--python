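@model = birth_death
  omega = 100
@compartments
  cell = 1
@species
  X = 0
@parameters
  k_in = 1
  k_out = 0.10000000000000001
@reactions
@r = birth
   -> X
  1
@r = death
  X -> 
  0.10000000000000001
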