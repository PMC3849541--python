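@model = srna_set_i
  concentration_unit = uM
  time_unit = min
  omega = 667
@compartments
  cell = 1
@species
  M = 0 "mRNA"
  P = 0 "protein"
  E = 0.10000000000000001 "degradation enzyme"
  C = 0 "enzyme-protein complex"
  S = 0 "small RNA"
@parameters
  k0G = 0.024
  kdM = 0.20000000000000001
  ks = 1.5
  km1 = 2
  k2 = 2
  k1 = 400
  kdS = 0.20000000000000001
  kR = 100
  alpha = 1
  k0S = 0.024
  enzyme_total = 0.10000000000000001
@reactions
@r = transcription
   -> M
  0.024
@r = mrna_decay
  M -> 
  0.20000000000000001
@r = translation
  M -> M + P
  1.5
@r = enzyme_binding
  P + E <-> C
  400, 2
@r = protein_degradation
  C -> E
  2
@r = srna_transcription
   -> S
  0.024
@r = srna_decay
  S -> 
  0.20000000000000001
@r = srna_mrna_removal
  S + M -> 
  100
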