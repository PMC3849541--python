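@model = srna_set_ii
  concentration_unit = uM
  time_unit = min
  omega = 667
@compartments
  cell = 1
@species
  M = 0 "mRNA"
  P = 0 "protein"
  E = 0.01 "degradation enzyme"
  C = 0 "enzyme-protein complex"
  S = 0 "small RNA"
@parameters
  k0G = 0.0023999999999999998
  kdM = 0.20000000000000001
  ks = 1.5
  km1 = 2
  k2 = 2
  k1 = 4000
  kdS = 0.20000000000000001
  kR = 1000
  alpha = 1
  k0S = 0.0023999999999999998
  enzyme_total = 0.01
@reactions
@r = transcription
   -> M
  0.0023999999999999998
@r = mrna_decay
  M -> 
  0.20000000000000001
@r = translation
  M -> M + P
  1.5
@r = enzyme_binding
  P + E <-> C
  4000, 2
@r = protein_degradation
  C -> E
  2
@r = srna_transcription
   -> S
  0.0023999999999999998
@r = srna_decay
  S -> 
  0.20000000000000001
@r = srna_mrna_removal
  S + M -> 
  1000
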