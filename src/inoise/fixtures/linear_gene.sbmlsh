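@model = linear_gene
  omega = 1
@compartments
  cell = 1
@species
  M = 0
  P = 0
@parameters
  k0 = 1
  ks = 5
  kdM = 1
  kdp = 0.20000000000000001
@reactions
@r = transcription
   -> M
  1
@r = mrna_decay
  M -> 
  1
@r = translation
  M -> M + P
  5
@r = protein_decay
  P -> 
  0.20000000000000001
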