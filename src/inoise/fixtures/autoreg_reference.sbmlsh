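@model = autoreg_reference_1gene
  concentration_unit = nM
  time_unit = h
  omega = 450
@compartments
  cell = 1
@species
  G = 0.0022222222222222222 "free gene"
  GPs = 0 "singly repressed gene"
  GPs2 = 0 "doubly repressed gene"
  M = 0 "mRNA"
  P = 0 "protein"
  Ps = 0 "phosphorylated protein"
  K = 10 "kinase"
  KP = 0 "kinase-protein complex"
  R = 10 "phosphatase"
  RPs = 0 "phosphatase complex"
  E = 100 "protease (P)"
  EP = 0 "protease-P complex"
  D = 10 "protease (Ps)"
  DPs = 0 "protease-Ps complex"
@parameters
  flux0 = 50
  ks = 50
  kdM = 5
  kdp = 0.5
  k1 = 0.5
  km1 = 1
  k2 = 0.5
  km2 = 1
  k3_factor = 0.5
  km3 = 450
  k4_over_k3 = 50
  km4 = 450
  k5 = 0.25
  km5 = 0.5
  kp5 = 0.5
  k6 = 5
  km6 = 5
  kp6 = 10
  omega_tilde = 450
  k0 = 22500
  k3 = 225
  k4 = 11250
  kp1 = 10
  kp2 = 10
  n_genes = 1
  K_total = 10
  R_total = 10
  E_total = 100
  D_total = 10
@reactions
@r = transcription
  G -> G + M
  22500
@r = mrna_decay
  M -> 
  5
@r = translation
  M -> M + P
  50
@r = protein_dilution
  P -> 
  0.5
@r = kinase_binding
  K + P <-> KP
  0.5, 1
@r = phosphorylation
  KP -> K + Ps
  10
@r = phosphatase_binding
  R + Ps <-> RPs
  0.5, 1
@r = dephosphorylation
  RPs -> R + P
  10
@r = operator1_binding
  Ps + G <-> GPs
  225, 450
@r = operator2_binding
  Ps + GPs <-> GPs2
  11250, 450
@r = proteaseE_binding
  P + E <-> EP
  0.25, 0.5
@r = P_degradation
  EP -> E
  0.5
@r = proteaseD_binding
  Ps + D <-> DPs
  5, 5
@r = Ps_degradation
  DPs -> D
  10
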