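# inoise

Intrinsic-noise analysis of biochemical reaction networks by the
system-size expansion of the chemical master equation, with exact
stochastic simulation as the reference.

## Who this is for

Modellers of gene regulation and small biochemical circuits who need the
size of molecular fluctuations — coefficients of variation and Fano
factors of mRNA, protein or metabolite copy numbers — across wide
parameter ranges, where brute-force Gillespie averaging is too slow and
the linear noise approximation may be too crude.  The package answers,
quantitatively: *when can you trust the LNA, and what do the
next-order corrections say when you cannot?*

## The methods

A well-mixed network of N species and R reactions
s<sub>1j</sub>X₁+…+s<sub>Nj</sub>X<sub>N</sub> →
r<sub>1j</sub>X₁+…+r<sub>Nj</sub>X<sub>N</sub> in a volume carrying
Ω molecules per unit concentration obeys a chemical master equation for
P(n, t).  Expanding it in powers of Ω<sup>−1/2</sup> about the
macroscopic trajectory (n/Ω = [X] + Ω<sup>−1/2</sup> ε) yields, order by
order:

| order | block | equations |
|---|---|---|
| Ω<sup>1/2</sup> | rate equations (REs), d[X]/dt = Σⱼ νⱼ fⱼ([X]) | N (nonlinear) |
| Ω<sup>0</sup> | LNA covariances: J σ + σ Jᵀ + D = 0 | N(N+1)/2 |
| Ω<sup>−1/2</sup> | EMRE mean corrections [εᵢ]₁ and third moments [εᵢεₖεₗ]₁ | N + N(N+1)(N+2)/6 |
| Ω<sup>−1</sup> | covariance corrections [εᵢεⱼ]₂ ("IOS") | N(N+1)/2 |

Here J is the Jacobian of the REs and D = Σⱼ νⱼνⱼᵀ fⱼ the diffusion
matrix.  Noise measures expand as
CV<sub>i</sub> = CV<sub>i</sub><sup>LNA</sup>(1 + c<sub>i</sub>/Ω) and
F<sub>i</sub> = F<sub>i</sub><sup>LNA</sup>(1 + f<sub>i</sub>/Ω); the
correction factors c, f vanish identically for networks of first-order
reactions and grow with the bimolecular rate constants.  Everything is
solved after exact integer conservation analysis eliminates the
dependent species (a closed 14-species gene circuit reduces to 9
independent species and 273 expansion equations, 264 of them linear at
steady state).

Alongside the expansion: Gillespie's direct method (compiled with
numba) with event-weighted time averaging, a brute-force stationary
solver of the truncated master equation for small systems, analytic LNA
power spectra and averaged SSA periodograms for noise-induced
oscillations, and steady-state parameter scans.

## Worked example

The bundled negative-autoregulation circuit (gene, mRNA, protein, a
phosphorylation cycle and two proteases; 14 species, 20 reactions):

```
$ inoise info autoreg
model: autoreg_reference_1gene
species: 14
reactions: 20
conservation laws: 5
independent species: 9
ios equations: 273 (9 nonlinear + 264 linear)
  law 0: D + DPs = 10
  law 1: E + EP = 100
  law 2: R + RPs = 10
  law 3: K + KP = 10
  law 4: G + GPs + GPs2 = 0.00222222
```

Conservation analysis finds the five molecular pools (gene, kinase,
phosphatase, two proteases), so the expansion runs on 9 species: 9
nonlinear rate equations plus 264 linear equations for the
covariances and their finite-volume corrections.

Noise measures for the sRNA-regulation model at the transcription
crossover (α = 1), as a tidy CSV:

```
$ inoise steadystate srna_i --order ios
species,order,measure,value
M,lna,mean,10.591618798106259
M,lna,variance,28.169894715457847
M,lna,cv,0.5277867710247889
M,lna,fano,2.6985737948624915
M,ios,cv,0.5236241756166261
M,ios,fano,2.656007093672645
...
```

Reading: the stationary mRNA level is ~10.6 molecules with variance
28.2, i.e. a Fano factor of 2.70 under the LNA — strongly
super-Poissonian because the sRNA–mRNA annihilation couples the two
transcripts.  The next-order (IOS) estimate lowers it to 2.66: near the
crossover the LNA *over*estimates transcript noise, and stochastic
simulations side with the corrected value.

The same analyses are available as library calls
(`inoise.sse_steady_state`, `inoise.ios_measures`,
`inoise.stationary_stats`, `inoise.lna_spectrum_ss`,
`inoise.steady_state_scan`, …); models come from SBML-shorthand files
(`inoise.read_sbmlsh`), the bundled builders in `inoise.models`, or
`inoise.build_network`.

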