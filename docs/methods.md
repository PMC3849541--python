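# Methods

## Model class and assumptions

`inoise` analyses well-mixed, mass-action reaction networks with at most
bimolecular reactions (order 0, 1 or 2; a third-order reactant raises an
error rather than silently extending the machinery).  The system size Ω
is stored as *molecules per unit concentration*, so copy number
n = Ω·x with no hidden Avogadro factors: a 50 fl compartment with
concentrations in nM has Ω ≈ 30 molecules/nM.  Propensities follow the
statistical law of mass action, with the combinatorial n(n−1) factor for
homodimeric reactions.  Custom (non-mass-action) propensity strings are
parsed and accepted by the stochastic simulator only; the expansion
tensors are defined for mass action.

All expansion methods require a *monostable* deterministic regime: a
unique stable fixed point of the reduced rate equations.  The steady
state solver refuses unstable or non-converged fixed points, naming the
offending eigenvalue; parameter scans flag such points and continue.

## Conservation analysis

Conserved pools make the Jacobian singular, so the expansion always runs
on the reduced network.  An integer basis Γ of the left null space of
the stoichiometric matrix S is computed exactly over the rationals
(sympy) and scaled to primitive integer vectors; Γ·S = 0 is asserted in
integer arithmetic.  The species eliminated by each law is the
last-indexed species it contains (implemented as a reduced row echelon
form with columns scanned from the last species to the first), which
makes the choice deterministic and reproducible.  Eliminated species are
affine functions of the retained ones; because the laws hold exactly
along every stochastic path, their fluctuations are the same linear
images, and means/covariances of eliminated species are recovered
without approximation.

A subtlety when comparing against discrete references (stochastic
simulation or the brute-force stationary solver): the discrete initial
state is `round(Ω·x₀)`, so if Ω times a conserved total is not an
integer the discrete chain lives on a *different conservation manifold*
than the continuous expansion (e.g. an enzyme total of 7.5 copies
becomes 8).  Comparisons in the test suite therefore use volumes for
which Ω × totals is integral.  This is a property of any
discrete-vs-continuum comparison, not of the implementation.

## The expansion blocks

Writing n/Ω = [X] + Ω^(−1/2) ε and expanding both the step operators and
the mass-action propensities (whose Ω^(−1) part f¹ⱼ comes from the
combinatorial factors: f¹ⱼ = −kⱼX_A for a reaction consuming 2A, zero
otherwise), collecting orders and taking moments yields, with
J = Σⱼ νⱼ∇fⱼ, D = Σⱼ νⱼνⱼᵀfⱼ and the mixed tensors
D³ᵢₖₗ = Σⱼ νᵢⱼνₖⱼνₗⱼfⱼ, J²ᵢ,ₖₗ = Σⱼ νᵢⱼ∂ₖ∂ₗfⱼ,
D²¹ᵢₖ,ₗ = Σⱼ νᵢⱼνₖⱼ∂ₗfⱼ (and the f¹ analogues J¹, J¹g, D¹, D²²):

* mean correction:  d[ε]₁/dt = J[ε]₁ + h,  hᵢ = ½ J²ᵢ,ₘₙ σₘₙ + J¹ᵢ
* third moments Tᵢₖₗ = [εᵢεₖεₗ]₁:
  dT/dt = (J T)_sym + (D ⊗ [ε]₁)_sym + (h ⊗ σ)_sym + (J² σ σ)_sym
  + (D²¹ σ)_sym + D³
* covariance correction s² = [εε]₂:
  ds²/dt = J s² + s² Jᵀ + ½(J² : T)_sym + (J¹ ⊗ [ε]₁)_sym + D²¹·[ε]₁
  + (J¹g σ)_sym + ½ D²² : σ + D¹

The only closure used is the Gaussian (Wick) factorisation of fourth
moments of ε under the leading-order distribution, which is exact at the
order retained.  For networks of at most bimolecular reactions the
macroscopic rates are at most quadratic, so all third derivatives vanish
and — given the rate-equation solution — every block above is *linear*.
Because these coefficient equations are easy to get wrong, they are
gated by independent oracles in the test suite rather than trusted:
exactness on first-order networks (corrections identically zero),
closed-form checks (birth–death: σ = X*, [ε³]₁ = X*, s² = 0), and
log–log fits of the residual error against the brute-force stationary
master equation on dimerisation and enzyme-cycle models, which must give
slope −2 ± 0.1 (each method accurate to one order beyond its leading
term).  Measured slopes are ≈ −2.00 to −2.02.

### Steady state and time course

Steady state: the N reduced rate equations are relaxed by LSODA until
the right-hand side is small, then polished with damped Newton to a
relative residual of 10⁻¹⁰.  The remaining blocks are solved directly —
σ and s² by Bartels–Stewart Lyapunov solves with iterative refinement
(rate constants spanning five decades can leave a single solve several
digits short; refinement brings the residual below 10⁻¹⁰·‖D‖), [ε]₁ by
one linear solve, and T through the Kronecker-sum operator
J⊕J⊕J on the full n³ tensor (n ≤ 14, so the dense solve is trivial) —
never by pseudo-time integration.

Time course: all blocks are packed into one state vector using the
symmetric packings i ≤ j and i ≤ k ≤ l (lexicographic).  The packing is
part of the public contract: an N-species reduced model integrates
exactly 2N + N(N+1) + N(N+1)(N+2)/6 equations (N = 9 → 273, of which
264 are linear).  Deterministic initial conditions imply all fluctuation
blocks start at zero.  Integration uses LSODA with rtol 10⁻⁸ / atol
10⁻¹² (exposed via `SSEConfig`).

### Noise measures

CV and Fano factors are reported for molecule numbers (Fano is
unit-dependent; a concentration-unit table would differ by Ω).  At LNA
order CV = Ω^(−1/2)√σᵢᵢ/Xᵢ and F = σᵢᵢ/Xᵢ; at IOS order the relative
corrections are applied multiplicatively,
CV·(1 + c/Ω) and F·(1 + f/Ω) with
c = ([εᵢεᵢ]₂ − [εᵢ]₁²)/(2σᵢᵢ) − [εᵢ]₁/(2Xᵢ) and f = 2c (both the
variance part and the mean part double).  Species whose deterministic mean is below 10⁻¹² are
excluded from tables rather than producing infinities.  IOS variances
are not guaranteed nonnegative outside the validity regime; a negative
value triggers a warning naming the species, not an error.

## Stochastic simulation

Gillespie's direct method, compiled with numba; the next-reaction
method is unnecessary at these network sizes.  Stationary statistics are
event-weighted time averages (piecewise-constant integration between
events), which avoids grid-discretisation bias; grid sampling exists
only for spectra.  Standard errors come from batch means over 16 equal
sub-windows.  Convergence is monitored at doubling checkpoints of the
averaging window; a run is flagged converged when mean and Fano change
by less than 1% between the last two checkpoints.  Plain (uncorrected)
estimators are reported; for short windows they are biased, which is why
the standard errors and the convergence flag are part of the output.
One named 32-bit seed drives each trajectory; ensembles and scans derive
per-run seeds from a `numpy.random.SeedSequence` spawned from the master
seed, so every figure is reproducible from one integer.

### Brute-force master-equation oracle

For small models the stationary distribution is computed exactly on a
truncated lattice: states are enumerated by breadth-first reachability
from the initial state within per-species copy-number caps, transitions
leaving the box are dropped, and the stationary vector of the truncated
generator is obtained by a sparse linear solve with one balance row
replaced by normalisation.  The probability mass on states with a
dropped transition is reported as the truncation deficit and must stay
below a bound (default 10⁻⁸).  This oracle is the arbiter for the
expansion's order-of-accuracy tests and for SSA cross-validation; it is
practical up to a few times 10⁴ states (one to three independent
species at the volumes used here).

## Power spectra

The LNA spectrum of the stationary fluctuations is
S(ω) = (Ω/2π)(J + iωI)⁻¹D(Jᵀ − iωI)⁻¹ (diagonal entries), in angular
frequency and normalised so that the two-sided integral equals the
molecule-number variance Ωσᵢᵢ — the normalisation is pinned by this
variance contract, and `SpectrumResult.variance_integral` evaluates it.
The SSA estimator is a Bartlett-averaged, Hann-windowed, mean-removed
periodogram of grid-sampled realisations with the same normalisation,
verified on white noise and on the birth–death Lorentzian
S(ω) = D/(2π(ω² + k²)).  A Nyquist guard compares the sampling interval
against the analytic peak location before simulating.  Peak statistics
(interior maximum exceeding S(0), located by local quadratic
refinement) report frequency, period 2π/ω*, and amplitude √(peak
power); absence of a peak is a valid result, and a 1-species LNA
spectrum is always monotone.

## Benchmark models and the choice of undocumented constants

Two published case studies are encoded with their printed rate
constants (tests assert every printed value verbatim):

**sRNA post-transcriptional regulation** (µM, min): transcription of
mRNA and of an sRNA at relative rate α, translation, enzymatic protein
degradation (P + E ⇌ C → E) and sRNA–mRNA mutual removal.  Two printed
parameter sets differ tenfold in transcription and in both bimolecular
associations.  The compartment volume and enzyme total are not printed;
defaults are Ω = 667 molecules/µM (≈1.1 fl) and enzyme totals of
0.1 µM (set i) / 0.01 µM (set ii), sized so the degradation capacity
exceeds the unregulated translation flux with ~10% free-enzyme reserve.
This puts the unregulated protein at ≈60 copies (set i) and ≈6 (set ii),
the regimes the analysis targets.  The printed product "k₀[G]" is
encoded directly as the zeroth-order transcription flux with the
constant gene pool folded in (5 species, 9 reactions).

**Negative autoregulation** (nM, h): transcription from a free
promoter, translation, a kinase/phosphatase phosphorylation cycle,
repression by the phosphorylated protein at two operator sites
(cooperative: the second association is 50× the first), and two
dedicated proteases — 14 species, 20 irreversible reactions, 5 pools,
9 independent species.  Printed rate products of the form "50·Ω̃ (nM)"
are interpreted as flux × Ω̃: the transcription rate constant is
k₀ = flux₀·Ω̃/N_G with flux₀ = 50 nM/h, so a single gene at
concentration 1/Ω̃ transcribes at 50 nM/h and the deterministic steady
state is independent of the gene copy number; likewise
k₃ = 0.5 nM·Ω̃ (nM h)⁻¹.  The pool totals K, R, E, D and the two
catalytic rates of the cycle are not printed; reference-variant
defaults are K = R = D = 10 nM, E = 100 nM, k_cat = 10 h⁻¹, giving a
stable fixed point with damped oscillations and ~89% repressed promoter
at the printed k₃.  The oscillatory variant (Ω̃ = 30 nM⁻¹, i.e. 50 fl;
flux₀ = 3000 nM/h) uses proportionally larger pools with doubled
protease headroom (K = R = D = 600 nM, E = 12000 nM): without the
headroom the proteases saturate for epochs long compared to the
oscillation period and episodic expression collapse swamps the spectrum
at low frequencies.  With it, the single-gene circuit shows a clear
noise-induced spectral peak (LNA period ≈ 1.25 h) whose amplitude and
period the LNA *underestimates* relative to simulation, and the effect
weakens as the gene copy number grows at fixed deterministic state.

Validation models: birth–death (Poisson closed forms), the two-stage
linear gene expression model (protein Fano 1 + k_s/(k_dM + k_dp),
derived symbolically in the tests), an enzymatic degradation cycle
parameterised by the stationary free-enzyme fraction δ (influx set to
k₂E_T(1−δ)), and dimerisation (the smallest network with a
combinatorial propensity; its one-dimensional master equation is the
cheapest brute-force reference).

### What the fixtures do and do not show

The defaults above reproduce the documented qualitative regimes:
transcript Fano factors peaking near the α-crossover with the
next-order peaks below the Gaussian ones, the protein-CV optimum of
set (i), the mean-level inversion at sub-single-copy sRNA, and the
spectral-peak underestimation.  Two published shape contrasts could
*not* be reproduced under the printed rate constants for any setting of
the unprinted pools we searched, and their tests are left failing
deliberately: (1) for set (ii), a Gaussian-level CV minimum coexisting
with a monotone corrected CV — in this implementation the spurious LNA
minimum only appears near enzyme saturation, exactly where the relative
correction is large and decreasing in α, so the corrected curve dips
wherever the LNA does (simulation, the final arbiter, is monotone, and
the corrected estimate tracks it inside its validity window); (2) for
the feedback-strength sweep, an interior maximum of the Gaussian mRNA
CV — we find the Gaussian CV monotone in the repressed fraction in every
pool regime, with simulations *above* it at strong feedback.  Both
hinge on constants the source tables omit.  These fixtures are
synthetic stand-ins for the published figure conditions in that
specific sense: rate constants are exact, pools and volumes are
documented choices.

Passing tests show correctness of the mathematics on mass-action
networks at these sizes; they do not show that any fixture quantitively
matches a particular laboratory system, nor that the expansion is
reliable when its corrections become O(1) (it is not, and the warning
machinery flags the symptom, negative variances, not the cause).

## Problem sizes and tolerances used in the shipped checks

Brute-force comparisons run at Ω between 6 and 80 (≤ a few times 10³
lattice states), SSA cross-checks average 2×10⁴–6×10⁴ time units after
a 5% burn-in, and the spectral comparison uses 4 realisations of 100 h
sampled at 0.1 h.  These sizes keep the full suite under ~2 minutes on
one core while leaving the Monte Carlo bands a few times wider than the
effects being asserted.  Steady-state residual 10⁻¹⁰ (relative),
Lyapunov residual 10⁻¹⁰·‖D‖, ODE tolerances rtol 10⁻⁸/atol 10⁻¹²,
master-equation truncation deficit 10⁻⁸ unless a test states otherwise.

## Known limitations

* Mass action only for the expansion; reaction order ≤ 2.
* Monostable regimes only; no bistability, limit cycles, or
  time-dependent rates.
* Mean corrections are carried to order Ω⁻¹ (the Ω⁻² mean term is out
  of scope; the variance correction already requires it only through
  the products retained).
* The brute-force oracle scales exponentially with independent species;
  it is a validation tool, not an analysis method.
* SSA performance is adequate for the bundled models (~10⁶–10⁸ events);
  no tau-leaping or hybrid acceleration.
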