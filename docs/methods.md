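# Methods

## The model

Glycolysis is modeled as a deterministic ODE system dx/dt = N·v(x) over
the free intracellular metabolites (Glc_in, Glc6P, Fru6P, Fru1,6BP,
DHAP, G3P, 1,3BPG, 3PG, 2PG, PEP, Pyr, ATP, ADP, NAD⁺, NADH, and in the
HeLa models intracellular lactate), with boundary species held constant:
extracellular glucose and lactate, inorganic phosphate, and the fixed
modulators Ery4P, 6PG, Fru2,6BP and citrate.  Each of the 12–13 enzymatic
steps (GLUT, HK, HPI, PFK-1, ALDO, TPI, GAPDH, PGK, PGAM, ENO, PYK, LDH,
plus the monocarboxylate carrier MCT in HeLa) is a closed-form
steady-state rate law with experimentally meaningful constants; four
first-order closure reactions (ATP turnover, a hexose-phosphate drain
toward glycogen/pentose phosphate, a triose-phosphate drain, and in
AS-30D none for redox since the GAPDH–LDH couple closes NAD⁺/NADH)
balance the cofactor cycles.

Cell-line differences follow the biology: AS-30D uses a one-isoform
glucose carrier, a hexokinase with mixed-type Fru1,6BP inhibition, an HPI
inhibited competitively by Ery4P, 6PG, Fru1,6BP *and* DHAP, and
mixed-type Fru1,6BP inhibition on TPI and GAPDH; intracellular lactate is
a boundary (no MCT step).  HeLa uses two-isoform GLUT and HK laws without
the Fru1,6BP feedback on HK/TPI/GAPDH, a three-inhibitor HPI (DHAP
excluded: its Ki of 9.4 mM is far above the 0.5–0.8 mM physiological
range), free intracellular lactate and an MCT export step.  The three
HeLa conditions differ in external glucose (25 / 5 / 1 mM) and in
carrier/hexokinase capacity.

Units: concentrations in mM, rates in mM·min⁻¹; equilibrium constants
are dimensionless on the concentration scale (the GAPDH Keq carries one
inverse-mM power).

### Rate-law conventions

* Ligand roles (A, B, C, P, Q, S, I, …) are bound to species by *name* in
  each `ReactionKinetics` record.  The stoichiometry map and the kinetic
  roles are independent, so reordering reactants in a reaction definition
  can never silently swap which concentration enters which term — a known
  hazard when rate equations and reaction syntax are maintained
  separately in GUI simulators.
* Mixed-type inhibition is implemented in the canonical Segel form
  v = (Vf·s − Vr·p) / (1 + I/Ki + (s + p)(1 + I/(αKi))), with a single α
  shared across all inhibitors of a reaction.  Every published layout of
  these laws that preserves detailed balance reduces algebraically to
  this form; it collapses to the uninhibited law at I = 0 and keeps the
  equilibrium point independent of I.
* The PFK-1 law is the concerted-transition (MWC) model with exclusive
  binding: occupancy term φ(1+φ)³/(L_app + (1+φ)⁴), φ the
  activator-rescaled Fru6P occupancy, multiplied by a hyperbolic ATP
  factor and a mixed-activation prefactor, minus a simple reversible MM
  block for the reverse reaction.  The apparent transition constant is
  L_app = L(1+CIT/Ki_CIT)⁴(1+ATP/Ki_ATP)⁴/(1+F26BP/Ka)⁴.  Whether the
  activator term divides or multiplies L is genuinely ambiguous in
  printed renderings of this law, so both readings sit behind the
  `activator_grouping` switch; the default ("divide") is the only
  physically sensible one — Fru2,6BP is an activator and must *lower* the
  apparent L — and the only one that makes the rate monotonically
  increasing in Fru2,6BP.
* Thermodynamic consistency: families whose numerator is written with
  Keq ((AB − PQ/Keq)-type) are consistent by construction; families with
  an explicit Vmr satisfy the Haldane relation (e.g. Vmr = Vmf·Kp/(Ks·Keq)
  for uni-uni), checked by `validate_model` and used by the synthetic
  sampler to derive every reverse rate.  Note that the Keq-form and
  Vmr-form random Bi-Bi laws share numerators under the Haldane choice
  but differ in two denominator cross terms (AQ/KaKq, PB/KpKb): they
  coincide exactly only on product-free states.

### Conservation structure

Moiety conservation is recovered, not declared: the integer left null
space of N over free species is computed exactly (sympy, rational
arithmetic) and cached by network signature.  Both cell-line networks
conserve ATP+ADP and NAD⁺+NADH; the AS-30D network additionally
conserves the lower-glycolysis pool 1,3BPG+3PG+2PG+PEP+Pyr+NAD⁺, a
consequence of treating intracellular lactate as a boundary (GAPDH is
the only entry into that pool and LDH the only exit, and they are
redox-coupled).  Steady states therefore depend on the conserved totals
implied by the initial concentrations; totals are state, not parameters,
and the uniqueness checks in the test suite perturb initial conditions
*within* the conservation manifold.

## Steady states

Two phases: LSODA integration in geometrically growing time chunks
(capped at 10⁴ min per chunk; BDF retried when LSODA reports failure)
until max|dxᵢ/dt|/max(|xᵢ|, 1 mM) < 10⁻⁹, then a Newton polish
(`scipy.optimize.root`, hybr with an lm fallback) on the moiety-reduced
equations N_R·v = 0, reaching residuals near machine precision.  A hard
budget of 60 000 right-hand-side evaluations per solve turns pathological
stiff grinds (possible for extreme random parameter sets) into a clean
`IntegrationError` carrying the last state.  Transient negative
excursions clamp rate-law inputs at zero and set a diagnostic flag.

Glycolysis has an absorbing "dead" steady state with ATP = 0 (the ATP
invested by HK/PFK-1 cannot be repaid once the triose pool empties).  It
is a genuine fixed point; `control_coefficients` refuses to run there,
since flux control is undefined at zero flux.

## Control analysis

The operational route scales each reaction's activity constants (Vmf and
Vmr together, preserving Keq) by (1 ± δ), re-solves the steady state
(Newton warm-started from the reference), and forms scaled central
differences; δ = 0.01 by default, inside the linear regime (halving δ
moves coefficients by < 10⁻³).  On hypersensitive models — random
parameter sets close to the fold into the dead state can have control
coefficients of order ten — a 1% step leaves the linear regime; the
finite-difference routine detects this through the summation-theorem
residuals and halves δ (down to 1.25×10⁻³) until the theorems close.  The structural route computes unscaled
elasticities ε = ∂v/∂x at the steady state and evaluates
C_S = −L(N_R ε L)⁻¹N_R, C_J = I + εC_S.  Because every rate law is
exactly linear in its activity constants, activity-based and rate-based
coefficients coincide.  Summation theorems hold to ~10⁻³ (finite
differences) and ~10⁻¹⁰ (matrix method); the two routes agree to < 0.02
on every model tested.  Summation closes only over *all* reactions —
closure steps (ATPase, drains) carry real control and are always
included.

## The curated parameter presets

Complete experimentally fitted parameter tables for these cell lines are
not available in machine-readable form, so the presets in
`glycontrol.presets` are curated synthetic stand-ins, assembled once
from (i) published inhibition constants — the HPI constants
(Ki_Ery4P = 1 µM, Ki_Fru1,6BP = 60 µM, Ki_6PG = 15 µM, Ki_DHAP = 9.4 mM)
and the mixed-type α = 2; (ii) textbook equilibrium constants, never
tuned; and (iii) physiologically plausible Km/Vmax values chosen so that
flux control concentrates upstream (GLUT/HK dominant, downstream enzymes
in catalytic excess), steady-state metabolites sit in the measured ranges
(Fru1,6BP ≈ 1–3 mM, DHAP ≈ 1–2 mM, ATP ≈ 5–7 mM, flux ≈ 10–20 mM/min),
and the feedback loops operate near their inhibition constants.

These presets reproduce the *structure* of the control analysis
measured in these cell lines — the exact producer/consumer sign pattern of concentration
control on Fru1,6BP and DHAP in all four models, the decoupling of flux
from downstream titration without feedback, and the
uncompetitive > mixed > competitive potency ordering — but not the
reported coefficient magnitudes, which depend on the full experimental
Vmax/Km tables (e.g. here GAPDH carries most of the negative
concentration control that experimentally fitted models attribute to
ENO and PYK).  Passing
tests therefore certify the method implementations and the qualitative
claims, not a numerical transcription of the original models.

## Synthetic data

`sample_model` draws every binding, inhibition, maximal-rate, closure
and allosteric constant log-uniformly within a multiplicative spread
around its preset reference (default ×3; ×10 for L, ×2 for α/β), clipped
to broad physiological envelopes (Km/Ki 0.01–10 mM, L 1–10⁶, α/β
0.1–10), then derives all reverse rates from the Haldane relations.
Equilibrium constants and isoform fractions are never sampled.  Draws
whose steady state collapses into the ATP-depleted dead state are
rejected and redrawn deterministically from the same seed (≈85% of
draws are viable; fully independent draws across the whole envelopes
were measured to collapse ~98% of the time, which is why the sampler is
reference-anchored).  Same seed, same model.

`simulate_observations` emulates metabolite tables (mean ± sd over n
replicate preparations): each readout is multiplied by mean-preserving
lognormal noise with a chosen CV (default 0.3, resembling the dispersion
of perchloric-acid extract assays); treatments are enzyme-activity
scalings, which is also how the pathway inhibitors oxamate and
iodoacetate are represented (ENO/PYK/LDH and GAPDH activity reduction,
not explicit drug-binding species).  What the generator does *not*
emulate: correlated assay errors across metabolites, systematic
extraction losses, day effects, or any OxPhos contribution to ATP.
`recover_activity_factor` inverts the generator by bounded 1-D
minimization of squared log-residuals; noiseless recovery is exact to
< 0.01 and at CV 0.2 the median over seeds stays within ±0.05 of truth.

## Numerical choices and degenerate inputs

* Integration: rtol 10⁻⁸, atol 10⁻⁹ mM; convergence on the scaled
  derivative norm at 10⁻⁹; Newton target residual 10⁻¹².
* Ki → ∞ (feedback-scenario toggling) is implemented as term removal,
  never as a large number, to avoid conditioning artifacts.
* Elasticities at |v| < 10⁻¹² are reported unscaled with a flag (the
  scaled coefficient is undefined).
* Near-singular reduced Jacobians (condition number > 10¹²) abort the
  matrix method with the near-null directions named.
* Models with no free species (all-boundary toys) short-circuit to a
  trivially converged "steady state" so that single-reaction control
  checks work.

## Known limitations

* Absolute fluxes/coefficients depend on the curated presets; only
  structural and qualitative claims transfer to the real cell lines.
* No OxPhos/adenylate-kinase coupling: the ATP/ADP ratio is shaped by
  glycolysis and a first-order ATPase alone.
* No methylglyoxal branch; DHAP toxicity is outside the kinetic model.
* The SBML layer is a subset (L3v2 core, content MathML, boundary flags,
  package annotations); it round-trips its own documents and evaluates
  foreign kinetic laws composed of +, −, ×, ÷, powers, exp and ln, but
  does not implement events, rules, function definitions or unit
  declarations, and performs structural rather than XSD validation.
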