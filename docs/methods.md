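# Methods

This note documents the models, estimators, numerical choices and known
limitations of `dcmflux`.

## Stoichiometric core

Species are element→count maps with integer charges; reactions are
species→signed-coefficient maps parsed from a plain-text grammar
(`2 CH2Cl2 + 2 H2O -> CH3COO- + 5 H+ + 4 Cl-`, explicit `e-` allowed).
Balance checks use exact rational arithmetic (`fractions.Fraction`), so a
reaction either balances to zero in every element and in charge or it does
not; there is no floating-point tolerance to tune.

The tetrahydrofolate carrier is modelled as an opaque pseudo-element `Fol`:
methylene-tetrahydrofolate is `Fol + C` (one carbon at the formaldehyde
oxidation level) and methyl-tetrahydrofolate is `Fol + CH2` (methanol
level). Because the carrier passes through every reaction unchanged it
cancels exactly in balances, which is how the packaged WLP reactions are
written. Mean carbon oxidation states use the fixed rules H = +1, O = −2,
Cl = −1, N = −3, `Fol` = 0 with net charge honoured; these are unambiguous
for every species in scope (the N = −3 choice covers all amines present).
A test asserts that for each redox fixture the explicit electron coefficient
equals the total change in carbon oxidation number, tying the two
bookkeeping systems together.

The per-acetate electron costs of the two acetogenic routes (4 e⁻ via
methylene reduction, 8 e⁻ via bicarbonate reduction) are derived at call
time from the balanced route reactions — coefficient of `e-` divided by the
coefficient of acetate — not stored as constants.

## Electron-partition flux model

Per mole of DCM entering as methylene, with partition fraction *f* of the
released electrons directed to bulk-bicarbonate reduction:

- methylene oxidised: *w* = 1/(2−*f*) (4 e⁻ released each);
- acetate via methylene reduction: (1−*f*)/(2−*f*);
- acetate via pool-bicarbonate reduction: *f*/(2(2−*f*)).

These follow from closing the methylene pool (oxidised + reduced = 1) and
the electron pool (4*w* = 4·methylene-route + 8·pool-route). Two exact
invariants hold for every *f*: total acetate = ½ per DCM, and bicarbonate
produced by oxidation equals bicarbonate consumed by acetogenesis (net flux
zero). `solve_fluxes` therefore computes in exact rationals, and the
property tests assert equality, not approximate closeness.

The inverse map from a labelled:unlabelled acetate molar ratio *r* is
*f* = e_pool/(e_pool + e_methylene·*r*) = 2/(2+*r*), consistent with the
route ratio of the forward solution; *r* = 1 gives *f* = 2/3 (67%).

### Isotopologue model

Acetate positions follow standard numbering (C1 = carboxyl, C2 = methyl).
Label state is governed by the ¹³C atom fractions of the methylene pool
(`p_methylene`) and the bulk bicarbonate pool (`p_pool`), and by a single
channeling probability *q*: any bicarbonate-derived carbon uses freshly
oxidised, methylene-derived bicarbonate (label fraction `p_methylene`) with
probability *q*, else the well-mixed bulk pool. *q* applies identically to
the carboxyl carbon of both routes, and pool-route carbons are labelled
independently (no pairing information is available to justify otherwise).
The bulk pool is treated as constant over the experiment (quasi-steady
30 mM pool); time-resolved label dynamics are out of scope.

The expected-dilution helper (labelled source / unlabelled pool, in %)
quantifies what a well-mixed pool would contribute; observed double-labelled
acetate far above it is the signature of channeling.

### Inverse fitting

`fit_isotope_params` minimises the sum of squared differences between model
and observed class fractions. A deterministic grid (step 0.01 per free
parameter; 0.05 when more than two are free) is scanned first; ties resolve
to the lexicographically smallest parameter vector (smallest *f*, then *q*).
The grid optimum seeds a bounded Nelder–Mead refinement
(xatol 1e-10, fatol 1e-14), so the whole procedure is deterministic.
Classes that an instrument did not resolve can be masked; model and
observation are then renormalised over the remaining classes. One-hot
observations with more than one free parameter are flagged non-identifiable
(the fit is still returned). Round-tripping the forward model recovers
(*f*, *q*) to better than 1e-3. Real observed distributions need not be
exactly representable by any (*f*, *q*) pair; the residual is reported, not
forced to zero.

## Carbonate speciation

Given measured aqueous bicarbonate, dissolved CO₂ follows from the first
dissociation equilibrium ([CO₂aq] = [HCO₃⁻][H⁺]/Ka1), the headspace partial
pressure from Henry's law, and the headspace amount from the ideal gas law
at the flask temperature. Gas-phase amounts are reported as
liquid-equivalent µM (µmol per litre of liquid), the convention used by the
labelled-pool ledger. Defaults Ka1 = 4.45×10⁻⁷ mol/l and
KH = 29.4 l·atm/mol are the conventional 25 °C values and are overridable,
because flask pH, temperature and volumes vary between setups and are often
not reported — which is also why measured headspace pools are accepted as
ledger *inputs* rather than re-predicted. Carbonate ion is neglected
(negligible below pH 8 in bicarbonate-buffered medium); no activity
corrections or temperature-dependent constants are attempted. Isotopologues
are assumed to partition identically, making the labelled-pool calculation
linear in the labelled concentration.

## Mass balance

Recovery is the sum of the labelled pools (µM ¹³C atoms) over the labelled
carbon consumed, in percent, reported unclamped — measurement uncertainty
can legitimately push it above 100%, and clamping would hide exactly the
information the ledger exists to show. Acetate's labelled carbon counts one
atom for each single-labelled class and two for the double-labelled class.
Biomass is converted from a net cell increase (cells per litre) via a
per-cell carbon content (default 50 fg C/cell, a typical value for small
rods, exposed as a parameter) and the molar mass of carbon.

## Kinetics estimators

**Lag and rate.** The model is flat at an initial level until a breakpoint,
then declines linearly; the breakpoint is searched only over observed
timepoints because weekly sampling cannot identify a continuous one.
Trailing observations sitting on the exhaustion floor (within 10% of the
series span of the minimum) are trimmed down to one, since the two-segment
model has no terminal plateau; time series deliberately extend past
depletion so that cell-count plateaus are observable. Whether a decline is
real is decided by an F-style test against the flat model (threshold 10);
otherwise the rate is zero and a flag is raised. The fit is invariant to
adding a constant to all concentrations. With recorded repeat amendments,
the substrate fit runs on negated cumulative consumption, which declines
monotonically through re-additions.

**Molar yields.** Product formed is regressed on cumulative substrate
consumed through the origin, per replicate, using all timepoints (endpoint
mode — final product over final consumption — is available for comparison
with simple endpoint arithmetic). Two robustness choices matter at the
default noise level, both exact on noise-free data:

- the substrate's initial level is taken from the two-segment fit rather
  than the first observation, whose error would shift every consumption
  value in common;
- the product baseline is the median over the pre-breakpoint window,
  because concentration noise is truncated at zero and the *mean* of
  near-zero observations is biased upward.

The reported s.e. combines the within-replicate regression variance, the
propagated variance of the estimated substrate level (a common-mode term
the regression residuals cannot see), and the between-replicate scatter.
In 100-simulation checks at default noise the estimators are unbiased to
within ~2% and ±2 s.e. intervals cover truth ≥ 93% of the time.

**Cell yields.** qPCR 16S copies are divided by the genomic operon count
(default 4) to give cells. The yield is the net increase in cells per litre
over moles consumed per litre. "Initial" and "final" counts are means over
the pre-breakpoint and post-depletion (≥99% of final consumption) windows
rather than single endpoints — with 20% lognormal qPCR noise a single
endpoint is the dominant error — and the total consumption uses the median
over the plateau window for the same zero-truncation reason as above. On
noise-free data this reduces to the endpoint formula exactly.

Replicates are aggregated as unweighted mean ± sample s.d. (n−1),
matching the usual "± s.d., n = 3" reporting convention.

## Synthetic data

The generator emulates the batch experiments the estimators assume: flat
substrate during the lag, zero-order consumption (re-amended per the
amendment list), products at fixed molar yields of cumulative consumption,
cells at a fixed cells-per-mole yield on top of an initial population, and
qPCR copies at operon-count × cells. Noise is additive Gaussian on
concentrations with s.d. = cv × initial substrate (default cv 5%),
truncated at zero, and mean-preserving lognormal on qPCR counts (default
cv 20%) — matching the visual error structure of replicate culture data
without overclaiming. One `numpy` generator seeded per call and a fixed
draw order make identical config + seed byte-identical on CSV output.

Presets carry the published growth parameters: DCM (2 mM, lag 21 d,
133 µM/day, 0.76 mol acetate/mol, 2.0×10¹⁴ cells/mol), methanol (5 mM,
14 d, 309 µM/day, 0.74 mol/mol, 5.7×10¹⁴), choline (5 mM, 11 d, 344 µM/day,
3.1 acetate and 1.3 monomethylamine mol/mol, 3.0×10¹⁴), glycine betaine
(5 mM, 7 d, 328 µM/day, 2.3 acetate and 0.95 monomethylamine mol/mol,
1.1×10¹⁴), and glycine betaine + H₂ (4.4 mM; endpoint yields 15/4.4 acetate
and 5.5/4.4 monomethylamine). For the +H₂ condition only completion within
~28 days is reported, so the preset chooses lag 3.5 d and 170 µM/day to
match that horizon. The default sampling design is weekly during the lag,
twice-weekly during consumption, the depletion day itself, and two
post-depletion points; initial cells default to 5×10⁶ cells/ml.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: instrument drift and calibration error,
replicate-specific lags (observed for some substrates), deviations from
strict zero-order kinetics near exhaustion, cell death after the plateau,
and community dynamics of cohabiting taxa.

The per-molecule isotopologue sampler draws each acetate molecule's route
from the steady-state route shares and each carbon's label state
independently, exactly as the forward model's assumptions state — so it
serves as an independent Monte-Carlo oracle, converging at the usual
n^(−1/2) rate.

## Problem sizes

Property and recovery tests use triplicate experiments of 10–16 timepoints,
100-simulation ensembles for bias/coverage checks, and 10⁵–10⁶ molecules
for Monte-Carlo agreement (20 random parameter draws at 10⁶ in the
acceptance suite); the acceptance script refits one seeded triplicate
experiment per growth condition.

## Known limitations

- The isotopologue model is the minimal one-parameter-channeling
  formalisation; co-localisation effects richer than a single probability,
  isotope fractionation (ε, Rayleigh behaviour) and time-resolved label
  dynamics are out of scope.
- Recovery arithmetic performs no natural-abundance correction; pool values
  are taken as given.
- The kinetics module fits zero-order rates only (no Monod/logistic
  growth), performs no qPCR standard-curve processing and no outlier
  rejection.
- Flask-specific headspace predictions require pH, temperature and volumes;
  when these are unreported the ledger must take measured headspace pools
  as inputs.
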