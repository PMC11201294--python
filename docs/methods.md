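# Methods

## Reaction free energies

The package works with three coupled reactions of syntrophic acid
degradation in anaerobic digesters:

1. Acetate oxidation: CH₃COO⁻ + H⁺ + 2 H₂O → 2 CO₂ + 4 H₂
2. Propionate oxidation: CH₃CH₂COO⁻ + 2 H₂O → CH₃COO⁻ + CO₂ + 3 H₂
3. Hydrogenotrophic methanogenesis: 4 H₂ + CO₂ → CH₄ + 2 H₂O

Standard free energies and enthalpies at 298.15 K are sums of tabulated
formation energies (`data/formation_energies.tsv`): Shock & Helgeson
(1990) for the two aqueous acid anions, Hanselmann (1991) for H₂, H⁺,
CO₂(g), H₂O(l) and CH₄(g). With these constants the three reactions
give ΔG°₂₉₈ = +54.96, +73.76 and −130.75 kJ/mol. The file records each
constant's literature source; replacing it swaps the entire basis.

Convention: the tabulated ΔG° refers to **all** species at unit
activity, including H⁺ (pH 0 reference). pH enters exclusively through
the reaction quotient; `delta_g_standard_at_ph` provides the
biochemists' pH-7-referenced view. This choice is forced by internal
consistency: −130.8 kJ/mol for the proton-free methanogenesis reaction
is the conventional value, and +54.9 kJ/mol for acetate oxidation is
only obtained with H⁺ at unit activity.

Translation to cultivation temperature (default 310.15 K) uses the
Gibbs–Helmholtz relation with temperature-independent ΔH°:

    ΔG°(T₂) = ΔG°(T₁)·T₂/T₁ + ΔH°(T₁)·(T₁ − T₂)/T₁,  T₁ = 298.15 K

In-situ values follow ΔG = ΔG°(T) + RT ln Q with
R = 8.314462618×10⁻³ kJ/(mol·K). Activities: solutes are molar
concentrations over 1 mol/L (ideal solution — no activity-coefficient
or ionic-strength model, and VFA enter as total concentrations without
acid–base speciation); gases are partial pressures over 1 bar (10⁵ Pa);
water is 1; H⁺ is 10^(−pH). CO₂ is treated as a gas-phase species
(pCO₂), not bicarbonate — no carbonate speciation.

Degenerate states: a product with zero activity yields Q = 0 and the
sentinel "unbounded exergonic" result (ΔG = −∞) rather than an
exception, because early timepoints can have no measurable product; a
reactant with zero activity is an error, since ln Q diverges and ΔG is
undefined.

### Critical concentration

The acetate level at which propionate oxidation reaches equilibrium is
the root of ΔG(c) = 0 with all other activities fixed. Because ΔG is
linear in ln c, the closed form

    c = exp[(−ΔG°_T/(RT) − ln Q_rest)/ν]

is exact; tests verify it against bisection on the ΔG surface and by
round-trip (|ΔG(c)| < 10⁻⁶ kJ/mol). Only aqueous species can be
inverted. With propionate 58 mM, pH₂ 5.3 Pa, pCO₂ 26,700 Pa at
310.15 K, the bundled constants give ≈ 4.15 M. The result is extremely
sensitive to ΔG°_T (each kJ/mol shifts c by ~50%), so the exact ΔH_f
basis matters; the bundled literature values are documented and
auditable for that reason.

## Culture measurements

Partial pressures are mole fraction × absolute headspace pressure.
Pressure inputs default to gauge readings (venting protocols are stated
as overpressure), converted with 1013.25 mbar atmospheric; an explicit
flag switches to absolute. Headspace gas is ideal; headspace volume is
treated as constant between records (weekly ~4 mL liquid sampling is
negligible against 300–500 mL headspace), and water-vapor pressure is
not subtracted.

Cumulative methane adds back the moles removed at each venting event
(n_pre − n_post by ideal gas, mole fractions unchanged by the release),
reporting production relative to the first record. Measurements on
vented days are pre-vent.

Free ammonia uses the ammonium dissociation constant
pKa(T) = 0.09018 + 2729.92/T (Hansen et al. 1998 parameterization;
both constants overridable):
fraction = (1 + 10^(−pH)/10^(−pKa))⁻¹, free NH₃ = TAN × fraction.
At 0.3 M TAN, pH 7.2 and 310.15 K this gives ~6 mM NH₃.

## Rates and phases

Degradation rates are OLS slopes of concentration vs day over an index
window of ±2 points around the focal day (window truncated at series
ends; width configurable — weekly sampling makes wider windows smear
phase boundaries). Slopes keep their mathematical sign internally; the
rate–pH₂ correlation negates consumption slopes by default so a
negative Pearson r reads "high pH₂, slow degradation". The p-value is
the standard two-sided t transform.

Phase labeling thresholds |rate| at 0.5 mM/day with a 2-point minimum
run: initial inactive run = lag, active runs = first/second degradation
phases, interior inactive runs = plateau. A trailing inactive run is
also labeled plateau; with the default generator the run ends at
substrate exhaustion so the case does not arise. The labeling is
descriptive plumbing and never feeds thermodynamic computations.

## Hydrogenase classification

Candidates are regex hits of canonical metal-binding motifs
(`data/hydrogenase_motifs.tsv`): the [FeFe] H-cluster L1 (TSCCPxW), L2
(MPCxxKxxE) and L3 (ExMACxxGCxxG), and the [NiFe] N-/C-terminal
nickel-binding CxxC motifs (RxCGxCxxxH, DPCxxCxxH/R), after Vignais &
Billoud (2007). The rule file is user-replaceable, so curated or
project-specific patterns can be dropped in verbatim. Genes matching
rules of both classes are flagged ambiguous with both hit sets, never
resolved by precedence.

Binding motifs alone cannot resolve HydDB-style groups below the metal
class, so calls accept an optional external group column (e.g. an HydDB
export) for refinement; querying the web service is out of scope. The
exception is the bifurcating A3 rule: an [FeFe] type-A call within an
inclusive ordinal distance of 5 coding sequences of a NuoF-annotated
gene on the same contig (strand-agnostic; NuoF found by a configurable
product-label regex) is upgraded to "FeFe A3" with the nearest NuoF and
distance recorded as evidence. The operation is idempotent and
cross-contig proximity never counts.

## Synthetic data

The batch generator reproduces the **shape and stoichiometry** of the
biphasic degradation pattern, not mechanistic kinetics (no Monod/ADM1
model is fitted anywhere). True trajectories are piecewise linear on a
daily grid: lag (15 d), first propionate degradation (1.0 mM/day for
63 d) with acetate gaining `acetate_yield` (default 1.0) per propionate
consumed, plateau (42 d) and second degradation (0.8 mM/day) during
both of which the acetate oxidizer consumes acetate at 1.2 mM/day down
to a 0.3 mM residual. Defaults mirror the 100 mM propionate regime; the
run ends at substrate exhaustion.

Gas bookkeeping follows the syntrophic stoichiometry with H₂
quantitatively relayed to methanogenesis: net 0.75 CH₄ + 0.25 CO₂ per
propionate, 1 CH₄ + 1 CO₂ per acetate oxidized. Carbon is conserved
exactly (tested to 10⁻⁹ relative) when acetate_yield = 1. Only a
fraction (default 0.1) of produced CO₂ reaches the headspace, emulating
the bicarbonate buffer so pCO₂ stays near 26,700 Pa; the absorbed pool
is tracked in the truth table. Venting triggers at sampling days when
gauge pressure exceeds 1,000 mbar, scaling headspace moles down to
100 mbar gauge. The measured H₂ trace is baseline (2.2 Pa) plus a pulse
(5.3 Pa) during the acetate-oxidation interval rather than a kinetic H₂
balance; the defaults are calibrated so that propionate oxidation ΔG
stays within the −25…−10 kJ/mol band and methanogenesis within
−30…−10 kJ/mol during active degradation (a regime constraint of the
packaged configuration, asserted in tests as band membership, not as
equivalence to any real culture). Gaussian noise is added per channel
last, from independent sub-seeds (VFA 1.0 mM, gas fractions 5×10⁻³,
x_H₂ 2×10⁻⁶, pressure 5 mbar, pH 0.03); one seed fixes the whole table.

What the generator does **not** emulate: community composition,
growth-dependent rate changes, the second late acetate peak, H₂
mass balance, CO₂/pH coupling, or correlated instrument drift. Tests
passing on synthetic data therefore establish the correctness of the
computations and their plumbing, not agreement with any particular
measured culture.

The proteome generator splices concrete motif instances into random
background sequences (length 300–600 aa) at recorded positions, placing
a NuoF-labeled neighbor at distance 1–5 for each planted A3 and, with
probability 0.5, a distance-6 NuoF negative control next to non-A3
[FeFe] plants. Planted genes occupy spaced ordinal blocks so proximity
evidence cannot leak between plants, and background sequences are
rejection-sampled against the rule file, so noiseless fixtures contain
no spurious motifs by construction — precision on fixtures measures the
pipeline, not the generator.

## Problem sizes and numerics

Randomized property tests run ~1,000 states over the free-energy
surface (monotonicity, Hess additivity, pH invariance, closed-form vs
bisection at 10⁻⁶ relative); the stoichiometry check averages 100
seeded replicates; classifier fixtures use 10 seeds × ~280 genes with
≥20 plants each. All computations are scalar closed forms or small OLS
fits; the entire suite runs in seconds. Quotients are accumulated in
log space to avoid under/overflow at pascal-scale H₂ activities.

## Known limitations

- ΔH° is temperature-independent (the Gibbs–Helmholtz step is a
  first-order correction over a 12 K span).
- No ionic-strength/activity-coefficient corrections at 0.3 M NH₄Cl,
  where they are not negligible in reality; results are conditional on
  the ideal-solution convention.
- The exact formation-enthalpy basis of any published analysis may
  differ from the bundled table by ~1 kJ/mol, which propagates to
  roughly ±50% on critical-concentration inversions; conclusions that
  survive only within such a window should be checked against the
  intended constant basis.
- Motif regexes detect canonical hydrogenases; divergent or truncated
  enzymes, and group-level assignment beyond the A3 proximity rule,
  require external curation.
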