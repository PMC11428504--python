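# Methods

This note documents the models, conventions, parameter choices and
limitations behind `radscav`. It states no empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and model

`radscav` post-processes per-species thermochemistry; it performs no
electronic-structure work. A species record carries the enthalpy (and
optionally Gibbs energy) of one chemical entity in one phase; everything else
is arithmetic on those records:

- **Descriptors.** BDE, IP, PDE, PA and ETE are differences of species
  enthalpies closed by the reference enthalpies of H•, H+ and e− (below).
  They characterise the three canonical radical-scavenging routes: concerted
  H-atom transfer (HAT), electron-then-proton transfer (SET-PT,
  first-step cost IP), and proton-then-electron transfer (SPLET, first-step
  cost PA).
- **Mechanism verdict.** Per compound and phase, the preferred route is the
  strict argmin of {min-site BDE, IP, min-site PA} — the committing step of
  each route. Exact ties are broken by the fixed priority HAT > SET-PT >
  SPLET and flagged, since an argmin over real-valued enthalpies does not
  otherwise define an order.
- **Double HAT.** From the first-formed phenoxyl radical, each candidate
  closed-shell product (benzodioxole via an ortho-methoxy, o-quinone via an
  ortho-hydroxyl) is scored by H(product) + H(H•) − H(first radical) — the
  same H-acceptor convention as the first-step BDE, applied to both steps.
  When a product is supplied in several spin states the lowest-enthalpy state
  is selected by default and the chosen state is recorded; strict selection
  is available. The bundled reaction-scheme fixture stores the published
  second-step energies directly as channel costs on this convention.
- **Kinetics.** Profiles are referenced to the pre-reaction complex (RC):
  ΔG‡ = G(TS) − G(RC) and ΔG = G(PC) − G(RC) by default, with a selector for
  separated-reactant/product referencing. Rates use conventional TST,
  k = σ·κ·(k_B T/h)·exp(−ΔG‡/RT), with the Wigner factor
  κ = 1 + (1/24)(hcν̃/k_BT)² when a TS imaginary wavenumber is available.
  σ and κ are always reported; no correction is ever applied silently. A TS
  below the RC marks the profile barrierless rather than raising.

## Units, constants, standard state

All internal energies are kcal/mol; hartree inputs are converted exactly once
at the I/O boundary with 627.5094740631 kcal·mol⁻¹·hartree⁻¹ (CODATA-derived,
fixed). Physical constants come from `scipy.constants` (CODATA 2018) and are
cross-checked at import (k_B·N_A = R). The default temperature is 298.15 K
and Gibbs energies are taken to be at the 1 M standard state, which makes the
bimolecular TST constant numerically M⁻¹ s⁻¹; an opt-in RT·ln(R′T) term is
provided for inputs at the 1 atm gas standard state (≈ 1.89 kcal/mol at
298.15 K) and is never applied by default.

## Reference enthalpies of H•, H+ and e−

Only the composite C = H(H+) + H(e−) − H(H•) is observable from a descriptor
table, through the identities IP + PDE = PA + ETE = BDE + C. The bundled
default table therefore anchors C per phase at the values the bundled
descriptor table itself implies — 313.3 (gas), 53.9 (water), 47.0 (ethanol)
kcal/mol, each with a per-phase spread of only 0.1 kcal/mol across the 19
rows — and documents the per-species split as a convention: gas
H(H+) = 5/2·RT = 1.481 and H(e−) = 0.752 (electron-convention translational
enthalpy), with H(H•) closing C; in solvents H(H•) keeps its gas value
(neutral-atom solvation neglected), H(e−) carries a literature-style
solvation enthalpy, and H(H+) absorbs the remaining calibration. Published
solvation enthalpies for the proton and electron scatter by tens of kcal/mol
across compilations, so no split is uniquely defensible; anchoring the
observable composite and declaring the split is the transparent choice. Any
user table with the same layout overrides the default (`--refs`).

## Tolerances and numerical conventions

- **Hess-closure audit.** 0.3 kcal/mol for printed one-decimal tables (four
  independently rounded summands), 1e-9 kcal/mol for species sets computed in
  double precision. Violations are flagged and logged, never auto-corrected.
- **Rendering.** Descriptors print at one decimal, rounded half away from
  zero; rate constants print as `m.mm × 10^e`. Machine-readable outputs are
  byte-stable across reruns of the same configuration.
- **Site labels.** ASCII apostrophes normalise to the Unicode prime
  (`4'-OH` ≡ `4′-OH`); the canonical site order 3′ < 4′ < 5′ < 5 < 7 breaks
  minimum ties deterministically.
- **Degenerate inputs.** Missing species leave descriptors absent (never
  zero); a descriptor absent everywhere raises a not-computable error rather
  than returning a default; ambiguous spin states must be resolved explicitly
  or by the declared lowest-enthalpy policy.

## Synthetic generator

The generator inverts the descriptor equations: parent at a fixed base
enthalpy (−1000 kcal/mol by default — arbitrary, since all descriptors are
translation-invariant), radical at base + BDE − H(H•), cation at
base + IP − H(e−), anion at base + PA − H(H+), with under-determined species
recovered through PDE/ETE when those are the supplied targets.
Over-determined rows are verified against every supplied target: the
consistency tolerance is 1e-9 kcal/mol for exact targets, and can be set to
0.3 kcal/mol to regenerate printed one-decimal tables, whose five columns
close only to rounding. Inconsistent rows are rejected with the row named.
Reaction profiles are built the same way: RC at the chosen complexation depth
below the separated reactants, TS at RC + barrier, PC at RC + reaction
energy. The complexation depths default to a nominal 5 kcal/mol (the
published profiles state only RC-referenced quantities, which do not depend
on them).

Noise, when requested, is independent Gaussian on every enthalpy — the
simplest stand-in for method error in computed thermochemistry — drawn from
`numpy.random.default_rng` (PCG64, a named and versioned generator) so one
seed reproduces one data set on any platform; sd = 0 is the identity. What
the generator does **not** emulate: correlated errors across related species
(real DFT errors partially cancel in isodesmic-like differences),
conformer-selection effects, or any structure–energy relationship. Passing
tests therefore demonstrate the correctness of the arithmetic, bookkeeping
and classification logic on realistic magnitudes, not the accuracy of any
electronic-structure method.

## Fixtures and known data discrepancies

The bundled tables transcribe the published descriptor and kinetics tables
verbatim. Two oddities are preserved, documented, and deliberately not
resolved:

- The Cy-3-*O*-glc block lists a 5′-OH row (gas BDE 89.8) and a 4′-OH row
  (94.0), although cyanidin's catechol B-ring has no 5′-OH, and the
  accompanying discussion quotes Cy 4′-OH = 89.8 in its cross-compound
  ranking. Both sources ship unedited (`table1_descriptors.csv` as printed;
  `section321_bde_ranking.csv` as quoted); ranking operations run on
  whichever table they are given. This is also why the gas-phase verdict for
  Cy reports its minimum BDE at 5′-OH.
- The published rate constants (e.g. 5.72 × 10⁹ M⁻¹ s⁻¹ at ΔG‡ = 7.6
  kcal/mol) exceed plain TST with σ = κ = 1 at 298.15 K (1.67 × 10⁷) by a
  factor the stated inputs cannot reproduce — the σ, κ and reference-state
  choices behind them are not published, nor are the TS imaginary
  frequencies. They are carried as a reference column only; the pipeline
  asserts that their ordering matches the barrier ordering and recomputes
  rates only under explicitly supplied σ/κ settings.

## Problem sizes

The bundled analyses are small (57 descriptor rows, 4 reactions) and run in
well under a second. The randomized generator round trip in the tests and
acceptance script uses 1000 target rows — enough to exercise every code path
and the 1e-9 recovery bound while keeping the whole suite near one second.
The noise-statistics check uses 200 replicates at sd = 0.5 kcal/mol, where
the √2·sd prediction for a difference of two independent Gaussians is
testable at 25% relative tolerance.

## Limitations

- No conformational search, geometry optimisation, frequencies, solvation
  models or charge analysis: thermochemistry is an input.
- Tunnelling beyond Wigner (Eckart, small-curvature) is not implemented.
- Descriptors come only from supplied thermochemistry or fixtures — no
  structure-based estimation.
- Glycoside-OH sites are representable in species tables but are not part of
  the canonical phenolic site set, reflecting their negligible involvement in
  the scavenging chemistry of these pigments.
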