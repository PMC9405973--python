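# Methods

## Thermodynamic conventions

All association constants cross the API in mM⁻¹ (the natural unit of
millimolar-syringe titrations) and are converted to M⁻¹ before any
logarithm, so free energies refer to the 1 M standard state.  Temperatures
are Celsius at the boundary and Kelvin (T = t + 273.15) internally; energies
are kcal mol⁻¹, entropies and heat capacities cal mol⁻¹ K⁻¹.  The gas
constant is R = 1.9872 cal mol⁻¹ K⁻¹.  Presentation rounding (tables, CLI
output) is half-away-from-zero; all internal arithmetic is unrounded.

The heat-capacity change is the unweighted ordinary-least-squares slope of
ΔH_b against temperature, assuming ΔCp_b constant over the narrow 25–35 °C
window.  An unweighted fit is deliberate: it reproduces a slope of exactly
(ΔH₃ − ΔH₁)/(T₃ − T₁) for three equally spaced points, which is how such
triplets are conventionally summarised; weighting by the reported ΔH errors
would move the slope by less than its own standard error but break that
correspondence.

## Metal-nucleotide linked equilibria

The ternary model has seven species: free protein E, free nucleotide G,
free Mg, the metal complexes MgG and (triphosphate only) Mg₂G, and the
protein complexes EG and EMG.  Mg₂G is assumed unrecognised by the protein.
Assumptions: ideal dilute solution (no activity coefficients or ionic-
strength corrections), no proton linkage, a single protein site.  The
metal-free ("EDTA") condition is modelled as total Mg = 0 rather than as an
explicit chelation equilibrium, since EDTA is only used to enforce that
state.

The solver is a damped Newton iteration on the logarithms of the three free
concentrations, which keeps every species positive by construction.  The
residual is the log-ratio of computed to target totals; the Jacobian
d ln T_i / d ln x_j is analytic and, because all its terms are positive
species fractions, well conditioned.  Iteration starts from the uncoupled
analytic solution (E/G quadratic, Mg/G quadratic), caps log-steps at 2,
backtracks on non-decreasing residuals, and stops below 10⁻¹³ on the worst
log-residual (about 10⁻¹³ relative mass-balance error), with a hard limit of
200 iterations and a diagnostic error naming the worst residual on failure.
Components with zero totals are eliminated rather than regularised.  The
test suite cross-checks the solver against an independent nested-bisection
oracle to 10⁻⁶ relative on every species over randomised parameter sets.

The Mg-nucleotide association constants are not measurable by this package
and are configuration inputs.  The shipped values (K_MgGTP = 10⁴ M⁻¹,
K_MgGDP = 10³·⁵ M⁻¹, K_Mg2GTP = 10² M⁻¹, zero stepwise enthalpies) are
placeholder literature-scale magnitudes, clearly marked as such in the
constants file, and should be replaced with condition-specific values.

## Injection-heat forward model

A perfusion (overfill) cell of volume V₀ receiving an injection dV displaces
dV of cell liquid.  The displaced liquid is taken to carry the mean of the
pre- and post-injection concentrations (the convention of the standard
instrument-vendor analysis), giving the total-concentration update
c → (c(V₀ − dV/2) + c_syr dV)/(V₀ + dV/2).  The measured heat of injection
i sums, over every heat-carrying complex s with formation enthalpy ΔH_s
(relative to free E, G, Mg),

    q_i = Σ_s ΔH_s [ V₀(B_s,i − B_s,i−1) + dV·(B_s,i + B_s,i−1)/2 − dV·B_s,syr ],

where B_s are the equilibrium complex concentrations at the cell composition
and B_s,syr credits pre-formed metal-nucleotide complexes entering from the
syringe.  Heats are normalised to kcal per mole of injectant.  Consequences
of this bookkeeping, verified in the tests: total heat at full saturation
equals n·ΔH·(cell protein moles) within 1 %, the normalised heats converge
on the closed-form Wiseman derivative as injections shrink, and cumulative
heat is partition-invariant (merging injections) to 10⁻⁹ only in the
negligible-displacement limit — at real geometry (2 µL into 200 µL) the
displacement terms make partitioning matter at the ~10⁻³ level, which is a
property of the convention, not a solver error.

Fitting is trust-region least squares (scipy) on the retained injections
(the customarily discarded first injection is dropped by default), over
(n, ln K, ΔH) with three deterministic K starts — a c ≈ 10 heuristic, half
and double — to avoid local minima; ln K parameterisation keeps K positive
and makes the reported standard error a delta-method error on K.  Standard
errors come from the Jacobian at the optimum.  A c-value (n·K·[cell
protein]) outside [0.1, 10⁵] triggers an identifiability warning.  The
stoichiometry can be floated or fixed; both modes are exposed because
either may have been used in any given legacy analysis.  The ternary fit
treats a ±Mg pair as one least-squares problem: the metal-free isotherm
pins (K_EG, ΔH_EG), the metal isotherm adds (K_EMG, ΔH_EMG); identical Mg
totals in both protocols are rejected as rank-deficient.

## Cooperativity cycles

κ is always computed from unrounded constants; table presentation rounds
last.  The closure check compares the two two-step routes of a
thermodynamic square: detailed balance requires equal products of
association constants and equal enthalpy sums.  The default tolerance of
0.2 ln-units reflects typical 10–30 % experimental errors on K.  The
packaged reference transcription contains one printed cycle row whose own
−TΔs, Δg and Δh are mutually inconsistent beyond any rounding; the
comparison machinery detects such rows generically (printed −TΔs versus
printed Δg − Δh against the combined half-units of the three cells) and
reports them as unverifiable instead of comparing against them.

## Structural-energetic deconvolution

ΔCp_rb = αΔASA_ap + βΔASA_p with α = 0.45 and β = −0.26 cal K⁻¹ mol⁻¹ Å⁻²;
the rigid-body values per complex are inputs in the constants file (computed
upstream from structures; this package does no surface-area computation).
The conformational surface change uses the hydrophobicity-weighted
coefficient α·f_ap + β·(1 − f_ap) = 0.2228 cal K⁻¹ mol⁻¹ Å⁻² with
f_ap = 0.68: an average interface is f_ap apolar and (1 − f_ap) polar, so
the polar coefficient must carry the complementary weight.  The alternative
reading in which f_ap multiplies both terms (coefficient 0.1292) fails to
reproduce the reference area magnitudes by ~70 % and is rejected by an
explicit test.  Per-residue area (47 Å²) and per-rotor entropy
(1.7 cal mol⁻¹ K⁻¹) are calibration constants of the residue/rotor
equivalents; both are configurable, and because the per-rotor value is only
constrained to the range 1.6–1.7 by the reference data, rotor counts are
asserted to ±1 only.  ΔS_solv = ΔCp_b ln(T/T_S) with T_S = 385.15 K, and
ΔS_r-t = −8 cal mol⁻¹ K⁻¹ for any bimolecular association.

The decomposition stage can take ΔCp_b either from the transcribed printed
column (default) or refitted from the enthalpy series.  The default is
"printed" because the original fits used unrounded enthalpies: from the
rounded printed triplets eight of ten complexes refit identically, but two
differ by up to 5 cal mol⁻¹ K⁻¹ purely through input rounding, which would
cascade into the derived areas.  The acceptance script uses the refit route,
for which the target complex gives the identical ΔCp_b.

## Comparison tolerances

A recomputed cell is compared to a printed reference cell within one unit
of the reference's last printed digit **plus** the first-order propagated
effect of the rounding already present in the transcribed inputs (K printed
to 1 mM⁻¹, ΔH to 0.1 or 0.01 kcal mol⁻¹).  The propagation is analytic per
quantity (e.g. for −TΔS: RT·δK/K + δΔH with δ the half-unit of the printed
input).  Without this term, cells that the original authors derived from
unrounded values would fail against a transcription that can only be as
precise as print.  Residue and rotor counts are compared within ±1.

## Synthetic data generator

The generator emulates a single-site (or metal-coupled ternary) titration:
forward-model heats plus i.i.d. Gaussian noise per injection on the raw
microcalorie scale — where instrument noise physically lives — plus an
optional constant blank offset; the blank experiment is the protein-free
prediction with independent noise.  The default protocol is a 200 µL cell,
40 µM protein, 19 × 2 µL injections of 2.5 mM ligand at 30 °C, and the
default noise is 0.05 µcal per injection.  Temperature series use
ΔH(T) = ΔH(T₀) + ΔCp(T − T₀) and the integrated van't Hoff relation with
constant ΔCp for K(T).  All randomness flows from a single integer seed;
replicate and member seeds derive from it as seed + p·i mod 2³¹ for a fixed
prime p, so every stream is reproducible without hidden global state.  Not
emulated: baseline drift, injection-peak shapes, instrument response
functions, titrant impurities or concentration errors — so passing recovery
tests demonstrate estimator correctness under the stated noise model, not
robustness to real-instrument systematics.

## Auxiliary assays

Michaelis–Menten rates v = V_max S/(K_m + S) are fitted by bounded
nonlinear least squares with k_cat = V_max/[E]; fluorescence titrations are
fitted as F = F₀ + (F_max − F₀)·fraction-bound with the exact single-site
ligand-depletion quadratic (the hyperbolic no-depletion limit is exposed as
an option, since either may match a legacy analysis).  Raw traces for these
assays are validated on synthetic data only.

## Problem sizes

The shipped analyses are desk scale: table reproduction and speciation
checks run in seconds; the stochastic recovery studies use 100 one-site
replicates, 25 temperature-series replicates and single ternary pairs,
which keeps the full test suite around ten seconds on one CPU while leaving
the Monte-Carlo medians stable to well within the asserted bounds.

## Known limitations

- No raw thermogram (power-trace) integration; integrated heats only.
- No multi-site, sequential-site or proton-linkage models.
- No error propagation into derived quantities beyond fitted standard
  errors; cycle and decomposition outputs carry no uncertainty estimates.
- The rigid-body ΔCp inputs and Mg-nucleotide constants are taken on trust
  from the constants file.
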