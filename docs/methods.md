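# Methods

## The model

`strainlfer` predicts activation enthalpies of ring-opening and
strain-promoted cycloaddition reactions from two ground-state quantities: the
reaction driving force and the delocalization of the breaking bond.

The starting point is Marcus theory with constant parabola curvature,

    ΔE‡ = ΔE‡_int · (1 + ΔE_r / (4·ΔE‡_int))²,

where ΔE_r is the reaction driving force (negative = exothermic; all energies
in kcal/mol) and ΔE‡_int the intrinsic barrier at ΔE_r = 0. The first-order
truncation is the Bell–Evans–Polanyi (BEP) relation ΔE‡ = c₀ + α·ΔE_r, with
sensitivity α; the exact truncation remainder is ΔE_r²/(16·ΔE‡_int), which
the test suite verifies in closed form. The package deliberately rejects
inputs in the Marcus inverted region (|ΔE_r| > 4·ΔE‡_int) rather than
extrapolating the parabola.

Delocalization of the breaking bond lowers the intrinsic barrier. Writing
ΔE‡_int = ΔE‡_int(0) + β·χ, with χ a delocalization descriptor and β < 0 a
sensitivity constant, gives the combined linear model

    ΔE‡ = c₀ + α·ΔE_r + β·χ,

which reduces to BEP at χ = 0. Three interchangeable descriptors are
supported:

* **χ_NBO = 2 − N_occ** (electrons): the departure of the breaking bond's
  natural-bond-orbital occupation from a full 2 e.
* **χ_ρ** (dimensionless): the ratio of the bond's excess kinetic energy
  density to the uniform-electron-gas reference, related to the electron
  localization function by ELF = (1 + χ_ρ²)⁻¹. The package converts between
  χ_ρ and ELF both ways; computing N_occ or χ_ρ from wavefunctions is out of
  scope — they are ingested as numbers.
* **n₃** (integer): the number of three-membered rings containing the
  breaking bond, computed from heavy-atom connectivity as the number of
  common neighbors of the bond's endpoints. This is the purely topological
  proxy: each fused three-membered ring lowers the intrinsic barrier by
  roughly 10 kcal/mol (~10⁷-fold in rate at 298 K).

Relative barriers between two substrates decompose exactly as
ΔΔH‡ = α·ΔΔH_r + β·Δχ (strain term plus delocalization term), and the
rule-of-thumb estimator specializes this to strain-release energies and ring
counts with the rounded sensitivities α = 0.5 and β = −10 kcal/mol per ring.
Barrier differences convert to relative rates by k_rel = exp(−ΔΔH‡/RT) with
R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹ and a default temperature of 298 K
(configurable; 298 exactly, not 298.15, to match the convention of the
quoted rate factors).

### Conventions and degenerate inputs

* Exothermic driving forces and strain-release energies are **negative**;
  lower ΔΔH‡ means faster.
* The breaking bond is always user-designated, never inferred; bond orders
  are ignored for ring topology, and heteroatom rings count in n₃ exactly
  like carbocycles. A three-membered ring sharing only one atom with the
  breaking bond (spiro arrangement) contributes nothing — the containing-ring
  definition reproduces every published ring-count assignment we pin in the
  tests.
* Negative predicted absolute barriers are returned but flagged with a
  `NegativeBarrierWarning`; fitted α outside (0, 1) or a negative intercept
  raise an `UnphysicalParameterWarning` rather than an error, since such fits
  are diagnostic information.

## Fitting

α, β and the intercept are estimated by ordinary least squares of ΔH‡ on
[1, ΔH_r, χ] (statsmodels OLS behind the `fit_lfer` surface), with an
optional ΔH_r² regressor. No weights or robust loss are used. Records are
fitted per reagent class (radical, anionic, cycloaddition) unless explicitly
mixed, because the sensitivities are class-specific. Rank-deficient designs
(e.g. a constant descriptor column, or a descriptor proportional to ΔH_r)
raise a `CollinearityError` naming the offending column pair.

R² is the in-sample coefficient of determination; RMSE is reported in the
population form √(SS_res/n) as primary, with the degrees-of-freedom variant
√(SS_res/(n−p)) exposed alongside (`rmse_dof`), since published
model-comparison statistics in this area are conventionally in-sample.
Leave-one-out diagnostics are available (`loo_diagnostics`) but play no role
in fitting.

## Synthetic data generator

`synthetic.generate` draws records from exactly the statistical model the
fitter assumes: ΔH_r uniform on an interval, χ either uniform on an interval
(χ_NBO-like) or an integer ring count uniform on {0..3} (n₃-like), and
ΔH‡ = c₀ + α·ΔH_r + β·χ + N(0, σ) with noise on the barrier only (driving
forces are treated as exact). Defaults emulate a small strained-ring test
set: n = 12 substrates, ΔH_r ∈ [−60, −10] kcal/mol (the span of typical
strain-release driving forces), α = 0.5, β = −10 kcal/mol per ring, σ = 2
kcal/mol — comparable to the ~2.5 kcal/mol residual error of fitted
quantum-chemistry barrier models. An optional Gaussian-copula correlation
between ΔH_r and χ stresses near-collinear designs while keeping both
marginals exactly uniform.

What the generator does *not* emulate: systematic quantum-chemistry errors,
heteroscedastic noise across reaction families, measurement error in the
driving force, and any nonlinearity beyond the optional quadratic term.
Passing parameter-recovery tests therefore demonstrates the estimator is
correct under the model's own assumptions, not that the linear model is an
adequate description of any particular real reaction family — that adequacy
is what the R²/RMSE statistics on real tables measure.

## Data handling

The canonical CSV schema is
`id, reagent, dHr_kcal_mol, dHact_kcal_mol, chi_nbo_e, chi_rho, n3, sre_kcal_mol`;
only `id` and `dHr_kcal_mol` are required, blank/"NA" cells become absent
fields (never zeros), unknown columns are preserved as annotations, and a
user-supplied column map absorbs foreign headers so externally deposited
tables can be loaded verbatim. Energies are stored as given, without
re-rounding. `inpaper_fixtures()` hard-codes the worked-example values quoted
in the primary literature (activation/reaction enthalpies for the
propellane/cyclopropane/cyclobutane triple, the sulfone SREs, ring-count
assignments, the quoted sensitivities per reaction class); rows whose driving
force was never printed carry a 0.0 placeholder flagged in their annotations
and are excluded from any fit because they lack ΔH‡.

The full externally deposited per-reaction tables are not redistributed with
this package; `tests/test_acceptance.py::test_deposited_table_reproductions`
documents the expected file locations (`data/deposited/*.csv`) and the fit
statistics it verifies when a user supplies them.

## Design choices

* The core graph type is dependency-free; SMILES input is an optional RDKit
  adapter, so the n₃ machinery works from plain adjacency listings.
* n₃ counts rings *containing* the breaking bond (cyclopropane's own ring
  counts, n₃ = 1); this is the only definition consistent with all published
  assignments.
* The Marcus curvature is held constant (no asymmetric-parabola variant), and
  the combined model is linear in ΔH_r; the optional ΔH_r² regressor covers
  the case where mild curvature remains, which in practice changes fitted
  statistics only marginally.
* Temperature and the α/β defaults of the rule of thumb are overridable but
  deliberately simple round numbers — the estimator is meant for mental
  arithmetic with an SRE table and a ring count.

## Problem sizes

Everything here is desk-scale: fits involve tens of records and the
Monte-Carlo parameter-recovery studies use 200 replicates of 12-record
datasets, so the full test suite and the acceptance script each run in well
under a minute on one CPU.

## Known limitations

Dipole and noncovalent TS effects, variation in bond force constants,
entropy/tunneling corrections and inverted-region kinetics are outside the
model; predictions for bonds whose delocalization descriptor lies far outside
the fitted range extrapolate linearly and can go negative (flagged, not
clipped). The n₃ proxy is blind to delocalization sources other than fused
three-membered rings (e.g. π-conjugation), for which χ_NBO or χ_ρ must be
used.
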