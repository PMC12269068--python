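# Methods

## Model

### Tableau and charge distribution

The chemical model is a classical equilibrium tableau: aqueous master ions
(H⁺, Na⁺, NO₃⁻, PMG³⁻), reactive goethite sites (singly coordinated
FeOH⁻⁰·⁵ at 3.45 sites nm⁻², triply coordinated Fe₃O⁻⁰·⁵), and two abstract
surface components — HNOM⁻¹, the adsorbed-NOM proxy, and S⁰, the steric
blocker. Every species is a stoichiometric combination of these with an
intrinsic log K and a charge-distribution triplet (Δz0, Δz1, Δz2) placing
the charge added by its formation reaction in the surface plane (0), the
inner Stern plane (1) or the head of the diffuse layer (2). Reference
charges of surface components sit in plane 0; validation enforces that
Δz0+Δz1+Δz2 equals the summed charge of the aqueous ions consumed, which
makes the triplets consistent with the superscript plane-charge notation of
speciation tables.

HNOM and S⁰ have no free (unreacted) species: their totals, supplied per
system in mol m⁻², distribute entirely over their surface species, so the
free-component activity acts as a bookkeeping unknown and the absolute
normalization of the bimolecular formation constants (log K = 0 for FeNOM
etc.) has no physical consequence.

Steric mirrors: for every FeOH species formed by protons or electrolyte
ions only, a copy with one S⁰ added and *identical* log K and Δz is
generated. Blocked sites therefore titrate and pair exactly like free ones
— the primary charging curve is invariant (verified to 1e-10 C m⁻² in the
tests) — but PMG and NOM species get no mirrors, so blocked sites are
invisible to them. Feasibility demands [HNOM] + [S⁰] below the singly
coordinated site total; the solver rejects infeasible inputs by name.

### Electrostatics

Extended Stern model: two capacitors C1 (plane 0–1) and C2 (plane 1–2),
Gouy–Chapman closure at plane 2 for a 1:1 electrolyte
(σ_d = −0.1174·√c·sinh(Fψ₂/2RT) at 25 °C). The three node equations

    σ0 = C1 (ψ0 − ψ1)
    σ0 + σ1 = C2 (ψ1 − ψ2)
    σ0 + σ1 + σ2 + σ_d = 0

close the system; charge balance of every converged result is checked to
1e-10 C m⁻². A single goethite surface is assumed (no multi-surface
assemblages, no Donnan volume for adsorbed NOM: the NOM-CD construction
places NOM charge in the compact layer by definition). Temperature is fixed
at 25 °C.

### Loading and blocking relations

* [≡HNOM] = (Γ_NOM/Γ_ref)·[≡FeNOM_T], Γ_ref = 1.6 mg m⁻².
* FeNOM_T\* = 2·FeNOM_T/Γ_ref (mol RCOO⁻ kg⁻¹; each HNOM is two
  carboxylates); inverted, FeNOM_T = slope·Q_RCOO·Γ_ref/2 with slope 0.89
  (± 0.10, 95% CI, stored as metadata and propagated first-order to
  FeNOM_T ± 0.20 — not used in fitting). For this humic acid
  (Q_RCOO = 2.5 mol kg⁻¹) the default FeNOM_T is 1.77 µmol m⁻².
* θ_S = K(H)ᵃIᵇ/(1+K(H)ᵃIᵇ), K = 80, a = 0.32, b = −0.33, with H the
  dimensionless proton activity 10^(−pH) — this reproduces the worked ~50%
  (pH 7) and ~85% (pH 4.5) occupations at 0.1 M. θ_S is definitionally the
  allowed fraction of the physical Stern-layer maximum (Γ_MST⁰ ≈ 1 mg m⁻²);
  the runtime path is θ_S → [≡S⁰] = θ_S·S⁰_max only, so Γ_MST⁰ is
  documentation, not a computed quantity.
* R = 0.5·(1 − f_OS), with f_OS = [FeOH₂–NOM]/([FeNOM]+[FeNOMH]+[FeOH₂–NOM]).
  The structural anchors are R = 0.5 for fully inner-sphere NOM and R = 0
  for fully outer-sphere; FeNOMH is counted with the inner-sphere pool. The
  protonated complex's contribution is structurally ambiguous, but this
  linear mapping reproduces all four published (f_OS, R) anchor pairs within
  ±0.03.

## Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| PZC / site protonation log K | 9.3 | – | measured for this goethite |
| singly coordinated site density | 3.45 | nm⁻² | goethite crystallography |
| triply coordinated site density | 2.7 | nm⁻² | literature goethite model |
| C1, C2 | 0.9, 0.74 | F m⁻² | literature goethite values |
| Na⁺/NO₃⁻ pair log K | −0.6 (relative) | – | literature |
| FeNOM / FeOH₂–NOM log K | 0, 0.6 | – | NOM-CD calibration |
| FeNOMH log K_H | 5.0 | – | literature-informed HA default |
| PMG pKa ladder | 10.14, 5.46, 2.23, 0.8 | – | literature |
| PMG surface complexes | 3 species, see `defaults.json` | – | literature-informed, calibrated to qualitative adsorption behaviour |
| FeNOM_T | 1.77 | µmol m⁻² | a priori from Q_RCOO |
| K, a, b of θ_S | 80, 0.32, −0.33 | – | published empirical relation |
| S⁰_max | 2.56 | µmol m⁻² | single-parameter fit of the reference dataset |

Only printed, study-specific constants are fixed in code (Table-style
tableau values); everything literature-sourced lives in
`snomcd/data/defaults.json` with a provenance note per key and can be
overridden by a user JSON/TOML file. The PMG surface set (a monodentate
phosphonate complex in two protonation states and a bidentate complex, with
amine/carboxylate charge placed outward) was chosen once to reproduce the
qualitative behaviour of the system — high adsorption (>70%) across the
experimental window, sub-detection dissolved PMG at pH 4 without HA,
sorption decreasing toward high pH and at reduced ionic strength for
pH ≳ 6 — and is deliberately swappable: refitting it to primary PMG–goethite
titration data would be the first step in any serious recalibration.

## Numerical solution

Unknowns: log₁₀ free activities of non-fixed components plus log₁₀
Boltzmann factors of the three planes. Damped Newton with analytic
Jacobian, step cap of 2 decades, 12-step backtracking line search on the
max-norm of the scaled residual; mass balances are scaled by their totals,
electrostatic residuals are in C m⁻². Convergence at 1e-11 (scaled,
default), typically 10–30 iterations from the cold start (free = 10% of
totals, ψ = 0) and ~1 ms per system; isotherm runs warm-start consecutive
points. pH is imposed as a fixed H⁺ activity (the proton balance is
dropped), matching the use of measured per-point pH values. Ionic strength
is nominal by default (0.1 / 0.01 M); a computed mode iterates Davies
corrections and the diffuse-layer concentration to a fixed point.
Components with zero totals and the species containing them are removed
before solving. The solver contains no randomness: identical inputs give
bit-identical outputs.

Fitting: `scipy.optimize.least_squares` (trust-region reflective) on
residuals log₁₀(model) − log₁₀(observed), bounds S⁰_max ∈ [0, 6] µmol m⁻²,
FeNOM_T ∈ [0.1, 5]; neutral start (3.0, 1.77), optional deterministic
multistart with ties broken by lower RMSE then lower S⁰_max. 95% CI from
the linearized covariance s²(JᵀJ)⁻¹ with a t quantile (PEST-style); r² is
computed on log₁₀ concentrations, consistent with the RMSE objective.
Observations at or below the detection limit (default 6·10⁻⁷ M) are
excluded from the objective.

## Synthetic data

The generator emulates the experimental design: composites at HA loadings
0.5–1.6 mg m⁻² and target pH 4–8 (with per-point jitter bounded to keep
each isotherm within 0.3 pH units, mimicking unadjusted drift), NaNO₃ at
0.1/0.01 M, and a 9-step PMG dilution series from a 1.45 mM stock (top
total 0.725 mM) in 10 g L⁻¹ goethite. `generate_design` crosses all factor
levels; `reference_design` reproduces the 16-isotherm study layout (144
points, ~110 above the detection limit at the default truth). Observations
are the model's own predictions with multiplicative log-normal noise
(σ = 0.2 log₁₀ units, matching the reference fit's residual scale) and LOD
censoring of the observed values.

What the generator does *not* emulate: real HA partitioning and composite
pre-equilibration chemistry (loading is assigned, as in the source design),
pH measurement error, inter-batch goethite variability, and any model
misspecification — synthetic recovery tests therefore validate the
estimator and solver, not the chemical realism of the database.

## Known limitations

* **Informative censoring.** Excluding below-LOD observations from the
  least-squares objective censors on the noisy observation: near-LOD points
  survive preferentially when their noise is positive. In the Monte-Carlo
  recovery study this biases S⁰_max upward by ~3% and drops the nominal 95%
  CI coverage to ~75% (15/20 replicates). Without censoring the estimator
  is unbiased with nominal coverage, so this is a property of
  detection-limit handling — shared by any RMSE-on-retained-points fit,
  including the reference study's — not of the solver or optimizer. A
  censored-likelihood (Tobit) objective would remove it at the cost of
  departing from the established RMSE objective.
* The PMG surface-complex constants are literature-informed defaults, not a
  refit of primary titration data; absolute dissolved-PMG levels carry that
  uncertainty even though the steric competition mechanism does not.
* Electrolyte is restricted to symmetric 1:1 (NaNO₃); no divalent cations,
  no phosphate or other oxyanion competitors (the tableau accepts them, the
  shipped database does not include them).
* No NOM partitioning, kinetics, titration of composites, mineral
  dissolution, or temperature dependence (25 °C throughout).
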