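# Methods

## Scope and model

`prekit` analyses inter-chain paramagnetic relaxation enhancement (PRE)
experiments on transient dimers of disordered proteins. The physical model
throughout is two-state fast exchange between free monomer and a transient
dimer: every observed rate is a population-weighted average of the free and
bound states. The pipeline begins at per-residue peak-intensity tables;
spectral processing, peak picking and resonance assignment are out of scope,
as is any Solomon–Bloembergen distance calibration of Γ₂ — enhancement rates
are interpreted only as contact evidence.

## Relaxation fitting

Each residue's intensity series over the delay schedule is modelled as a
two-parameter mono-exponential, I(t) = I₀·exp(−R₂t). The default schedule is
12, 32, 104, 12, 124, 64, 48, 94, 64, 20 ms with 12 and 64 ms duplicated.
Duplicates are fitted jointly as independent points (preserving degrees of
freedom) and separately feed the noise estimator.

**Noise model.** Intensity noise is homoscedastic relative (fractional) and
pooled across residues: per replicate group the unbiased per-measurement
relative SD — |I₁−I₂|/(√2·mean) for a pair — is pooled by degrees of freedom.
The √2 calibration makes the estimator unbiased; the raw RMS half-difference
would systematically underestimate σ by √2. With relative noise ε the
propagated PRE-rate uncertainty on a schedule with delay spread
Sxx = Σ(t−t̄)² is σ(Γ₂) = ε·√(2/Sxx), ≈ 0.41 s⁻¹ at the default ε = 0.035 —
consistent with the sub-2-Hz Γ₂ errors typical of these experiments.

**Fit mechanics.** Weighted nonlinear least squares (σᵢ = ε·Iᵢ), initialised
from the log-linear closed form (which also serves as the independent oracle
in tests); zero intensities fall back to a direct fit with I₀ ≥ 0. R₂ errors
come from the parameter covariance at those σᵢ. A residue is marked failed —
recorded with a reason, never silently zeroed — on non-convergence, a
negative rate at the optimum, or relative rate uncertainty above 100%.

## PRE rates and significance

Γ₂ = R₂^para − R₂^dia residue-wise with quadrature errors; a residue must fit
successfully in both arms to appear. The three-clause contact filter
(≥ 2·mean, > Q3, ≥ 8 s⁻¹) is evaluated per strip over all successfully
fitted residues — prolines and failed residues are excluded because they are
never fitted, and residues broadened beyond detection are likewise absent
rather than imputed. Q3 uses linear interpolation between order statistics
(the numpy default), documented so the brute-force oracle in the tests uses
the identical convention. Colour binning of contact maps clamps negatives to
zero and saturates above 12 s⁻¹; rendering is a pure function of stored
values.

Region defaults: αS N 1–60, NAC 61–95, C 96–140 (hot spot 38–45);
βS N 1–60, NAC 61–84, C 85–134. These standard synuclein boundaries are
configuration defaults and overridable. A (strip, region) pair counts as
interacting only with ≥ 3 contiguous significant residues, guarding against
single-residue noise passes; head-to-head means an N-terminal probe contacts
the N-terminal region, head-to-tail an N-terminal probe contacts the
C-terminal region. Sequence alignment (for cross-species residue mapping)
is global affine-gap alignment, BLOSUM62 with open −10 / extend −0.5; on the
αS/βS pair this yields the expected single 11-residue NAC gap.

## Titration fitting and classification

The fitted isotherm is the single-site saturation form
Γ₂^app(x) = Γ₂^free + (Γ₂^bound − Γ₂^free)·x/(K_D + x), with x the absolute
molar concentration of the spin-labelled species (ratio × 250 μM), forced by
the three named parameters and the meaning of Γ₂^bound as the saturation
ceiling. Γ₂^free is fitted rather than pinned to zero even though the x = 0
point implies Γ₂ ≈ 0.

Fits are error-weighted (χ² = Σ[(Γ₂ᵢ − model)/σᵢ]²; an unweighted variant is
exposed), initialised from the x = 0 point, 2·max(Γ₂) and the median x, and
bounded: K_D ∈ (0, 1 M], Γ₂^bound ∈ [0, 500 s⁻¹]. Uncertainties come from
the covariance at the optimum scaled by reduced χ², and K_D additionally
from a Δχ² = 1 profile likelihood: K_D is stepped on a log scale with the two
linear parameters re-optimised in closed form, and the crossings are located
by bisection; an end that reaches a bound before crossing is reported open.

Classification compares the isotherm against a two-parameter straight line
using the small-sample-corrected information criterion
AICc = χ² + 2k + 2k(k+1)/(n−k−1) with a 2-unit margin (the conventional
weak-evidence boundary; configurable). Specific requires the isotherm
favoured by ≥ 2 AICc units with K_D and Γ₂^bound interior to their bounds and
Γ₂^bound ≥ Γ₂^free; a K_D or Γ₂^bound pinned at a bound (the linear limit of
the hyperbola) flags the fit nonspecific. Residues whose Γ₂ at the
designated titration point (default: the highest retained point; a different
ordinal is configurable) does not exceed 15 s⁻¹ are noninteracting and are
not fitted. With n = 5 retained points the AICc correction for the
three-parameter model is 24 units, which effectively disables the saturation
model; this is the statistical reason the synthetic titrations retain all
six points (see below). Fitting is residue-by-residue; no global shared-K_D
model is attempted.

## Synthetic data

The generator emulates: per-residue baseline R₂ drawn uniformly from
10–25 s⁻¹ (typical disordered-chain amide rates at moderate field and 15 °C),
constant across arms; contact segments per spin-label strip with bound-state
amplitudes and per-residue K_D; dimer occupancy; mono-exponential decays
with multiplicative Gaussian intensity noise, independent across duplicate
delays; and proline gaps (no amide proton, hence absent rows). Everything is
deterministic under the scenario seed.

Default scenarios encode the study conditions: 250 μM visible chain,
titration ratios 0–1.5 (αS visible) or 0–2 (βS visible), 3.5% intensity
noise. `homo` gives the N-probes (11, 44) a nonspecific hot-spot segment
36–44 (K_D 5 mM — far above the sampled concentrations, so titrations stay
linear — amplitude 400 s⁻¹) and a specific C-terminal segment 124–140
(amplitude 60 s⁻¹, per-residue K_D lognormal about a 500 μM median, clipped
to 90–1200 μM), plus the symmetric C-probe→hot-spot segment; `hetero` gives
the N-probes a specific βS C-terminal segment 105–134 (amplitude 50 s⁻¹,
K_D about a 100 μM median, clipped to 40–350 μM) and an extremely weak N–N
segment 37–41 (10 s⁻¹); `beta-beta` has no segments. Segment amplitudes
taper linearly over three edge residues. No experimental amplitude scale is
published for Γ₂^bound; these values are plausibility choices tuned to put
observed Γ₂ in the 8–25 s⁻¹ display range at the realised occupancies.

**Occupancy models.** `exact_dimer` solves the A + B ⇌ AB mass balance
exactly (in the cancellation-free quadratic form); `hyperbolic` treats total
spin-labelled concentration as free ligand — the approximation the fitted
isotherm itself makes. Contact-map scenarios default to `exact_dimer`: at a
single mixing ratio the model only scales amplitudes, so the more realistic
equilibrium costs nothing. Quantitative K_D-recovery checks and the
titration-shape checks generate under `hyperbolic`: fitting the hyperbolic
isotherm to exact-dimer titrations at 250 μM visible chain shifts the
apparent K_D upward by roughly the bound visible-chain concentration
(measured ≈ 4× at K_D = 100 μM), so recovery of the generating constant is
only a well-posed calibration target when generator and estimator share the
occupancy model. The estimator's behaviour under model mismatch is
characterised separately by the identifiability tests (large-K_D exact-dimer
profiles are increasingly flagged nonspecific).

**Exclusions.** The ability to drop titration points (e.g. a top point
compromised by chemical-shift perturbations in a real experiment) is carried
in the configuration (`excluded_points` / `excluded_ratios`), but synthetic
titrations retain the full grid by default: the generator produces no
chemical-shift artifact, and five-point grids cripple AICc model selection
as noted above.

**What passing tests do and do not show.** The generator draws independent
Gaussian noise per point and per residue; real spectra have correlated
baseline distortions, overlap-dependent intensity errors, exchange
broadening and incomplete label reduction in the diamagnetic control, none
of which are modelled. Passing recovery tests therefore demonstrates the
estimators are correct and well-calibrated under the stated statistical
model at the study's design, not that real-data systematics are negligible.

## Numerical choices and problem sizes

Decay fits use analytic log-linear initialisation and tight tolerances
(1e-14), achieving ≤ 1e-6 relative agreement with the closed form on exact
data. Titration fits use a bounded trust-region least-squares optimiser with
Jacobian-based scaling (the concentrations are ~1e-4 in molar units).
Degenerate inputs are handled explicitly: all-zero titrations are flagged
unidentifiable, exactly linear data drive a parameter to its bound and are
flagged, constant intensity series fit R₂ = 0.

Test and acceptance problem sizes: full contact-map runs fit ~135 residues
× 2 arms × 4 strips per scenario; titration-shape fractions use 20 seeded
replicates of the site-44 strip; noisy K_D recovery uses 100 replicates;
filter-oracle comparison uses 1000 random strips. A complete acceptance run
takes well under a minute on one core.

## Known limitations

- Mono-exponential decay is assumed; strongly broadened residues in the
  intermediate-exchange regime would deviate.
- The significance filter's mean and quartile are computed over detected
  residues only; a strip with many peaks broadened beyond detection would
  bias the strip statistics.
- K_D from a 6-point titration with max x ≈ 1.5–3.8×K_D is weakly
  identified above ~1 mM; such residues are deliberately routed to
  "nonspecific" rather than reported with meaningless intervals.
- The exact-dimer/hyperbolic mismatch means absolute fitted K_D from real
  equimolar titrations is an apparent constant, biased upward by roughly the
  bound-partner concentration; comparisons between groups (homo vs hetero)
  are unaffected.
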