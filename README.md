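# prekit

Inter-chain NMR paramagnetic relaxation enhancement (PRE) analysis for
transient, low-affinity complexes of intrinsically disordered proteins —
built around the α-synuclein / β-synuclein dimer system.

Transient dimers of disordered chains exist at populations of a few percent
and lifetimes of hundreds of microseconds, far below what chemical-shift
mapping can see. Inter-chain PRE catches them: an MTSL nitroxide label on an
NMR-blind (¹⁴N) chain broadens the amide resonances of every residue of the
visible (¹⁵N) chain that comes near it. `prekit` turns per-residue
peak-intensity decay tables from such experiments into contact maps and
residue-specific dissociation constants, and ships a synthetic-data generator
so the whole pipeline is testable end to end without spectrometer data.

## The analysis

1. **Transverse relaxation rates.** Each residue's peak intensity across the
   relaxation-delay schedule (12, 32, 104, 12, 124, 64, 48, 94, 64, 20 ms;
   12 and 64 ms duplicated for error statistics) is fitted to
   I(t) = I₀·exp(−R₂t) by weighted nonlinear least squares. The replicate
   pairs give a pooled relative intensity-noise estimate that propagates into
   σ(R₂).

2. **PRE rates.** Γ₂ = R₂(paramagnetic) − R₂(diamagnetic) per residue, with
   quadrature error propagation. A residue counts as a significant contact
   only if Γ₂ ≥ 2·mean(Γ₂) of its strip **and** Γ₂ > Q3 **and** Γ₂ ≥ 8 s⁻¹.
   Strips from spin labels at several sites (11, 44, 90, 132 on αS;
   11, 44, 80, 134 on βS) assemble into a contact map annotated with the
   N-terminal (1–60), NAC, and C-terminal regions, from which dimer
   topologies (head-to-head, head-to-tail) are read off.

3. **Dissociation constants.** Titrating the spin-labelled chain (ratios
   0–1.5 or 0–2 at 250 μM visible chain) and assuming fast exchange gives

   Γ₂^app(x) = Γ₂^free + (Γ₂^bound − Γ₂^free) · x / (K_D + x)

   with x the spin-labelled chain concentration. Residues whose Γ₂ at the
   designated titration point exceeds 15 s⁻¹ are fitted (error-weighted
   Levenberg–Marquardt-type optimisation; K_D intervals from a Δχ²=1
   profile-likelihood scan) and classified **specific** (saturating isotherm
   preferred by small-sample-corrected AIC), **nonspecific** (linear), or
   **noninteracting**.

The synthetic generator emulates the full design: per-residue baseline R₂,
contact segments with bound-state enhancements, occupancies from an exact
two-species dimerisation equilibrium (or its hyperbolic excess-ligand limit),
multiplicative intensity noise, proline gaps, and three default scenarios
(`homo` αS/αS, `hetero` αS-labelled/βS-visible, `beta-beta`).

## Worked example

`python examples/03_titration_kd.py` simulates the αS-44-MTSL → βS titration
and fits per-residue dissociation constants:

```
classification counts: {'noninteracting': 104, 'specific': 22}

residue   class        K_D fit (uM)   68% interval      K_D truth
    115   specific            107   [  102,   112]        106
    116   specific             93   [   88,    97]         89
    117   specific            102   [   97,   107]        100
    ...

C-terminal specific group (n=22): median K_D 105 uM, range 60-198 uM
```

Every fitted K_D is the affinity of the transient heterodimer as reported by
one β-synuclein C-terminal residue; the fitted values track the generating
constants within their profile-likelihood intervals. `examples/01_*` and
`examples/02_*` walk through the relaxation-fitting and contact-map stages
the same way — the αS/αS map shows both head-to-head and head-to-tail
contact blocks, the αS/βS map only a broad head-to-tail block (βS 105–134),
and the βS/βS map is empty.

## Command line

The same pipeline is scriptable from the shell:

```bash
prekit simulate hetero --seed 1 --out-dir run/
prekit fit-r2      --config run/run.yaml
prekit compute-pre --config run/run.yaml
prekit contact-map --config run/run.yaml
prekit fit-kd      --config run/run.yaml
prekit report      --config run/run.yaml
```

`run.yaml` registers peak tables by (site, arm, ratio) and holds sequences,
regions, delays, concentrations and thresholds; real experiments plug in by
pointing the table entries at their own TSV exports (or Sparky-style peak
lists via `prekit.io.series_from_sparky`).

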