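"""Residue-specific dissociation constants from a PRE titration.

Simulates the alpha-44-MTSL titration into visible beta-synuclein (ratios
0-2 at 250 uM), selects residues whose Gamma2 at the top titration point
exceeds 15 s^-1, fits the three-parameter saturation isotherm per residue,
classifies each profile, and summarises the specific group's K_D.
"""

from prekit import scenario
from prekit.pipeline import titration_fits_for_scenario
from prekit.titration import group_summary

config = scenario("hetero", seed=1, occupancy_model="hyperbolic")
fits, truth = titration_fits_for_scenario(config)

counts = {}
for f in fits.values():
    counts[f.classification] = counts.get(f.classification, 0) + 1
print("classification counts:", counts)

truth_kd = dict(zip(truth.residue_index, truth.kd))
print("\nresidue   class        K_D fit (uM)   68% interval      K_D truth")
for r, f in sorted(fits.items()):
    if f.classification != "specific" or not (115 <= r <= 125):
        continue
    s = f.saturation
    print(
        f"{r:7d}   {f.classification:<11}  {s.kd * 1e6:10.0f}   "
        f"[{s.kd_low * 1e6:5.0f}, {s.kd_high * 1e6:5.0f}]   "
        f"{truth_kd.get(r, float('nan')) * 1e6:8.0f}"
    )

median, (lo, hi), n = group_summary(fits, range(105, 135))
print(
    f"\nC-terminal specific group (n={n}): median K_D {median * 1e6:.0f} uM, "
    f"range {lo * 1e6:.0f}-{hi * 1e6:.0f} uM"
)
print(
    "\nEach K_D is the dissociation constant of the transient heterodimer as "
    "seen from one beta-synuclein residue; saturating (specific) profiles "
    "yield finite K_D, linear profiles are classified nonspecific."
)
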