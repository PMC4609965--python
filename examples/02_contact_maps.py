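"""Build inter-chain PRE contact maps for the three default scenarios.

Runs the full chain — simulate peak tables for both arms at equimolar mixing,
fit R2 residue-wise, subtract to Gamma2, apply the three-clause significance
filter — and prints the significant contact blocks and the inferred dimer
topology for each spin-label strip.
"""

from prekit import scenario
from prekit.pipeline import contact_map_for_scenario
from prekit.plotting import plot_contact_map


def blocks(residues):
    """Compress a residue set into contiguous runs for printing."""
    out, run = [], []
    for i in sorted(residues):
        if run and i != run[-1] + 1:
            out.append(run)
            run = []
        run.append(i)
    if run:
        out.append(run)
    return ", ".join(f"{r[0]}-{r[-1]}" if len(r) > 1 else str(r[0]) for r in out) or "-"


for name in ("homo", "hetero", "beta-beta"):
    result = contact_map_for_scenario(scenario(name, seed=1))
    print(f"\n=== {name} (visible chain: "
          f"{result.contact_map.strips[0].sample.visible_species}-synuclein) ===")
    for site, sig in result.contact_map.significant_sets().items():
        print(f"  spin label {site:>3}: significant residues {blocks(sig)}")
    print(f"  dimer topologies: {', '.join(sorted(result.topologies)) or 'none'}")
    plot_contact_map(result.contact_map, f"contact_map_{name}.png")

print(
    "\nSignificant residues mark transient inter-chain contacts (Gamma2 at "
    "least twice the strip mean, above the third quartile and >= 8 s^-1). "
    "The alpha/alpha map shows both head-to-head (N probes to N-terminus) and "
    "head-to-tail (N probes to C-terminus) dimers; alpha/beta shows only "
    "head-to-tail contacts; beta/beta shows none."
)
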