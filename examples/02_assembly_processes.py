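"""Partition community assembly into the five ecological processes.

For every pair of guts the script computes βNTI (phylogenetic z-score
against a tip-shuffling null) and the abundance-based Raup–Crick index,
classifies the pair (homogeneous/variable selection, homogenizing
dispersal / dispersal limitation, stochastic drift), and compares the
process mix of same-site versus different-site pairs with proportion tests.
"""

from gutscape import SimulationConfig, simulate_spatial_survey
from gutscape.assembly import (NullModelConfig, compare_fractions,
                               partition_assembly)

cfg = SimulationConfig(n_taxa=200, n_sites=12, samples_per_site=(5, 5),
                       depth=2000, seed=1)
study = simulate_spatial_survey(cfg)

result = partition_assembly(study.table, study.tree, study.metadata,
                            NullModelConfig(n_randomizations=1000, seed=1))

for cond in ("all_pairs", "within_site", "between_site"):
    fr = result.fractions[cond]
    mix = ", ".join(f"{p}={100 * f:.1f}%" for p, f in fr.fractions.items()
                    if f > 0.005)
    print(f"{cond} ({fr.n_pairs} pairs): {mix}")

shift = compare_fractions(result.fractions["between_site"],
                          result.fractions["within_site"])
print("\nsite-induced shift (between - within), chi-square with Yates:")
for process, row in shift.iterrows():
    print(f"  {process:24s} delta={100 * row['delta']:+6.1f} pp  "
          f"p={row['p']:.2e}")
# Same-site guts are dominated by homogenizing dispersal (they share one
# microbial pool); crossing sites shifts the balance toward stochastic
# drift and variable selection — the geographic signature the survey
# design is meant to expose.
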