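"""Discover enterotypes in genus-level profiles.

Draws 160 gut profiles from a two-component Dirichlet mixture — a majority
component dominated by the core genera (Gilliamella, Snodgrassella) and a
minority "dysbiotic" component dominated by Pseudomonas — then runs the
full enterotyping recipe: Jensen–Shannon distances, PAM clustering,
CH-index model selection, silhouette validation, and per-genus
Kruskal–Wallis contrasts.
"""

from gutscape.enterotype import compare_enterotypes, find_enterotypes
from gutscape.synthetic import simulate_enterotype_mixture

profiles, truth = simulate_enterotype_mixture(160, enterotype_fraction=0.1,
                                              seed=2)
model = find_enterotypes(profiles, seed=0)

print(f"CH-optimal number of enterotypes: k={model.k}")
print("CH index by k:", {k: round(v, 1) for k, v in model.ch_by_k.items()})
print(f"mean silhouette width: {model.mean_silhouette:.3f}"
      f"{'  (weak structure!)' if model.weak_structure else ''}")

sizes = model.labels.value_counts().sort_index()
print("cluster sizes:", dict(sizes))

pred, t = model.labels.to_numpy(), truth.to_numpy()
agreement = max((pred + 1 == t).mean(), (2 - pred == t).mean())
print(f"agreement with planted labels: {100 * agreement:.1f}%")

contrasts = compare_enterotypes(profiles, model.labels)
top = contrasts.sort_values("p_adj").head(4)
print("\nmost differential genera (Kruskal-Wallis, BH-adjusted):")
for genus, row in top.iterrows():
    print(f"  {genus:18s} H={row['H']:6.1f}  p_adj={row['p_adj']:.2e}")
# With a planted 10% dysbiotic fraction the pipeline finds exactly two
# clusters, assigns essentially every sample correctly, and flags the
# pathogen genus as the dominant discriminator.
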