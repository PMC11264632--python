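"""Relate community structure and alpha diversity to the environment.

On a survey with a planted temperature-driven niche and a richness gradient,
the script runs the whole association battery: VIF collinearity screen,
per-covariate adonis-style screens of the Bray–Curtis matrix, Poisson GLMs
of chao1, distance–decay regression with Mantel permutation, CCA with a
permutation ANOVA, and envfit arrows.
"""

from gutscape import SimulationConfig, simulate_spatial_survey
from gutscape.diversity import alpha_diversity, bray_curtis, rarefy
from gutscape.env_assoc import (cca, cca_permutation_test, ddr_fit, env_table,
                                envfit, glm_alpha, marginal_adonis_screen,
                                vif_screen)

cfg = SimulationConfig(n_taxa=200, n_sites=20, samples_per_site=(4, 6),
                       depth=2000, seed=3)
study = simulate_spatial_survey(cfg, richness_gradient=1.0)
table = rarefy(study.table, 1000, seed=3)
meta = study.metadata.loc[table.sample_ids]
env = env_table(meta)

vif = vif_screen(env)
print(f"VIF screen: max={vif['vif'].max():.1f} "
      f"({'all pass' if vif['pass'].all() else 'collinearity!'} at <10)")

dm = bray_curtis(table)
screen = marginal_adonis_screen(dm, env, n_perm=999, seed=3)
print("\nper-covariate adonis screen (R2, p):")
for var, row in screen.iterrows():
    print(f"  {var:26s} R2={row['R2']:.3f}  p={row['p']:.3f}")

alpha = alpha_diversity(table)
fit = glm_alpha(alpha["chao1"], env["annual_mean_temperature"], "poisson")
print(f"\nchao1 ~ AMT (Poisson GLM): slope={fit.slope:+.3f} "
      f"p={fit.slope_p:.1e}  (richness rises with temperature)")

ddr = ddr_fit(dm, meta, n_perm=999, seed=3)
print(f"distance-decay: slope={1000 * ddr['slope']:+.3f} similarity/1000 km, "
      f"r={ddr['r']:+.2f}, Mantel p={ddr['p']:.3f}")

occupied = table.counts.sum(axis=1) > 0
cca_table = table.filter_taxa(
    [t for t, k in zip(table.taxon_ids, occupied) if k])
res = cca(cca_table, env)
test = cca_permutation_test(res, n_perm=999, seed=3)
print(f"CCA: {100 * res.constrained_inertia / res.total_inertia:.1f}% of "
      f"inertia constrained, permutation p={test['p']:.3f}")

arrows = envfit(res.site_scores.iloc[:, :2], env, n_perm=999, seed=3)
strongest = arrows["r2"].idxmax()
print(f"envfit: strongest covariate = {strongest} "
      f"(r2={arrows.loc[strongest, 'r2']:.2f})")
# The temperature covariate that actually drives the niche comes out on
# top in every screen, while the purely correlated covariates show weaker
# but nonzero association — the pattern to expect in real surveys.
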