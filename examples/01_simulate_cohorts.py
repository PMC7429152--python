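"""Generate a synthetic cohort with LD-blocked genotypes, polygenic lung
function, GOLD/PRISm categories and downstream phenotypes."""

from copdprs import SimConfig, simulate_cohort

cfg = SimConfig(n_individuals=4000, n_variants=500, seed=1)
G, ph = simulate_cohort(cfg, prs_link=0.3)

print(f"cohort: {G.n} individuals x {G.m} variants")
print(f"moderate-to-severe COPD prevalence: {ph['copd'].mean():.3f}")
print("GOLD/PRISm categories:")
print(ph["gold_category"].value_counts().to_string())
print(f"mean pack-years: {ph['pack_years'].mean():.1f}")

# COPD requires both airflow obstruction (FEV1/FVC < 0.7) and reduced FEV1
# (< 80% predicted); PRISm has the reduced FEV1 with a preserved ratio.
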