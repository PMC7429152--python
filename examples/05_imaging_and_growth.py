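"""Associate the combined PRS with CT imaging phenotypes (linear, Tobit,
ordinal, subtype-vs-reference) and lung-growth patterns."""

from copdprs.phenoassoc import (
    continuous_assoc, gold_contrasts, growth_pattern_assoc, ordinal_assoc,
    subtype_vs_reference, tobit_assoc,
)
from copdprs.pipeline import run_pipeline, validate_config

cfg = validate_config({
    "seed": 7, "out_dir": "scratch/example05",
    "simulate": {"train": {"n_individuals": 3000, "n_variants": 400},
                 "ld_panel_n": 300, "tuning_n": 1000,
                 "cohorts": [{"name": "test", "n": 4000}]},
    "build": {"lambda_values": [0.003, 0.01, 0.03]},
    "stages": ["simulate", "build", "score", "combine"],
})
ctx = run_pipeline(cfg)["context"]
ph = ctx["cohorts"]["test"]["ph"]
prof = ctx["combined"]["test"]

wap = continuous_assoc(ph, prof, "wap_pct")
print(f"WAP: {wap.estimate:+.3f} %/SD (p={wap.p:.2e})")

laa = continuous_assoc(ph, prof, "laa950_pct", transform="log")
print(f"log %LAA<-950: {laa.estimate:+.3f} per SD (p={laa.p:.2e})")

tob = tobit_assoc(ph, prof, "lh_centrilobular_pct")
print(f"Tobit centrilobular: latent beta {tob.beta_latent:+.3f} per SD "
      f"(sigma {tob.sigma:.2f}, {tob.n_censored}/{tob.n} censored)")

ordn = ordinal_assoc(ph, prof, "visual_emphysema_grade")
print(f"visual emphysema: OR {ordn.or_per_sd:.2f} per SD of being in a higher grade")

for sub, res in subtype_vs_reference(ph, prof).items():
    print(f"CT subtype {sub} vs normal imaging: OR {res.odds_ratio:.2f} (p={res.p:.2e})")

for (a, b), res in gold_contrasts(ph, prof).items():
    print(f"mean score {a} vs {b}: {res.estimate:+.3f} (p={res.p:.2e})")

growth = growth_pattern_assoc(ph, prof)
print(f"reduced lung growth: OR {growth.odds_ratio:.2f} per SD (p={growth.p:.2e})")
# Tobit reports the effect on the latent uncensored emphysema percentage;
# the ordinal OR is the proportional odds of a higher visual grade per SD.
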