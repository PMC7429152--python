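"""Evaluate the combined PRS in a test cohort: OR per SD, decile risk
gradient, AUC model comparison and a Youden screening cutoff.  Uses the
pipeline to produce the score, then the evaluation functions directly."""

from copdprs.evaluate import auc_models, decile_analysis, fit_or_per_sd, youden_and_metrics
from copdprs.pipeline import run_pipeline, validate_config

cfg = validate_config({
    "seed": 5, "out_dir": "scratch/example03",
    "simulate": {"train": {"n_individuals": 3000, "n_variants": 400},
                 "ld_panel_n": 300, "tuning_n": 1000,
                 "cohorts": [{"name": "test", "n": 3000}]},
    "build": {"lambda_values": [0.003, 0.01, 0.03]},
    "stages": ["simulate", "build", "score", "combine"],
})
ctx = run_pipeline(cfg)["context"]
ph = ctx["cohorts"]["test"]["ph"]
prof = ctx["combined"]["test"]

res = fit_or_per_sd(ph, prof, covariates=("age", "sex", "height", "pack_years"))
print(f"OR per SD of combined PRS: {res.odds_ratio:.2f} "
      f"(95% CI {res.or_ci[0]:.2f}-{res.or_ci[1]:.2f}, p={res.p:.2e})")

deciles = decile_analysis(prof, ph["copd"].to_numpy())
print(f"decile 10 vs decile 1 OR: {deciles[-1].odds_ratio:.2f}")

for roc in auc_models(ph, prof):
    line = f"AUC {roc.model}: {roc.auc:.3f}"
    if roc.comparison:
        other, delta, p = roc.comparison
        line += f"  (vs {other}: delta={delta:+.3f}, DeLong p={p:.2e})"
    print(line)

m = youden_and_metrics(ph["copd"].to_numpy(), prof.std)
print(f"Youden cutoff {m.cutoff:.2f}: sens {m.sensitivity:.2f}, spec {m.specificity:.2f}, "
      f"PPV {m.ppv:.2f}, NPV {m.npv:.2f}")
# The OR per SD is covariate-adjusted; the decile OR compares the risk tails;
# the AUC rows show what the score adds over clinical risk factors.
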