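"""Reproducible end-to-end runs: simulate -> build -> score -> combine ->
evaluate -> meta -> epi -> pheno.

A YAML (or dict) config declares the study conditions and which stages to
run; every stage derives its random seed deterministically from the global
seed, writes plain-text outputs under the run directory, and records them
(with content hashes) in a manifest.  Re-running an identical config
reproduces every output bit for bit, apart from manifest timestamps.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine, evaluate, ld, meta, phenoassoc, simulate, sumstats

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline", "STAGES"]

STAGES = ["simulate", "build", "score", "combine", "evaluate", "meta", "epi", "pheno"]

_SIMCONFIG_KEYS = {f.name for f in dc_fields(simulate.SimConfig)} - {"seed"}

DEFAULTS = {
    "seed": 0,
    "out_dir": "copdprs_run",
    "stages": list(STAGES),
    "simulate": {
        "train": {"n_individuals": 5000, "n_variants": 1000, "block_size": 10,
                  "within_block_rho": 0.5, "h2_fev1": 0.4, "h2_ratio": 0.4},
        "ld_panel_n": 500,
        "tuning_n": 2000,
        "cohorts": [
            {"name": "cohortA", "ancestry": "EUR", "n": 4000},
            {"name": "cohortB", "ancestry": "EUR", "n": 4000},
        ],
        "prs_link": 0.3,
        "write_genotypes": False,
    },
    "build": {
        "s_values": [0.2, 0.5, 0.9, 1.0],
        "lambda_values": [0.001, 0.0022, 0.0046, 0.01, 0.022, 0.046, 0.1],
        "metric": "trait_r2",
    },
    "evaluate": {"covariates": ["age", "sex", "height", "pack_years", "pc1", "pc2"]},
    "meta": {},
    "epi": {"pack_years_threshold": 20.0},
    "pheno": {},
}


class ConfigError(ValueError):
    """Configuration schema violation, with a JSON-pointer-style path."""


@dataclass
class RunConfig:
    data: dict

    def __getitem__(self, key):
        return self.data[key]

    @property
    def seed(self) -> int:
        return self.data["seed"]

    @property
    def out_dir(self) -> Path:
        return Path(self.data["out_dir"])

    @property
    def stages(self) -> list:
        return self.data["stages"]


def _check_keys(block: dict, allowed: set, path: str):
    for k in block:
        if k not in allowed:
            raise ConfigError(f"{path}/{k}: unknown key {k!r}")


def validate_config(source) -> RunConfig:
    """Validate and normalize a run config (path, YAML string or dict).

    Unknown keys are rejected with the offending path; defaults are injected
    for everything omitted.
    """
    if isinstance(source, dict):
        raw = copy.deepcopy(source)
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("/: config must be a mapping")

    _check_keys(raw, set(DEFAULTS), "")
    cfg = copy.deepcopy(DEFAULTS)

    for key, val in raw.items():
        if key in ("seed",):
            if not isinstance(val, int) or val < 0:
                raise ConfigError("/seed: must be a non-negative integer")
            cfg["seed"] = val
        elif key == "out_dir":
            cfg["out_dir"] = str(val)
        elif key == "stages":
            for st in val:
                if st not in STAGES:
                    raise ConfigError(f"/stages: unknown stage {st!r}")
            cfg["stages"] = list(val)
        else:
            if not isinstance(val, dict):
                raise ConfigError(f"/{key}: must be a mapping")
            if key == "simulate":
                _check_keys(val, {"train", "ld_panel_n", "tuning_n", "cohorts", "prs_link", "write_genotypes"}, "/simulate")
                if "train" in val:
                    _check_keys(val["train"], _SIMCONFIG_KEYS, "/simulate/train")
                    cfg["simulate"]["train"].update(val["train"])
                for k in ("ld_panel_n", "tuning_n", "prs_link", "write_genotypes"):
                    if k in val:
                        cfg["simulate"][k] = val[k]
                if "cohorts" in val:
                    for i, c in enumerate(val["cohorts"]):
                        _check_keys(c, {"name", "ancestry", "n"}, f"/simulate/cohorts/{i}")
                    cfg["simulate"]["cohorts"] = val["cohorts"]
            elif key == "build":
                _check_keys(val, {"s_values", "lambda_values", "metric"}, "/build")
                cfg["build"].update(val)
            elif key == "evaluate":
                _check_keys(val, {"covariates"}, "/evaluate")
                cfg["evaluate"].update(val)
            elif key == "epi":
                _check_keys(val, {"pack_years_threshold"}, "/epi")
                cfg["epi"].update(val)
            elif key in ("meta", "pheno"):
                _check_keys(val, set(), f"/{key}")
    return RunConfig(cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _assoc_dict(r) -> dict:
    return {
        "estimate": r.estimate, "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "p": r.p, "n": r.n, "model": r.model, "odds_ratio": r.odds_ratio,
    }


def _sim_cfg(base: dict, seed: int, n: int | None = None, arch_seed: int | None = None) -> simulate.SimConfig:
    kw = dict(base)
    if n is not None:
        kw["n_individuals"] = n
    return simulate.SimConfig(seed=seed, architecture_seed=arch_seed, **kw)


class _Pipeline:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.ctx: dict = {}
        self.out = cfg.out_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = {"seed": cfg.seed, "config": cfg.data, "stages": []}

    def _record(self, stage: str, outputs: dict):
        self.manifest["stages"].append(
            {
                "name": stage,
                "outputs": {name: _sha256(Path(p)) for name, p in outputs.items()},
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    def _need(self, key: str, stage: str):
        if key not in self.ctx:
            raise RuntimeError(f"stage {stage!r} requires output {key!r}; run its prerequisite stages")
        return self.ctx[key]

    # -- stages ------------------------------------------------------------

    def stage_simulate(self):
        sc = self.cfg["simulate"]
        seed = self.cfg.seed
        train_cfg = _sim_cfg(sc["train"], seed=seed, arch_seed=seed)
        G_train = simulate.simulate_ld_genotypes(train_cfg)
        ph_train = simulate.simulate_lung_phenotypes(G_train, train_cfg)
        ss_fev1 = simulate.simulate_gwas_sumstats(G_train, ph_train["fev1_pct_pred"].to_numpy(), "FEV1")
        ss_ratio = simulate.simulate_gwas_sumstats(G_train, ph_train["fev1_fvc"].to_numpy(), "FEV1_FVC")

        panel_cfg = _sim_cfg(sc["train"], seed=seed + 101, n=sc["ld_panel_n"], arch_seed=seed)
        G_panel = simulate.simulate_ld_genotypes(panel_cfg)

        tune_cfg = _sim_cfg(sc["train"], seed=seed + 202, n=sc["tuning_n"], arch_seed=seed)
        G_tune, ph_tune = simulate.simulate_cohort(tune_cfg, prs_link=sc["prs_link"])

        cohorts = {}
        outputs = {}
        for i, cohort_def in enumerate(sc["cohorts"]):
            c_cfg = _sim_cfg(sc["train"], seed=seed + 303 + i, n=cohort_def["n"], arch_seed=seed)
            G_c, ph_c = simulate.simulate_cohort(c_cfg, prs_link=sc["prs_link"])
            cohorts[cohort_def["name"]] = {"G": G_c, "ph": ph_c, "ancestry": cohort_def.get("ancestry", "EUR")}
            p = self.out / f"phenotypes_{cohort_def['name']}.tsv"
            simulate.write_phenotypes_tsv(ph_c, p)
            outputs[p.name] = p
        for name, tab in (("sumstats_fev1.tsv", ss_fev1), ("sumstats_ratio.tsv", ss_ratio)):
            p = self.out / name
            cols = {"id": "SNP", "chrom": "CHR", "pos": "BP", "effect_allele": "A1",
                    "other_allele": "A2", "beta": "BETA", "se": "SE", "p": "P", "n": "N"}
            tab.table.rename(columns=cols)[list(cols.values())].to_csv(p, sep="\t", index=False)
            outputs[name] = p
        if sc["write_genotypes"]:
            for label, G in (("train", G_train), ("panel", G_panel), ("tuning", G_tune)):
                p = self.out / f"dosages_{label}.tsv"
                simulate.write_dosage_tsv(G, p)
                outputs[p.name] = p
        self.ctx.update(
            sumstats={"FEV1": ss_fev1, "FEV1_FVC": ss_ratio},
            G_panel=G_panel, G_tune=G_tune, ph_tune=ph_tune, cohorts=cohorts,
            block_size=train_cfg.block_size,
        )
        return outputs

    def stage_build(self):
        bc = self.cfg["build"]
        ss = self._need("sumstats", "build")
        G_panel = self._need("G_panel", "build")
        blocks = ld.compute_ld_blocks(G_panel, block_assignment=self.ctx["block_size"])
        grid = engine.TuningGrid(
            s_values=tuple(bc["s_values"]), lambda_values=tuple(bc["lambda_values"]), metric=bc["metric"]
        )
        weights, outputs = {}, {}
        for trait, column in (("FEV1", "fev1_pct_pred"), ("FEV1_FVC", "fev1_fvc")):
            w, report = engine.tune_hyperparameters(
                ss[trait], blocks, self.ctx["G_tune"], self.ctx["ph_tune"], grid, trait_column=column
            )
            weights[trait] = w
            p = self.out / f"weights_{trait.lower()}.tsv"
            sumstats.write_weights(w, p)
            outputs[p.name] = p
            rp = self.out / f"tuning_report_{trait.lower()}.tsv"
            report.to_csv(rp, sep="\t", index=False)
            outputs[rp.name] = rp
        self.ctx["weights"] = weights
        self.ctx["ld_blocks"] = blocks
        return outputs

    def stage_score(self):
        weights = self._need("weights", "score")
        outputs = {}
        profiles = {"tuning": {}}
        for trait, w in weights.items():
            profiles["tuning"][trait] = engine.score_individuals(self.ctx["G_tune"], w, cohort="tuning")
        for name, c in self._need("cohorts", "score").items():
            profiles[name] = {t: engine.score_individuals(c["G"], w, cohort=name) for t, w in weights.items()}
        for name, by_trait in profiles.items():
            for trait, prof in by_trait.items():
                p = self.out / f"profile_{name}_{trait.lower()}.tsv"
                prof.table.assign(n_variants_used=prof.n_variants_used).to_csv(p, sep="\t", index=False)
                outputs[p.name] = p
        self.ctx["profiles"] = profiles
        return outputs

    def stage_combine(self):
        profiles = self._need("profiles", "combine")
        model, _ = engine.combine_scores(
            profiles["tuning"]["FEV1"], profiles["tuning"]["FEV1_FVC"],
            labels=self.ctx["ph_tune"]["copd"].to_numpy(), mode="fitted",
        )
        combined = {}
        outputs = {}
        for name in self._need("cohorts", "combine"):
            _, prof = engine.combine_scores(
                profiles[name]["FEV1"], profiles[name]["FEV1_FVC"],
                mode="fixed", coefficients=(model.b_fev1, model.b_ratio),
            )
            combined[name] = prof
            p = self.out / f"profile_{name}_combined.tsv"
            prof.table.to_csv(p, sep="\t", index=False)
            outputs[p.name] = p
        mp = self.out / "combined_model.json"
        mp.write_text(json.dumps(
            {"b_fev1": model.b_fev1, "b_ratio": model.b_ratio, "intercept": model.intercept,
             "source": "tuning"}, indent=2))
        outputs[mp.name] = mp
        self.ctx["combined_model"] = model
        self.ctx["combined"] = combined
        return outputs

    def stage_evaluate(self):
        covs = self.cfg["evaluate"]["covariates"]
        results = {}
        for name, c in self._need("cohorts", "evaluate").items():
            prof = self._need("combined", "evaluate")[name]
            ph = c["ph"]
            or_sd = evaluate.fit_or_per_sd(ph, prof, covariates=covs)
            deciles = evaluate.decile_analysis(prof, ph["copd"].to_numpy())
            rocs = evaluate.auc_models(ph, prof)
            youden = evaluate.youden_and_metrics(ph["copd"].to_numpy(), prof.std)
            exac = evaluate.exacerbation_models(ph, prof)
            results[name] = {
                "ancestry": c["ancestry"],
                "n": int(len(ph)),
                "n_cases": int(ph["copd"].sum()),
                "n_controls": int((1 - ph["copd"]).sum()),
                "or_per_sd": _assoc_dict(or_sd),
                "deciles": [_assoc_dict(r) for r in deciles],
                "auc": {r.model: {"auc": r.auc, "se": r.se, "ci": [r.ci_low, r.ci_high],
                                  "comparisons": r.comparisons} for r in rocs},
                "youden": {"cutoff": youden.cutoff, "sensitivity": youden.sensitivity,
                           "specificity": youden.specificity, "ppv": youden.ppv, "npv": youden.npv},
                "exacerbations": {k: {"base": _assoc_dict(b), "adjusted": _assoc_dict(a)}
                                  for k, (b, a) in exac.items()},
            }
        p = self.out / "evaluation.json"
        p.write_text(json.dumps(results, indent=2))
        self.ctx["evaluation"] = results
        return {p.name: p}

    def stage_meta(self):
        ev = self._need("evaluation", "meta")
        ests = [v["or_per_sd"]["estimate"] for v in ev.values()]
        ses = [v["or_per_sd"]["se"] for v in ev.values()]
        out = {}
        if len(ests) >= 2:
            fixed = meta.meta_fixed_iv(ests, ses)
            random_ = meta.meta_random_dl(ests, ses)
            ess = meta.meta_ess_auc(
                [v["auc"]["prs"]["auc"] for v in ev.values()],
                [v["n_cases"] for v in ev.values()],
                [v["n_controls"] for v in ev.values()],
                ses=[v["auc"]["prs"]["se"] for v in ev.values()],
            )
            for label, m in (("fixed_iv", fixed), ("random_dl", random_), ("ess_auc", ess)):
                out[label] = {"estimate": m.estimate, "se": m.se, "ci": [m.ci_low, m.ci_high],
                              "Q": m.Q, "I2": m.I2, "tau2": m.tau2, "k": m.k}
        p = self.out / "meta.json"
        p.write_text(json.dumps(out, indent=2))
        self.ctx["meta"] = out
        return {p.name: p}

    def stage_epi(self):
        thr = self.cfg["epi"]["pack_years_threshold"]
        name, c = next(iter(self._need("cohorts", "epi").items()))
        ph = c["ph"]
        prof = self._need("combined", "epi")[name]
        exposure = ph["pack_years"].to_numpy() > thr
        outcome = ph["copd"].to_numpy()
        ar = meta.attributable_risk(exposure, outcome)
        deciles = evaluate.assign_deciles(prof.std)
        impact = meta.targeted_impact(deciles, exposure, outcome)
        out = {
            "cohort": name,
            "rr": ar.rr, "ar_pct": ar.ar_pct, "par_pct": ar.par_pct, "p_exposed": ar.p_exposed,
            "impact": impact.impact.to_dict(orient="records"),
        }
        p = self.out / "epi.json"
        p.write_text(json.dumps(out, indent=2))
        self.ctx["epi"] = out
        return {p.name: p}

    def stage_pheno(self):
        name, c = next(iter(self._need("cohorts", "pheno").items()))
        ph = c["ph"]
        prof = self._need("combined", "pheno")[name]
        cont = phenoassoc.continuous_assoc(ph, prof, "wap_pct")
        laa = phenoassoc.continuous_assoc(ph, prof, "laa950_pct", transform="log")
        tobit = phenoassoc.tobit_assoc(ph, prof, "lh_centrilobular_pct")
        ordinal = phenoassoc.ordinal_assoc(ph, prof, "visual_emphysema_grade")
        subtype = phenoassoc.subtype_vs_reference(ph, prof)
        gold = phenoassoc.gold_contrasts(ph, prof)
        growth = phenoassoc.growth_pattern_assoc(ph, prof)
        out = {
            "cohort": name,
            "wap_pct": _assoc_dict(cont),
            "log_laa950_pct": _assoc_dict(laa),
            "tobit_lh_centrilobular": {
                "beta_latent": tobit.beta_latent, "se": tobit.se, "p": tobit.p,
                "sigma": tobit.sigma, "n_censored": tobit.n_censored,
            },
            "visual_emphysema_ordinal": {
                "or_per_sd": ordinal.or_per_sd, "ci": [ordinal.ci_low, ordinal.ci_high], "p": ordinal.p,
            },
            "ct_subtypes": {str(k): _assoc_dict(v) for k, v in subtype.items()},
            "gold_contrasts": {f"{a}_vs_{b}": _assoc_dict(v) for (a, b), v in gold.items()},
            "growth_pattern": _assoc_dict(growth),
        }
        p = self.out / "pheno.json"
        p.write_text(json.dumps(out, indent=2))
        self.ctx["pheno"] = out
        return {p.name: p}

    def run(self) -> dict:
        for stage in STAGES:
            if stage not in self.cfg.stages:
                continue
            logger.info("running stage %s", stage)
            try:
                outputs = getattr(self, f"stage_{stage}")()
            except Exception:
                self._write_manifest()
                logger.error("stage %s failed; partial outputs persisted in %s", stage, self.out)
                raise
            self._record(stage, outputs)
        self._write_manifest()
        return self.manifest

    def _write_manifest(self):
        (self.out / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def run_pipeline(cfg: RunConfig | dict | str) -> dict:
    """Execute the configured stages; returns the run manifest."""
    if not isinstance(cfg, RunConfig):
        cfg = validate_config(cfg)
    pipe = _Pipeline(cfg)
    manifest = pipe.run()
    manifest["context"] = pipe.ctx  # in-memory results for library callers
    return manifest
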