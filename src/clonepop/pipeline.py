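"""End-to-end orchestration with a single validated configuration.

The pipeline runs the analysis stages in dependency order over either user
inputs (VCF + annotation + cytosine reports) or, when no VCF is given, a
self-generated synthetic cohort.  Every output is stamped with the
configuration hash and seed; stage toggles isolate outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clonal, demography, diversity, filters, sweep
from .branch import threepop_scan, validate_candidates
from .fixtures import generate_methylome_fixture
from .genotypes import GenotypeMatrix
from .methylome import call_methylated, mc_proportion, nonconversion_rate, weighted_ml
from .models import DemographicModel
from .simulate import simulate_population_set

ALL_STAGES = (
    "filter", "clonal", "diversity", "sweep", "branch", "methylome", "abc",
)


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 1
    vcf: str | None = None                 # None -> simulate a demo cohort
    population_table: dict = field(default_factory=dict)
    cytosine_reports: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    # demo-simulation parameters
    n_per_pop: int = 8
    L: int = 300_000
    # stage parameters
    window_size: int = 50_000
    window_step: int = 10_000
    ld_max_dist: int = 100_000
    abc_sims: int = 300
    abc_tolerance: float = 0.1
    sigma_priors: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list:
    """Schema and cross-field checks; returns diagnostics (empty = valid)."""
    diags = []
    if config.vcf is not None and not os.path.exists(config.vcf):
        diags.append(f"VCF path does not exist: {config.vcf}")
    for sid, path in config.cytosine_reports.items():
        if not os.path.exists(path):
            diags.append(f"cytosine report missing for {sid}: {path}")
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        diags.append(f"unknown stages: {sorted(unknown)}")
    for pop, s in config.sigma_priors.items():
        if not (0.0 <= s <= 1.0):
            diags.append(f"sigma prior for {pop} outside [0, 1]: {s}")
    if not (0 < config.abc_tolerance <= 1):
        diags.append(f"abc_tolerance outside (0, 1]: {config.abc_tolerance}")
    if config.vcf is not None and config.population_table:
        try:
            from .vcfio import read_vcf

            samples = read_vcf(config.vcf).sample_ids
            missing = set(config.population_table) - set(samples)
            if missing:
                diags.append(f"population table samples absent from VCF: {sorted(missing)}")
        except Exception as exc:
            diags.append(f"VCF unreadable: {exc}")
    return diags


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; returns the report dict
    (also written to <out_dir>/report.json)."""
    diags = validate_config(config)
    if diags:
        raise ValueError("configuration invalid: " + "; ".join(diags))
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    gm = _load_or_simulate(config)
    stage = dict.fromkeys(ALL_STAGES, True) | config.stages

    if stage.get("filter"):
        gm_f, casc = filters.filter_cascade(gm)
        casc.to_csv(os.path.join(config.out_dir, "filter_cascade.tsv"), sep="\t", index=False)
        report["stages"]["filter"] = {
            "input_sites": int(gm.n_sites), "surviving": int(gm_f.n_sites)
        }
        gm = gm_f

    if stage.get("clonal"):
        dist = clonal.pairwise_genotype_distances(gm)
        part = clonal.clonal_families(dist)
        reps = clonal.select_representatives(part, gm)
        per_sample, med_h = clonal.individual_heterozygosity(gm)
        fam_df = pd.DataFrame(
            [(fi, s, reps[fi]) for fi, fam in enumerate(part.families) for s in fam],
            columns=["family", "sample", "representative"],
        )
        fam_df.to_csv(os.path.join(config.out_dir, "clonal_families.tsv"), sep="\t", index=False)
        report["stages"]["clonal"] = {
            "n_families": len(part.families),
            "median_heterozygosity": {k: float(v) for k, v in med_h.items()},
        }

    pops = sorted({p for p in gm.populations.values() if p})
    if stage.get("diversity"):
        rows = []
        for pop in pops:
            idx = gm.sample_index(gm.samples_in(pop))
            pi = diversity.region_pi(gm, callable_length=config.L, sample_idx=idx)
            curve = diversity.ld_decay(gm, max_dist=config.ld_max_dist, sample_idx=idx)
            rows.append((pop, pi, curve.decay_distance_at(0.2)))
        div = pd.DataFrame(rows, columns=["population", "pi", "ld_decay_bp"])
        div.to_csv(os.path.join(config.out_dir, "diversity.tsv"), sep="\t", index=False)
        windows = diversity.sliding_windows(gm, config.window_size, config.window_step, "pi")
        windows.to_csv(os.path.join(config.out_dir, "pi_windows.tsv"), sep="\t", index=False)
        report["stages"]["diversity"] = {
            r["population"]: {"pi": float(r["pi"]), "ld_decay_bp": float(r["ld_decay_bp"])}
            for _, r in div.iterrows()
        }

    if stage.get("sweep"):
        clr = sweep.clr_scan(gm)
        mu = sweep.mu_scan(gm)
        clr.to_csv(os.path.join(config.out_dir, "sweep_clr.tsv"), sep="\t", index=False)
        mu.to_csv(os.path.join(config.out_dir, "sweep_mu.tsv"), sep="\t", index=False)
        report["stages"]["sweep"] = {
            "clr_positions": len(clr), "mu_windows": len(mu),
            "clr_top1pct": len(sweep.top_fraction(clr, 0.01)) if len(clr) else 0,
        }

    if stage.get("branch") and all(p in pops for p in ("america", "asia", "europe")):
        res = threepop_scan(gm, ("america", "asia", "europe"))
        for br, pop in (("a", "asia"), ("b", "europe")):
            res[br].to_csv(
                os.path.join(config.out_dir, f"branch_clr_{pop}.tsv"), sep="\t", index=False
            )
        top_b = sweep.top_fraction(res["b"].dropna(subset=["value"]), 0.01)
        val = validate_candidates(top_b.head(3), gm, pops)
        val.to_csv(os.path.join(config.out_dir, "branch_validation.tsv"), sep="\t", index=False)
        report["stages"]["branch"] = {
            "windows_per_branch": int(len(res["a"])),
            "omega_a": res["params"].omega_a,
            "omega_b": res["params"].omega_b,
        }

    if stage.get("methylome"):
        reports = _load_methylomes(config)
        wml_rows = []
        for sid, rec in reports.items():
            e = nonconversion_rate(rec)
            called = call_methylated(rec, e)
            for ctx in ("CpG", "CHG", "CHH"):
                wml_rows.append(
                    (sid, ctx, e, weighted_ml(called, context=ctx).wml,
                     mc_proportion(called, ctx))
                )
        wml = pd.DataFrame(
            wml_rows, columns=["sample", "context", "nonconversion", "wml", "mc_proportion"]
        )
        wml.to_csv(os.path.join(config.out_dir, "methylation_wml.tsv"), sep="\t", index=False)
        report["stages"]["methylome"] = {
            ctx: float(wml[wml["context"] == ctx]["wml"].mean()) for ctx in ("CpG", "CHG", "CHH")
        }

    if stage.get("abc"):
        rng = np.random.default_rng(config.seed)
        priors = demography.PriorSpec()
        ref = demography.build_reference_table(
            list(demography.SCENARIOS), priors, config.abc_sims,
            seed=int(rng.integers(2**31 - 1)), n_per_pop=4, L=60_000,
        )
        obs = demography.summarize(gm, config.L)
        res = demography.abc_reject(obs, ref, config.abc_tolerance)
        report["stages"]["abc"] = {
            "model_posterior": res.model_posterior,
            "winning_scenario": res.winning_scenario,
        }

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _load_or_simulate(config: PipelineConfig) -> GenotypeMatrix:
    if config.vcf is not None:
        from .vcfio import read_vcf

        return read_vcf(config.vcf, populations=config.population_table)
    model = DemographicModel()
    if config.sigma_priors:
        model = model.with_params(sexuality={**model.sexuality, **config.sigma_priors})
    gm, _ = simulate_population_set(model, config.n_per_pop, config.L, seed=config.seed)
    return gm


def _load_methylomes(config: PipelineConfig) -> dict:
    if config.cytosine_reports:
        from .fixtures import read_cytosine_report

        return {sid: read_cytosine_report(p) for sid, p in config.cytosine_reports.items()}
    fx = generate_methylome_fixture(n_samples=2, seed=config.seed)
    return fx.reports
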