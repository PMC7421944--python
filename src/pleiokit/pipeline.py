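"""Configuration-driven end-to-end pipeline.

A YAML config names the stages to run and their parameters; stages
execute in dependency order (simulate -> gwas -> clump -> condfdr/conjfdr
-> ldsc/greml -> clinical) and every run writes a provenance record
(config hash, seed, package version) next to its outputs.  Reruns with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clinical import clinical_matrix
from .clumping import ClumpParams, clump_independent, define_loci
from .containers import ValidationError
from .grm import Greml, compute_grm
from .gwas import run_gwas
from .io import write_loci_bed, write_plink, write_sumstats
from .ldsc import LdscH2, LdscRg, ld_scores
from .overlap import (MHC, REGION_8P23, conj_fdr, exclude_regions,
                      genomic_inflation_correct, harmonize_pair, shared_loci)
from .simulate import (SimulationConfig, simulate_clinical_cohort,
                       simulate_phenotype, simulate_ld_genotypes,
                       simulate_sumstats_pair)

logger = logging.getLogger(__name__)

_STAGE_ORDER = ["simulate", "gwas", "clump", "conjfdr", "ldsc", "greml",
                "clinical"]


class ConfigSchemaError(ValidationError):
    """Config violates the schema; the message points at the offending key."""


def _require(cfg: dict, key: str, ctx: str):
    if key not in cfg:
        raise ConfigSchemaError(f"missing key {ctx}.{key}")
    return cfg[key]


def pipeline_run(config_path, out_dir=None) -> Path:
    """Run the stages requested in a YAML config; returns the artifact dir."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict):
        raise ConfigSchemaError("config root must be a mapping")
    seed = int(_require(cfg, "seed", "<root>"))
    stages = _require(cfg, "stages", "<root>")
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigSchemaError(f"unknown stage(s) {sorted(unknown)} "
                                "in stages")
    out = Path(out_dir or cfg.get("out_dir", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimulationConfig(seed=seed, **cfg.get("simulation", {}))
    state: dict = {}
    for stage in _STAGE_ORDER:
        if stage not in stages:
            continue
        logger.info("pipeline stage: %s", stage)
        _STAGE_FNS[stage](cfg, sim_cfg, state, out, seed)

    provenance = {
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "seed": seed,
        "version": __version__,
        "stages": [s for s in _STAGE_ORDER if s in stages],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out


# -- stage implementations ---------------------------------------------

def _stage_simulate(cfg, sim_cfg, state, out, seed):
    panel = simulate_ld_genotypes(sim_cfg, cfg.get("n_ref"))
    ss1, ss2, truth = simulate_sumstats_pair(sim_cfg, panel)
    state.update(panel=panel, ss1=ss1, ss2=ss2, truth=truth)
    write_plink(panel, out / "panel")
    write_sumstats(ss1, out / "trait1.sumstats.tsv")
    write_sumstats(ss2, out / "trait2.sumstats.tsv")


def _stage_gwas(cfg, sim_cfg, state, out, seed):
    panel = state["panel"]
    h2 = cfg.get("gwas", {}).get("h2", sim_cfg.h2_a)
    n_causal = cfg.get("gwas", {}).get("n_causal",
                                       max(1, panel.n_variants // 100))
    y, truth = simulate_phenotype(panel, h2, n_causal, seed=seed + 1)
    res = run_gwas(panel, y)
    state.update(gwas=res, phenotype=y, pheno_truth=truth)
    write_sumstats(res.sumstats, out / "gwas.sumstats.tsv")


def _stage_clump(cfg, sim_cfg, state, out, seed):
    ss = state.get("gwas").sumstats if "gwas" in state else state["ss1"]
    params = ClumpParams(**cfg.get("clump", {}))
    indep = clump_independent(ss, state["panel"], params)
    loci = define_loci(indep, ss, state["panel"], params)
    state["loci"] = loci
    write_loci_bed(loci, out / "loci.bed")


def _stage_conjfdr(cfg, sim_cfg, state, out, seed):
    sub = cfg.get("conjfdr", {})
    ss1, lam1 = genomic_inflation_correct(state["ss1"])
    ss2, lam2 = genomic_inflation_correct(state["ss2"])
    pair = harmonize_pair(ss1, ss2, panel=state["panel"])
    pair, n_excluded = exclude_regions(pair, [MHC, REGION_8P23])
    values = conj_fdr(pair, n_prune=sub.get("n_prune", 20), seed=seed)
    report = shared_loci(pair, values, state["panel"],
                         threshold=sub.get("threshold", 0.05))
    state.update(pair=pair, conjfdr=values, shared=report)
    table = pair.table.assign(conjfdr=values)
    table.to_csv(out / "conjfdr.tsv", sep="\t", index=False)
    report.table.to_csv(out / "shared_loci.tsv", sep="\t", index=False)


def _stage_ldsc(cfg, sim_cfg, state, out, seed):
    ld = ld_scores(state["panel"])
    h2 = LdscH2(state["ss1"], ld).fit()
    rg = LdscRg(state["ss1"], state["ss2"], ld).fit()
    state.update(ldsc_h2=h2, ldsc_rg=rg)
    (out / "ldsc.txt").write_text(h2.summary() + "\n" + rg.summary() + "\n")


def _stage_greml(cfg, sim_cfg, state, out, seed):
    panel = state["panel"]
    if "phenotype" not in state:
        h2 = cfg.get("greml", {}).get("h2", sim_cfg.h2_a)
        y, _ = simulate_phenotype(panel, h2,
                                  max(1, panel.n_variants // 100),
                                  seed=seed + 1)
        state["phenotype"] = y
    grm = compute_grm(panel)
    res = Greml(state["phenotype"], grm).fit()
    state["greml"] = res
    (out / "greml.txt").write_text(res.summary() + "\n")


def _stage_clinical(cfg, sim_cfg, state, out, seed):
    sub = cfg.get("clinical", {})
    effects = sub.get("effects", {})
    cohort = simulate_clinical_cohort(effects,
                                      n_cases=sub.get("n_cases", 200),
                                      n_controls=sub.get("n_controls", 400),
                                      seed=seed + 2)
    res = clinical_matrix(cohort, q_level=sub.get("q", 0.05))
    state["clinical"] = res
    res.table.to_csv(out / "clinical_matrix.tsv", sep="\t", index=False)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "gwas": _stage_gwas,
    "clump": _stage_clump,
    "conjfdr": _stage_conjfdr,
    "ldsc": _stage_ldsc,
    "greml": _stage_greml,
    "clinical": _stage_clinical,
}
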