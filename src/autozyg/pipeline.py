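"""Run configuration, stage orchestration, and reproducibility manifests.

A run is described by a YAML config validated against a typed schema.  All
stochastic stages draw from streams spawned off a single root seed, so a
re-run with an identical config and inputs reproduces identical output
checksums for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import addsim as _addsim
from . import assoc as _assoc
from . import consang as _consang
from . import io as _io
from . import par as _par
from . import roh as _roh
from . import sibling as _sibling
from . import synthdata as _synth
from .exceptions import ConfigError

log = logging.getLogger("autozyg")

__all__ = ["RunConfig", "RunManifest", "load_config", "run_pipeline"]

_STAGE_ORDER = ["simulate", "roh", "classify", "assoc", "sibling", "par", "addsim"]


class SynthBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_founders: int = 60
    sites_per_chrom: int = 1500
    n_chroms: int = 8
    chrom_length_bp: int = 120_000_000
    maf: list = Field(default_factory=lambda: ["uniform", 0.05, 0.5])
    union_mix: dict[str, int] = Field(
        default_factory=lambda: {"first_cousin_1g": 100, "unrelated": 100}
    )


class RohBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    maf_min: float = 0.05
    hwe_p_min: float | None = None
    denominator_bp: int | None = None  # default: simulated genome length


class ClassifyBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    classes: list[str] = Field(
        default_factory=lambda: ["first_cousin_1g", "unrelated"]
    )
    n_per_class: int = 100
    froh_max: float = 0.18


class PhenoModelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["binary", "quantitative"] = "binary"
    intercept: float = -2.0
    or_at_0625: float | None = 1.39
    froh_coefficient: float | None = None
    residual_sd: float = 1.0


class AssocBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    phenotype_file: str | None = None
    model: PhenoModelBlock = Field(default_factory=PhenoModelBlock)
    family: Literal["binomial", "gaussian"] = "binomial"


class SiblingBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    or_at_0625: float = 1.39
    prevalence: float = 0.1
    n_pairs: int = 1000
    n_sims: int = 200
    alpha: float = 0.05 / 7


class ParBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    population: str = "population"
    p1: float = 0.28
    p2: float = 0.12
    or_at_0625: float = 1.39
    or_ci95: list[float] = Field(default_factory=lambda: [1.17, 1.63])
    pd_grid: list[float] = Field(default_factory=lambda: [0.05, 0.15])


class AddsimBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_loci: int = 1000
    n_individuals: int = 6000
    n_sims: int = 100
    d_grid: list[float] = Field(
        default_factory=lambda: [round(x, 1) for x in np.arange(0.5, 1.51, 0.1)]
    )
    alphas: list[float] = Field(default_factory=lambda: [0.05, 0.05 / 61])


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "autozyg_out"
    cohort: str = "synthetic"
    stages: list[str] = Field(default_factory=lambda: ["simulate", "roh"])
    synthdata: SynthBlock = Field(default_factory=SynthBlock)
    roh: RohBlock = Field(default_factory=RohBlock)
    classify: ClassifyBlock = Field(default_factory=ClassifyBlock)
    assoc: AssocBlock = Field(default_factory=AssocBlock)
    sibling: SiblingBlock = Field(default_factory=SiblingBlock)
    par: ParBlock = Field(default_factory=ParBlock)
    addsim: AddsimBlock = Field(default_factory=AddsimBlock)


class RunManifest(BaseModel):
    config_hash: str
    package_version: str
    seed: int
    outputs: dict[str, str] = Field(default_factory=dict)  # path -> sha256
    wall_clock_s: float = 0.0


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        locs = "; ".join(
            "/" + "/".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid run config: {locs}") from None
    _validate_paths(cfg)
    return cfg


def _validate_paths(cfg: RunConfig) -> None:
    if cfg.assoc.phenotype_file and not Path(cfg.assoc.phenotype_file).exists():
        raise ConfigError(f"missing input file: {cfg.assoc.phenotype_file}")
    unknown = set(cfg.stages) - set(_STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")


def _hash_config(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order, writing stage
    outputs under ``outdir`` and a JSON manifest with output checksums."""
    from importlib.metadata import version

    t0 = time.time()
    _validate_paths(cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            _STAGE_ORDER, np.random.SeedSequence(cfg.seed).spawn(len(_STAGE_ORDER))
        )
    }
    stages = [s for s in _STAGE_ORDER if s in cfg.stages]
    outputs: dict[str, str] = {}
    state: dict = {}
    for stage in stages:
        log.info("stage %s (seed %d)", stage, seeds[stage])
        _RUNNERS[stage](cfg, seeds[stage], outdir, state, outputs)

    try:
        pkg_version = version("autozyg")
    except Exception:
        pkg_version = "unknown"
    manifest = RunManifest(
        config_hash=_hash_config(cfg),
        package_version=pkg_version,
        seed=cfg.seed,
        outputs=outputs,
        wall_clock_s=time.time() - t0,
    )
    (outdir / "manifest.json").write_text(manifest.model_dump_json(indent=2))
    return manifest


def _register(path: Path, outputs: dict[str, str]) -> None:
    outputs[path.name] = _io.sha256_file(path)


def _stage_simulate(cfg, seed, outdir, state, outputs):
    sb = cfg.synthdata
    panel = _synth.generate_founders(
        sb.n_founders, sb.sites_per_chrom, sb.n_chroms,
        maf_sampler=tuple(sb.maf) if isinstance(sb.maf, list) else sb.maf,
        chrom_length_bp=sb.chrom_length_bp, seed=seed,
    )
    rng = np.random.default_rng(seed)
    genos, truths = [], []
    for label, n in sb.union_mix.items():
        g, t = _synth.simulate_union_offspring(
            panel, label, n, seed=int(rng.integers(2**31))
        )
        genos.append(g)
        truths.append(t)
    G = np.vstack(genos)
    truth = pd.concat(truths, ignore_index=True)
    state.update(panel=panel, genotypes=G, truth=truth)
    gpath, tpath = outdir / "genotypes.tsv", outdir / "truth.tsv"
    _io.write_genotypes_tsv(gpath, G, panel.sites, truth["sample_id"].tolist())
    truth.to_csv(tpath, sep="\t", index=False)
    _register(gpath, outputs)
    _register(tpath, outputs)


def _stage_roh(cfg, seed, outdir, state, outputs):
    if "panel" not in state:
        raise ConfigError("roh stage requires the simulate stage")
    panel, G = state["panel"], state["genotypes"]
    ids = state["truth"]["sample_id"].tolist()
    Gq, sites_q, _ = _roh.site_qc(
        G, panel.sites, maf_min=cfg.roh.maf_min, hwe_p_min=cfg.roh.hwe_p_min
    )
    segs = _roh.call_roh(Gq, sites_q, panel.gmap, sample_ids=ids)
    denom = cfg.roh.denominator_bp or panel.gmap.total_bp
    froh = _roh.froh_per_sample(segs, ids, denom)
    state.update(segments=segs, froh=froh)
    spath, fpath = outdir / "segments.tsv", outdir / "froh.tsv"
    _io.write_segments_tsv(spath, segs)
    froh.rename_axis("sample_id").reset_index().to_csv(fpath, sep="\t", index=False)
    _register(spath, outputs)
    _register(fpath, outputs)


def _stage_classify(cfg, seed, outdir, state, outputs):
    if "segments" not in state:
        raise ConfigError("classify stage requires the roh stage")
    panel = state["panel"]
    model = _consang.train_pr_classifier(
        panel, cfg.classify.classes, n_per_class=cfg.classify.n_per_class, seed=seed
    )
    ids = state["truth"]["sample_id"].tolist()
    X = _consang.summarize_samples(state["segments"], ids)
    pred = _consang.classify_pr(model.classifier, X.to_numpy())
    pred.insert(0, "sample_id", ids)
    froh = state["froh"].reindex(ids).to_numpy()
    pred["highly_consanguineous"] = _consang.select_highly_consanguineous(
        pred["label"].to_numpy(), froh, cfg.classify.froh_max
    )
    state["predictions"] = pred
    ppath = outdir / "pr_predictions.tsv"
    mpath = outdir / "pr_classifier.json"
    pred.to_csv(ppath, sep="\t", index=False)
    mpath.write_text(model.classifier.to_json())
    _register(ppath, outputs)
    _register(mpath, outputs)


def _stage_assoc(cfg, seed, outdir, state, outputs):
    if "froh" not in state:
        raise ConfigError("assoc stage requires the roh stage")
    froh = state["froh"].to_numpy()
    if cfg.assoc.phenotype_file:
        pheno = _io.read_phenotypes_tsv(cfg.assoc.phenotype_file)
        y = pheno.set_index("sample_id").reindex(state["froh"].index)[
            "phenotype"
        ].to_numpy()
    else:
        mb = cfg.assoc.model
        coef = (
            mb.froh_coefficient
            if mb.froh_coefficient is not None
            else float(np.log(mb.or_at_0625) / 0.0625)
        )
        model = _synth.PhenotypeModel(
            kind=mb.kind, intercept=mb.intercept, froh_coefficient=coef,
            residual_sd=mb.residual_sd,
        )
        y = _synth.simulate_phenotypes(froh, None, model, seed=seed)
    res = _assoc.fit_glm_association(
        y, froh, family=cfg.assoc.family, cohort=cfg.cohort
    )
    out = pd.DataFrame(
        [
            {
                "phenotype": res.phenotype,
                "cohort": res.cohort,
                "beta": res.beta,
                "se": res.se,
                "p": res.p,
                "or_at_0625": res.or_at_0625,
                "or_ci_low": res.or_ci95[0],
                "or_ci_high": res.or_ci95[1],
                "n": res.n,
                "n_cases": res.n_cases,
            }
        ]
    )
    apath = outdir / "association.tsv"
    out.to_csv(apath, sep="\t", index=False)
    _register(apath, outputs)


def _stage_sibling(cfg, seed, outdir, state, outputs):
    sb = cfg.sibling
    est = _sibling.simulate_replication_power_binary(
        _sibling.PowerConfig(
            or_at_0625=sb.or_at_0625, prevalence=sb.prevalence,
            n_pairs=sb.n_pairs, n_sims=sb.n_sims, alpha=sb.alpha,
        ),
        seed=seed,
    )
    path = outdir / "sibling_power.json"
    path.write_text(
        json.dumps(
            {
                "power": est.power,
                "mc_se": est.mc_se,
                "n_sims": est.n_sims,
                "config": sb.model_dump(),
                "seed": seed,
            },
            indent=2,
        )
    )
    _register(path, outputs)


def _stage_par(cfg, seed, outdir, state, outputs):
    pb = cfg.par
    prev = _par.ConsanguinityPrevalence(pb.population, pb.p1, pb.p2)
    results = []
    for pd_ in pb.pd_grid:
        risk = _par.RiskEstimate.from_or_at_0625(
            pb.or_at_0625, tuple(pb.or_ci95), pd_
        )
        r = _par.par_from_prevalence(prev, risk)
        results.append(
            {
                "population": r.population,
                "pd": r.pd,
                "par_percent": r.par_percent,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "par_first_cousin": r.par_first_cousin,
                "par_second_cousin": r.par_second_cousin,
            }
        )
    path = outdir / "par.json"
    path.write_text(json.dumps(results, indent=2))
    _register(path, outputs)


def _stage_addsim(cfg, seed, outdir, state, outputs):
    ab = cfg.addsim
    arch = _addsim.build_additive_architecture(ab.n_loci, seed=seed)
    table = _addsim.froh_power_additive(
        _addsim.FrohPowerConfig(
            d_grid=tuple(ab.d_grid), alphas=tuple(ab.alphas),
            n_sims=ab.n_sims, n_individuals=ab.n_individuals,
        ),
        arch,
        seed=seed,
    )
    path = outdir / "addsim_power.tsv"
    table.to_csv(path, sep="\t", index=False)
    _register(path, outputs)


_RUNNERS = {
    "simulate": _stage_simulate,
    "roh": _stage_roh,
    "classify": _stage_classify,
    "assoc": _stage_assoc,
    "sibling": _stage_sibling,
    "par": _stage_par,
    "addsim": _stage_addsim,
}
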