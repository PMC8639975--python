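"""Pipeline orchestration: stages wired in dependency order.

Every stage reads its inputs from disk artifacts (or the simulated
bundle), writes one TSV/JSON artifact plus a ``.meta.json`` provenance
sidecar (package version, stage seed, parameters, input checksums), and
can be rerun in isolation. A single global seed fans out to per-stage
seeds through a fixed hash so partial reruns stay deterministic; no
artifact embeds a timestamp, so identical configurations produce
byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, cohortqc, exprassoc, genemap, setstat, sigsearch, synthio
from . import io as sio

log = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "simulate": set(synthio.SimulationConfig.__dataclass_fields__) - {"seed"},
    "inputs": {"genotypes_vcf", "phenotypes", "genes_bed", "gene_sets", "expression", "eqtl"},
    "qc": {"maf_min", "hwe_min", "miss_max"},
    "gwas": {"trait", "normalization"},
    "simplem": {"variance_explained_C", "block_size", "alpha", "suggestive"},
    "prune": {"r2_max", "window"},
    "map": {"window_bp"},
    "gsea": {"weight", "n_perm", "min_size", "max_size"},
    "search": {"criterion", "candidates", "n_candidates"},
}

_DOMAIN = {
    ("qc", "maf_min"): (0.0, 0.5), ("qc", "hwe_min"): (0.0, 1.0),
    ("qc", "miss_max"): (0.0, 1.0),
    ("simplem", "variance_explained_C"): (0.0, 1.0),
    ("prune", "r2_max"): (0.0, 1.0),
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: dict | None = field(default_factory=dict)  # None => read inputs
    inputs: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=lambda: {"trait": "si_delta"})
    simplem: dict = field(default_factory=dict)
    prune: dict = field(default_factory=dict)
    map: dict = field(default_factory=dict)
    gsea: dict = field(default_factory=dict)
    search: dict = field(default_factory=dict)

    def validate(self) -> None:
        for section, allowed in _SCHEMA.items():
            block = getattr(self, section)
            if block is None:
                continue
            unknown = set(block) - allowed
            if unknown:
                raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
        for (section, key), (lo, hi) in _DOMAIN.items():
            block = getattr(self, section) or {}
            if key in block and not (lo <= block[key] <= hi):
                raise ConfigError(f"{section}.{key}={block[key]} outside [{lo}, {hi}]")
        trait = (self.gwas or {}).get("trait", "si_delta")
        if trait not in ("si_baseline", "si_delta"):
            raise ConfigError(f"gwas.trait must be si_baseline or si_delta, got {trait!r}")
        if self.simulate is None:
            need = {"genotypes_vcf", "phenotypes", "genes_bed", "gene_sets", "expression", "eqtl"}
            missing = need - set(self.inputs)
            if missing:
                raise ConfigError(f"simulate disabled but inputs missing: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ConfigError(f"input file for {key!r} not found: {path}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(_SCHEMA) | {"seed"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            **{s: getattr(self, s) for s in _SCHEMA},
        }


def demo_config(seed: int = 0) -> PipelineConfig:
    """A small self-contained configuration exercising every stage."""
    return PipelineConfig(
        seed=seed,
        simulate={
            "n_families": 40, "offspring_per_family": (2, 3),
            "n_snps": 150, "n_ld_blocks": 15, "n_genes": 60,
            "signature_genes": ("G0010", "G0025", "G0040"),
            "n_coupled_genes": 10, "n_gene_sets": 20,
            "causal_snps_delta": [(12, 0.35), (70, 0.35)],
            "eqtl_pairs": [("rs000005", "G0050", 0.4)],
        },
        gsea={"n_perm": 300},
        search={"n_candidates": 50},
    )


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_meta(artifact: Path, stage: str, seed: int, params: dict, inputs: list[Path]) -> None:
    meta = {
        "stage": stage,
        "sensigen_version": __version__,
        "seed": seed,
        "parameters": params,
        "input_checksums": {p.name: _checksum(p) for p in sorted(inputs) if p.exists()},
    }
    artifact.with_suffix(artifact.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n"
    )


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run all stages in dependency order; returns artifact paths."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception:
                (outdir / f"{name}.failed").write_text("stage failed\n")
                log.error("stage %s failed", name)
                raise
            timings[name] = time.perf_counter() - t0
            log.info("stage %-8s %.2fs", name, timings[name])
        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if config.simulate is not None:
            sim = synthio.SimulationConfig(
                **config.simulate, seed=stage_seed(config.seed, "simulate")
            )
            bundle = synthio.simulate_cohort(sim)
            paths = synthio.write_cohort(bundle, outdir / "cohort")
            artifacts.update({f"cohort_{k}": v for k, v in paths.items()})
            _write_meta(paths["pheno"], "simulate", sim.seed,
                        {k: v for k, v in config.simulate.items()}, [])
        else:
            bundle = synthio.CohortBundle(
                cohort=sio.read_phenotypes(config.inputs["phenotypes"]),
                genotypes=sio.read_vcf(config.inputs["genotypes_vcf"]),
                expression=sio.read_expression(config.inputs["expression"]),
                genes=sio.read_bed(config.inputs["genes_bed"]),
                gene_sets=sio.read_gmt(config.inputs["gene_sets"]),
                eqtl=sio.read_eqtl(config.inputs["eqtl"]),
            )
        state["bundle"] = bundle

    @stage("qc")
    def _qc():
        b = state["bundle"]
        filtered, report = cohortqc.qc_filter(b.genotypes, **config.qc)
        path = outdir / "qc_report.tsv"
        report.to_tsv(path)
        artifacts["qc_report"] = path
        state["geno"] = filtered
        _write_meta(path, "qc", config.seed, config.qc, [])

    @stage("adjust")
    def _adjust():
        b = state["bundle"]
        trait = config.gwas.get("trait", "si_delta")
        method = config.gwas.get("normalization", "zscore")
        adj = cohortqc.adjust_trait(b.cohort, trait, method=method)
        path = outdir / "adjusted_trait.tsv"
        with open(path, "w") as fh:
            for line in yaml.safe_dump(adj.recipe, sort_keys=True).splitlines():
                fh.write(f"# {line}\n")
            adj.values.rename("adjusted").rename_axis("subject_id").to_csv(fh, sep="\t")
        artifacts["adjusted_trait"] = path
        state["adjusted"] = adj
        _write_meta(path, "adjust", config.seed, {"trait": trait, "method": method}, [])

    @stage("gwas")
    def _gwas():
        b = state["bundle"]
        table = assoc.lmm_scan(state["adjusted"], state["geno"], b.cohort["family_id"])
        path = outdir / "gwas.tsv"
        table.to_csv(path, sep="\t", index=False)
        artifacts["gwas"] = path
        state["assoc"] = table
        _write_meta(path, "gwas", config.seed, config.gwas,
                    [artifacts["qc_report"], artifacts["adjusted_trait"]])

    @stage("simplem")
    def _simplem():
        pars = dict(config.simplem)
        alpha = pars.pop("alpha", 0.05)
        suggestive = pars.pop("suggestive", 1e-5)
        m_eff = assoc.simplem_meff(state["geno"], **pars)
        res = assoc.thresholds(m_eff, alpha=alpha, suggestive=suggestive,
                               m_total=state["geno"].n_snps)
        path = outdir / "simplem.json"
        path.write_text(json.dumps({
            "m_total": res.m_total, "m_eff": res.m_eff,
            "threshold_genomewide": res.threshold_genomewide,
            "threshold_suggestive": res.threshold_suggestive,
        }, indent=2, sort_keys=True) + "\n")
        artifacts["simplem"] = path
        state["thresholds"] = res
        _write_meta(path, "simplem", config.seed, config.simplem, [artifacts["gwas"]])

    @stage("map")
    def _map():
        b = state["bundle"]
        window = config.map.get("window_bp", 20_000)
        pos = genemap.map_positional(state["geno"].snp_meta, b.genes, window_bp=window)
        eq = genemap.map_eqtl(state["geno"].snp_meta["snp_id"], b.eqtl)
        snp_map = genemap.combine_maps(pos, eq)
        path = outdir / "snp_gene_map.tsv"
        snp_map.to_csv(path, sep="\t", index=False)
        artifacts["snp_gene_map"] = path
        state["snp_map"] = snp_map
        _write_meta(path, "map", config.seed, {"window_bp": window}, [artifacts["gwas"]])

    @stage("prune")
    def _prune():
        kept = genemap.prune_by_ld(state["assoc"], state["geno"], **config.prune)
        path = outdir / "pruned_snps.txt"
        path.write_text("\n".join(kept) + "\n")
        artifacts["pruned_snps"] = path
        state["pruned"] = kept
        _write_meta(path, "prune", config.seed, config.prune, [artifacts["gwas"]])

    @stage("glossi")
    def _glossi():
        b = state["bundle"]
        table = setstat.run_setstat(state["assoc"], state["pruned"],
                                    state["snp_map"], b.gene_sets)
        path = outdir / "glossi.tsv"
        table.to_csv(path, sep="\t", index=False)
        artifacts["glossi"] = path
        _write_meta(path, "glossi", config.seed, {},
                    [artifacts["gwas"], artifacts["pruned_snps"], artifacts["snp_gene_map"]])

    @stage("rank")
    def _rank():
        b = state["bundle"]
        trait = config.gwas.get("trait", "si_delta")
        ranked = exprassoc.rank_genes(b.expression, b.cohort, trait)
        path = outdir / "ranked_genes.tsv"
        ranked.to_csv(path, sep="\t", index=False)
        artifacts["ranked_genes"] = path
        state["ranked"] = ranked
        _write_meta(path, "rank", config.seed, {"trait": trait}, [])

    @stage("gsea")
    def _gsea():
        b = state["bundle"]
        pars = dict(config.gsea)
        res = exprassoc.gsea_preranked(
            state["ranked"], b.gene_sets,
            seed=stage_seed(config.seed, "gsea"), **pars,
        )
        path = outdir / "gsea.tsv"
        res.to_csv(path, sep="\t", index=False)
        artifacts["gsea"] = path
        _write_meta(path, "gsea", stage_seed(config.seed, "gsea"), pars,
                    [artifacts["ranked_genes"]])

    @stage("search")
    def _search():
        b = state["bundle"]
        pars = dict(config.search)
        criterion = pars.get("criterion", "adjusted_r2")
        cands = pars.get("candidates")
        if cands is None:
            n_cand = min(pars.get("n_candidates", 50), len(b.expression))
            cands = list(b.expression.index)[:n_cand]
        elif isinstance(cands, (str, Path)):
            cands = [line.strip() for line in Path(cands).read_text().splitlines() if line.strip()]
        res = sigsearch.search_all_triads(b.expression, b.cohort, cands, criterion=criterion)
        path = outdir / "search.tsv"
        res.table.head(1000).to_csv(path, sep="\t", index=False)
        top = res.top_model
        baseline = sigsearch.covariate_only_baseline(b.cohort)
        report = {
            "n_models_fitted": res.n_models_fitted,
            "criterion": res.criterion,
            "top_model": {
                "genes": list(top.genes),
                "coefficients": {k: float(v) for k, v in top.coefficients.items()},
                "r2": top.r2, "adjusted_r2": top.adjusted_r2,
                "f_statistic": top.f_statistic, "model_p": top.model_p, "n": top.n,
            },
            "diagnostics": res.diagnostics,
            "covariate_only": {k: baseline[k] for k in
                               ("r2", "adjusted_r2", "f_statistic", "model_p")},
        }
        ypath = outdir / "top_model.yaml"
        ypath.write_text(yaml.safe_dump(report, sort_keys=True))
        artifacts["search"] = path
        artifacts["top_model"] = ypath
        state["search"] = res
        _write_meta(path, "search", config.seed, {"criterion": criterion,
                    "n_candidates": len(cands)}, [])
        _write_meta(ypath, "search", config.seed, {"criterion": criterion,
                    "n_candidates": len(cands)}, [path])

    return {"artifacts": artifacts, "timings": timings, "state": state}
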