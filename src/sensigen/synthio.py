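"""Synthetic nuclear-family cohort generator.

Emulates the statistical structure of a family exercise-intervention study:
nuclear families (two parents plus offspring) genotyped at SNPs arranged in
haplotype blocks (so nearby SNPs are in linkage disequilibrium), a positive
baseline insulin-sensitivity index Si, and a training response dSi composed
of a shared family intercept, covariate effects, a negative coupling to
log baseline Si, optional per-SNP additive effects, a three-gene expression
signature with all pairwise interactions, and Gaussian noise.

The family intercept variance is set analytically so the marginal
intraclass correlation of dSi equals ``family_icc_delta``. Offspring
genotypes are produced by gene-dropping (one parental haplotype inherited
per block), which guarantees Mendelian consistency by construction.

Everything is driven by one integer seed: identical configurations produce
byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .io import MISSING, GenotypeMatrix

__all__ = ["SimulationConfig", "CohortBundle", "simulate_cohort", "write_cohort", "read_cohort"]

_SNP_SPACING_BP = 4_000
_GENE_LENGTH_BP = 6_000


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


def _default_covariate_effects() -> dict:
    # Units: trait change per unit covariate (age in years, vo2max in
    # mL/kg/min, log-BMI unitless, sex indicator female=1).
    return {
        "si_baseline": {"sex": -0.10, "age": -0.004, "log_bmi": -0.30, "vo2max_per_kg": 0.008},
        "si_delta": {"sex": -0.40, "age": -0.010, "log_bmi": -0.50, "vo2max_per_kg": 0.020},
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design
    (99 nuclear families, family ICC of the training response 0.29,
    negative baseline-to-response coupling, a 3-gene interaction signature
    sized so its in-sample fit at 47 subjects is around R^2 = 0.5)."""

    n_families: int = 99
    offspring_per_family: tuple[int, int] = (2, 4)  # inclusive range
    n_snps: int = 300
    n_ld_blocks: int = 30
    haplotype_pool_size: int = 8
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    causal_snps_baseline: list[tuple[int, float]] = field(default_factory=list)
    causal_snps_delta: list[tuple[int, float]] = field(default_factory=list)
    family_icc_delta: float = 0.29
    baseline_to_delta_slope: float = -0.5
    covariate_effect_sizes: dict = field(default_factory=_default_covariate_effects)
    n_genes: int = 120
    signature_genes: tuple[str, str, str] = ("G0010", "G0025", "G0040")
    signature_coefficients: tuple[float, ...] = (0.2, 0.2, 0.2, 0.7, 0.7, 0.7)
    noise_sd_expression: float = 1.0
    noise_sd_trait: float = 0.9
    delta_mean: float = 0.5
    n_coupled_genes: int = 15
    expression_coupling: float = 0.6
    trait_latent_sd: float = 0.5
    eqtl_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    n_gene_sets: int = 40
    set_size_range: tuple[int, int] = (8, 30)
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_families < 1 or self.n_snps < 1 or self.n_genes < 3:
            raise ConfigError("n_families, n_snps >= 1 and n_genes >= 3 required")
        if not (1 <= self.n_ld_blocks <= self.n_snps):
            raise ConfigError("n_ld_blocks must be in [1, n_snps]")
        if self.haplotype_pool_size < 2:
            raise ConfigError("haplotype_pool_size must be >= 2")
        lo, hi = self.offspring_per_family
        if not (1 <= lo <= hi):
            raise ConfigError("offspring_per_family range must satisfy 1 <= lo <= hi")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.family_icc_delta <= 0.95):
            raise ConfigError("family_icc_delta must be in [0, 0.95]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        for idx, _ in list(self.causal_snps_baseline) + list(self.causal_snps_delta):
            if not (0 <= idx < self.n_snps):
                raise ConfigError(f"causal SNP index {idx} out of range [0, {self.n_snps})")
        genes = set(self.gene_ids())
        if len(set(self.signature_genes)) != 3:
            raise ConfigError("signature_genes must be 3 distinct gene ids")
        if not set(self.signature_genes) <= genes:
            raise ConfigError("signature_genes must be a subset of the gene list")
        if len(self.signature_coefficients) != 6:
            raise ConfigError("signature_coefficients must be (a, b, c, d, e, f)")
        for snp, gene, _ in self.eqtl_pairs:
            if gene not in genes:
                raise ConfigError(f"eQTL gene {gene!r} not in gene list")
        if self.n_coupled_genes > self.n_genes - 3:
            raise ConfigError("n_coupled_genes leaves no room for signature genes")


@dataclass
class CohortBundle:
    """Everything one simulated study produces."""

    cohort: pd.DataFrame
    genotypes: GenotypeMatrix
    expression: pd.DataFrame  # genes x subjects
    genes: pd.DataFrame       # gene_id, chrom, start, end, strand (BED 0-based)
    gene_sets: dict[str, list[str]]
    eqtl: pd.DataFrame
    truth: dict | None = None  # latent quantities, never written to disk

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CohortBundle)
            and self.cohort.equals(other.cohort)
            and self.genotypes == other.genotypes
            and self.expression.equals(other.expression)
            and self.genes.equals(other.genes)
            and self.gene_sets == other.gene_sets
            and self.eqtl.equals(other.eqtl)
        )


# ---------------------------------------------------------------------------
# genotype simulation

def _simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator,
                        n_parent_pairs: int, offspring_counts: np.ndarray):
    """Blockwise haplotype-pool founders + gene-dropping to offspring."""
    block_sizes = np.full(cfg.n_ld_blocks, cfg.n_snps // cfg.n_ld_blocks)
    block_sizes[: cfg.n_snps % cfg.n_ld_blocks] += 1
    block_edges = np.concatenate([[0], np.cumsum(block_sizes)])

    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_snps)
    # pool haplotypes per block: (pool, block_snps) binary
    pools = [
        (rng.random((cfg.haplotype_pool_size, size)) < freqs[lo:hi]).astype(np.int8)
        for size, lo, hi in zip(block_sizes, block_edges[:-1], block_edges[1:])
    ]

    n_off_total = int(offspring_counts.sum())
    n_subjects = 2 * n_parent_pairs + n_off_total
    hapA = np.empty((n_subjects, cfg.n_snps), np.int8)
    hapB = np.empty((n_subjects, cfg.n_snps), np.int8)

    # subject layout: per family, father, mother, then offspring
    fam_starts = np.concatenate([[0], np.cumsum(offspring_counts + 2)])
    for b, pool in enumerate(pools):
        lo, hi = block_edges[b], block_edges[b + 1]
        pick = rng.integers(0, cfg.haplotype_pool_size, size=(n_parent_pairs, 4))
        inherit = [rng.integers(0, 2, size=(c, 2)) for c in offspring_counts]
        for f in range(n_parent_pairs):
            s = fam_starts[f]
            father = pick[f, :2]
            mother = pick[f, 2:]
            hapA[s, lo:hi], hapB[s, lo:hi] = pool[father[0]], pool[father[1]]
            hapA[s + 1, lo:hi], hapB[s + 1, lo:hi] = pool[mother[0]], pool[mother[1]]
            for o in range(offspring_counts[f]):
                hapA[s + 2 + o, lo:hi] = pool[father[inherit[f][o, 0]]]
                hapB[s + 2 + o, lo:hi] = pool[mother[inherit[f][o, 1]]]
    dosage = (hapA + hapB).astype(np.int8)
    return dosage, fam_starts


def _make_snp_meta(cfg: SimulationConfig) -> pd.DataFrame:
    pos = _SNP_SPACING_BP * (np.arange(cfg.n_snps) + 1)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:06d}" for i in range(cfg.n_snps)],
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )


def _make_gene_annotation(cfg: SimulationConfig) -> pd.DataFrame:
    span = _SNP_SPACING_BP * (cfg.n_snps + 1)
    starts = np.round(np.arange(cfg.n_genes) * span / cfg.n_genes).astype(int)
    return pd.DataFrame(
        {
            "gene_id": cfg.gene_ids(),
            "chrom": "1",
            "start": starts,
            "end": starts + _GENE_LENGTH_BP,
            "strand": np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-"),
        }
    )


def _genes_near_snps(genes: pd.DataFrame, snp_pos: np.ndarray, window: int = 20_000) -> list[str]:
    hits: list[str] = []
    for _, g in genes.iterrows():
        lo, hi = g.start + 1 - window, g.end + window
        if np.any((snp_pos >= lo) & (snp_pos <= hi)):
            hits.append(g.gene_id)
    return hits


# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    lo, hi = cfg.offspring_per_family
    offspring_counts = rng.integers(lo, hi + 1, size=cfg.n_families)
    dosage, fam_starts = _simulate_genotypes(cfg, rng, cfg.n_families, offspring_counts)
    n = dosage.shape[0]

    subject_id, family_id, role, sex = [], [], [], []
    for f in range(cfg.n_families):
        fam = f"F{f + 1:03d}"
        subject_id += [f"{fam}_P1", f"{fam}_P2"]
        family_id += [fam, fam]
        role += ["parent", "parent"]
        sex += ["M", "F"]
        for o in range(offspring_counts[f]):
            subject_id.append(f"{fam}_O{o + 1}")
            family_id.append(fam)
            role.append("offspring")
            sex.append("M" if rng.random() < 0.5 else "F")
    is_parent = np.array([r == "parent" for r in role])
    female = np.array([s == "F" for s in sex], dtype=float)

    age = np.where(
        is_parent,
        np.clip(rng.normal(53.0, 5.0, n), 35.0, 65.0),
        np.clip(rng.normal(25.0, 5.0, n), 17.0, 40.0),
    )
    bmi = np.exp(rng.normal(math.log(25.0), 0.12, n))
    vo2 = np.clip(rng.normal(33.0, 8.0, n), 12.0, None)

    cov = cfg.covariate_effect_sizes

    def cov_term(which: str) -> np.ndarray:
        e = cov.get(which, {})
        return (
            e.get("sex", 0.0) * female
            + e.get("age", 0.0) * age
            + e.get("log_bmi", 0.0) * np.log(bmi)
            + e.get("vo2max_per_kg", 0.0) * vo2
        )

    # baseline Si: lognormal (positivity), effects act on the log scale
    log_si = math.log(3.5) + cov_term("si_baseline") + rng.normal(0.0, 0.40, n)
    for idx, beta in cfg.causal_snps_baseline:
        log_si += beta * dosage[:, idx]
    si_baseline = np.exp(log_si)

    # expression: per-gene standardized log-scale values, then planted effects
    gene_ids = cfg.gene_ids()
    expr = rng.normal(0.0, cfg.noise_sd_expression, size=(cfg.n_genes, n))
    expr = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, ddof=1, keepdims=True)
    gindex = {g: i for i, g in enumerate(gene_ids)}
    snp_index = {f"rs{i + 1:06d}": i for i in range(cfg.n_snps)}
    for snp, gene, effect in cfg.eqtl_pairs:
        j = snp_index[snp] if isinstance(snp, str) else int(snp)
        expr[gindex[gene]] += effect * dosage[:, j]

    latent = rng.normal(0.0, 1.0, n)
    coupled = [g for g in gene_ids if g not in cfg.signature_genes][: cfg.n_coupled_genes]
    for g in coupled:
        expr[gindex[g]] += cfg.expression_coupling * latent

    a, b, c, d, e, f_ = cfg.signature_coefficients
    t1, t2, t3 = (expr[gindex[g]] for g in cfg.signature_genes)
    signature = a * t1 + b * t2 + c * t3 + d * t1 * t2 + e * t1 * t3 + f_ * t2 * t3

    rest = (
        cfg.delta_mean
        + cov_term("si_delta")
        + cfg.baseline_to_delta_slope * log_si
        + signature
        + cfg.trait_latent_sd * latent
        + rng.normal(0.0, cfg.noise_sd_trait, n)
    )
    for idx, beta in cfg.causal_snps_delta:
        rest += beta * dosage[:, idx]

    fam_codes = np.repeat(np.arange(cfg.n_families), offspring_counts + 2)
    fam_raw = rng.normal(0.0, 1.0, cfg.n_families)
    u = fam_raw[fam_codes]
    icc = cfg.family_icc_delta
    if icc > 0 and np.std(u, ddof=1) > 0:
        u = (u - u.mean()) / np.std(u, ddof=1)
        sigma_u = math.sqrt(icc / (1.0 - icc) * np.var(rest, ddof=1))
        u = sigma_u * u
    else:
        u = np.zeros(n)
        sigma_u = 0.0
    si_delta = u + rest

    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage = np.where(mask, np.int8(MISSING), dosage)

    cohort = pd.DataFrame(
        {
            "subject_id": subject_id,
            "family_id": family_id,
            "role": role,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "vo2max_per_kg": vo2,
            "si_baseline": si_baseline,
            "si_delta": si_delta,
        }
    )
    snp_meta = _make_snp_meta(cfg)
    genotypes = GenotypeMatrix(dosage=dosage, snp_meta=snp_meta, subjects=subject_id)
    genes = _make_gene_annotation(cfg)
    expression = pd.DataFrame(expr, index=gene_ids, columns=subject_id)

    gene_sets: dict[str, list[str]] = {}
    slo, shi = cfg.set_size_range
    for k in range(cfg.n_gene_sets):
        size = int(rng.integers(slo, shi + 1))
        members = sorted(rng.choice(gene_ids, size=min(size, cfg.n_genes), replace=False))
        gene_sets[f"SET_{k + 1:03d}"] = members
    if len(coupled) >= 2:
        gene_sets["COUPLED_MODULE"] = sorted(coupled)
    if cfg.causal_snps_delta:
        pos = snp_meta["pos"].to_numpy()[[i for i, _ in cfg.causal_snps_delta]]
        near = _genes_near_snps(genes, pos)
        if near:
            gene_sets["CAUSAL_DELTA_LOCI"] = sorted(near)

    eqtl = pd.DataFrame(
        [
            (s if isinstance(s, str) else f"rs{int(s) + 1:06d}", g, eff)
            for s, g, eff in cfg.eqtl_pairs
        ],
        columns=["snp_id", "gene_id", "effect"],
    )

    truth = {
        "family_effects": fam_raw * (sigma_u if icc > 0 else 0.0),
        "family_effect_subject": u,
        "rest": rest,
        "latent": latent,
        "signature": signature,
        "coupled_genes": coupled,
        "sigma_family": sigma_u,
        "offspring_counts": offspring_counts,
    }
    return CohortBundle(cohort, genotypes, expression, genes, gene_sets, eqtl, truth)


# ---------------------------------------------------------------------------
# on-disk layout

_FILES = {
    "vcf": "genotypes.vcf",
    "pheno": "phenotypes.tsv",
    "bed": "genes.bed",
    "gmt": "gene_sets.gmt",
    "expr": "expression.tsv",
    "eqtl": "eqtl.tsv",
}


def write_cohort(bundle: CohortBundle, directory) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FILES.items()}
    io.write_vcf(bundle.genotypes, paths["vcf"])
    io.write_phenotypes(bundle.cohort, paths["pheno"])
    io.write_bed(bundle.genes, paths["bed"])
    io.write_gmt(bundle.gene_sets, paths["gmt"])
    io.write_expression(bundle.expression, paths["expr"])
    io.write_eqtl(bundle.eqtl, paths["eqtl"])
    return paths


def read_cohort(directory) -> CohortBundle:
    directory = Path(directory)
    return CohortBundle(
        cohort=io.read_phenotypes(directory / _FILES["pheno"]),
        genotypes=io.read_vcf(directory / _FILES["vcf"]),
        expression=io.read_expression(directory / _FILES["expr"]),
        genes=io.read_bed(directory / _FILES["bed"]),
        gene_sets=io.read_gmt(directory / _FILES["gmt"]),
        eqtl=io.read_eqtl(directory / _FILES["eqtl"]),
    )


def triad_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Conditions of the expression-signature substudy: ~47 subjects whose
    training response is the displayed three-gene interaction equation plus
    covariates and noise (no family intercept or latent coupling), with the
    noise sized so the true model's in-sample R^2 is about 0.5."""
    base = SimulationConfig(
        n_families=20, offspring_per_family=(1, 2), n_snps=20, n_ld_blocks=4,
        n_genes=60, signature_genes=("G0010", "G0025", "G0040"),
        signature_coefficients=(0.15, 0.15, 0.15, 0.75, 0.75, 0.75),
        noise_sd_trait=1.6, family_icc_delta=0.0,
        trait_latent_sd=0.0, expression_coupling=0.0,
        seed=seed,
    )
    return replace(base, **overrides)


def small_config(**overrides) -> SimulationConfig:
    """A reduced configuration for fast tests and demos (same structure)."""
    base = SimulationConfig(
        n_families=40, offspring_per_family=(2, 3), n_snps=120, n_ld_blocks=12,
        n_genes=60, signature_genes=("G0010", "G0025", "G0040"),
        n_coupled_genes=10, n_gene_sets=20,
    )
    return replace(base, **overrides)
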