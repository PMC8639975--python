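# sensigen

Integrative genetics and transcriptomics of insulin-sensitivity
trainability, as a tested, fully synthetic-data-driven pipeline.

The insulin sensitivity index S<sub>i</sub> (mU/[L·min], from a
frequently-sampled IVGTT) improves with endurance exercise training, but
the response ΔS<sub>i</sub> = S<sub>i</sub><sup>post</sup> −
S<sub>i</sub><sup>baseline</sup> varies enormously between people and runs
in families. `sensigen` implements the analysis chain used to dissect that
heterogeneity in a nuclear-family intervention cohort:

1. **Genotype QC** — MAF ≥ 5%, Hardy–Weinberg exact test p ≥ 10⁻⁶,
   missingness ≤ 10%.
2. **Family GWAS** — per-SNP additive association of the covariate-adjusted
   trait under a random-intercept linear mixed model,
   `y = μ + β·g + u_family + ε`, `u ~ N(0, σ²_f)`, fitted by REML;
   multiple testing by **SimpleM**: the effective number of independent
   tests m_eff is the count of leading eigenvalues of the SNP correlation
   matrix reaching 99.5% of its trace, and the genome-wide threshold is
   α / m_eff.
3. **SNP→gene mapping** — positional (gene body ± 20 kb) and eQTL lookup;
   greedy LD pruning (r² > 0.8) keeping the smaller association p.
4. **Gene-set statistics on GWAS p-values (GLOSSI)** — Fisher combination
   −2Σln pᵢ ~ χ²₂ₖ over the pruned SNPs of each set, Bonferroni-adjusted.
5. **Transcriptome ranking + preranked GSEA** — genes ranked by the Wald t
   of `trait ~ expression + covariates` under the same family mixed model;
   weighted Kolmogorov–Smirnov enrichment score, gene-label permutation
   NES, Benjamini–Hochberg FDR.
6. **Three-gene interaction signature search** — every triple (θ₁, θ₂, θ₃)
   from a candidate interactor list is fitted by OLS to

   ΔS<sub>i</sub> = aθ₁ + bθ₂ + cθ₃ + dθ₁θ₂ + eθ₁θ₃ + fθ₂θ₃ + sex + VO₂max/kg + ε

   (C(50, 3) = 19,600 models for a 50-gene list), ranked by adjusted R²,
   with residual diagnostics and transfer of the winning model *form* to a
   replication cohort.

No external data are required: the `synthio` module simulates nuclear
families (Mendelian gene-dropping over haplotype-block LD), covariates,
baseline S<sub>i</sub>, a ΔS<sub>i</sub> with a tunable family intraclass
correlation and a planted three-gene interaction signature, expression,
gene sets and eQTL tables, and writes them as VCF / TSV / BED / GMT.

## Worked example

```sh
sensigen run --demo --seed 7 --out demo/
```

simulates a 40-family cohort (~185 subjects, 150 SNPs, 60 genes) and runs
every stage in about two seconds. Selected output from `demo/`:

* `simplem.json` — 134 SNPs pass QC, `m_eff = 83`, genome-wide threshold
  0.05/83 ≈ 6.0 × 10⁻⁴: LD inside haplotype blocks makes ~38% of the
  nominal tests redundant.
* `gsea.tsv` — the top set is `COUPLED_MODULE` (the 10 genes the generator
  couples to the trait through a shared latent factor): ES = 0.84,
  NES = 1.88, nominal p = 0.0047.
* `top_model.yaml` — the exhaustive search fits 19,600 models and ranks
  the planted signature triple first:

  ```
  genes: [G0010, G0025, G0040]   r2: 0.454   adjusted_r2: 0.429
  covariate_only: adjusted_r2: 0.018
  diagnostics: normality_p 0.057, heteroscedasticity_p 0.258, linearity_p 0.835
  ```

  The three-gene interaction model explains ~43% of the variance in
  ΔS<sub>i</sub> where sex and VO₂max/kg alone explain ~2%, and the
  residual diagnostics show no violation of normality, homoscedasticity
  or linearity.

Every stage writes a TSV/JSON artifact plus a `.meta.json` provenance
sidecar; rerunning with the same configuration reproduces every artifact
byte for byte. Individual stages are also exposed as subcommands
(`sensigen gwas`, `sensigen gsea --rnk ranked.tsv --gmt sets.gmt --perm
1000 --seed 7`, `sensigen search`, ...) and as plain library functions.

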