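# knockblock

Group-knockoff inference for GWAS from summary statistics: estimate
block-diagonal LD from individual-level genotypes, solve the
maximum-entropy group-knockoff optimization, share the resulting
parameters as an HDF5 bundle, and use that bundle together with marginal
Z-scores to report *distinct* discoveries with group-level false discovery
rate (FDR) control.

## Who this is for

Standard GWAS pipelines test marginal association and require
post-processing (clumping, fine-mapping) to interpret hits. Knockoff-based
analysis instead tests *conditional* independence hypotheses, so each
discovery is a distinct signal — but classical knockoffs need
individual-level data. The ghost-knockoff trick moves all
individual-level work into a one-time LD-processing step: once a cohort's
LD panel has been processed, anyone with marginal Z-scores from that
population can run a knockoff analysis in minutes. This package implements
both halves for statistical geneticists who want that workflow
self-contained in Python.

## Model

With `Sigma = diag(Sigma_1, ..., Sigma_b)` the block-diagonal variant
correlation matrix, each block is processed as:

1. **Covariate-adjusted LD** — `Sigma_i = X_adj' X_adj / n` with
   `X_adj = (I - C(C'C)^-1 C') X_i`, eigenvalues floored at `1e-5`, then
   rescaled to an exactly unit diagonal.
2. **Grouping** — average-linkage hierarchical clustering at absolute
   correlation cutoff 0.5 defines non-overlapping variant groups;
   *group-key* variables (greedy forward selection until the remaining
   members' average `R^2` on the keys reaches `c = 0.5`) carry the
   cross-group dependence.
3. **Maximum-entropy knockoffs** — on the key submatrix,

       max_S  log det( ((m+1)/m) Sigma_RR - S ) + m log det(S),
       s.t.   S >= 0,  ((m+1)/m) Sigma_RR - S >= 0,

   with `S` block-diagonal over groups and `m = 5` knockoff copies; the
   full sampling matrix `D` is assembled from `S` via the conditional
   (Schur-complement) formula and satisfies `((m+1)/m) Sigma - D >= 0`.
4. **Ghost sampling and filtering** — knockoff Z-score copies
   `z_k = (I - D Sigma^-1) z + e_k` are drawn from the exact joint
   Gaussian law; per-group importance (sum of squared Z-scores) feeds the
   multiple-knockoff kappa/tau filter at target FDR `q`.

See `docs/methods.md` for assumptions, parameter semantics, and numerical
details.

## Worked example

Build a bundle from binary PLINK input and run inference on Z-scores
(files as produced by `knockblock.simulate.write_fixtures`; any
VCF/PLINK cohort works the same way):

```bash
solveblock --bed cohort --out bundle/ --m 5 --cutoff 0.5 --key-c 0.5
ghostgwas --zfile z.tsv --bundle bundle/ --q 0.10 --seed 2025 --out hits.tsv
```

which prints (for the 800-sample, 40-variant demonstration cohort
generated by `examples/make_example.py`):

```
read 800 samples x 40 variants
after QC: 40 variants
1 LD blocks
  block 1:[0,40) -> 40 groups, 40 keys
bundle written: bundle/manifest.json
2 group discoveries at target FDR 0.1 (threshold 132.2); written to hits.tsv
```

`hits.tsv` has one row per discovered group: its chromosome, position
span, representative variant (largest |Z| member), the tau statistic, and
the selection threshold:

```
block  group  chrom  pos_start  pos_end  rep_variant  rep_z   tau     kappa  threshold
1      21     1      105000     105000   snp21        -25.97  527.99  0      132.25
1      35     1      175000     175000   snp35        -15.60  132.25  0      132.25
```

The cohort was simulated with four causal variants (`snp21`, `snp27`,
`snp35`, `snp36`); both discovered groups contain a causal variant —
`snp35` and `snp36` are correlated neighbours, so one representative
stands for that signal, while `snp27`'s effect is too weak to clear the
threshold at this sample size. At latent correlation 0.5 the realized
dosage correlations fall below the 0.5 grouping cutoff, so every variant
forms its own group here; tighter LD yields multi-variant groups with a
reduced key set. The end-to-end synthetic experiment is available as a library call
(`knockblock.run_fdr_experiment`) or CLI:

```bash
knockblock-sim --config sim.yaml --out results/
```

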