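# blocktest

Block-level association tests for case-control sequencing and GWAS cohorts.

Univariate GWAS testing assumes an additive mode of inheritance and pays a
multiple-testing penalty that grows brutal on dense sequencing panels.
`blocktest` instead summarises the association signal of *all* not-very-rare
SNPs in a linkage-disequilibrium (LD) block in a single statistic, and can
combine evidence across additive, dominant and recessive genotype codings
(the **ADR** extension) so that a non-additive causal variant is not missed.

## Methods implemented

For a block of *m* SNPs, per-SNP score statistics
Z<sub>A</sub>, Z<sub>D</sub>, Z<sub>R</sub> (one per mode of inheritance)
are computed by regressing the 0/1 phenotype on each coded genotype column.
Block-level tests:

- **SS-T** — the truncated sum of squares
  Σ<sub>j</sub> Z²<sub>j</sub>·I(Z²<sub>j</sub> ≥ t), which drops weak
  statistics that only add noise; *t* = 6 ("SS-6") is the recommended
  default.  Significance comes from multivariate-normal simulation of the
  null statistic vector using the block's LD (statistic-correlation) matrix.
- **V-SS / V-minP** — VEGAS-style sum of squares (SS-T at t = 0) and maximum
  Z², same simulation null.
- **Bonferroni** and **Simes** on the per-SNP p-values.
- **GATES** — Simes with an effective number of tests
  m<sub>eff</sub> = m − Σ<sub>λᵢ>1</sub>(λᵢ − 1) from the eigenvalues of the
  p-value correlation matrix.
- **PC** — sum of squares of the first k (default 3) principal-component
  statistics U<sub>j</sub> = v<sub>j</sub>·Z/√λ<sub>j</sub>, χ²(k) under the
  null; **S-PC** — Simes combination of Simes and PC.

Every method has an ADR variant: the three statistic/p-value vectors are
stacked (length 3m) and the test multiplicity is conservatively set to 3m.

The package also ships the simulation machinery used to study these tests:
a latent-normal genotype simulator parameterised by the polychoric
correlation (PCC), penetrance-based case-control phenotype simulation
(relative risks R1/R2 or a per-carrier probability-scale effect δ,
calibrated to prevalence K), a synthetic reference-panel generator with
LD-block inference (average-linkage clustering on 1 − PCC²), and a paired
size/power evaluation harness.

## Worked example

`examples/block_test_cohort.py` simulates a 10-SNP block (latent correlation
0.8, allele frequency 0.1) with one recessive causal SNP (R2 = 3.14,
prevalence 5%), samples 1,000 cases and 1,000 controls, and runs every test:

```
causal SNP: snp1 (recessive, R2=3.14)
method          plain p      ADR p
bonferroni       0.1234    0.02052
gates           0.09634    0.01357
pc               0.2576     0.1468
s_pc             0.2354    0.04103
simes            0.1177    0.02052
ss_6            0.07293    0.01998
v_minp          0.07193    0.01199
v_ss            0.05894    0.04695
```

The additive-only column dilutes the recessive signal (heterozygotes carry
no extra risk); the ADR column, which also tests the dominant and recessive
codings at a 3m multiplicity, is roughly five to ten times smaller for most
methods.  The other examples show the SS-T threshold sweep, the ADR power
gain under a recessive mode, and LD-block inference on a synthetic panel.

Real data enter through a VCF (ALT-dosage hard calls) or a plain 0/1/2
genotype TSV plus a two-column phenotype table, via the API
(`blocktest.analyze_block`) or the CLI:

```sh
blocktest test --vcf cohort.vcf --pheno pheno.tsv --t 6 --B 1000 --out results.tsv
blocktest blocks --panel panel.tsv --pcc2 0.64 --out blocks.tsv
blocktest power --config setting.yaml --seed 1 --out power.tsv
```

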