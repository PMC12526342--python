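# aridpop

Post-variant-calling population genomics for whole-genome resequencing
panels of clonally propagating plants — built for studies like a
multi-hundred-sample desert-tree panel where cuttings and human-mediated
planting mean many "individuals" are clones, population structure is
subtle, and every downstream statistic depends on getting the filtering
and clone pruning right first.

The package takes a jointly genotyped multi-sample VCF and runs the full
analysis chain as one tested library (plus a thin `aridpop` CLI):

1. **Quality filtering** — biallelic SNPs with QUAL ≥ 30, per-genotype
   GQ ≥ 20 and DP ≥ 5, per-site missingness < 10%, MAF ≥ 0.05; samples
   with > 20% missing genotypes removed; windowed LD pruning
   (50 SNPs / step 5 / r² > 0.5).
2. **Clone detection** — PLINK-style method-of-moments identity-by-descent;
   pairs with PI_HAT ≥ 0.95 are clonemates, clonal groups are the
   transitive closure, and each group keeps its lowest-missingness member.
3. **Ancestry** — sNMF-style nonnegative matrix factorization of one-hot
   genotypes, X ≈ QG with Q rows on the simplex, K chosen by the masked
   cross-entropy criterion over K = 1..10 with replicated runs; DAPC
   (40 PCs, 3 discriminant functions) as an independent cross-check.
4. **Diversity** — Ho, unbiased He, F = 1 − Ho/He, a per-sample π proxy,
   with ANOVA + Tukey HSD group comparisons.
5. **Differentiation** — Weir–Cockerham FST (variance components a, b, c;
   weighted Σa / Σ(a+b+c)), pairwise and in 50 kb / 10 kb sliding windows;
   top-1% outlier windows intersected with GFF3 gene models (±2500 bp).
6. **Gene flow** — frequency-based ABBA–BABA D-statistics with 1 Mb
   block-jackknife Z scores and an f4-ratio admixture fraction, globally
   and per chromosome.
7. **Phylogeny** — cosine genetic distances, neighbor-joining, 1000
   SNP-resampling bootstraps, Newick export.
8. **LD decay** — binned r² vs distance, weighted spline fit, half-decay
   distance.
9. **Map layout** — a "flower expansion" that displaces co-located sample
   markers onto a circle around their shared centroid.

A first-class **synthetic-data generator** (Balding–Nichols demes with
known F, planted clones, planted filter failures, a four-population
quartet with controllable introgression) provides known-truth inputs, so
every stage is validated by recovery rather than by fixtures.

## Worked example

```python
from aridpop.synthetic_data import SimConfig, simulate_structured
from aridpop.qc_filter import FilterConfig, filter_sites
from aridpop.differentiation import pairwise_fst

cfg = SimConfig(seed=11, n_demes=4, deme_sizes=[20, 20, 20, 20],
                bn_f=[0.02, 0.03, 0.05, 0.12], n_snps=4000)
gm, truth = simulate_structured(cfg)
gm = filter_sites(gm, FilterConfig())
print(f"{gm.n_samples} samples x {gm.n_sites} SNPs after filtering")
print(pairwise_fst(gm, truth.deme_labels()).round(4))
```

prints

```
80 samples x 3868 SNPs after filtering
        1       2       3       4
1  0.0000  0.0261  0.0355  0.0706
2  0.0261  0.0000  0.0402  0.0754
3  0.0355  0.0402  0.0000  0.0841
4  0.0706  0.0754  0.0841  0.0000
```

Under the Balding–Nichols model the expected pairwise FST between demes
with drift parameters F_i and F_j is ≈ (F_i + F_j)/2, here 0.025–0.085 —
each estimate lands on its target, and deme 4 (F = 0.12, the
low-diversity cluster) is the most differentiated, the pattern this kind
of study reports for its geographically restricted group.

The same flow is available from the shell:

```bash
aridpop simulate --out-dir sim --seed 3 --n-snps 600 --demes 2
aridpop filter --vcf sim/sim.vcf --out filt.vcf --report rep.tsv
aridpop prune  --vcf filt.vcf --out pruned.vcf
aridpop clones --vcf pruned.vcf --out clones.tsv
aridpop fst    --vcf pruned.vcf --labels sim/populations.tsv \
               --gff sim/sim.gff3 --out-prefix fstout
```

## Layout

```
src/aridpop/        io_core, qc_filter, clones, ancestry, diversity,
                    differentiation, introgression, phylo, ld_decay,
                    geo_layout, synthetic_data, pipeline, cli
tests/              unit + property + recovery suites
docs/methods.md     models, estimators, defaults, and limitations
```
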