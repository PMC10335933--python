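# panpav

Pan-genome presence/absence variation (PAV) analysis for crop
populations, built around the wild → landrace → cultivar design of a
foxtail-millet-style diversity panel. The package provides, as one
tested library with a CLI:

* **Pan-gene classification and growth curves** — gene families are
  classified from their occupancy count *c* over *N* accessions
  (core: *c* = *N*; soft core: ⌈0.9 *N*⌉ ≤ *c* ≤ *N* − 1; dispensable:
  2 ≤ *c* < ⌈0.9 *N*⌉; private: *c* = 1), and permutation growth
  curves with a power-law closure fit pan(*n*) ≈ *K n*<sup>γ</sup> + *C*
  decide whether the pan-genome is closed.
* **PAV selection scans** — carrier-frequency contrasts between wild
  and landrace ("domestication") and landrace and cultivar
  ("improvement") accessions, tested per PAV with a two-sided Fisher
  exact test and Benjamini–Hochberg FDR; flagged PAVs with monotone
  frequencies across the three groups are favorable PAVs (favPAVs),
  mapped to genes and promoters.
* **TE association** — PAV–TE overlap enrichment against a
  random-placement null, and high-confidence TE-derived PAV calling
  from single-intact-TE colocation plus target-site-duplication (TSD)
  detection at insertion breakpoints.
* **Diversity scans** — sliding-window nucleotide diversity π, the
  ratio π_wild/π_landrace, and Weir–Cockerham F_ST with empirical
  tail-quantile selection thresholds.
* **SV-aware GWAS** — an EMMAX-style mixed model (VanRaden kinship,
  genotype PCs as fixed covariates), a blockwise-eigenvalue effective
  marker number for Bonferroni thresholds, greedy locus clustering
  (≤ 50 kb from the lead and LD R² ≥ 0.3), candidate genes in ±50 kb
  windows, and SV-vs-SNP LD complementarity (untagged-SV fraction).
* **Genomic selection and breeding potential** — gradient-boosting
  feature gain (FG) per marker, selection at ROF = 1 − FG_i/FG_max ≤
  0.99, six SNP/SV/combined marker panels, repeated-split Pearson
  prediction precision, and exhaustive 2^k haplotype enumeration over
  the top-k markers to estimate the attainable GEBV improvement.
* **A synthetic-population generator** — Balding–Nichols drift across
  the three groups, planted monotone-frequency selected PAVs, TE/gene
  annotations with planted TSDs, and additive multi-environment
  phenotypes with known effects — so the whole pipeline runs and is
  validated end to end without any external data.

## Worked example

```python
from panpav import SimConfig, simulate_dataset, SelectionScan, classify_families

data = simulate_dataset(SimConfig(seed=1))      # 35/40/35 panel
print(classify_families(data.presence).summary())
res = SelectionScan(data.pavs, data.groups).fit()
print(res.summary())
```

```
     category  count  proportion
0        core   1250        0.25
1    softcore   2000        0.40
2 dispensable   1500        0.30
3     private    250        0.05
         class  count
0       domPAV     67
1       impPAV     75
2       favPAV     62
3  favPAV_gain     33
4  favPAV_loss     29
```

The composition recovers the generator's designed category shares
exactly. Of the 62 favPAV calls, 58 are among the 60 planted selected
PAVs (sensitivity 96.7%, precision 93.5% at this seed); the remainder
are drift-differentiated PAVs that happen to satisfy the monotonicity
rule.

The same analyses are available from the shell:

```bash
panpav run --outdir demo --seed 1     # all stages + provenance manifest
panpav pavscan --outdir demo --q-max 0.01 --min-delta 0.25
```

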