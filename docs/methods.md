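# Methods

This note documents the models and conventions behind `panpav`, the
parameters that matter, and the design choices made where the standard
literature leaves room.

## Synthetic populations

The generator (`panpav.synthdata`) is the reference definition of the
data the analyses expect. It emulates a three-group crop diversity
panel — wild progenitors, landraces and modern cultivars — with these
components:

**Drift model.** Each marker has an ancestral allele frequency
*p* ~ U(0.05, 0.95); the lower bound keeps most markers above the
MAF ≥ 0.05 filter used downstream. Group frequencies follow the
Balding–Nichols construction, Beta(*p*(1−*F*)/*F*, (1−*p*)(1−*F*)/*F*)
with a per-group drift parameter *F* (`f_drift`, default 0.05).
*F* maps onto the expected F_ST-like divergence of each group from the
ancestral pool; the default produces windowed wild-vs-landrace
Weir–Cockerham F_ST around 0.05, a modest, realistic level of
within-species structure. The real panel's demographic parameters are
not published, so these defaults are conventions, stated here once.
SNP dosages are Binomial(2, *f*); PAV carriers Bernoulli(*f*);
genotypes are missing completely at random at rate 0.02.

**Planted selected PAVs.** `n_selected_pav` PAVs (default 60, round-
robin over domestication/improvement × gain/loss) receive fixed group
frequencies instead of drift: the labeled contrast is shifted by
`delta_f` (default 0.5) and the remaining leg continues in the same
direction with a margin of 0.25 (clipped to [0, 1]). The margin is
what makes the monotonicity rule resolvable: with ~35–40 accessions
per group the sampling error of a frequency difference is ≈ 0.11, so a
zero-margin leg would be violated in roughly half of the realizations
and recovery of the planted favPAVs would be capped near 50%.

**Annotations.** Genes are non-overlapping intervals from an
exponential gap/uniform length walk. TE intervals come from an
alternating exponential TE/gap walk whose means are chosen so expected
coverage equals `te_fraction` (default 0.605, a typical repeat content
for a cereal genome); realized coverage concentrates within ±2
percentage points on a 10-Mb genome. 70% of TEs are flagged intact.
PAV positions themselves are uniform, so TE-overlap enrichment is
weak by design — only the planted TE-derived PAVs (relocated to span
exactly one intact TE) push the observed fraction above the null.

**TSDs.** Half of the insertion PAVs (configurable) receive planted
target-site duplications of length 4–10 bp: an exact k-mer is placed
as the suffix of the left flank and the prefix of the right flank,
rejection-sampled so the duplication does not extend by accident.
All other PAVs receive flanks rejection-sampled to contain *no*
breakpoint-anchored duplication in the 4–10 range. TSD ground truth
is therefore exact: detection must recover 100% of planted TSDs and
call nothing elsewhere.

**Phenotypes.** Each trait draws `n_causal` markers with N(0, 1)
additive effects; the phenotype is Σ effect × dosage + environment
offset + Gaussian noise scaled so the genic variance fraction equals
`h2`. `h2 = 0` removes the genetic term entirely; `h2 = 1` removes the
noise. Environments differ by a fixed mean offset only (no G×E).

**Determinism.** All draws derive from named sub-streams of the
config seed (`SeedSequence((seed, stream_id))`), so enlarging one
component (say, the SNP panel) never perturbs another (say, the
phenotypes), and identical configs give byte-identical outputs.

**What the generator does not emulate** — and hence what passing
tests do not establish about real data: linkage disequilibrium
(markers are independent given the group; LD-dependent measurements
construct LD explicitly by copying/perturbing columns), recombination
maps, selection acting on SNPs, genotyping error beyond missingness,
shared TE families, and G×E interaction.

## Pan-genome composition and closure

Occupancy-count rules as in the README; the soft-core boundary is
generalized as ⌈0.9 *N*⌉, which reproduces the canonical 100–110 band
at *N* = 111. Growth curves add accessions in uniformly random order;
within every ordering the pan count is non-decreasing and the core
count non-increasing (asserted). The "detrended" curve is the
increment series Δpan(*n*). Closure is decided from a least-squares
fit of pan(*n*) ≈ *K n*<sup>γ</sup> + *C* on the mean curve: "closed"
iff γ < 1 − tol (default tol = 0.05) and the final increment is below
ε·pan(*N*) (default ε = 10⁻³); the plateau point *n** is the first *n*
whose increment falls below that bound. A constant curve
short-circuits to γ = 0, closed. Both thresholds are configurable;
they are conventions, since no standard definition of a "detrended"
growth curve or plateau criterion exists.

## PAV selection scan

Carrier frequency per group is carriers / non-missing calls; a group
with no callable genotypes masks the PAV for contrasts touching it.
Translocations are excluded from scans (carrier semantics ambiguous)
but kept in I/O. The two-sided Fisher exact p sums hypergeometric
probabilities ≤ the observed table's probability; the implementation
precomputes a p-value grid per margin pair, which makes 10⁵-scale
replicate scans cheap while remaining the same statistic (equality
with both scipy and a direct enumeration oracle is tested to 1e-12).

"Substantially different frequencies" is operationalized as BH-FDR
q ≤ 0.01 **and** |Δf| ≥ 0.25 (both configurable). The effect-size
floor matters because the Fisher p conflates sample size with effect;
the q-threshold alone would flag tiny shifts in large panels.
A favPAV requires the full wild ≤ landrace ≤ cultivar ordering (or its
reverse) with strict inequality in every flagged contrast; ties are
allowed in the unflagged leg. Under drift, a null PAV that reaches
significance in one contrast rarely continues monotonically into the
third group, which is what gives favPAV recovery its precision.

Promoters default to 2,000 bp upstream of the strand-aware
transcription start; genes with unknown strand take the promoter on
both sides and are flagged in the output. Distance profiles bin each
PAV by distance to the nearest gene body into powers-of-two-kb bins.

TE-derived classification requires intersection with exactly one
intact TE, reciprocal overlap ≥ 0.8 of both lengths (configurable;
"colocated" has no standard quantitative definition), and a detected
TSD. TSD detection is anchored at the breakpoint: the duplication must
end at the left breakpoint and begin at the right one, lengths scanned
from 10 down to 4 so the longest match wins (anchoring leaves at most
one candidate per length, so no further tie-breaking is needed). On
i.i.d. uniform flanks the false-call rate is ≈ 1 − Π(1 − 4⁻ᵏ) ≈ 0.5%,
matched by simulation in the tests.

## Diversity scans

Windows default to 20 kb size / 2 kb step, tiling each chromosome
from 0. Per-site diversity is the unbiased heterozygosity
2p̂q̂·n/(n−1) over non-missing allele counts; windowed π sums variant
sites and divides by the full window span, so monomorphic sequence
counts as zero difference — the convention of the standard windowed-π
tools. π-ratio is per-window π_wild/π_landrace (0/0 → NaN). F_ST is
Weir & Cockerham (1984) for two populations of diploids, with window
values as ratio-of-sums of the per-site variance components a/(a+b+c);
sites with fewer than two called individuals in either group are
masked, and monomorphic windows are NaN. Selection thresholds are
empirical tail quantiles (default upper 1%) of each statistic;
published absolute cutoffs are properties of a particular dataset, not
parameters, so the package always derives them from the data at hand.

## Mixed-model association

Markers are filtered at MAF ≥ 0.05 and missingness < 0.1; missing
dosages are mean-imputed for model fitting. Kinship is VanRaden's
centered cross-product; zero-variance markers are excluded, and a
panel with no polymorphic marker yields a zero matrix (no relatedness
signal). Genotype principal components (default 10) enter as *fixed*
covariates with the kinship as the random effect — the EMMAX
convention; describing PCs as a "random effect matrix" is nonstandard
and was not followed. The variance ratio δ = σ²_e/σ²_g is estimated
once on the null model by maximum likelihood via the
eigendecomposition of K; each marker is then tested by OLS in the
rotated, whitened space with per-marker residual variance (Wald t).
With K = I and no PCs this reduces exactly to ordinary least squares,
which the tests verify to 1e-8.

The effective number of independent tests M_eff uses the blockwise
eigenvalue (Li–Ji-style) estimator, Σ[1(λ ≥ 1) + (λ − ⌊λ⌋)] over the
eigenvalues of each 1,000-marker block's correlation matrix: exactly M
for orthogonal markers and M/2 when every marker is duplicated.
Significance thresholds α/M_eff are reported for α = 0.05 and 0.01
(plain Bonferroni on M is available as the conservative alternative).
The default genome-wide p cutoff 7.81 × 10⁻⁸ corresponds to
α = 0.05 at the reference panel's published marker count.

Locus clustering is greedy: the smallest-p unassigned significant
marker becomes a lead (ties broken by chromosome order then position);
unassigned significant markers within 50 kb and with dosage R² ≥ 0.3
(pairwise-complete) join its locus. The result is a deterministic
partition of the significant markers. Candidate genes are those
intersecting ±50 kb of the lead. SV–SNP complementarity reports, per
polymorphic SV, the maximum R² against SNPs within ±50 kb of its
breakpoints; an SV is untagged below R² = 0.5 (or with no flanking
SNP). Monomorphic SVs are excluded and counted.

## Genomic selection and breeding potential

Feature gain is LightGBM's total split gain per marker
(200 trees, learning rate 0.05, 15 leaves, deterministic single-thread
settings); unused markers get FG = 0. The selection statistic is
ROF_i = 1 − FG_i/FG_max, keeping markers with ROF ≤ 0.99, i.e.
FG ≥ 1% of the maximum. The orientation matters: the alternative
1 − FG_max/FG_i is ≤ 0 for every marker and would make the 0.99
threshold select everything, so the statistic as implemented is the
one under which the threshold is meaningful. ROF is scale-invariant
in FG.

The six panels combine the ROF-selected ("cg") SNP/SV sets with the
GWAS-significant sets by union, for SNPs, SVs and both. Prediction
uses either the gradient-boosting model or a ridge ("GBLUP-flavoured")
linear predictor behind one contract; precision is the Pearson
correlation between held-out phenotypes and predictions over repeated
random splits (default 100; an exact 580/100 split is used when the
panel has 680 accessions, otherwise 85%/15%). Replicates with a
constant held-out truth or prediction are excluded and counted.

Breeding potential takes the highest-GEBV accession (optionally within
the cultivated group) as background and enumerates all 2^k assignments
of the top-k (default and cap 20, i.e. 1,048,576 combinations) FG
markers to {absent, homozygous carrier}; the report carries
GEBV_max_haplotype, GEBV_max_cultivated and the improvement
100 × (hap − cult)/cult, undefined (reported as such) when the
denominator is 0. Under an additive linear model the enumeration
provably equals the closed-form optimum (each positive-effect marker
at its maximum dosage, each negative at 0), which the tests assert
exactly; for the tree model the enumerated optimum is a lower bound on
nothing and a guarantee of nothing beyond the enumerated set, which is
why the cap refuses k > 20 rather than approximating.

## I/O conventions

Internal coordinates are 0-based half-open everywhere; conversions
happen only at format boundaries (VCF and GFF3 are 1-based). SVs are
written sequence-resolved when the inserted sequence is known,
otherwise symbolically with SVTYPE/SVLEN/END (SVLEN negative for
deletions); a symbolic record at POS p with END e maps to [p, e), and
insertions are points. write∘read round-trips are exact and tested.
Every pipeline run writes a resolved config copy and a manifest with
the seed, config hash and per-file SHA-256 checksums, so a run is
reproducible from its output directory alone.

## Problem sizes in the shipped checks

The test suite and the acceptance script run at desk scale, chosen so
each statistical property is measured with adequate replication while
the whole suite stays fast: the reference panel is 110 accessions with
2,000 SNPs / 1,000 PAVs / 5,000 families on a 2 × 5 Mb genome; error
control uses 200 replicate null scans of 2,000 PAVs; power and
recovery properties use 50 seeds; the association panel is 600
accessions with ~3,800 markers; the breeding enumeration runs the full
2^20 with the linear predictor. Quantities that depend on panel size
(marker counts, locus counts, precision values) are therefore not
comparable to any particular published panel; rule-based and
oracle-checked quantities (classification boundaries, Fisher p-values,
π/F_ST arithmetic, panel set algebra, the 2^20 count) are exact at any
scale.
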