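# Methods

## The analysis model

The package operates on consensus-base SNV profiles: at every site
(identified by scaffold, 0-based position and reference base) each
sample contributes at most one call, the base supported by the most
reads in that sample. Within-sample allele frequencies are deliberately
not modelled — the unit of analysis is the dominant strain's base, so a
sample's profile over a MAG's sites is a *pseudo-haplotype* and
between-sample comparisons are sequence comparisons.

Coordinates follow one internal convention: 0-based, half-open.
Conversions happen only at the file boundary (SNV tables arrive 0-based;
GFF3/gene tables arrive 1-based inclusive).

### Site filters

Sites enter the association machinery after three filters applied in a
fixed order, so the per-rule removal counts in `filter_counts` are
unambiguous:

1. *presence* — called in ≥ 20 % of samples;
2. *biallelic* — exactly two distinct bases among the non-missing calls;
3. *frequency* — the major base ≤ 90 % of calls and the minor ≥ 10 %.

Allele fractions are computed over called samples only. Boundary
semantics are literal: a site whose major base is exactly 90 % (minor
exactly 10 %) is kept. With biallelic 0/1 coding the two frequency knobs
are complements; both are exposed because they are conceptually distinct
(`major_max`, `maf_min`). Fractions are computed from integer counts so
that boundaries such as 9-of-10 land exactly. The minor base is coded 1;
an exact 50/50 tie is resolved alphabetically (lower base coded 0) for
determinism.

### Genomic dissimilarity and strains

Pairwise dissimilarity is the Kimura 2-parameter distance over
pairwise-complete positions,
`d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`,
with `P` the transition (A↔G, C↔T) and `Q` the transversion fraction.
Missing-data contract: fewer than `min_overlap` (default 10) jointly
called sites, or a non-positive log argument (saturation), yields a
*missing* distance — never an infinity — and saturated pairs are
counted. Ten sites is the smallest overlap at which the substitution
fractions are stable enough to be worth reporting; below that the
estimate is dominated by sampling noise.

Per MAG, the distance matrix is divided by its maximum defined entry
(an all-zero matrix is left unchanged). Normalization is per MAG, not
global: clustering is per MAG, and a global maximum would couple
unrelated organisms. Strains are complete-linkage clusters of the
normalized matrix. Samples with missing distances to more than half of
the others are dropped (and listed) rather than imputed, because
complete linkage cannot accept missing dissimilarities; any residual
undefined entries are resolved by iteratively dropping the worst sample.
The cut is a free parameter — a height on the normalized [0, 1] scale or
a requested cluster count `k` (used for two-strain analyses); no default
cut is claimed to be canonical. Labels are renumbered by cluster size
(ties by smallest member id), so they are independent of input order.

Strain-by-day structure is scored per (cluster, day) with a two-sided
Fisher exact test on the 2×2 membership table, BH-adjusted within the
MAG. Pathway enrichment (below) uses one-sided tests instead because
enrichment is directional; strain-time association is not.

### Temporal and group statistics

Day is ordinal for Spearman trend tests and categorical for
Kruskal–Wallis tests. "Within-group genomic distance" means the pairwise
distances among samples sharing both group and day; the per-MAG group
scan pools these per group and runs a Kruskal–Wallis test across the
three groups, BH-adjusted across MAGs. The per-gene temporal test
summarizes a gene as the per-sample mean of the 0/1 genotype over the
gene's called sites (the minor-allele load) and tests it across days;
a per-site mode is provided as an alternative since the gene-level
summary is a modelling choice, not a given.

### Association scans

Continuous traits: ordinary least squares `trait ~ SNV + day`, Wald test
on the SNV slope. Binary traits: maximum-likelihood logistic regression.
Group effects on genotypes invert the model: `SNV ~ group + day` with
the control group as reference and a likelihood-ratio test of the two
group indicators jointly (2 df) — a Wald test on a single indicator
would not treat the three-level factor coherently. Day enters as a
numeric covariate (15/35/56) by default since the model has a single
day term; a categorical encoding is a flag.

Fits require ≥ 20 usable samples and ≥ 3 samples in each genotype class;
smaller cells produce records with a `skip_reason` instead of unstable
estimates. Logistic fits are declared separated/non-converged when the
optimizer fails, does not converge at tolerance 1e-8 within 100
iterations, or any coefficient exceeds 15 in absolute value (odds ratios
beyond e^15 are numerically meaningless here); such records carry a flag
and a missing p.

BH FDR is applied across all (site × trait) tests of a scan jointly
("study-wide"); per-trait adjustment is a flag. The realized BH p-value
threshold is whatever the step-up procedure yields on the data at hand —
no fixed genome-wide p cut is hard-coded. LD pruning is greedy within
each (MAG, trait) stratum: records sorted by ascending p (ties broken by
site key), the best kept, and every remaining record with
pairwise-complete genotype r² above the threshold (default 0.9) removed
and logged against the kept record.

Repeated measures per animal across days are not modelled (no random
effects, no population-structure correction); this is a known
limitation of the plain regression design and is listed below.

### Gene mapping and pathway enrichment

A differential site belongs to every gene whose CDS interval contains it
(half-open: lower bound inside, upper bound outside); overlapping genes
each count once. Genes with more than 3 differential SNVs are labelled
"multiple". Per MAG, hit genes are tested for over-representation in
each COG pathway with a one-sided Fisher exact test against the
background of the MAG's COG-annotated genes (genes without a COG are
excluded from both margins; a gene in several pathways enters each
table independently), BH-adjusted across all (MAG, pathway) pairs.
The background choice — all annotated genes rather than genes with ≥ 1
SNV call — is a flag-selectable alternative.

## The synthetic-data generator

`simulate_study` emulates the statistical structure of a three-arm
transplantation study: 12 animals per group (CON/RMT/RFT), sampled on
days 15, 35 and 56 (108 samples). Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| MAGs × sites | 6 × 200 (2 scaffolds each) | enough sites for stable K2P estimates at desk scale |
| strains per MAG | 2, divergence 0.2 | two clearly separated haplotypes; 40 divergent sites/MAG |
| transition:transversion | 2:1 | typical bacterial substitution bias |
| consensus error ε | 0.02 | substitutes a uniformly random different base; deliberately creates tri-allelic sites so the biallelic filter has work to do |
| missingness by day | 0.50 / 0.30 / 0.20 | coverage improves with age, reproducing rising per-sample SNV counts |
| RMT replacement | prob. 0.8, 2 MAGs | transplantation switches an animal's dominant strain wholesale (whole-MAG replacement, not per-site drift) |
| temporal turnover | 1 MAG, P(strain 2) = 0.1/0.6/0.9 by day | per-animal monotone switching; strain 1 enriched early |
| planted effects | 12 site→metabolite slopes (β = 1 residual SD) on 4 metabolites, 3 sites each | multiple correlated causal sites per metabolite mirror how associated sites cluster within a MAG; they sit on one MAG's divergent sites and are therefore in near-perfect LD — the pruning step's target |
| genes | 200 per MAG, 90 bp with 10 bp gaps | ~90 % CDS coverage, so most differential SNVs fall inside genes |
| pathways | 8, with a planted 10-gene pathway receiving 8 of 20 hit genes in a 200-gene background | a clearly enriched target plus diffuse off-pathway hits |
| phenotypes | 4 continuous (loading 0.8 on planted metabolites) + 1 binary (logistic) | closes the SNV → metabolite → phenotype chain |

Planted effect sites are chosen among divergent sites that remain
callable, biallelic and common on the realized data — otherwise a
"planted" effect would be unmeasurable by construction. Metabolites are
`γ·(day − mean) + Σ β·genotype + N(0,1)` with γ = 0.02 per day. All
randomness flows from one seed through named substreams, so components
can be regenerated independently and output trees are byte-identical
given a seed.

Two focused panels back the scan analyses: `simulate_trait_panel`
(n = 120 samples, 100 sites of which 50 causal, one per trait, MAF
uniform on 0.3–0.5, 20 % missing genotypes, β = 1) and
`simulate_group_panel` (50 shifted + 50 null sites, baseline allele
probability 0.3, shift of 2.0 on the log-odds scale in the RMT group).
The panel MAF range covers common variants — the regime where
single-site effects of one residual SD are detectable under study-wide
FDR control with ~100 usable samples, which is also where the real
scan's reportable hits live; rarer variants would need either larger β
or larger n than the desk-scale design provides.

What the generator does **not** emulate: read-level noise and coverage
(missingness is a Bernoulli mask, not a coverage model), within-sample
strain mixtures (consensus calls only), linkage decay along the genome
(sites within a MAG are either perfectly strain-linked or independent),
compositional abundance effects, and real taxonomic structure. Passing
tests demonstrate the statistical machinery is correct and calibrated
under this structure; they do not certify performance on real
metagenomes, where coverage, mixture and reference biases dominate.

## Numerical choices

* K2P saturation (log argument ≤ 0) → missing, with a counter; keeps
  normalization well-defined.
* Perfect OLS fits (zero residual variance) report p = 0 with zero
  standard error; a constant response reports p = 1.
* BH q-values: step-up with NaN passthrough; `m` counts non-missing
  p-values only.
* 50/50 allele ties, cluster-label ties, and p-value ties in pruning are
  all broken lexicographically, making every output order-invariant and
  byte-reproducible.
* Result tables are written with 10 significant digits (feature tables
  with 17, so simulated values round-trip exactly).

## Known limitations

* **Pooled pairwise distances are pseudoreplicated.** The per-MAG group
  scan feeds C(n,2) within-group distances per pool into a rank test
  that assumes independent observations, but the pairs share samples.
  Any sample-level variation (strain mixtures across animals, or even
  per-sample consensus-error counts) acts as a random effect, so null
  p-values are anti-conservative: planted MAGs are recovered with
  sensitivity ~1, but unplanted MAGs are flagged far above the nominal
  rate, and exact planted-set recovery at FDR 0.05 is not attainable
  with this test design. The scan is provided as specified — it is the
  field's common practice — with this caveat documented; a
  permutation-based or sample-level summary test would be the principled
  replacement.
* Repeated measures per animal are not modelled in the scans.
* Whole-MAG strain replacement makes all divergent sites of a MAG
  statistically redundant; per-site effect sizes in the full study are
  therefore sums over the correlated planted sites.
* The dendrogram export approximates a strain tree; no maximum-likelihood
  phylogenetics is attempted.
* Exact inStrain column-dialect variants beyond the minimal schema
  (scaffold, position, ref_base, con_base, class) are untested against
  real tool output; extra columns are ignored by design.

## Problem sizes

The test and acceptance runs use desk-scale sizes chosen to exercise
every code path with stable statistics: the default study (108 samples ×
1200 sites), 100–200 replicate scans for power and calibration, 10,000
Monte-Carlo draws for type-I error of the rank tests, and 100 replicates
for noisy strain recovery. `scripts/acceptance.py` reruns all of these
from scratch and reports each quantity with the problem size it used.
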