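# Methods

This note documents the models implemented in `oralsite`, the synthetic
cohort generator that stands in for sequencing data, the numerical choices
made where the design was genuinely open, and what the package's tests do
and do not establish about real data.

## Data model and table preparation

The central object is an integer count table of samples × features (ASVs or
collapsed taxa), read and written in the `#OTU ID` TSV dialect (features as
rows, samples as columns) alongside a 7-rank taxonomy TSV and a sample
metadata TSV (`sample_id`, `individual_id`, `habitat` ∈ {saliva,
buccal_mucosa}, optional `sex`, `age`).

Preparation follows the standard amplicon workflow, in this fixed order:

1. **Singleton removal** — features whose total count over the *merged*
   table equals 1 are dropped (table-wide totals, not per-sample).
2. **Rarefaction ("leveling")** — every sample is subsampled without
   replacement to a common depth of `floor(0.95 × minimum sample total)`
   (e.g. a minimum of 50,201 reads gives a depth of 47,690). Subsampling
   uses a single seeded multivariate-hypergeometric draw; samples below the
   depth are dropped with a warning, never padded. The order matters —
   singleton removal before leveling — and the two operations do not
   commute.
3. **Rank collapse** — counts are summed over features sharing a lineage
   prefix; features unassigned at the rank (or absent from the taxonomy)
   are pooled into an `Unassigned` bucket so per-sample totals are
   conserved exactly.

## Diversity and group statistics

Shannon entropy is reported in bits (base 2, configurable), Chao1 is the
bias-corrected estimator `S_obs + F1(F1−1)/(2(F2+1))`, and Simpson is the
Gini–Simpson index `1 − Σp²`. β diversity is Bray–Curtis on relative
abundances, embedded by non-metric MDS minimizing Kruskal stress-1
(initialized from classical metric scaling plus random restarts; stress and
a convergence flag are reported, and coordinates are only defined up to
rotation/reflection, so all tests use rotation-invariant quantities).

Group contrasts use the Welch (unequal-variance) two-sample *t*-test —
the robust default where the test variant is otherwise unspecified — and
report group means ± standard errors with significance stars at 0.01/0.001.
The per-taxon differential-abundance table reports raw p values (stars as
above) plus a clearly labelled Benjamini–Hochberg column as an extension.
Age associations use Spearman rank correlation per habitat.

## Community assembly

### Neutral community model

Under Sloan's neutral model, a taxon with metacommunity relative abundance
*p* has local relative abundance *x* ~ Beta(*Nm·p*, *Nm·(1−p)*), where
*Nm* (local community size × immigration probability) is the only free
parameter — only the product is identifiable from occupancy data. The
classic expected detection frequency uses a hard detection limit *d*:
`F(p) = 1 − I_d(Nm·p, Nm·(1−p))`, with `d = 1/depth` after leveling.

A taxon in a sequenced sample, however, is detected when **at least one of
R reads** hits it, an event whose exact neutral expectation has the closed
form

```
F(p) = 1 − E[(1−x)^R] = 1 − B(Nm·p, Nm·(1−p)+R) / B(Nm·p, Nm·(1−p))
```

The default fit uses this exact form (with `R = 1/d`); the hard-threshold
curve remains available via `detection="threshold"`. The distinction
matters: on simulated neutral data the threshold fit overestimates *Nm* by
roughly 8%/20%/36% at *Nm* = 100/1000/10000 (reads can detect taxa just
below *d*), while the exact form is unbiased to ~1%.

*Nm* is estimated on the log scale by iteratively reweighted least squares
with binomial weights `F̂(1−F̂)/n`; the 95% parameter CI comes from the
weighted large-sample covariance (coverage ≈ 95% in simulation).
Goodness of fit is `R² = 1 − SSE/SST` on unweighted occupancies; when every
taxon occurs in every sample the fit is degenerate and R² is reported as
NaN (poor fit).

**Partition band.** Taxa are classified above/fit/below a 95% band around
the fitted curve. The band combines a Wilson binomial interval at the
observed number of samples with a delta-method term propagating the
sampling uncertainty of the estimated abundance `p̂` through the slope of
the occupancy curve. The second term is essential: mid-curve, the
abundance uncertainty — not binomial occupancy noise — dominates the
scatter, and a pure Wilson band misclassifies ~10–15% of genuinely neutral
taxa. With the combined band, ≥97% of taxa from neutral simulations fall
in the "fit" class while a taxon forced present in every sample at tiny
abundance is still flagged "above".

### Null model and deterministic strength

For one group of samples, observed β diversity (`obs.beta`) is the mean
pairwise Bray–Curtis dissimilarity. Null communities preserve — exactly,
per draw, asserted at run time — each sample's read total and richness and
each taxon's occupancy count: presence/absence is randomized by curveball
trades along a Markov chain (burn-in 20·n trades, 5·n between draws), then
each sample's reads are reassigned to its present taxa by a seeded
multinomial with probabilities proportional to regional (group-mean)
relative abundance, with one guaranteed read per present taxon. A
stochastic refill is deliberate: a deterministic proportional refill would
collapse the null variance and make the standardized effect size
`ses.beta = (obs.beta − mean.null.beta)/sd.null.beta` explode even on
null-true data.

The deterministic strength is a symmetric per-pair departure measure,

```
SS = (D_obs − D̄_null)/D_obs   if D_obs > D̄_null      (divergence)
SS = (D̄_null − D_obs)/D̄_null  otherwise              (convergence)
DS = 100 × mean(SS) over pairs
```

bounded [0, 100]; pairs with both values zero are skipped with a warning.
The exact DS definition in the literature this statistic descends from is
not fully specified, so this form is an implementation choice of the
package; DS values are therefore comparable **within** analyses run by
this package (e.g. across habitats or filter strengths) but not to DS
numbers produced by other implementations. Note also that *any* excess
β diversity relative to the null — including stable subject-level
compositional differences — registers as deterministic departure, which is
why cohorts with strong individual signatures score high DS.

## Habitat classification

Random forest (500 trees, impurity importance) on ASV relative abundances:
stratified 70/30 sample-level split (an `individual_aware` grouped split is
available so both samples of one subject can be forced to the same side),
importance ranking fitted on the training split only, refit on the top-30
features, train/test accuracy and per-class confusion. Ties in importance
break by feature id, making the ranking deterministic; the whole pipeline
is a pure function of (table, metadata, seed).

## Personal discrimination

* **Unique species**: species are ranked by overall mean relative
  abundance (rank 1 = most abundant; per habitat by default); among
  species ranked strictly outside the top 100, those whose positive counts
  are confined to one individual's samples are unique to that individual.
  No abundance floor is applied. If a table holds fewer species than the
  threshold, all species are candidates (with a warning). The
  discriminated fraction is the share of individuals owning ≥1 unique
  species.
* **Core microbiome**: genera with a positive count in at least one sample
  of *every* individual. Adding individuals can only shrink the core.
* **Microbial code**: per individual (mean of relative abundances over the
  individual's samples in the chosen habitat), restricted to the core
  genera and renormalized to sum to 1; invariant to sequencing depth.
  Matching ranks reference codes by Bray–Curtis distance, ties broken by
  identifier.

## The synthetic cohort generator

The generator emulates a 50-subject paired-habitat study: two samples per
individual, read depths uniform on the published 50,201–199,533 range, and
genus profiles whose means are the published per-habitat values for the
ten most differential genera (Streptococcus-dominated mucosa vs a more
even saliva) plus nine further core oral genera at modest equal means
(their per-habitat means are not reported). Genera are expanded into 2
species each (geometric split), and a configurable log-series rare tail
(400 taxa, x = 0.995 by default) supplies the hundreds of low-abundance
species the rank-outside-100 rule needs.

Each sample's composition is a three-component mixture:

```
comp = λ_det · c_h  +  λ_ind · π_i  +  (1 − λ_det − λ_ind) · δ_ih
```

* `c_h` — deterministic habitat target over the core resident genera
  (habitat filtering; guarantees the core is present in everyone);
  λ_det = 0.15.
* `π_i ~ Dirichlet(θ · pooled)` — one draw per individual, shared by both
  habitats (the personal signature); λ_ind = 0.25, θ = 8.
* `δ_ih ~ Dirichlet(θ_w · b_h)` — habitat-specific residual;
  θ_w (`within_individual_theta`) = 100.

The residual mean `b_h` is solved so that the expected composition of each
habitat equals its configured profile **exactly**, whatever the weights
(negative solutions are rejected as incompatible weight/profile
combinations). Counts are multinomial at the drawn depth, and all
randomness derives from one master seed through named substreams, so
outputs are byte-reproducible.

Parameter rationale: θ = 8 puts between-subject dispersion in the range
implied by the published group standard errors (which correspond to
per-taxon Dirichlet concentrations of roughly 4–15 at n = 50); θ_w = 100
encodes that two samples from one mouth are far more alike than samples
from different mouths — the premise without which individual-level
matching could not work; λ_ind is capped near 0.26 by the requirement that
mucosal Neisseria's mean stays reproducible, and 0.25 sits just inside.

Two further assembly modes provide ground truth: **neutral** draws each
community from Dirichlet(*Nm*·p), whose marginals are exactly the Sloan
Beta distributions (used for parameter-recovery and self-null
experiments), and **filtered** scales the divergence between the two
habitat profiles by `filter_strength` ∈ [0, 1] (0 = identical habitats),
the generator's habitat-filtering dial: on the pooled two-habitat sample
set, DS rises monotonically with it.

`inject_unique_species` plants per-individual unique species at a target
relative abundance (≥1 read) into all of an individual's samples, moving
the reads from the sample's most abundant features so totals are
preserved, and returns the planted truth; a planted taxon that lands
inside the top-100 ranking is recorded as a warning.

### Verification-experiment designs

Some properties are verified on purpose-built configurations rather than
the defaults, because the property concerns bookkeeping, not biology:

* **Planted-unique recovery** uses a flat rare tail (150 taxa,
  x = 0.9999) and a near-deterministic background (θ = 2000) so no
  *natural* unique species arise and the recovered fraction equals the
  planted 13/25 = 0.52 exactly.
* **Core-of-16 construction** uses profiles naming exactly the 16 core
  genera (rescaled to 98% of the community) with a uniform rare tail, so
  every tail taxon drops out of some subject and the computed core is
  exactly the seeded 16.
* **Classifier null calibration** sets `individual_weight = 0`: with
  paired individual effects and no habitat signal, a test sample's twin
  sits in the training set with the *opposite* label, and the forest
  anti-learns (accuracy systematically below 50%). With exchangeable
  samples the null accuracy is chance, as it should be.
* **DS monotonicity** uses θ = 200 profiles so the habitat-filter signal
  is not drowned by subject-level overdispersion.

## What the synthetic data does and does not establish

The generator reproduces the study's design (paired habitats, published
genus means, read-depth range, planted rare uniques, guaranteed core) but
not real 16S data's full complexity: no compositional covariance between
genera beyond the Dirichlet, no sequencing error, chimeras or
contamination, a stylized rare tail, and ASV richness two orders of
magnitude below a real denoised table (hundreds of species vs tens of
thousands of ASVs). Consequently absolute values of richness-sensitive
quantities differ from the published ones — Shannon means land near 4.5/3.4
bits rather than 7.08/5.68, observed β diversity near 0.25 rather than
0.96, and classification is easier (test accuracy ~100% vs 93.3%) — while
directions and contrasts (saliva more diverse, Streptococcus enriched in
mucosa, strong habitat separability, 52% unique-species discrimination,
16-genus core) are preserved. Passing tests establish the correctness and
calibration of the *methods*, not numerical equality with any particular
sequencing study.

## Problem sizes used by the test suite and acceptance script

Simulation experiments run at desk scale chosen for statistical adequacy:
neutral-model recovery uses 20 replicates of 100 samples × 300 taxa at
20,000 reads across Nm ∈ {100, 1000, 10000}; null-model calibration uses
20 replicates of 20 samples with 99 null draws (the analysis default is
999, used by the acceptance script); classifier calibration uses 100 null
and 20 effect-size replicates at n = 50/habitat; discrimination
experiments use 25–50 subjects at 20,000 reads. The acceptance script runs
the main cohort at the full published read-depth range.

## Known limitations

* Only the product *Nm* is identifiable; the fit never separates N and m.
* The null model conditions on observed marginals estimated from the same
  data; its ses has a mild negative bias (≈ −0.6 on self-null data), well
  within the ±2 band used for calibration.
* DS is an implementation-specific statistic (see above).
* NMDS can reach local minima; restarts mitigate but do not eliminate
  this, and the stress value should always be inspected.
* Phylogenetic null models (βNTI/RC_bray) and LEfSe-style cascades are out
  of scope.
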