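# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Curation model

The raw input is a samples × MOTU table of read counts. Two threshold rules
define the curated data set:

* **Within-sample relative abundance.** Cells carrying strictly less than
  `per_sample_rel_abundance` (default 1e-4, i.e. 0.1‰) of the sample's
  total reads are zeroed. "Strictly less" means a cell exactly at the
  cutoff survives. The denominator is the sample's *raw* total — the
  cutoff is a property of the sequencing run, evaluated before any
  taxonomy-based exclusion. This choice also makes the abundance filter
  and the flag-based column exclusions commute exactly, which is the
  order-independence property the tests assert.
* **Data-set-wide minimum reads.** MOTUs whose total across all samples is
  strictly below `min_reads_per_motu` (default 5) are dropped, as are
  columns left all-zero by the cell filter.

Taxonomy ranks follow tiered identity/coverage thresholds (species at
coverage ≥ 98 and identity ≥ 99, genus at identity > 96, family at > 90,
else unassigned); a best hit shared by multiple taxa demotes the call one
rank at a time. Exclusion flags (reference miss, predator DNA, contaminant,
coprophage, secondary prey) remove whole columns. Each removed MOTU is
attributed to exactly one rule, the first matching in the order
no-match → predator DNA → contaminant → coprophage → secondary prey →
low abundance, so the curation report's counts always reconcile with the
column difference.

One caveat is inherent to table-level curation: relative-abundance filtering
applied to MOTU columns can differ marginally from the same filter applied
to raw sequences before clustering, because clustering merges read variants.
The package starts from detection tables and documents this rather than
resolving it.

## Diet composition (wPOO)

For a group of samples, each sample with nₖ > 0 detected prey contributes
weight 1/S to the group profile, split evenly across its prey:
pᵢ = (1/S) Σₖ Iᵢₖ/nₖ. Samples with no detections are excluded from S; they
carry no information about relative use. Group profiles (species, season,
colony × season) are always wPOO over the pooled samples of the group, not
means of sub-profiles — the definition operates on individual faecal
extracts, and pooling keeps the weights interpretable as per-sample
occurrence shares. A config switch (`wpoo_weighting=False` semantics via
raw occurrence proportions) is deliberately *not* the default: weighting by
1/nₖ is what keeps prey-rich samples from dominating.

## Richness and sampling effort

Incidence counts come from the binary table: m samples, S_obs observed
prey, Q₁ uniques, Q₂ duplicates. Chao2 uses the classic minimum-estimator
form S_obs + ((m−1)/m)·Q₁²/(2Q₂), switching to the bias-corrected form
S_obs + ((m−1)/m)·Q₁(Q₁−1)/(2(Q₂+1)) when Q₂ = 0 (and always when
`chao2_bias_corrected` is set, since the exact variant used by any given
richness software is rarely stated). `samples_needed(g)` inverts the
standard sample-based extrapolation
S(m+m*) = S_obs + Q̂₀·[1 − (1 − Q₁/(mQ̂₀+Q₁))^{m*}], Q̂₀ = S_est − S_obs,
solving in closed form and verifying by stepping, and returns the smallest
total m+m* with S(m+m*) ≥ g·S_est (or m if already reached).

## Breadth, overlap and the RA3 null

Levins' breadth B = 1/Σpᵢ² is scale-free (inputs are renormalized) and
ranges from 1 to the number of resources used. Morisita-Horn overlap
C = 2Σpᵢqᵢ/(Σpᵢ² + Σqᵢ²) is computed after aligning the two profiles on
the union of their prey; absent prey count as zero, and adding prey absent
from both leaves C unchanged.

Significance of overlap uses Lawlor's randomization algorithm 3: every
profile's utilization values are independently permuted across *all*
resource states of the comparison group (the union of prey), so zeros move
and which resources are used is randomized while each profile's value
multiset — hence its Levins breadth — is retained. The test statistic is
either one pair's overlap or the mean pairwise overlap of several profiles
(both modes exposed, since published analyses rarely state which grouping
was tested). p = (1 + #{null ≥ observed})/(1 + iterations), upper-tail,
because the scientific claim is "overlap higher than expected by chance".
An RA2 variant (permute only within the observed support, retaining the
zero structure) is available for sensitivity analysis, not as default.

## Ordination and PERMANOVA

Overlap matrices become dissimilarities as D = 1 − C by default. The
square-root form √(1−C) is available by flag; the choice only matters for
metricity, and the PCoA consumer of these distances reports rather than
hides any negative eigenvalues. PCoA is the Gower double-centering
B = −½ J D² J followed by a symmetric eigendecomposition; coordinates are
eigenvectors scaled by √λ for eigenvalues above a relative tolerance of
1e-10, and a Cailliez correction can be requested explicitly. PCA of the
presence/absence matrix is a plain column-centered SVD; loadings rank the
prey driving sample similarity.

PERMANOVA is one-factor: SS_total = Σd²/n over all pairs, SS_within sums
squared within-group distances over group sizes, and
pseudo-F = (SS_between/(g−1))/(SS_within/(n−g)). The p-value permutes group
labels with the +1 correction. Perfect separation gives F = ∞, which
compares correctly in the permutation tail. Sequential multi-factor
partitioning is out of scope.

## RLQ and the fourth corner

The linking table L is analyzed in correspondence-analysis geometry:
P = L/L₊₊, row weights r, column weights c. Predictors (R) are
weighted-standardized under r, traits (Q) under c; binary indicators and
the ordinal size score are treated as quantitative. The fourth-corner
statistic for predictor x and trait q is r_xq = Σᵢⱼ pᵢⱼ x̃ᵢ q̃ⱼ, identical
to the Pearson correlation on the table inflated to one record per unit of
count — the brute-force oracle the tests compare against at machine
precision. RLQ decomposes the full crossed matrix M = X̃ᵀPQ̃ by SVD;
eigenvalues are squared singular values, they sum to the total co-inertia
ΣM², and the first eigenvalue bounds every single-pair squared correlation.

Inference combines two permutation models: model 2 permutes whole rows of
L (testing the R–L link; implemented as the equivalent permutation of
sample predictor rows), model 4 permutes whole columns (the Q–L link).
Each model yields a two-sided p with the +1 correction; the combined
model-6 p is the cell-wise maximum, which rejects only when both links are
supported and controls type I error when either is absent — the null
calibration test confirms the combined test is conservative. BH-FDR
(statsmodels) is applied across the whole trait × predictor grid jointly.

Habitat composition enters R through the additive log-ratio transform with
"farmland" as the default reference part and a pseudocount of half the
smallest non-zero proportion when zeros occur (multiplicative replacement);
a raw-proportion parameterization is available because published tables
often label predictors by raw habitat class. Predator identity enters as
one binary indicator per species present. Empty rows or columns of L are
dropped with a warning before any weighting, since they carry zero mass
but would contaminate the CA weights.

## Synthetic-data generator

The generator emulates the sampling design the analysis assumes: three
predator species over nine colonies (5/2/2), 11 sampling dates covering
mid-April to early October (17-day spacing, so all three seasons are
represented), one pooled community sample (15–20 pellets) per colony and
date, and six replicate smaller samples (1–3 pellets) per date for one
focal colony per species. Per pellet, prey i from a colony of species s at
date t is present with probability
logistic(αᵢ + φᵢ(t) + Σₘ B[s,m]·Q[i,m]):

* **αᵢ** — baseline detectability, Normal(−4.0, 1.3) plus an order offset
  (0 for Lepidoptera, −1.0 for Diptera, −1.7 otherwise), so synthetic
  diets are moth-dominated with dipterans second, matching the taxonomic
  skew of real long-eared-bat diets.
* **φᵢ(t)** — a Gaussian phenology bump of amplitude 2.0 (log-odds) at a
  prey-specific peak date with width 1.5–3 date steps, producing the
  seasonal turnover that lowers between-season overlap.
* **B** — the planted species × trait preference matrix in log-odds units;
  the default plants +1.5 for (auritus, closed habitats) and
  (macrobullaris, open habitats). +1.5 is the effect size at which the
  parameter-recovery simulations operate; at the default dataset size the
  planted cell is recovered with the correct sign essentially always, and
  the desk-scale profile (`small_config`: one colony per species, 60 prey,
  6 dates) was sized once so that repeated-simulation studies stay fast
  while retaining high power.

A sample detects the union of its pellets' prey; reads per detection are
negative binomial (mean 300, dispersion 1) shifted to ≥ 1 — the curation
logic depends only on the thresholds, not on the count law. To give
curation real work, the generator mixes in sub-threshold noise detections
(1–2 reads), a pool of rare MOTUs whose data-set totals are forced below
the 5-read minimum, and flagged contaminant/coprophage/secondary-prey/
predator-DNA/no-match MOTUs at normal read depth. Habitat compositions are
Dirichlet rows whose concentration depends on the resident species; the 17
binary habitat traits form two blocks (closed- vs open-habitat) positively
correlated within and negatively between, through a shared latent axis.

What the generator does **not** emulate: within-order abundance dynamics
and prey-prey dependence (each prey enters pellets independently), PCR and
primer bias, chimeras, or spatial movement of predators. One visible
consequence is that synthetic utilization distributions are much more even
than field diets — synthetic Levins breadths are far larger than values
measured on real guano — so passing tests demonstrate correctness of the
estimators and calibration of the tests, not that the generator reproduces
field effect sizes. All conclusions drawn from the synthetic study are
relative (planted vs null, between vs within season), never absolute.

## Numerical conventions

* Seasons are half-open calendar intervals [Apr 15, Jun 15), [Jun 15,
  Aug 15), [Aug 15, Oct 16), configurable; each date maps to exactly one
  season and dates outside the window are errors.
* All permutation p-values carry the +1 correction and are never zero;
  fourth-corner p-values are two-sided (associations can be negative),
  RA3 and PERMANOVA are upper-tail.
* Exceedance comparisons in permutation loops use a 1e-12 slack so the
  identity permutation always counts.
* PCoA eigenvalue positivity uses a tolerance relative to the largest
  eigenvalue (1e-10); RLQ/fourth-corner degenerate predictors (zero
  weighted variance) raise an error naming the column.
* Randomness everywhere flows through `numpy.random.default_rng(seed)`;
  identical seeds give byte-identical outputs, including the generator.
* The production permutation count is 9,999 (α = 0.05); the test suite and
  pipeline default use 199 for repeated-simulation studies, which is the
  package's chosen desk-scale resolution for p-values (smallest attainable
  p = 0.005).

## Known limitations

* Categorical fourth-corner statistics (χ², η²) are not implemented; all
  traits are treated as quantitative scores, which matches binary/ordinal
  trait tables but not nominal ones.
* PERMANOVA is one-factor; crossed or nested designs need an external tool.
* `samples_needed` trusts the Chao2 asymptote; when Q₁ is large relative
  to Q₂ the extrapolation is known to be a lower bound, and the returned
  effort should be read as "at least this many samples".
* The curated occurrence table treats detection as binary; read counts are
  used only by the curation thresholds, so any quantitative signal beyond
  occurrence is deliberately discarded, following the wPOO philosophy.
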