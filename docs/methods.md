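# Methods

`rfecomm` analyzes how root fungal endophyte (RFE) communities differ among
plant functional groups (PFGs) and what drives the turnover. This note
documents the statistical models, the synthetic world the package tests
itself against, and the numerical choices made where the design was open.

## The analysis pipeline

### Rarefaction and alpha diversity

Sequencing depth is uneven across samples, so OTU counts are subsampled
without replacement to a common depth — by default the minimum observed
sample total. The draw is multivariate hypergeometric per sample (each
retained read drawn from the sample's reads), performed once per run and
deterministic under a seed; we deliberately do not average over repeated
rarefactions. Zero entries can never gain counts, and every retained
sample sums exactly to the target depth.

Alpha diversity is OTU richness (count of OTUs with nonzero counts) and
Shannon entropy `H = -sum p_i ln p_i` in natural-log units (the default of
the community-ecology tools this pipeline mirrors; a log2 variant is a
trivial rescale by `1/ln 2`). Shannon is computed on post-rarefaction
counts.

### Group-difference GLMs and letter displays

Group differences in richness are tested with a Poisson GLM (log link);
Shannon diversity uses a Gaussian GLM (identity link). Fitting is IRLS via
statsmodels with convergence tolerance 1e-8. Pairwise group contrasts are
Wald tests on coefficient differences from the single full-factor fit
(z under Poisson, t under Gaussian), **unadjusted** at alpha = 0.05 by
default because the source analysis states a plain p < 0.05 rule; an
adjustment can be layered on by the caller. Significance letters come from
the insert-and-absorb compact letter display: two groups share a letter
exactly when their pairwise test is nonsignificant. The construction
guarantees the iff-property (splitting a column for one significant pair
never severs any nonsignificant pair, and columns only shrink), which the
test suite checks as a property rather than trusting the construction.

### Ordination and PERMANOVA

Community dissimilarity is Bray-Curtis on counts or relative abundances;
trait and abundance dissimilarities are Euclidean (absolute differences
for scalar traits). PCoA eigendecomposes the Gower-centered matrix
`-1/2 J D^2 J`. Negative eigenvalues (Bray-Curtis is generally
non-Euclidean) are reported raw and excluded from both the coordinates and
the proportion-explained denominator; a Lingoes correction is available by
flag for users who need a full embedding.

PERMANOVA is Anderson's one-way pseudo-F computed directly from pairwise
squared distances:

    SS_total  = sum_{i<j} d_ij^2 / N
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    F = (SS_between / (a-1)) / (SS_within / (N-a))

with `p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)` from label
permutations only, deterministic under a seed. 999 permutations by default
(the community default of the tools this replaces; the source analysis
does not state a count). Pairwise PERMANOVA runs each unordered group pair
on its sub-matrix; Benjamini-Hochberg adjustment across pairs defaults ON
with raw p always reported, since the source analysis does not state its
adjustment. An all-zero distance matrix (identical communities) is
degenerate: F is defined as 0 and p as 1. The implementation is authored
in-package because the permutation stream must be seedable; scikit-bio's
`permanova` serves as an independent cross-check in the tests.

For species-level analyses, replicate samples are aggregated by averaging
per-sample **relative abundances** over each species' replicates (option:
pool raw counts and renormalize). Averaging proportions was chosen so that
replicates with different sequencing depths contribute equally.

### Trait attribution (random forest)

The design has one row per unordered species pair from *different*
functional groups — 470 rows for the 32/6/4/3 study layout. The response
is the Bray-Curtis dissimilarity between the two species' aggregated
profiles; the predictors are the absolute differences of nitrogen
concentration (mg/g), root length (cm), root biomass (g), C:N, water
content (% fresh mass), and field abundance (individuals/m^2) — six
separate predictors in one joint forest.

The forest is bagged scikit-learn regression trees with
`mtry = max(1, p // 3)` candidate predictors per split (the regression
convention) and 500 trees by default. %IncMSE for predictor j is the mean
over trees of the increase in out-of-bag MSE when j's values are permuted
among that tree's OOB rows, expressed as a percentage of the mean per-tree
OOB MSE; importances are unscaled (not divided by their standard
deviation). Significance follows the response-permutation recipe: the
forest is refit on `n_null_reps` response-permuted copies of the design
and `p = (1 + #{null %IncMSE >= observed}) / (1 + n_null_reps)`, bounded
below by `1/(n_null_reps+1)` — so p < 0.01 requires at least 100 null
replicates.

Caveat, attached to every result object: species-pair rows are not
independent (each species enters many pairs), so these p-values are
anti-conservative in that respect. The classical alternative (MRM /
Mantel-style regression on distance matrices) is the right tool when that
matters; it is out of scope here.

### SPEC-OCCU marker OTUs

For each OTU and group H:

    specificity(OTU, H) = mean abundance of the OTU over H's samples
                          / sum over all groups of those group means
    occupancy(OTU, H)   = fraction of H's samples containing the OTU

Specificity sums to exactly 1 across groups for any observed OTU (the
denominator is the sum of the numerators). Occupancy is read as
*within-group* frequency — the Dufrene-Legendre fidelity component and the
only reading under which the SPEC-OCCU plot's 0.7 x 0.7 marker box makes
sense; the records carry both statistics so users can audit this choice.
An OTU is a marker of H when **both** statistics are >= 0.7, inclusive
(the boundary case specificity = occupancy = 0.7 is a marker). Abundance
means counts as supplied: the pipeline passes rarefied counts (group mean
counts are depth-confounded otherwise); relative abundances are an
equivalent alternative since specificity is scale-invariant within a
sample... within a *group*, strictly, which is why rarefying first is the
default.

Marker OTUs are then summarized by trophic mode (FUNGuild-style guild
strings consumed as an input table): every distinct mode combination —
single, dual, or triple — is its own category, canonicalized to the fixed
order Pathotroph-Saprotroph-Symbiotroph; multi-mode OTUs are never split
fractionally across modes. Unannotated markers count as "Unassigned". The
functional comparison applies Bray-Curtis + pairwise PERMANOVA to the
per-sample mode profiles.

## The synthetic world

The generator emulates the field design the pipeline targets: 45 species
in four functional groups (32 dicot forbs DF, 6 grasses G, 4 legumes L,
3 monocot forbs MF), 3 replicate root samples per species (135 samples),
with sequencing depths drawn uniformly from 2,000-20,000 reads — uneven on
purpose so rarefaction is a nontrivial step (real per-sample depths are
not published for the study design being emulated; this range is a free
choice of plausible MiSeq amplicon depths).

Composition model, per dataset:

1. a shared base composition is drawn from a symmetric Dirichlet
   (concentration 0.5: sparse, heavy-tailed, microbiome-like);
2. each group's base multiplies the shared base by a lognormal divergence
   factor (sd `group_divergence`, default 0.5) and renormalizes —
   `divergent_groups` restricts which groups diverge, and 0 gives an
   exactly exchangeable null;
3. planted markers (5 per group by default) are chosen among OTUs at or
   above the median base abundance — real marker OTUs are abundant taxa
   (they carry sizable sequence fractions), and markers planted on rare
   OTUs cannot survive rarefaction. Each is boosted `marker_boost`-fold in
   its home group and suppressed by the same factor elsewhere, so
   `marker_boost = 1` is an exact null (no suppression either);
4. each species' composition displaces its group base along a fixed
   standard-normal OTU loading vector, proportionally to
   `trait_effect_size` times the species' standardized nitrogen
   concentration — nitrogen is the designated driving trait, so recovery
   tests have an interpretable target;
5. each replicate applies lognormal per-OTU noise (sd `noise_sd`,
   default 0.5) and draws counts from a multinomial at its depth.

Step 1 + step 5 give overdispersed compositional counts in the
Dirichlet-multinomial spirit; the per-sample noise is logistic-normal
rather than Dirichlet so that `noise_sd = 0` degenerates cleanly to an
exact multinomial (a strict DM parameterization has no finite
concentration at zero noise).

Traits are drawn per species from group-specific normals (legumes
nitrogen-rich at 25 mg/g, grasses nitrogen-poor and deep-rooted, monocot
forbs wet-rooted; C:N derived from a drawn carbon concentration of
~420 mg/g), and abundance from group-specific lognormals with dicot forbs
most and monocot forbs least abundant. Unknown group labels get
hyperprior-drawn trait means so arbitrary test configurations work.
Taxonomy assigns phyla at fixed realistic probabilities (Ascomycota
dominant); guilds assign Unassigned with probability 0.3 and otherwise a
random 1-3-mode combination weighted toward single modes.

All draws come from one `numpy` Generator seeded from the config; the
group-divergence perturbation is drawn unconditionally so the stream
layout — and hence everything downstream — is comparable across configs
that differ only in which groups diverge. Identical configs give
byte-identical datasets.

### Default calibration

`trait_effect_size = 0.25` and `group_divergence = 0.5` were fixed once,
at design time, by two fidelity requirements: the natural (non-planted)
marker rate should be ~1% of OTUs, matching the rarity of markers in real
surveys of this design, while pairwise PERMANOVA still separates all
groups decisively (R^2 ~ 0.7). The documented strong-effect setting for
power and recovery scenarios is `trait_effect_size = 1.0` (or
`group_divergence = 1.0` on a single divergent group). These values were
not revisited after the acceptance tests were written.

### What a green test does and does not establish

The generator produces group-structured, overdispersed, compositional
count data with planted ground truth, which is what the pipeline's
statistics consume. It does **not** simulate read-level artifacts
(chimeras, tag switching, taxonomy-assignment error), phylogenetic
correlation among OTUs, spatial or temporal autocorrelation among samples,
or trait measurement error. Passing recovery tests therefore establish the
*statistical machinery* is correct and calibrated on its stated
assumptions — not that those assumptions hold for any particular field
dataset.

## Numerical choices and degenerate inputs

- Rarefaction: explicit depths exceeding a sample's total raise, naming
  the offending samples; `depth="min"` never raises.
- All-zero samples: richness 0, Shannon 0, with a warning; all-zero rows
  make Bray-Curtis undefined and raise.
- OTUs absent from every sample get specificity 0 in all groups and an
  `undefined` flag rather than NaN.
- PCoA eigenvalue positivity tolerance is `1e-10` x the leading
  eigenvalue; requesting more axes than positive eigenvalues truncates
  with a warning.
- GLM: Poisson requires integer responses; a group with an all-zero
  response under the log link warns (the MLE diverges).
- Letter display ties: columns are lettered in order of each column's
  first group, so output is deterministic.
- p-value conventions everywhere: `(1 + exceedances) / (1 + replicates)`,
  never exactly zero.

## Scaled-down test settings

Two acceptance checks scale simulation sizes for runtime on one CPU, never
thresholds: the random-forest recovery loop uses 25-tree forests (99 null
replicates — the minimum giving p <= 0.01; the planted signal is ~40x the
decoy importances, far above forest-size noise), and the PERMANOVA
calibration uses a reduced exchangeable community (12 species, 36 samples,
60 OTUs) for its 500 replicates.

## Known limitations

- One-way designs only: no multi-factor or stratified PERMANOVA, no
  dispersion (PERMDISP) test, so significant PERMANOVA results conflate
  location and dispersion differences, as in the analysis being mirrored.
- Pair-design non-independence (above).
- The letter display is minimal-or-near-minimal for realistic group
  counts (<= 8) but minimality is not guaranteed in general.
- Marker detection shares the indicator-species caveat: specificity and
  occupancy are descriptive statistics; no permutation test of marker
  status is performed (the IndVal product statistic and its test are
  deliberately out of scope).
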