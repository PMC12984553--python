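# rfecomm

Analysis pipeline for **root fungal endophyte (RFE) communities across
plant functional groups (PFGs)** — for microbial ecologists asking whether
functional groupings of host plants (grasses, legumes, dicot/monocot
forbs) carry distinct root mycobiomes, and which host traits drive the
turnover.

From an OTU count table, sample metadata, species traits, taxonomy, and
FUNGuild-style guild annotations, the package computes:

- **Alpha diversity and GLMs** — rarefaction to minimum depth, OTU
  richness and Shannon `H = -Σ p_i ln p_i`; group differences via Poisson
  (log-link) and Gaussian GLMs, rendered as compact letter displays.
- **Ordination and PERMANOVA** — Bray-Curtis dissimilarity
  `d(u,v) = Σ|u_i − v_i| / Σ(u_i + v_i)`, principal coordinates of the
  Gower-centered matrix `−½ J D² J`, and one-way/pairwise PERMANOVA with
  the pseudo-F

  `F = (SS_between / (a−1)) / (SS_within / (N−a))`,

  permutation p-values, and Benjamini-Hochberg adjustment across pairs.
- **Trait attribution** — a random forest regressing cross-group
  species-pair community dissimilarity on per-trait absolute differences
  (N, root length, root biomass, C:N, water content, abundance), with
  out-of-bag permutation importance (%IncMSE) and response-permutation
  p-values.
- **SPEC-OCCU marker OTUs** — per (OTU, group) specificity
  (group-mean abundance / sum of group means; sums to 1 across groups) and
  occupancy (fraction of the group's samples containing the OTU); OTUs
  with both ≥ 0.7 are markers, summarized by trophic mode and compared
  with a functional PERMANOVA.
- **Synthetic data** — a seeded generator emulating the 45-species /
  4-group / 3-replicate study design with planted marker OTUs and
  nitrogen-driven community turnover, so every stage is testable with
  known ground truth.

## Worked example

```python
from rfecomm import (SimulationConfig, simulate_dataset, rarefy,
                     bray_curtis, pairwise_permanova, build_pair_design,
                     fit_importance, spec_occu, marker_sets, recover_markers)

ds = simulate_dataset(SimulationConfig(seed=11))        # 135 samples x 300 OTUs
rare = rarefy(ds.otu_table, depth="min", seed=11)

pw = pairwise_permanova(bray_curtis(rare), ds.metadata["group"],
                        n_permutations=999, seed=11)
print(pw[0])
# PermanovaResult(statistic=133.181..., r_squared=0.5431..., p_value=0.001,
#                 n_permutations=999, groups=('DF', 'G'), p_adjusted=0.001)

design = build_pair_design(rare, ds.metadata, ds.traits)  # 470 cross-group pairs
imp = fit_importance(design, n_trees=200, n_null_reps=99, seed=11)
print(imp.importance.head(3).round(2).to_string(index=False))
# predictor  pct_inc_mse  p_value significance
#  nitrogen        10.21     0.01            *
# abundance         8.56     0.01            *
#  cn_ratio         7.79     0.01            *

records = spec_occu(rare, ds.metadata, threshold=0.7)
sets = marker_sets(records, rare, ds.metadata)
print({g: len(v) for g, v in sets.markers.items()})
# {'DF': 5, 'G': 7, 'L': 5, 'MF': 5}
print(recover_markers(records, ds.truth.markers))
# {'sensitivity': 1.0, 'fdr': 0.0909..., 'n_planted': 20, 'n_flagged': 22, 'n_recovered': 20}
```

Reading the output: all six group pairs separate (pseudo-F ≫ 1 at the
minimal attainable p = 1/1000), nitrogen distance is the strongest
predictor of community turnover — the generator plants it as the driving
trait — and the ≥ 0.7 specificity/occupancy filter recovers every planted
marker, plus a handful of naturally group-specific OTUs.

The same stages are available from a shell:

```sh
rfecomm simulate --out data/ --seed 11
rfecomm diversity --table data/otu_table.tsv --metadata data/metadata.tsv --out out/ --seed 11
rfecomm permanova --table data/otu_table.tsv --metadata data/metadata.tsv --out out/ --seed 11
rfecomm importance --table data/otu_table.tsv --metadata data/metadata.tsv \
    --traits data/traits.tsv --out out/ --seed 11
rfecomm markers --table data/otu_table.tsv --metadata data/metadata.tsv --out out/ --seed 11
rfecomm functional --table data/otu_table.tsv --metadata data/metadata.tsv \
    --guilds data/guilds.tsv --out out/ --seed 11
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on the default synthetic world:
it generates the 135-sample dataset, rarefies, fits the diversity GLMs with
letter displays, runs PCoA and all pairwise PERMANOVAs, fits the
trait-attribution forest on the 470 cross-group species pairs, applies the
SPEC-OCCU marker filter and scores it against the planted truth, and
compares marker trophic-mode compositions — printing each stage's results
and writing the JSON result object to `--out` (~30 s on one CPU).

See `docs/methods.md` for the models, the synthetic world's assumptions,
and numerical conventions.
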