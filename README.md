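# nichepart

Trophic-niche partitioning analysis for diet DNA-metabarcoding data.

`nichepart` implements the full analysis chain used to compare the diets of
sympatric insectivorous predators — the motivating system is three cryptic
long-eared bat species (*Plecotus auritus*, *P. austriacus*,
*P. macrobullaris*) whose prey spectra are read out of faecal pellets by COI
metabarcoding — from raw MOTU detection tables to trait-level inference of
foraging-habitat preferences:

1. **Curation** of samples × MOTU read-count tables: a strict within-sample
   relative-abundance filter (cells < 0.1‰ of the sample's reads are
   zeroed), a data-set-wide minimum read count per MOTU (< 5 reads dropped),
   tiered taxonomy assignment (species at ≥ 98% coverage and ≥ 99%
   identity; genus > 96%; family > 90% identity; ambiguous multi-taxon hits
   demoted one rank), and removal of contaminants, coprophages, secondary
   prey and predator DNA, with a reconciled report of every removal.
2. **Diet composition** as weighted percent of occurrence (wPOO): each
   faecal sample carries unit weight split evenly over the prey it
   contains, giving a utilization distribution *p* with
   pᵢ = (1/S) Σₖ Iᵢₖ/nₖ.
3. **Richness**: incidence counts (uniques Q₁, duplicates Q₂) feed the
   Chao2 minimum estimator S_est = S_obs + ((m−1)/m) · Q₁²/(2Q₂) and the
   sample-based extrapolation that answers "how many samples to reach 95%
   of the asymptote".
4. **Niche breadth and overlap**: Levins' B = 1/Σpᵢ² and the Morisita-Horn
   index C = 2Σpᵢqᵢ/(Σpᵢ² + Σqᵢ²), with significance from Lawlor's RA3
   randomization (each consumer's utilization values permuted across all
   resource states, retaining niche breadth).
5. **Ordination and tests**: PCoA (Gower double-centering, negative
   eigenvalues reported), PCA of the presence/absence matrix, and
   one-factor PERMANOVA with a permutation pseudo-F.
6. **Trait inference**: the R (sample predictors: predator species and
   ALR-transformed colony habitat composition), L (samples × prey) and Q
   (prey × 19 ecological traits) tables are crossed by RLQ ordination and
   cell-wise fourth-corner correlations, tested by combining whole-row
   (model 2) and whole-column (model 4) permutations of L as
   p₆ = max(p₂, p₄), with Benjamini-Hochberg FDR across the grid.

A synthetic-data generator reproduces the study design (3 species, 9
colonies, 11 biweekly dates, pooled "community" samples of 15–20 pellets
and replicate "smaller" samples of 1–3 pellets) with planted
species × prey-trait preference effects and recorded ground truth, so every
stage is verifiable at desk scale.

## Worked example

```python
import nichepart as npk

table, assignments, traits, habitat, manifest = npk.worked_example()

pa = npk.wpoo(table.subset(["A1", "A2", "A3"]))   # auritus samples
pb = npk.wpoo(table.subset(["B1", "B2", "B3"]))   # austriacus samples
print({prey: float(w) for prey, w in pa.round(4).items()})
print("Levins:", npk.levins(pa), npk.levins(pb))
print("Morisita-Horn:", round(npk.morisita_horn(pa, pb), 4))
inc = npk.incidence_summary(table.subset(["A1", "A2", "A3"]))
print("Chao2:", npk.chao2(inc))
```

prints

```
{'m01': 0.4167, 'm02': 0.25, 'm03': 0.0833, 'm04': 0.0833, 'm06': 0.1667}
Levins: 3.6000000000000014 6.75
Morisita-Horn: 0.1957
Chao2: 8.0
```

Sample A2 contains two prey, so each contributes 1/2 of its unit weight;
`m01`, found in all three auritus samples, accumulates
(1/3)(1/4 + 1/2 + 1/2) = 5/12 ≈ 0.4167 of the diet. The auritus profile is
spread over five prey with effective breadth 3.6; the two species share only
`m06`, giving a low overlap of 9/46 ≈ 0.196. Three auritus samples hold 5
observed prey, of which Q₁ = 3 uniques and Q₂ = 1 duplicate, so Chao2
estimates 5 + (2/3)·9/2 = 8 prey at the asymptote.

The same objects drive the command line:

```bash
nichepart simulate --seed 3 --out-dir data/
nichepart curate --detections data/detections.tsv --meta data/metadata.tsv \
    --assignments data/assignments.tsv --out-dir curated/
nichepart diet --occurrence curated/occurrence.tsv \
    --meta curated/metadata_occurrence.tsv --group-by species --out-dir diet/
nichepart overlap --profiles diet/wpoo_profiles.tsv --iters 9999 --seed 1 \
    --out-dir overlap/
nichepart pipeline --simulate --seed 1 --perms 999 --out-dir run/
```

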