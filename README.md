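# morphdiv

2D geometric morphometrics for family-level **morphological disparity**:
from TPS landmark/semilandmark files to Procrustes-aligned shapes, species
means, tangent-space PCA, and disparity comparisons with permutation
inference.

The package grew out of a classic question in evolutionary morphology: are
tenrecs (Tenrecidae) — often described as an exceptionally diverse radiation
— really more morphologically diverse in cranial shape than their closest
relatives, the golden moles (Chrysochloridae)? Answering it requires a
pipeline that (i) turns digitized skull photographs (landmarks plus outline
semilandmarks in dorsal, ventral and lateral views) into comparable shape
variables, (ii) summarises each species by its mean shape in a common
morphospace, and (iii) quantifies and tests family-level dispersion. Museum
landmark data are rarely redistributable, so the package also ships a
synthetic skull-landmark generator with known truth, which makes every stage
of the pipeline testable end to end — including the *masking* phenomenon,
where an over-sampled, low-variance genus (e.g. the 19 *Microgale* species
among 31 tenrecs) drags down a family's apparent disparity.

## The method

1. **Input.** TPS files (one record per specimen: `LM=`, coordinates,
   optional `CURVES=`/`POINTS=` blocks, `ID=`, `SCALE=`), a sliders file of
   before/slide/after triples, and a specimen table
   (`specimen_id,species,family,view[,side]`). Left-side specimens are
   mirrored back before alignment.
2. **Outline economy.** Semilandmark counts follow the length-accuracy rule:
   the smallest `n` such that `n` equally spaced points measure the outline's
   length to ≥ 95% of the densely digitized length.
3. **Alignment.** Generalized Procrustes analysis: centre, scale to unit
   centroid size `CS = sqrt(Σᵢ ‖xᵢ − x̄‖²)`, rotate to an iterated consensus
   (proper rotations only), sliding each semilandmark along its
   neighbour-chord tangent to the position minimizing Procrustes distance to
   the consensus.
4. **Ordination.** Species-mean shapes are flattened and decomposed by PCA
   on the covariance matrix; the leading axes holding 95% of the variance
   define the morphospace.
5. **Disparity.** For a family of `n` species with scores `PCnᵢ` on the `m`
   retained axes and family centroid `PCcᵢ`,

   `diversity = (1/n) · Σ_species sqrt( Σᵢ (PCnᵢ − PCcᵢ)² )`

   — the mean Euclidean distance of member species to their own family
   centroid, reported with its standard error.
6. **Inference.** Welch's two-tailed t on the per-species distances; a
   label-shuffling permutation test (1,000 shuffles, group sizes preserved)
   on the disparity difference; and PERMANOVA (pseudo-F on Euclidean
   distances, 999 permutations) on morphospace positions.

## Worked example

```python
import morphdiv as md

# a synthetic study at the default sampling frame: 31 tenrec-like species
# (19 of them a tight Microgale-like cluster) vs 12 golden-mole-like species
synth = md.generate_dataset(md.default_config(seed=1, view="dorsal"))
dataset = md.Dataset(configs=synth.configs, sliders=synth.sliders,
                     table=synth.table)
res = md.run_view(dataset, seed=101,
                  family_order=["Tenrecidae", "Chrysochloridae"])

print(f"retained axes: {res.retained}")
print(f"Tenrecidae     {res.disparity_first.mean:.4f} ± {res.disparity_first.se:.4f}")
print(f"Chrysochloridae {res.disparity_second.mean:.4f} ± {res.disparity_second.se:.4f}")
t, df, p = res.welch
print(f"Welch t={t:.2f} (df={df:.1f}, p={p:.2f})")
print(f"permutation p={res.permutation.p_value:.3f}  "
      f"null range [{res.permutation.null_min:.4f}, {res.permutation.null_max:.4f}]")
print(f"npMANOVA F={res.manova.pseudo_F:.2f} R2={res.manova.r_squared:.2f} "
      f"p={res.manova.p_value:.3f}")
```

prints

```
retained axes: 2
Tenrecidae     0.0182 ± 0.0021
Chrysochloridae 0.0178 ± 0.0022
Welch t=0.11 (df=30.9, p=0.91)
permutation p=0.958  null range [-0.0211, 0.0207]
npMANOVA F=82.93 R2=0.67 p=0.001
```

Read: the two families occupy clearly distinct regions of the morphospace
(PERMANOVA F = 82.9, p at the 1/1000 permutation floor), yet the tenrec-like
family is **no more dispersed** than the golden-mole-like one (disparity
0.0182 vs 0.0178, permutation p ≈ 0.96) — its 19-species low-variance
cluster is masking the diversity of the remaining species. Thinning the
cluster to 5 species (`md.subset_species`) and re-running the whole pipeline
from alignment onward raises the tenrec-like disparity to 0.0227.

The same workflow is available from the shell:

```bash
morphdiv simulate --seed 1 --out data/
morphdiv align --tps data/landmarks.tps --sliders data/sliders.txt \
               --table data/specimens.csv --out aligned.csv
morphdiv pca --aligned aligned.csv --table data/specimens.csv --out scores.csv
morphdiv disparity --scores scores.csv --out table1.csv
morphdiv permtest --scores scores.csv --n-perm 1000 --seed 101
morphdiv npmanova --scores scores.csv --n-perm 999 --seed 102
```

or, configuration-driven, `morphdiv run-all --config run.yaml` (see
`morphdiv.pipeline.run_analysis` for the YAML schema).

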