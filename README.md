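# trabqtl

Genetic dissection of trabecular bone structure, as a reusable,
tested pipeline.  `trabqtl` targets the workflow used to map bone
micro-architecture loci in chromosome-substitution (consomic) mouse
panels: 3D morphometry of segmented micro-CT volumes, many-to-one
screening of a consomic panel against the host strain, and
block-partition QTL mapping on subconsomic strains that carry donor
fragments of a single chromosome.  It is aimed at skeletal geneticists
and quantitative-genetics method developers who want every stage of
that workflow to be scriptable and verifiable on synthetic data.

## What it computes

**Morphometry** (`trabqtl.morphometry`) — the six standard trabecular
parameters from a binary voxel volume with a slab ROI below the growth
plate:

- BV/TV: bone volume fraction (exact voxel counting);
- Tb.Th, Tb.Sp: mean trabecular thickness and separation by
  inscribed-sphere (local-thickness) fitting, with
  Tb.Sp(V) = Tb.Th(complement of V) by construction;
- Tb.N = 1/(Tb.Th + Tb.Sp) (direct 3D model; plate model behind a flag);
- Conn.D = β₁/TV, with β₁ = β₀ − χ + β₂ from the 3D Euler
  characteristic χ (26-connected foreground, 6-connected background);
- SMI = 6·V·S′/S², the structure-model index, with S′ the derivative
  of surface area under infinitesimal dilation of the triangulated
  surface (0 for ideal plates, 3 for ideal rods, 4 for spheres).

**Panel screen** (`trabqtl.screen`) — Dunnett's many-to-one test of
every strain against the control per parameter (equicorrelated
multivariate-t; seeded Monte Carlo for unbalanced panels), ascending
strain ordering, the 6×6 Spearman correlation matrix over individual
animals, and the nonadditivity index

    100 · Σ_s (mean_s − mean_control) / (mean_donor − mean_control)

summed over significant consomic strains — values far above 100%
indicate epistasis.

**Block mapper** (`trabqtl.genmap`) — aligns subconsomic strains to
minimize the donor-fragment difference between neighbors (exact
subset-DP optimum, host and donor parents anchored at the ends),
partitions the chromosome into breakpoint-delimited blocks, runs
two-sided Welch tests on every neighboring pair at a Bonferroni
threshold of α divided by the number of pairs, and localizes each
significant pair to the block(s) on which the two genotypes differ,
with the donor-allele effect direction.

**Synthetic data** (`trabqtl.phantoms`, `trabqtl.panels`) — phantoms
(plates, rod lattices, balls, tori) with closed-form ground truth, and
consomic/subconsomic panel simulators with planted per-chromosome
effects, a planted epistasis gap, and planted block-level QTL.

## Worked example

```
$ trabqtl run --seed 7 --out demo_out
```

runs simulate → screen → map-blocks and writes all reports.  From a
run with seed 7:

- `screen_summary.json` reports `nonadditivity_percent: BVTV 1385.1,
  TbN 1303.7` — the summed effects of the significant
  single-chromosome substitutions are ~14× the parental difference,
  i.e. strongly nonadditive (a purely additive panel would sum to
  100%), and `strain_order` puts the donor parent (MSM) lowest and the
  host (B6) highest for BV/TV.
- `qtl_calls.json` lists ten blocks and the planted QTL calls, e.g.
  `{"blocks": ["Block10"], "parameter": "BVTV", "direction":
  "decrease", "pair": ["B6", "Sub-10"], "p": 0.0002}` — the donor
  allele in the most telomeric block lowers bone volume fraction.

Phantom morphometry from Python:

```python
from trabqtl import PhantomSpec, make_phantom, measure_all

plate = make_phantom(PhantomSpec(
    "parallel_plates", voxel_um=10, shape_voxels=(100, 100, 100),
    plate_thickness_um=100, plate_spacing_um=400))
print(measure_all(plate))
# BVTV=0.2, TbN=2.0/mm, ConnD=0.0, TbSp=0.4 mm, SMI=0.0, TbTh=0.1 mm
```

matching the closed forms t/(t+s), 1/(t+s), t and s exactly.

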