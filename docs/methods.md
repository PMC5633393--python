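# Methods

This note documents the models, estimators, defaults and numerical
choices behind `trabqtl`, and what the synthetic-data tests do and do
not establish about real data.

## Coordinate and image conventions

Volumes are 3D boolean arrays (foreground = bone) with an isotropic
voxel edge in µm; anisotropic voxels are rejected.  Axis 0 is the bone
axis.  The ROI is the half-open axial slab
`[reference + offset, reference + offset + width)` with 0-based slice
indices; the reference (growth-plate) slice is supplied by the user —
no growth-plate detection is attempted.  Structures truncated by the
ROI faces are included with no edge correction, matching the usual
slab-ROI practice; estimates on structures that leave the box are
therefore boundary-censored, and Tb.Sp of a near-empty volume is
explicitly flagged as such.

## Morphometry estimators

**BV/TV** is exact integer counting.

**Local thickness** (Tb.Th, and Tb.Sp via the complement) follows the
inscribed-sphere definition: thickness at a point is the diameter of
the largest sphere containing the point that fits in the phase.  The
implementation visits the distinct Euclidean-distance-transform radii
in descending order, quantized to 0.5 voxel, and marks every voxel
each radius class reaches; the quantization bounds the diameter error
by half a voxel, and the distance-to-voxel-centre convention adds at
most another half voxel.  On plate phantoms with even thickness in
voxels the recovered Tb.Th is exact; balls are recovered to ~1 voxel.
No installed package provides this operator, so it is implemented
here.

**Euler characteristic** is the vertex − edge + face − cell count of
the union of closed voxel cubes, fully vectorized through shifted
logical ORs.  The closed-cube complex realizes exactly the 26-connected
foreground / 6-connected background convention, which must be fixed
for χ to be well defined.  Tests verify it against an independent
set-based brute-force count and against the configuration-count
implementation in scikit-image.  **Conn.D** is β₁/TV with
β₁ = β₀ − χ + β₂; β₀ from 26-connected labelling, β₂ from 6-connected
background components that do not touch the image boundary.

**SMI** is 6·V·S′/S².  The binary volume is embedded as an
approximate signed distance field (outside-EDT minus inside-EDT,
shifted half a voxel so the zero level lies midway between boundary
voxel centres), smoothed with a σ = 1 voxel Gaussian, and triangulated
by marching cubes at level 0.  S′ is a central difference obtained by
displacing the vertices of that *same* mesh ±0.25 voxel along their
outward normals.  Two choices matter and were made deliberately after
measuring the alternatives on phantoms with known SMI:

- re-running marching cubes at a dilated iso-level changes the mesh's
  voxelization facets as well as its position, biasing S′ by tens of
  percent; displacing a fixed mesh keeps the derivative consistent
  with the measured surface (ball: 4.03 vs 2.9 for re-triangulation);
- the un-smoothed field overestimates S by ~8% on curved surfaces;
  the light smoothing brings S within 1% without disturbing features
  of ≥ 10 voxels.

Surfaces crossing the image border are left open (no caps), so
plates and rods that run out of the box behave as unbounded.  The
sign of S′ is kept: predominantly concave structures legitimately
give negative SMI.  Measured limits at 10-voxel features: plate 0.00,
rod 3.08, ball 4.03.

**Tb.N** defaults to the direct 3D model 1/(Tb.Th + Tb.Sp), which
matches the verbal definition "number per unit length" and modern
practice; the historical plate model (BV/TV)/Tb.Th is available
behind a flag.  For parallel plates the direct model equals the
line-intercept count exactly; for rod lattices the two differ by
construction (the background inscribed sphere spans the diagonal gap,
not the pitch), so no intercept equivalence is claimed there.

The commercial software used for the original measurements implements
unpublished variants of Tb.N and SMI; numerical identity with
per-strain values measured by that software is not claimed, only
definitional fidelity and correctness in the phantom limits.

## Phantoms

Phantoms are generated implicitly — the defining inequality is
evaluated at voxel centres — so geometry can be rigidly rotated about
the volume centre without resampling, and generation is deterministic.
Patterns are centred on the volume so plates/rods at the faces are
clipped symmetrically; BV/TV of the plate phantom is exact when
thickness and period are integer voxels.  Features below 2 voxels are
rejected as unrepresentable.

## Consomic panel simulator

Study conditions: 26 single-substitution strains (whole autosomes,
four centromeric/telomeric split chromosomes, X, Y, Mt — Y and Mt are
ordinary substitution labels) plus host and donor parents, 8
animals/strain at 10 wk.  An animal's value is the strain mean plus
i.i.d. Gaussian noise per parameter (real panels report mean ± SE, so
nothing finer is modelled).  Host/donor means and noise SDs are fixed
at values typical of 10-wk proximal-tibia metaphyses (e.g. BV/TV
0.155 vs 0.060, SD 0.012).

Epistasis is modelled as the gap between the donor parent and the sum
of single-substitution effects: consomic strain means carry their full
per-chromosome effect, while the donor — which carries every
substitution — expresses only the parental difference.  Auto-generated
effects share one strain-weight vector across BV/TV, Tb.N, Conn.D,
Tb.Sp and SMI (producing the strong cross-parameter correlations seen
in real panels, |ρ| ≳ 0.6) with weights bounded inside the parental
range, scaled so the effects sum to `epistasis_coefficient` × the
parental difference.  The default coefficient is 13.9, i.e. a
nonadditivity index near 1390% when all strains reach significance;
Tb.Th gets independent small two-sided effects and stays uncorrelated.
No generative mechanism for the interaction itself is modelled — the
shrinkage-at-the-full-genotype construction is the simplest mechanism
with the observed signature.

What passing tests show: the screen, ordering, correlation and index
machinery are correct on panels with known architecture.  What they do
not show: robustness to unequal variances across strains, batch/age
structure, or non-Gaussian tails, none of which the generator
emulates.

## Dunnett screen

Classical equicorrelated many-to-one comparisons with the pooled
within-group variance (df = N − g).  For balanced panels the
distribution of max|Tᵢ| is evaluated by 48-point Gauss–Legendre
quadrature over the pooled-SD chi factor × 48-point Gauss–Hermite over
the shared control variate; k = 1 reproduces the two-sided t p-value
to 1e-5 and k = 3 matches `scipy.stats.dunnett` to ~1e-3.  Unbalanced
panels use a seeded 40 000-draw Monte-Carlo reference with the exact
correlation λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)).  Groups with zero pooled
variance report p = 1 with a `degenerate` flag.  Missing animals are
dropped listwise per parameter.  Family-wise type-I error measures
0.052 over 2000 simulated null panels at α = 0.05.

The correlation matrix is computed over pooled individual animals
(midrank ties), as in the original figure legend; a per-strain-means
mode is available behind a flag.  The nonadditivity index sums only
strains flagged significant at α (an option includes all), excludes
both parents, and is invariant under shared affine rescaling of the
parameter.

## Subconsomic mapping

Strain alignment minimizes the total symmetric-difference length (Mb)
of donor-interval sets between neighbors.  The exact optimum is found
by dynamic programming over subsets (Held–Karp style) for ≤ 12
strains, with the host parent anchored first and the full-donor parent
last (disable-able); reconstruction greedily picks the smallest
strain label that preserves optimality, so ties are resolved
lexicographically and deterministically.  Larger panels fall back to
greedy nearest-neighbor with a warning.

Blocks are the atoms generated by all interval endpoints, merged where
no strain in the panel distinguishes adjacent atoms, numbered from the
centromeric end.  This is a disjoint tiling: when a significant pair
differs in several non-adjacent atoms the call is reported once with
the full candidate set and an `ambiguous` flag rather than as a single
spanning "block" — nested spanning regions (as in real panels, where
one pair's differing region can contain another pair's) are thus
representable without overlapping block definitions, and no
cross-comparison subtraction of effects is attempted.

Neighbor tests are two-sided Welch t-tests.  The per-test threshold
is the family α divided by the realized number of pairs — the
convention of the original analysis — not by pairs × parameters.  A
consequence, quantified here, is that multi-parameter testing inflates
the family error: with 3 parameters over 9 pairs, ~10% of null panels
show at least one spurious flag.  The default pair list is the n−1
adjacent pairs; extra comparisons (e.g. a parental closing pair) can
be injected explicitly and enter the divisor.

Breakpoints read from marker tables are placed at the midpoint between
flanking discordant markers (outer-bound mode available).  Interval
endpoints are therefore valid on markers, chromosome ends, or
midpoints of consecutive markers; a write-read cycle of a genotype map
is allele-exact and idempotent at interval level, and block structure
is invariant because strains sharing a breakpoint marker shift
identically.

## Default subconsomic geometry and recovery conditions

The default map uses a 102.254 Mb chromosome with 13 markers and ten
blocks; the eight fragment strains form a chain in which each adjacent
pair differs in one block except the donor-side pair, which differs in
two non-adjacent blocks and carries no planted QTL.  The paper-style
default plants four QTL: Block2 raises Tb.Th, Block6 raises BV/TV,
Block8 and Block10 lower BV/TV and Tb.N (6 replicates/strain at 6 wk).

The quantitative recovery study uses the single-parameter variant
(four BV/TV-only QTL, effects ~10× the SE of a strain mean, 9 tests at
the 0.05/9 threshold): 200 seeded panels give ≥ 95% exact recovery of
the planted block set and directions, the residual failures being the
~2.7% familywise false-positive mass on the five effect-free pairs.
Under the 3-parameter default the same planted effects are always
recovered but exact-set recovery is capped near 90% by the pairs-only
Bonferroni divisor — a property of the original testing convention,
not of the implementation.

## Problem sizes

Defaults were chosen so the full validation runs on a laptop-class
single core: phantoms up to 200³ voxels (the SMI working size),
500 random ≤ 6³ volumes for the Euler oracle, 100 panels for the
alignment oracle, 200 panels for QTL recovery and 2000 for screen
calibration; the complete suite takes under a minute.

## Known limitations

- No grayscale segmentation, BMD calibration, cortical metrics or
  growth-plate detection; inputs are already-binary volumes.
- Local thickness and χ assume clean binary masks; speckle noise
  should be removed upstream.
- The Dunnett implementation assumes homoskedastic groups (classical
  model); the neighbor tests do not (Welch).
- QTL calls are per comparison; effects of nested regions are not
  decomposed.
- Candidate-gene annotation, synteny lookup and LOD-based interval
  mapping are out of scope.
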