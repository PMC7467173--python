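# Methods

`domfit` places rigid protein domain models into intermediate-resolution
(~8–12 Å) cryoEM density and selects a mutually consistent arrangement of
all domains. This note records the models, the numerical choices, and what
the synthetic benchmarks do and do not demonstrate.

## Density model and grids

A map is a scalar field on a regular grid in right-handed xyz order. The
grid corner sits at `origin`; the center of voxel `(i, j, k)` is
`origin + (i + ½, j + ½, k + ½)·voxel_size`. Files are MRC2014 mode-2
(float32); maps stored with permuted axis order (MAPC/MAPR/MAPS ≠ 1,2,3)
are canonicalized on read via gemmi. Map alignment is out of scope: inputs
to composite-map construction must already be aligned, and `resample`
(trilinear, zero outside the source extent) brings them to a common grid.

Simulated density places an isotropic Gaussian on each atom, scaled so its
grid sum equals the atomic mass, with width

    sigma = resolution / (pi·sqrt(2)),

a common convention relating a Gaussian's Fourier falloff to nominal
resolution; the convention string is recorded in the map metadata and the
width is configurable. Gaussians are truncated per axis at 4 sigma, which
keeps the grid sum within ~0.1% of the total mass when the grid pads the
model by ≥3 sigma.

## Composite maps

Focused reconstructions of a flexible particle resolve different regions
at different quality. To merge aligned focused maps: each map is
normalized to [0, 1]; non-reference maps are histogram-matched to the
reference by empirical quantile mapping (linear interpolation between
sorted values, stable tie order, so the remap is monotone and idempotent
against a fixed reference); the merged value at a voxel is the
density-weighted mean `Σ dᵢ² / Σ dᵢ`, i.e. each map's weight at a point is
proportional to its own (normalized) density there, and exactly 0 where
all maps are 0. The operation is permutation-invariant in its inputs.

## Rigid-body docking

Docking one domain into a map is a six-dimensional search scored by
model–map density overlap.

**Translations** are restricted to up to 50 000 high-density voxel
centers, selected greedily in order of decreasing density with a 2 Å
minimum separation (ties broken by voxel index; the greedy result is
checked against a quadratic-time reference implementation in the tests).

**Rotations** come from a deterministic super-Fibonacci quaternion
spiral, sized at 4× the ideal sphere-covering count for the requested
angular step (default 15°), which empirically keeps both nearest-neighbor
spacing and covering radius below the step; the identity is always
included.

**Coarse score.** For rotation R and candidate point p, the score is the
voxel sum of (simulated density of the rotated domain, mean-subtracted
within its own footprint) times the map, with the domain centroid placed
at p. Because candidate points are voxel centers and the Gaussian
simulation is translation-equivariant under integer-voxel shifts, the
score over *all* points for one rotation is exactly an FFT
cross-correlation of the map with the rotated-domain kernel (plus a
second correlation with the footprint indicator for the mean term). The
FFT path is therefore bit-equivalent (to ~1e-13) to simulating each pose
and summing voxel products, which is how the test oracle computes it.
Kernels are cropped per rotation to the rotated bounding box and batched
by shape so FFT plans are reused. An optional flag normalizes scores by
the rotation's self-overlap norm (off by default).

**Refinement.** The top candidates by coarse score (default 1000) are
locally optimized over the 6 rigid-body parameters to maximize a masked
real-space correlation: Pearson correlation between simulated and
observed density over voxels within `mask_radius` (default 4 Å) of the
pose's atoms. During optimization (Powell, small iteration budget) the
mask is frozen at the starting pose for speed; the reported refined score
is re-evaluated with a fresh mask at the final pose, and a move is only
accepted if that honest score does not decrease — so refinement never
lowers the masked RSC.

**Redundancy pruning** walks placements by descending refined score and
keeps one iff its CA-RMSD (no superposition) to every kept placement
exceeds 11 Å, stopping at 200. Ties are broken by input order.

## Assembly scoring

Assembly assigns to each *slot* one candidate placement or NOT_FOUND.
Domains sharing more than 20% of their residues (alternative parses of
the same region) share one slot. The total score (lower is better) is

    w_dens · Σ_placed (−RSC_i)
  + Σ_pairs [ w_centroid_energy · E_pair + w_proximity · prox ]
  + w_distance_constraint · Σ_links penalty
  + n_not_found · not_found_offset

with the published weight magnitudes as defaults: w_dens = 260,
w_proximity = 1000, w_centroid_energy = 150, w_distance_constraint =
30 000. Density enters as −RSC so those magnitudes keep their meaning as
relative term scales under lower-is-better optimization.

The functional forms of the inter-domain terms are this package's
choices (the protocol fixes their roles and signs, not their shapes):

* **Interface energy** is a residue-level potential on one bead per
  residue (CB, else CA): an attractive well of depth 0.05 for bead–bead
  distances in 5–8 Å with linear ramps over 4–5 and 8–9 Å, and quadratic
  soft-sphere repulsion below 4 Å (scale 10 per pair). The well depth is
  set so a genuine two-domain interface (tens of contacts) scores a few
  negative units — commensurate with the weight magnitudes above, which
  were fitted for a coarse-grained energy of that scale. The pair energy
  is evaluated as E(combined) − E(separated by 200 Å), so isolated pairs
  score exactly 0.
* **Pairwise interface optimization** precedes energy evaluation: the two
  domains slide along their inter-centroid axis (smallest displacement
  first, split equally, total ≤ 5 Å) to reach contact (some CA pair
  < 8 Å) without clash (no CA pair < 4 Å). If the pair is still severely
  clashing (soft-sphere clash score > 3), clashing residues that are
  loops (CA-geometry P-SEA assignment) and surface-exposed (< 10 CA
  within 12 Å in their own domain) are removed before rescoring. A pair
  that remains severely clashing after this is screened out by assigning
  it a large positive energy (+50, configurable) — the analogue of an
  exploding hard-sphere term at inter-penetration. All pairwise results
  are cached symmetrically before sampling.
* **Linker proximity**: for chain-adjacent domains, the gap between the
  C-terminal CA of the earlier domain and the N-terminal CA of the later
  one must be closable by the unmodeled linker. Penalty is 0 up to
  `n_link · 3.5 Å + 4 Å` and quadratic beyond; 3.5 Å is a safely
  spannable per-residue span, 4 Å a base allowance. Same-chain pairs that
  are not sequence-adjacent carry no penalty.
* **Cross-links** give a flat-bottom penalty per link: 0 up to the CA–CA
  threshold (default 30 Å, the accepted reach of BS3-type reagents),
  linear with slope 1 beyond, capped at 30. Links with an endpoint in an
  unplaced (NOT_FOUND) domain contribute a configurable missing-data
  penalty, 0 by default — unplaced domains are not punished through
  their links, the NOT_FOUND offset governs that trade-off instead.
  The NOT_FOUND offset defaults to 0: placing a domain is then favored
  exactly when its weighted density gain and interface terms are jointly
  favorable, and any domain with positive RSC beats NOT_FOUND unless its
  placements clash.

Intra-slot and inter-slot cross-link penalties, interface energies and
proximity terms are collapsed into per-slot vectors and per-slot-pair
matrices, so a Monte Carlo move costs a handful of table lookups; the
table-based score is verified against the explicit per-term scorer in the
tests (agreement to 1e-6, and the reported per-term breakdown re-weights
to the total exactly).

## Annealing and the iterative loop

Sampling runs many independent trajectories (default 50 000, desk scale
200), each performing `n_steps` Metropolis moves (default 200 000, desk
scale 5 000). A move reassigns one uniformly chosen unfrozen slot to a
uniformly chosen alternative option (including NOT_FOUND). Temperature
decays geometrically from kT = 100 to kT = 1; the start value spans
accept-almost-all to accept-rarely for score differences at the weight
magnitudes above. Trajectories are vectorized with NumPy and reproducible
under a seed.

Convergence is assessed over the ten best-scoring trajectory endpoints:
distinct final states are taken best-first, each voting with its
multiplicity (the number of trajectories that ended there). A slot
freezes when one placement — placements of the same domain variant within
5 Å CA-RMSD count as the same — holds a strict majority of the votes.
Using endpoint multiplicity rather than one vote per distinct state
matters at desk scale, where a small problem may have only a handful of
distinct basins and the (heavily populated) optimum basin would otherwise
be outvoted by rarely-visited runners-up.

The iterative loop alternates sampling, freezing, removal of the frozen
domains' density (voxels within 3 Å of their atoms set to 0), and
redocking of the unfrozen domains into the remaining density, stopping
when a round freezes nothing new. The frozen set never shrinks.

## Validation statistics

* **FSC**: standard Fourier shell correlation over concentric frequency
  shells up to Nyquist; threshold crossings are linearly interpolated and
  reported in Å. Symmetric in its arguments and invariant to positive
  scaling.
* **Masked RSC**: identical semantics to the docking stage; reported per
  domain together with the best-vs-second-best gap of a docking run (the
  placement-confidence measure).
* **Cross-link satisfaction**: per-link CA–CA distance and
  satisfied/violated/unmapped status; links with endpoints missing from
  the model are excluded from denominators, and inter-domain links are
  classified against a user-supplied domain table (different chains or
  different labeled domains).
* **Interface residues**: any-atom distance below 5 Å (heavy-atom cutoff;
  configurable) to a different domain.
* Model maps for FSC are produced by the same Gaussian simulator at the
  map's nominal resolution. Domains with internal (pseudo)symmetry are
  reported like any other; excluding them is left to the user.

## Subdomain splitting

Contact-map bipartitioning in the DDomainParse family: for each sequence
cut point, the inter-segment CA contact count (8 Å cutoff, |i−j| > 2) is
normalized by the geometric mean of the intra-segment counts; the best
cut is applied recursively when the normalized score is below 0.28 and
both segments keep ≥ 20 residues. Segments that are not themselves
compact (fewer internal contacts than half their length, e.g. a bare
extended linker) are merged into the neighbor they contact most, so the
returned segments are compact, disjoint, sequence-contiguous and cover
the domain exactly.

## Synthetic benchmark conditions

The fixtures module generates everything the tests need, with no
downloads, as pure functions of their seeds:

* **Domains** are idealized CA/CB helical bundles (canonical α-helix CA
  geometry: 2.3 Å radius, 1.5 Å rise, 100°/residue; CB beads 1.5 Å
  radially outward). Helix lengths and positions are jittered so domains
  are asymmetric — symmetric shapes would make rigid-body poses
  degenerate at 10 Å, which is a property of the shape, not the method.
* **Complexes** place consecutive domains of one chain (10-residue
  unmodeled linkers) in random orientations, packed so that no
  inter-domain atom pair is below 5 Å, every domain touches the complex,
  and each adjacent pair's terminal gap stays closable with ≥ 5 Å slack
  (so pairwise sliding cannot push the truth past the closability bound).
* **Maps** are simulated at 10 Å resolution, voxel size resolution/3,
  matching the regime the score weights were fitted for.
* **Decoys** are random orientations placed near *other* domains' true
  locations — regions that genuinely contain density, emulating the
  plausible-but-wrong solutions real docking produces — each ≥ 5 Å
  CA-RMSD from the truth.
* **Cross-links** are sampled from inter-domain residue pairs with true
  CA–CA ≤ 30 Å; a configurable violation fraction is drawn from pairs
  beyond 30 Å, emulating links from flexible or disordered regions.

What passing these benchmarks shows: the search, scoring and sampling
machinery recovers planted ground truth under the stated noise-free
density model with realistic geometry. What it does not show: robustness
to experimental map artifacts (CTF effects, B-factor falloff, local
resolution variation, segmentation errors), to inaccurate domain models
(the fixtures dock the exact generating coordinates), or to the
cross-link false-positive structure of real XL-MS data beyond the simple
violation-rate model.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run desk-scale versions of the
pipeline: docking studies use 20 fixtures of 100–150 residues with a 15°
rotation grid, up to 4000 search points and 30 refined candidates;
annealing checks use 200 trajectories × 5000 steps against exhaustive
enumeration (125 assignments); the end-to-end run uses a 4-domain complex
with 3 decoys per domain and 5 cross-links. The full-scale defaults
(50 000 points, 1000 refinements, 200 kept placements, 50 000 × 200 000
annealing) remain the shipped configuration values.

## Known limitations

* Maps must be pre-aligned; no fitting-based alignment is provided.
* The coarse score is exact only because candidate translations are
  voxel centers; off-lattice translations are reached only through
  refinement.
* The interface potential is residue-level and cannot rank side-chain
  packing quality; it screens geometry, it does not design interfaces.
* Cross-link endpoints present in several slots are attributed to the
  first containing slot.
* Linker rebuilding between placed domains, all-atom refinement, and
  score-weight refitting are out of scope.
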