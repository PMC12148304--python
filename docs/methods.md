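# Methods

This note documents the models, numerical choices and known limitations of
`fibrilforge`. Units are Å for coordinates and bond geometry, nm for
fibril-scale lengths (D-band, lateral spacing, fibril length/radius).

## Crystal symmetry expansion (`crystal`)

The fractional↔Cartesian mapping uses the upper-triangular orientation
matrix with rows (a, b·cosγ, c·cosβ), (0, b·sinγ, cyz) and
(0, 0, √(c² − cxz² − cyz²)), where cxz = c·cosβ and
cyz = c·(cosα − cosβ·cosγ)/sinγ. Its determinant equals the closed-form
triclinic volume; cells where c² − cxz² − cyz² ≤ 0 are rejected as
degenerate. Cells are validated on construction (positive lengths, angles
in (0°, 180°)).

**Copy inclusion rule.** A symmetry copy is included when *any* of its
atoms lies within the contact distance d_c of *any* atom of the original
(distance inclusive at exactly d_c). The alternative — a center-of-mass
criterion — would shift absolute copy counts slightly; the any-atom rule is
the stricter reading of a "contact" and is what the brute-force test oracle
implements independently.

**Candidate bound.** Only lattice indices with
|n_i| ≤ ⌈extent_i + d_c/h_i⌉ + 1 are examined, where extent_i is the
molecule's fractional extent along axis i and h_i = V / |a_j × a_k| is the
perpendicular height of the cell along that axis. Any copy with an index
beyond this bound is displaced by more than d_c plus the molecule extent in
the direction normal to the other two axes, so it cannot contact the
original: the bound is conservative by construction.

**Space groups.** The collagen cell is P1, which is supported exactly.
Other symbols are validated against the crystallographic tables (via gemmi)
but only their pure-translation operators (centering vectors) are applied,
with a warning; rotational operators are out of scope because the target
system never uses them.

**Clash rule.** Two atoms clash when d < f·(rw_i + rw_j) with overlap
fraction f = 0.6 by default (exposed as a parameter: the appropriate
overlap tolerance is a modelling choice, not a constant of nature). Radii
come from a fixed Bondi-style table; unknown elements default to 1.7 Å.
Removal granularity is whole copies, greedy in enumeration order, and the
identity copy is never removed. Neighbor searches use a k-d tree with a
per-pair exact distance check, so the tree path and the O(n²) path retain
identical sets (asserted in tests); systems under 5,000 atoms use the
direct path.

## Bravais-lattice optimization (`lattice`)

Copies map to integer lattice points p = round(C⁻¹·t); a translation whose
fractional image deviates from an integer by more than 10⁻³ is rejected
loudly ("translation off Bravais lattice") rather than silently rounded —
a copy that is not a pure lattice translate would corrupt the discrete
model.

The solution space δ = (δx, δy, δz) selects the δz outermost layers at each
axial end (processed outermost-first, lower block then upper block, for
deterministic reports). Within a layer lz the candidate set is the
rectangle spanned by the extreme occupied (nx, ny) indices minus the
occupied points; δx and δy optionally pad that rectangle (default 0 — the
axial boundary is where expansion depletes the lattice). Candidates are
visited uniformly at random without replacement under a seeded generator;
each candidate is visited once (acceptances update the occupied set, so
later candidates see earlier additions, but rejected candidates are not
revisited). A trial molecule — the reference molecule translated by
C·(p′ − p_ref) — is accepted iff

* some inter-crosslink atom pair between the trial and an existing molecule
  is within the contact cutoff (3.0 Å, the typical non-covalent contact
  distance in proteins), where "crosslink atoms" means the designated
  reactive side-chain atoms from the registry, not whole residues; and
* the full trial structure introduces no steric clash (same rule and
  overlap fraction as the expansion filter).

Zero additions is a valid outcome. Reports (candidates, accepted, rejected
by distance, rejected by clash, per layer) serialize as JSON lines.

**Connectivity.** A molecule end (N or C) counts as connected when any of
its reactive atoms is within the contact cutoff of another molecule's
reactive atoms; the three fractions (both ends, one end, neither) sum to 1.

**Packing statistics.** The radial density profile counts lattice points
per annulus of the transverse plane about the lattice origin, normalized by
annulus area. The packing-uniformity metric is the standard deviation of
the 0/1 occupancy over each layer's bounding rectangle: filling boundary
vacancies raises occupancy toward 1 and lowers this number, which is the
quantity the optimizer is expected to improve.

## Crosslink engineering (`crosslinks`)

Crosslink types live in a versioned YAML registry (name → valence, member
residue codes, reactive atom names per code); users can merge their own
file. Divalent types join exactly two residues, trivalent exactly three,
and removal always removes whole units.

* **Mixing** assigns each molecule independently a class (single type for
  both telopeptides, or an `N-C` pair such as `PYD-HLKNL`) with the given
  normalized probabilities under a seeded generator. Sites are retyped and
  member residues renamed to the registry codes; coordinates are not
  altered (the registry carries no alternative side-chain geometries —
  a deliberate simplification documented here; downstream topology tools
  consume the type annotations from the manifest).
* **Removal** draws exactly round(rate·K) of the K units without
  replacement (banker's rounding, so realized counts are reproducible and
  exact — a per-unit Bernoulli mode exists behind `mode="bernoulli"`). The
  rate applies per crosslink *unit*, not per residue. Every member residue
  of a selected unit is replaced by lysine: backbone atoms are kept
  verbatim and the side chain is rebuilt by superposing the ideal-geometry
  lysine from the chemical component dictionary onto the local N/CA/C
  frame. Residues without a complete backbone (the synthetic fixture site
  residues) are renamed with their reactive atoms stripped.
* **Unit derivation** after optimization matches sites greedily by
  increasing link distance, each site used at most once (a reactive side
  chain forms one crosslink); mutually linked trivalent-site triangles are
  extracted first as trivalent units, and trivalent pairs lacking a third
  partner stay unlinked.

## Sequence threading (`sequence_threading`)

The collagenous domain must keep glycine every third residue, so alignment
is two-step: telopeptides align with an ordinary affine-gap global aligner
(BLOSUM62; hydroxyproline scored as proline), while the declared helical
region aligns at whole-triplet granularity — tokens of three residues,
gap unit of three columns — so the reading frame is preserved by
construction. The helical segment of the target must be a multiple of three
residues; anything else is reported as a frame error rather than silently
re-framed. Identity below a configurable floor (30%) triggers a
distant-homolog warning.

Threading is rigid: backbone N/CA/C/O are copied verbatim for aligned
positions, substituted side chains are rebuilt at ideal geometry (component
dictionary superposed on N/CA/C), deletions drop the residue, and
insertions are rejected — inside the helical region because they would
break the frame, outside because a frozen backbone offers nothing to build
an inserted residue on (a refinement engine would; this package
deliberately has none). Consequently the per-residue *backbone* RMSD of a
substitution-only threading is identically 0 and the all-atom value stays
well under 2 Å; both are reported because published collagen homology
pipelines measure RMSD after refinement, where the backbone value is small
but nonzero.

The axial rise per triplet is the mean along-axis distance between
consecutive Gly-Cα per chain, averaged over chains, with the axis taken as
the first principal component of all Cα positions (robust to slight
supercoiling). The canonical value for collagen is ≈ 8.6 Å (3 × 2.86 Å per
residue).

## Assembly (`assembly`)

The fibril axis convention is z: the c axis of the upper-triangular
orientation matrix is the only one with a z-component, and all analysis
modules share this convention.

* **Merging** renumbers serials contiguously, gives each molecule a segid
  (`M000`, `M001`, …) and reuses chain IDs cyclically over 62 symbols; a
  JSON manifest maps molecule → (segid, chain relabeling) so merging is
  losslessly invertible. Assemblies beyond 99,999 atoms switch the serial
  field to hybrid-36 encoding with a warning.
* **Cutting** removes residues whose Cα falls outside [z₀, z₀ + L]
  (z₀ defaults to the assembly minimum — the anchor is configurable because
  no convention exists), cuts only at residue boundaries, and drops chains
  left with fewer than 3 residues. L is capped at 335 nm, the length of one
  full triple helix.
* **Capping** adds a neutral acetyl (ACE: CH3, C, O) before each chain
  N-terminus and an N-methylamide (NME: N, CH3) after each C-terminus at
  idealized amide geometry (C–N 1.335 Å, trans arrangement), built by
  internal-coordinate placement from the terminal N/CA/C. Caps are heavy
  atoms only — hydrogens are left to the downstream topology generator, as
  is standard before MD setup — so capping adds exactly 3 + 2 atoms per
  chain. Chains with incomplete terminal backbones are flagged and left
  uncapped rather than guessed at.

## Structure metrics (`analysis`)

* **D-band.** 1-D K-means (k = 10 by default; k-means++ seeding, 100
  restarts, tolerance 10⁻¹⁰, seeded) on the z-coordinates of crosslinking
  residues. Adjacent sorted-center distances below 38 nm are overlaps, at
  or above are gaps; D = mean(overlap) + mean(gap), robust to the edge
  effects of a 10-cluster banding (per-pair distances are also reported).
  If all distances fall on one side of the threshold the banding is
  degenerate and D is undefined (warning). One-dimensional K-means at this
  restart count reliably attains the global optimum; tests verify it
  against an exact dynamic-programming clustering oracle.
* **Lateral spacing.** Each molecule is reduced to the center of mass of
  its Cα atoms within a central axial slab (middle 50%, suppressing end
  effects), projected on the transverse plane; for each of the four
  quadrants around a molecule the nearest-neighbor distance is collected,
  and the pooled spacings give mean ± std. The quadrant frame is fixed
  laboratory axes with a configurable rotation; angles are snapped to
  10⁻⁶ degrees before binning because a neighbor sitting exactly on a
  quadrant boundary would otherwise flip quadrants on float noise. For
  lattices whose directions coincide with the quadrant boundaries the
  frame should be rotated off-axis (the tests use 45°) — otherwise edge
  molecules contribute second-neighbor distances, a degeneracy real
  (jittered, quasi-hexagonal) fibrils do not exhibit.
* **Radius.** A quantile (default 95th percentile) of transverse distances
  of molecule representative points from the axis through their centroid —
  a percentile, not the maximum, so stray outer molecules do not define the
  radius.

## Synthetic fixtures (`fixtures`)

The generators are pure functions of their parameters and seed.

* The **ideal triple helix** places Cα exactly on three phase-shifted
  helices (rise 2.86 Å/residue, ~103° left-handed twist, radius 2.5 Å,
  Gly-Pro-Hyp repeat), with backbone N/C/O interpolated along the curve and
  optional ideal side chains. The three 120° phases cancel transverse
  covariance exactly, so the principal axis equals the construction axis
  and the measured rise per triplet equals 3 × rise identically.
* The **template** is a one-molecule unit cell (15 Å × 15 Å × 670 Å,
  orthorhombic) whose c axis encodes the 67 nm period: crosslink-capable
  residues sit at z = 0 and z = 270 Å (the designed gap/overlap
  transitions) and the Cα-only body spans ~658 Å so axial neighbors fall
  within small contact distances. Crosslink reach is lateral: four reactive
  atoms extend ±6.5 Å toward the lateral neighbors, leaving 2.0 Å between
  reactive atoms of adjacent molecules — crosslinkable at the 3 Å cutoff
  yet above the 0.6·(1.55+1.55) = 1.86 Å clash threshold. This cell is a
  *designed* stand-in, not the experimental collagen cell (which is not
  reproduced here); expanding and optimizing it yields the designed
  banding (D = 67 nm) and pitch (1.5 nm) by construction.
* The **pre-staggered fibril** arranges molecules in mutually crosslinked
  lateral pairs cycling through five axial period offsets, giving designed
  band positions 0, 27, 67, 94, … nm, full both-end connectivity for even
  molecule counts, and explicit crosslink-unit bookkeeping for removal
  arithmetic.

**What passing tests do and do not show.** The fixtures have exact lattice
geometry, skeletal bodies and synthetic crosslink chemistry; they validate
the algorithms (expansion, clash filtering, optimization, banding,
spacing, arithmetic) quantitatively, but they say nothing about the
biochemical realism of a model built from a real collagen template — real
templates bring non-orthogonal cells, molecules spanning several cells,
and crosslink geometry with sub-Å variation that shifts absolute chain
counts and band widths.

## Problem sizes

Default test and example runs use a 19-copy expansion (~700 Cα atoms per
copy) optimized to 27 molecules, fibrils of 10–60 fixture molecules for
analysis statistics, and 10⁴ molecules (minimal bodies) for the binomial
mixing checks — sizes chosen so the designed quantities are measured with
negligible discretization error while the whole suite runs in well under a
minute.

## Known limitations

* No refinement: threading keeps the template backbone frozen; inserted
  residues cannot be built and side-chain packing is ideal-geometry only.
* Space-group rotations beyond P1 are not applied (translations only).
* Crosslink mixing changes annotations and residue codes, not coordinates;
  force-field parameterization of crosslink chemistry is out of scope.
* No solvation, topology generation or mechanics — the output is a
  starting structure for MD engines, not a simulation setup.
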