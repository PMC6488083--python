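# Methods

## Model

A self-assembling complex is treated as an ordered list of rigid monomers.
Each monomer is reduced, per interaction kind, to a single point dipole:

* **Charges.** Electrostatic: formal side-chain charges at neutral pH,
  Asp/Glu −1 and Lys/Arg +1. Histidine (pKa ≈ 6, mostly neutral at pH 7)
  and the terminal NH₃⁺/COO⁻ groups are excluded by default; both can be
  switched on (`include_his`, `include_termini`), since whether they
  belong in the budget is a genuine modelling choice. Hydrophobic: the
  residue's Eisenberg normalized-consensus index used verbatim as a signed
  charge (positive = hydrophobic); alternative scales load from a
  two-column text table. Zero-valued entries are dropped (none exist in
  the shipped scale).
* **Charge positions.** Electrostatic charges sit on the charged-group
  centroid of the side chain (Asp OD1/OD2, Glu OE1/OE2, Lys NZ, Arg
  NH1/NH2/NE, His ND1/NE2); hydrophobic charges on the side-chain
  heavy-atom centroid (Gly: CA). Both modes are configurable down to plain
  CA because the literature is not unanimous on the carrier atoms; missing
  atoms fall back one level with a logged warning.
* **Moment.** P = Q⁺(c⁺ − c⁻) with charge-magnitude-weighted centroids.
  This surrogate is translation invariant for any net charge and reduces
  to the exact Σqᵢrᵢ when the set is neutral (asserted to 1e-9 in the
  acceptance suite). The alternative conventions Q⁻(c⁺−c⁻) and Σqᵢrᵢ are
  provided for sensitivity analysis only; conventions must not be mixed,
  and the exact convention is origin-dependent for non-neutral sets.
  A dipole is undefined whenever one charge subset is empty; it carries a
  zero moment and contributes zero energy downstream, surfacing as NaN in
  tables and `indeterminate` labels rather than errors.
* **Application point.** The midpoint of c⁺ and c⁻ (symmetric default);
  the monomer's geometric center is available via configuration. Centroid
  separations for real monomers typically fall in 1–10 Å, checked softly
  (warning only) because synthetic toys legitimately fall outside.

## Energies

enD = −[3(u·D₁)(u·D₂) − D₁·D₂]/r³ with 4πε₀ = 1, and
enH = +[3(u·H₁)(u·H₂) − H₁·H₂]/(k·e^r) with k = 1; negative values are
attractive. The flipped sign implements the inverted affinity of
hydrophobic charges (like attracts like); the exponential gives the
shorter range. Units are arbitrary and kind-specific: enH and enD are
never magnitude-compared, and mixing kinds in a kernel is a type error.

The distance in the enH exponent needs a length unit, which the model
itself does not fix. The default is `scaled`: r/r₀ with r₀ = 10 Å, chosen
because e^(−r) with r in Å at typical inter-monomer separations (~25 Å)
drives enH to ~10⁻¹¹ of its orientational prefactor and makes values
numerically useless; r₀ = 10 Å puts typical separations at a few decay
lengths. `angstrom` and `nanometer` modes exist for calibration against
published values. The choice is a positive constant across any rotation
grid, so scan minima locations are invariant to it (tested).

* Consecutive-pair statistics: mean and sample (n−1) SD of the pair
  energy over ordinal neighbours (i, i+1) in assembly order — not spatial
  nearest neighbours — optionally truncated to the first n pairs. Pairs
  with an undefined dipole are dropped from the count.
* Growth curves: E(N) is the all-pairs sum over the first N elements
  (sequential), or over a chosen inner element plus its N−1 nearest
  elements by application-point distance (around-center); each point is
  checked against a brute-force double loop in the tests.
* Classification: by the sign pattern of the two consecutive-pair means
  only — enH<0≤enD hydrophobically driven, enD<0≤enH electrostatically
  driven, both negative dual-attractive, both non-negative dual-repulsive,
  undefined mean indeterminate.

## Scans

The dimer frame anchors at dipole 2's application point: x along the
inter-dipole vector, y ⊥ the plane of x and the original moment 2,
z = x × y (right-handed; when moment 2 is parallel to x, y is an arbitrary
perpendicular, logged). Only the moment vector rotates, in 10° steps over
[0°, 350°]; coordinates, separation and the other kind's dipole stay
fixed. Minima are grid argmins; ties (within 1e-12 of the span, e.g. the
flat scan about a moment's own axis) resolve toward the angle closest to
0°, preferring the positive alias, and are flagged. Angles are reported on
[0°, 350°] with a signed alias in (−180°, 180°] since both spellings are
common.

Translations re-pose the pair at the native center distance |r| with the
moments parallel: displacement ⊥ moment 1 (side-by-side), ∥ moment 1
(top-down, on the same side as the native separation), or the normalized
sum of both (staggered), each followed by a fresh rotation scan. The
arrangements are defined on the dipole abstraction, not atom coordinates —
atoms never enter the kernels. Steric clash detection is deliberately
absent: scans annotate the landscape, they never exclude angles, and the
model makes no kinetic or absolute free-energy claims.

## Structure input

gemmi parses PDB/mmCIF (gzip accepted). A monomer is one polymer chain by
default; a grouping rule (list of chain tuples) builds composite elements
such as heterodimers or pentameric blocks, and also overrides assembly
order. Model 1 of NMR ensembles is used unless asked otherwise. Waters,
hetero compounds, hydrogens and non-standard residues are dropped (the
latter with a warning); altLoc keeps the highest occupancy, ties broken by
label order. Coordinates stay in Å throughout.

## Synthetic study systems

The generators build assemblies whose energetics are known in closed
form, emulating the geometry class of helical/fibrillar growth:

* a **rigid screw** (`make_helical_assembly`): template monomer rotated by
  k·twist about z, offset radially, raised by k·rise — consecutive pairs
  are congruent, so pair energies are constant along the chain and growth
  is exactly linear in N for neighbour-dominated sums;
* a **linear stack** with per-monomer specs (`make_linear_assembly`),
  needed for the dual-attractive ground truth (constant H with
  alternating D is not a rigid screw of a single template);
* seeded random charge clouds, optionally exactly neutral, for the
  pseudo-vs-exact dipole and invariance properties.

The default study conditions used by `scripts/acceptance.py` are 12
monomers per assembly (11 consecutive pairs), monomer spacing ~8 Å,
charge separations ~2 Å, and charge magnitudes taken from the Eisenberg
extremes (Ile +1.38, Arg −2.53) and unit formal charges — sizes at which
every quantity computes in seconds while keeping the geometry in the
regime the model targets. Toys reproduce the *structure* of the problem
(dipole orientations, screw symmetry, sign patterns) but not the
heterogeneity of real monomers: residue-level disorder, shape variability
and steric context are absent, so passing tests demonstrate correctness
of the computation, not biological validity of any particular published
value. Real deposited assemblies are analyzed with the same code path via
`scripts/reproduce_reference_systems.py` (requires network access to the
PDB).

## Numerical choices

* Sample (ddof = 1) standard deviations; SD of a single pair is NaN.
* PDB writing quantizes coordinates to 1e-3 Å (format columns); round-trip
  energy agreement is asserted at 1e-4 relative on toys whose length scale
  keeps quantization noise below that.
* Frame orthonormality and rotation composition are exact to 1e-9;
  rotations use quaternion-backed `scipy.spatial.transform.Rotation`.
* Degenerate inputs: coincident application points raise a singular
  geometry error; empty charge subsets flow through as undefined dipoles;
  an empty monomer selection or unparsable file is an error naming the
  cause.

## Known limitations

No solvation physics, pH titration or partial charges; no absolute free
energies, temperature dependence or kinetics; no steric model; no coupled
co-rotation of H and D during scans (the two kinds are scanned
independently). The hydrophobic kernel is an analogy with a chosen range
law, not a derived force field — its sign structure, not its magnitude,
is the scientific content.
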