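# Methods

`surfagg` post-processes molecular-dynamics trajectories of short
amyloidogenic peptides — the working system is the seven-residue
amyloid-beta fragment Aβ(16–22), sequence KLVFFAE — either in bulk solution
or adsorbed on an Au(111) slab, and characterises how aggregation differs
between the two environments.  This note records the models, conventions,
parameters and design decisions behind each stage, and what the synthetic
generator does and does not emulate.

## Coordinate and unit conventions

All internal lengths are nanometres, times picoseconds, masses amu.  File
readers convert at the boundary (PDB stores Å, GRO/XTC nm; MDAnalysis
normalises both).  Boxes are orthorhombic.  Solution systems are treated as
periodic in x, y and z; surface systems as periodic in x and y only, because
the slab plus its vacuum-adjusted water column makes z-wrapping physically
meaningless for peptide–surface distances, even when the file declares a z
box length.  Peptide copies are identified by chain/segment ID when present
and by residue-numbering restarts otherwise, since GRO files often carry no
chain information.  A heavy atom is anything that is not hydrogen or
deuterium, decided from the element field when present, else from the atom
name by PDB parsing rules.

## Oligomer detection

Two peptides belong to the same oligomer when any pair of their heavy atoms
is closer than 4 Å (0.4 nm) under the minimum-image convention; clusters are
the connected components of this contact graph (single linkage).  The
inequality is strict: a pair at exactly 0.40 nm is not a contact, so the
boundary behaviour is deterministic.  Connected components are delegated to
`scipy.sparse.csgraph`; the test suite holds them against an independent
union-find oracle on hundreds of random frames.

The oligomer size histogram over a trailing window (default 100 ns, the
convention for production trajectories; shorter synthetic runs fall back to
the trailing 20 % with a warning) is peptide-weighted by default:
P(s) ∝ s · count(s), the probability that a randomly chosen peptide in a
randomly chosen window frame sits in a cluster of size s.  This matches the
"probability of finding all peptides in a single aggregate" reading of such
histograms.  A cluster-weighted mode (fraction of observed clusters of size
s) is available via `weighting="cluster"`.

## Gyration-tensor shape descriptors

For a cluster, the mass-weighted second-moment tensor about the centre of
mass is diagonalised and the square roots of its eigenvalues reported as
principal radii Gmax ≥ Gmid ≥ Gmin (nm), commensurate with molecular
lengths; the raw eigenvalues (nm²) are emitted alongside.  Mass weighting is
the default (the common MD-tool convention); a geometric mode exists.
Before the tensor is computed the cluster is made whole across periodic
boundaries: the lowest peptide index anchors a breadth-first traversal of
the contact graph, and each newly attached peptide is shifted by the box
vector that makes its closest heavy-atom pair to its parent obey the
minimum image.  A cluster that winds around a periodic axis cannot be
unwrapped consistently; it is flagged (extent covering a full axis, or a
contact edge longer than the cutoff after unwrapping) rather than silently
wrapped.  The monolayer signature used in the analyses is that Gmin of a
flat adsorbed aggregate stays at the single-molecule value, while compact
solution aggregates have larger Gmin.

## Contact and hydrogen-bond maps

The residue–residue contact map applies the same strict 4 Å heavy-atom
criterion per residue pair, restricted to *inter*molecular pairs.  Entry
(a, b) is the fraction of (window frame, unordered peptide pair)
combinations in which residue a of one peptide touches residue b of the
other in either direction, so the matrix is symmetric with entries in
[0, 1]; an absolute-count mode exists for comparison with the hydrogen-bond
map.

No universal geometric hydrogen-bond criterion exists; the package uses the
convention of common MD analysis tools: donor–acceptor heavy-atom distance
≤ 3.5 Å and hydrogen–donor–acceptor angle ≤ 30°, both configurable.
Donors are backbone amide N–H, acceptors backbone carbonyl O; Lys/Glu
side-chain sites can be included by flag where the topology resolves them.
The map reports mean interpeptide bond counts per frame by residue pair.
In an ideal antiparallel β-sheet the interpeptide hydrogen bonds fall on
the anti-diagonal (a + b ≈ R + 1), which is the packing signature the
analyses look for in solution aggregates.

## Conformational classification

Similarity to a reference conformation is measured by the distance RMSD
over all intramolecular Cα–Cα pairs,

    DRMSD = sqrt( (1/N) Σ_i (r_i − r_i_ref)² ),  N = R(R−1)/2 = 21 for R = 7,

computed internally in nm and reported in Å (the conventional axis unit).
The metric needs no superposition and is invariant to rigid motions and to
reflection; mirror images are indistinguishable, a documented property of
the metric rather than a defect to correct.  Pair ordering is lexicographic
over residue-position pairs (p, q), p < q.

Two constructed reference conformations ship with the package:

* **fibril** — an ideal extended β-strand at (φ, ψ) = (−139°, +135°),
  standing in for the strand conformation of this peptide in amyloid
  fibrils;
* **surface** — a flat-lying bent conformation at (φ, ψ) = (−60°, −60°),
  rigidly oriented so both phenylalanine side-chain pseudo-atoms are
  coplanar at minimal height, standing in for the conformation a single
  molecule adopts on the gold surface.

Both are synthetic stand-ins built by the generator, not extracted from any
deposited structure; user-supplied references (PDB with Cα extracted, or a
plain-text 21-value distance vector) are accepted everywhere.  The bent
dihedral pair was chosen, once, so that the conformer is clearly bent
(lower-left Ramachandran quadrant), clearly distinct from the β reference
(> 1 Å DRMSD separation), and has a well-separated smallest principal axis,
which keeps the monolayer Gmin comparison free of the near-degeneracy a
thinner conformer exhibits.

DRMSD histograms use 0.1 Å bins, Ramachandran densities 5° bins over
(−180°, 180°]; neither is prescribed by anything upstream, both are
configurable.  φ is defined for residues 2..R, ψ for 1..R−1; densities pool
interior residues over peptides and window frames.  Quadrant occupancies
(upper-left = β-strand region, lower-left = α-helical region) summarise the
densities.

## Surface geometry

The Au(111) slab is an ABC-stacked fcc(111) surface cut from a lattice with
parameter a = 4.14 Å: in-plane nearest-neighbour spacing a/√2 = 2.927 Å,
interlayer spacing a/√3, rectangular surface cell (d, √3·d) with two atoms
per layer, d = a/√2.  A 20 × 12 × 5-layer slab therefore measures
5.855 nm × 6.085 nm and holds 2400 atoms.  The builder exists for synthetic
fixtures and geometry checks; it models no force-field sites.  The top layer
is detected from coordinates (the max-z band of gold atoms, 0.5 Å
tolerance) rather than trusted from construction metadata, so externally
produced slabs work.  Areal peptide density is n/(N_A·Lx·Ly); four peptides
on the cell above give 1.86 × 10⁻⁷ mol m⁻².  (The analogous figure for
eight peptides is 3.72 × 10⁻⁷ mol m⁻².)

"In contact with the surface" has no standard numeric definition; the
package uses: any heavy atom within 0.5 nm of the top-layer z, in at least
50 % of window frames.  Both numbers are configurable and recorded in the
run manifest.  An aggregate is a monolayer when every adsorbed-phase peptide
is in surface contact, a multilayer when only some are, detached when none
is.  Residue z-profiles report window-mean residue centre-of-mass heights
above the top layer, and the per-peptide centre-of-mass z series is kept at
full time resolution.

## Synthetic data

The generator builds peptides at backbone-plus-pseudo-side-chain resolution
(N, H, Cα, C, O and one side-chain pseudo-atom per residue): sufficient for
every analysis in the package — heavy-atom contacts, Cα distance metrics,
φ/ψ dihedrals, amide hydrogen-bond geometry — while keeping fixtures tiny.
Backbone geometry uses standard bond lengths and angles with NeRF internal-
coordinate placement, so planted dihedrals are recovered exactly by the
analysis.  Coil conformations draw dihedrals uniformly with clash rejection.

`plant_configuration` realises a requested ground truth exactly: cluster
members are chained at a planted closest-heavy-atom separation of 0.30 nm
(serpentine rows; solution clusters stack rows in z into compact blocks,
surface clusters stay in-plane; mixed adsorbed/detached clusters stack the
detached members on top, giving multilayers), clusters are laid out on a
grid with verified > 0.4 nm separations, adsorbed peptides sit with their
Phe pseudo-atoms 0.3 nm above the top layer and detached ones at 2.0 nm.
The realised contact graph is verified against the planted partition before
emission and the build aborts on any mismatch.  Gaussian coordinate noise
(if requested) is added last; connectivity is re-checked afterwards and the
outcome recorded in the ground-truth record, never silently repaired, so
recovery statistics measure the analyser honestly.  All randomness flows
from the single seed in the spec; at zero noise the construction is
bit-deterministic.

The Langevin aggregator is a deliberately simple stochastic stand-in that
produces aggregation-like kinetics for exercising the time-series analyses:
one bead per residue, harmonic bonds at 0.38 nm (k = 500 kJ mol⁻¹ nm⁻²), a
weak angle term, WCA cores with Lennard-Jones attraction between
hydrophobic beads (L, V, F, A; ε = 12 kJ mol⁻¹ ≈ 5 kT) and between the
oppositely charged termini (ε = 8 kJ mol⁻¹), and, when a slab is present, a
Gaussian wall well at 0.30 nm depth ε = 25 kJ mol⁻¹ acting on Phe beads
(1 kJ mol⁻¹ for the rest).  The update is overdamped position Langevin with
kT = 2.494 kJ mol⁻¹, friction γ = 5 and dt = 5 × 10⁻⁴ in reduced time, with
the deterministic displacement capped at 0.05 nm per step so steric
overlaps relax over several steps instead of catapulting beads across the
box.  These parameters were chosen for numerical stability and for the
qualitative behaviours the generator must exhibit (no spurious aggregation
when attractions are off; full aggregation of four peptides in a 3.2 nm box
within ~15 000 steps; Phe beads ending closer to the wall than the charged
termini).  It makes no claim to approximate all-atom energetics: there is
no water, no electrostatics beyond the residue-class pair rules, and no
polarizable gold.

**What passing synthetic tests shows, and what it does not.**  The planted
fixtures prove the analysis chain is correct — criteria are applied exactly,
invariants hold, planted truths are recovered — and the Langevin runs prove
the pipeline behaves sensibly on noisy, kinetically evolving input.  They do
not validate force-field physics, sampling convergence, or any biological
conclusion about real peptides on real gold; production claims require real
trajectories.

## Numerical choices and degenerate inputs

* Strict `<` at every distance cutoff; boundary cases are deterministic.
* Cluster ordering: size descending, ties by smallest member index;
  members ascending.  Permutation equivariance is tested.
* Gyration eigenvalues are clipped at zero before the square root (guards
  against −1e−17 from `eigvalsh` on planar clusters).
* Trailing-window selection uses a 1 ns × 10⁻⁹ time epsilon; trajectories
  shorter than the window raise unless the trailing-20 % fallback is
  explicitly allowed (the pipeline allows it, with a warning).
* Degenerate inputs rejected with specific errors: empty trajectories,
  non-monotonic frame times, atom-count mismatches, mismatched peptide
  copies (named by chain), empty cluster member sets, hydrogen-free
  topologies in hydrogen-bond analysis, surface analyses without a surface.
* The synthetic packer raises on infeasible layouts (clusters that cannot
  fit the periodic cell at ≥ 0.45 nm separation) rather than emitting a
  frame that violates the planted truth.

## Problem sizes

Default analysis problem sizes in the tests and the acceptance script —
2–8 peptides, 1–6 frames per synthetic trajectory, 50-seed recovery sweeps,
200-frame oracle sweeps, 10⁴-step Langevin runs — were chosen as the
smallest sizes at which every property being checked is non-trivially
exercised; all analyses scale to production trajectories (hundreds of
nanoseconds, thousands of frames) without algorithmic changes since every
per-frame cost is polynomial in a small peptide count.

## Known limitations

* Cell-list acceleration is not implemented; contact detection is all-pairs
  per peptide pair, which is ample at Nmol ≤ 8 but quadratic beyond.
* The hydrogen-bond donor/acceptor assignment covers backbone amide and
  carbonyl groups (plus Lys/Glu side chains by flag at all-atom
  resolution); exotic protonation states are out of scope.
* DRMSD cannot distinguish mirror images.
* The multi-model PDB reader carries no physical time; callers must supply
  the frame stride.
* `classify_adsorption` labels the whole system, not individual aggregates;
  with several coexisting aggregates the per-peptide flags remain the
  authoritative output.
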