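# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `dimerflex`, in the spirit of a methods appendix.

## Elastic network model

One site per residue at the Cα position; springs of uniform constant
*k* (default 1, arbitrary units) between all site pairs within a cutoff
(default 12 Å), across chain boundaries like any other pair. The Hessian
is the standard isotropic second-derivative matrix of the harmonic
pair-distance energy: for a spring (i,j) with separation vector **d**,
the off-diagonal 3×3 block is −k **d****d**ᵀ/|**d**|², accumulated on the
diagonal with opposite sign. Because only "equal spring constants within
a cutoff" is physically specified, the eigenvalue scale is arbitrary:
only mode shapes and their ordering carry meaning.

Modes are numbered from 1 including the six trivial zero modes of a
connected network, so the first informative mode is mode 7. Trivial
modes are identified by eigenvalue < 1e−8 × the largest eigenvalue; a
disconnected network (> 6 zero modes) is an error unless explicitly
allowed. Eigenvector sign is arbitrary; every simulation therefore runs
both parallel and antiparallel to its bias, and no sign convention is
imposed. Near-degenerate eigenvalues can swap mode order under small
parameter changes; `classify_cleft_modes` therefore identifies the
anti-symmetric and symmetric cleft motions among modes 7–9 by the
analytic derivative of the two intersite distances along each
eigenvector (opposite signs = anti-symmetric) rather than by index.

`atomize_bias` maps a per-residue eigenvector onto all atoms of each
residue and rescales the field so the root-mean-square per-atom
displacement equals the step size (default 0.01 Å). Residues without a
Cα are absent from the network and from bias mapping.

## Constraint network and rigidity

Constraints and their body-bar multiplicities (all configurable in
`RigidityConfig` and recorded with every run):

| constraint | rule | bars |
| --- | --- | --- |
| covalent bond | distance < sum of covalent radii + 0.45 Å | 5 |
| peptide / partial double bond | backbone C–N between residues | 6 |
| hydrogen bond / salt bridge | energy ≤ cutoff (default −2.0 kcal/mol) | 5 |
| hydrophobic tether | C/S pair within vdW sum + 0.25 Å, different residues | 2 |

Hydrogen-bond energies use a Mayo-style potential: well depth
8 kcal/mol, donor–acceptor equilibrium 2.8 Å, radial form
5(R₀/R)¹² − 6(R₀/R)¹⁰, attenuated by cos²θ of the bond angle (zero at or
below 90°). With explicit hydrogens the angle is measured at the
hydrogen; without them a fallback uses the donor's bonded heavy atoms to
define the donor direction — a documented approximation, since rigidity
analysis normally requires placed hydrogens. Salt bridges (Arg/Lys/His
donors to Asp/Glu carboxylates) receive a fixed favourable energy
(−10 kcal/mol) so they always pass the cutoff. Lowering the cutoff can
only remove bonds, a monotonicity the tests assert.

Two resolutions are supported. **Atomistic** mode treats atoms as 6-DOF
bodies and runs the exact (6,6) pebble game (correct for generic
body-bar frameworks): each vertex holds six pebbles and a bar is
independent iff seven pebbles can be gathered on its endpoints.
**Coarse** mode (Cα-only structures) treats sites as 3-DOF point joints
with single-bar constraints: consecutive-residue bonds within 4.5 Å and
non-local tethers within 5.5 Å. Three-dimensional bar-joint rigidity has
no exact counting characterization (double-banana-type circuits satisfy
Maxwell counting everywhere yet hide a dependency), so the point game
augments the classic six-pebble rule and a seventh-pebble search over
the endpoints' neighbours with a numerical safeguard: a counting-
accepted bar is vetted against the span of previously accepted
constraint rows (reorthogonalized Gram–Schmidt, relative tolerance
1e−8). The floppy count is then exact for the actual (generic, jittered)
coordinates and insertion-order invariant.

Dihedral labels and clusters: in atomistic mode a covalent bond is
locked iff a pebble search can no longer free seven pebbles across it
(its relative freedom is exhausted); in coarse mode a constraint is
locked iff the numerical infinitesimal-flex space restricted to its
local environment (endpoints plus common neighbours, falling back to
the neighbourhood union for sparsely connected bonds) contains only
rigid-body motions. Rigid clusters are connected components over locked
constraints. Floppy counts always come from the game itself.

## Geometric simulation

Templates: one rigid template per rigid cluster. Flexible regions get
local templates matched to the freedoms the rigidity analysis assigns:
in atomistic mode each variable bond contributes two atom-centred
templates overlapping on the bond (bond lengths and angles kept, the
dihedral free); in coarse mode the bare atom pair (only the distance is
a constraint at Cα resolution). Noncovalent constraints that cross
template boundaries are maintained as distance restraints — hydrogen
bonds at their input length, hydrophobic tethers allowed to shorten but
not stretch.

Each step displaces all atoms along the fixed bias field (recomputed
from the input-structure eigenvector, not from the moving structure)
plus an independent random kick per atom, uniform in a sphere (default
radius 0.01 Å, seeded). Relaxation then iterates: fit each template to
the current atoms by least-squares (Kabsch) superposition; move atoms to
the average of their templates' proposals; restore cross-template pair
distances; separate non-bonded overlapping pairs symmetrically. Steric
radii are per-element hard spheres scaled by 0.85 (soft sterics); 1–2
and 1–3 bonded pairs and directly constrained pairs are exempt.
Convergence requires the worst violation — where the template term is
*twice* the largest atom-to-proposal deviation, an upper bound on any
internal distance error — to fall below the tolerance (default
0.125 Å) within 200 iterations; failure is a returned flag, and the step
is rolled back.

Jamming ends a trajectory in either of two ways: the configured number
of consecutive relaxation failures (default 20), or — because a blocked
motion can also manifest as the relaxation silently undoing the bias
each step — net motion over the last 20 accepted steps below 15% of the
driven displacement. The second criterion is this package's
concretization of the qualitative "onset of jamming"; the last
satisfiable frame ends the trajectory, and every emitted frame satisfies
the tolerance. Frames are saved every 100 steps by default, plus the
final frame.

## Measures and statistics

All measures operate on named sites (chain, author residue number, atom
name), configured in code or YAML, so the same machinery serves real
enzymes and the synthetic fixture. Angles are interior angles in
degrees [0, 180]; dihedrals are signed, IUPAC convention, (−180, 180].
Note that reversing a dihedral quad (D,C,B,A) leaves the signed value
unchanged — so a pure chain relabelling exchanges the two cleft angles
but cannot flip the dihedral's sign; only true reflections flip it.
dRMS is the raw root-mean-square of the configured cross-cleft
distances (not an RMS deviation from a reference's distances; the
alternative convention can be built from the same primitives if
needed).

PCA aligns every frame on the first frame over an alignment selection
(Kabsch), then accumulates the mass-unweighted covariance of the
analysis selection's Cartesian coordinates; eigenvectors are reported by
descending variance, and any trajectory sharing the atom identities can
be projected onto them. The cosine content of a projection series p(t)
against cos(iπt/T) is (⟨c,p⟩)²/(⟨c,c⟩⟨p,p⟩) with both series
mean-centred — the harmonic index is explicit because only the i-th
half-period cosine is an orthogonality partner of the i-th diffusive
mode. Windowed Pearson correlations use the sample (n−1) convention,
report zero-variance windows as missing (never 0), and support a
burn-in. Frame clustering is average-linkage agglomeration on the
pairwise RMSD matrix (fit on one selection, RMSD over another), with
medoid centroids.

## The synthetic homodimer

The generator emulates the architecture that makes cooperative motion
possible in domain-swapped two-domain homodimers: two rigid core domains
(5×4×3 sites each, ~3.8 Å lattice spacing, jittered ±0.15 Å) pack into
one dimer body; each chain's small mobile domain (25 sites) crosses the
midline on a 3-residue linker and packs against its partner, fusing into
a single domain-swapped top lobe above the body; the ~11 Å gaps between
the lobe's two halves and the cores beneath them are the two binding
clefts. The structure is exactly C2-symmetric (chain B is the rotated
image of chain A, jitter included), so the clefts are equivalent and
normal modes split cleanly into symmetric and anti-symmetric pairs: a
see-saw rocking of the lobe is the anti-symmetric cooperative motion, a
vertical approach the symmetric one. Designated sites (an intersite
pair per cleft, a hinge triple per chain kept in one rotation plane so a
hinge rotation of φ changes the measured angle by exactly φ, cleft tips,
dRMS site sets) are annotated for the measures layer, and
`make_open_closed_pair` provides reference conformations related by a
known rigid rotation.

Sizes (60 core + 25 mobile residues per chain) keep full-pipeline tests
in seconds. What the toy does *not* emulate: real secondary structure
and sequence, side-chain packing, solvent, and the all-atom steric
texture that sets absolute closure depths in real proteins — so passing
tests demonstrate the *mechanics and statistics* of the pipeline
(cooperative character, jamming, recovery of planted signals), not
force-field-level realism.

Companion generators plant known ground truth for the statistics layer:
trajectories along specified orthonormal internal directions with chosen
amplitude variances and noise, and bivariate normal series of specified
population correlation.

## Numerical choices and degenerate inputs

* Coordinates are Å throughout; containers store them in single
  precision, so construction-exactness claims hold to ~1e−5.
* Alternate locations: highest occupancy wins (ties alphabetical);
  waters always dropped; other heteroatoms dropped unless requested.
* Eigen-decompositions use symmetric dense solvers; trivial-mode and
  rank thresholds are relative (1e−8) to the spectrum/row scale.
* Zero-weight mode combinations, trivial-mode indices, mismatched
  selections, clashing hinge rotations, single-frame PCAs and
  zero-variance correlation windows raise or return missing values
  explicitly rather than degrading silently.
* Pipeline outputs embed the resolved configuration, a hash of its
  scientific fields, and the seed, making every run directory
  reproducible bit-for-bit for the measure tables.

## Limitations

* The point-mode pebble game is exact only thanks to its numerical
  safeguard; a purely combinatorial 3D bar-joint game cannot be, and
  the safeguard decides ranks at the actual coordinates (near-singular
  geometries resolve to their actual, not generic, rank).
* Heavy-atom hydrogen-bond detection is an approximation; for serious
  rigidity work on crystal structures, add hydrogens first.
* Geometric simulation explores geometric feasibility, not free energy:
  closure depths and jamming points are bounds set by the constraint
  network, and carry no thermodynamic weight.
* The crystal-structure acceptance checks require the deposited
  open/closed structures of the decapping enzyme and fetch them on
  demand; they cannot run without network access or a local copy.
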