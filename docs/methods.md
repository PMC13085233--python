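# Methods

This note records the model, the algorithmic conventions, and the design
choices behind `mbescreen`, in the spirit of a package reference manual.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Expansion and assembly

The package implements the truncated many-body expansion
E_MBE(n) = Σ ΔE_S over all retained subsystems S with |S| ≤ n, where
ΔE_S = Σ_{T⊆S, T≠∅} (−1)^{|S|−|T|} E_T (for |S| = 1, ΔE_A = E_A).  Written
this way, monomer terms, two-body corrections and all higher orders are one
uniform object, and the untruncated expansion telescopes exactly to the
supersystem energy for *any* backend — the central correctness oracle, and
one the suite checks to 1×10⁻⁸ kcal/mol on systems of up to eight
fragments.

Coefficients are accumulated in exact integers during resummation; energy
sums use `math.fsum` (compensated summation).  Both are needed for the
telescoping identity to hold at tight tolerance: the resummed complete
MBE(n) must reproduce the closed-form coefficient
(−1)^(n−k) C(N−k−1, n−k) of every k-mer, and coefficients of hundreds of
magnitude-cancelling terms would otherwise drown the identity in rounding.

The supramolecular interaction energy ΔE_int = E_P:L − E_P − E_L is
assembled from retained ligand-containing terms of order ≥ 2 only.  The
cancellation of protein-only terms is exact *when the three expansions
share screening decisions*; the implementation guarantees this by defining
the protein expansion as the restriction of the complex's graph to
ligand-free keys.  The intact-ligand monomer cancels against E_L because
both are emitted from the identical geometry; the code computes the
difference and errors if it is nonzero rather than assuming it.  A Δ term
that survives screening contributes in full even when some of its subset
energies belong to screened-out nodes: the subsets' energies are fetched
from the energy store, which is deliberately independent of graph status,
because the inclusion–exclusion definition of ΔE requires them to exist.

## Graph construction and the missing-parent screen

Layer 1 always contains all N monomers, and layer 2 candidates are all
pairs: monomer parents can never be missing, so the parental screen only
begins to bite at order 3.  Layers iterate in lexicographic key order and
all containers are keyed by canonical sorted tuples, so runs are
reproducible bit for bit.

Three construction algorithms are provided and are interchangeable:
propose-and-check (enumerate C(N,k) candidates, count retained parents,
require ≥ k−M), plus-one (each retained (k−1)-mer ∪ one monomer; a k-mer
with p retained parents is generated exactly p times, threshold k−M), and
grandparents (pairwise unions of (k−1)-mers sharing a (k−2)-subset; a k-mer
with p retained parents occurs exactly C(p,2) times, threshold
(k−M)(k−M−1)/2).  Two conventions make the equivalence exact rather than
approximate:

* the grandparents algorithm groups retained parents by *every* (k−2)-subset
  (the subset lattice), not only by (k−2)-sets that are themselves retained
  graph nodes.  Grouping by retained nodes undercounts whenever a shared
  grandparent was screened out while two of its "children" survived (possible
  for k ≥ 4 with M ≥ 1), and would reject candidates the other two
  algorithms accept;
* when k − M ≤ 0 every candidate is admissible by definition, including
  candidates no retained parent can generate, so the union-based algorithms
  delegate to exhaustive enumeration in that regime (it only occurs in
  complete-expansion runs with M ≥ k).

Automatic selection uses grandparents whenever k ≥ 3 and k − M > 1, else
plus-one; propose-and-check is available by explicit override.  The default
allowance is M = 1, configurable including 0 and ≥ 2.

## Screening

Screens run cheap-to-expensive — parental, then distance, then energy — but
each is a pure predicate on a candidate, so the retained set is independent
of the order of application (asserted on random instances).

Distance: R of a subsystem is the maximum over fragment pairs of the
minimum interatomic member-atom distance (caps excluded: they are
bookkeeping artifacts of the cut, not chemistry).  The default sense
*removes a subsystem whose R exceeds d_k*, i.e. retains compact subsystems
within the cutoff — the orientation consistent with the physics (distant
fragments interact weakly, only residues near the ligand matter) and with
the observation that distance cutoffs *reduce* subsystem counts.  The
inverted sense is occasionally written in the screening literature; it is
available as `distance_sense="literal"` for auditability.  Inequalities are
strict in both senses, so boundary values survive.

Energy: remove a k-mer iff |ΔE^low| < τ_k (strict, so τ = 0 removes
nothing).  Low-level subset energies flow through the shared store, each
computed at most once per run.  If any required subset evaluation fails to
converge the candidate is *retained* — when the screen cannot prove a term
negligible, the conservative action is to keep it — and the incident is
logged.

Default thresholds: τ₃ = 0.05 kcal/mol and d₂ = 8 Å with M = 1, the
combination that performs well for protein-scale screening; a two-body
energy threshold has no single good default (useful values span roughly
0.05–1 kcal/mol and trade cost against accuracy) and must be set
explicitly.  No default d₃ is set; cluster-style runs typically use
d₂ = 6 Å, d₃ = 5 Å.

## Fragmentation conventions

Residue fragments cut the Cα–C(O) backbone bond; the carbonyl group
travels with the *following* residue so each fragment is
N–Cα–sidechain + preceding carbonyl.  Each severed valence is capped with a
hydrogen placed along the cut-bond vector at 1.09 Å from the retained heavy
atom (a standard C–H length; deterministic, no optimisation).  A cap is
emitted in a subsystem geometry only when its partner fragment is outside
the subsystem; for interior cuts both real atoms are present and the caps
are dropped, which is what makes the all-fragment union reproduce the input
structure atom-for-atom.

Ionic cofactors merge with every residue having an atom strictly within
2.5 Å (minimum interatomic distance; merging is transitive via union-find,
hence idempotent, and a bridging ion is logged).  The ligand is never
merged and never fragmented: it must remain a separable monomer for ΔE_int
to be defined.  Fragment formal charges come from a residue-template table
(Asp/Glu −1, Lys/Arg +1 by default, His neutral unless overridden, ions by
formal charge, per-residue overrides available); every fragment defaults to
a singlet, and subsystem multiplicity combines spins as 1 + Σ(m_f − 1).
Crystallographic waters are dropped unless explicitly kept — water
selection is structure preparation, not computation.  Coordinates are Å
throughout and residue indices follow the source file (1-based).

## Toy potentials

The toy backend is E = Σ_{pairs, interfragment} [C q_i q_j / r + LJ(r)]
+ E_ind, with C = 332.0637 kcal·Å/(mol·e²).  Intra-fragment pairs are
excluded; fragments are rigid, so intra-fragment terms would be additive
constants that cancel in every correction anyway, and excluding them makes
isolated monomer energies exactly zero.

E_ind places one isotropic induced point dipole per fragment at the
centroid of its non-cap atoms, responding to the permanent charges of all
other fragments *and to the other induced dipoles*.  The mutual-induction
equations (α⁻¹ − T)μ = F are solved exactly as a dense 3f×3f linear system,
and E_ind = −½ C Σ μ_f·F_f.  Self-consistency is the point: linear-response
induction is genuinely many-body at every order, so the fixture produces
nonzero corrections up to order N — a field evaluated from permanent
charges only would truncate identically at third order (|ΣF|² expands
pairwise in its sources) and could not exercise the high-order machinery.
With α = 0 the potential is strictly pairwise additive, giving the exact
MBE(2) limit as a second oracle.  A singular induction solve is reported as
an unconverged evaluation, exercising the same failure path a real engine
would.

Units are fixed at kcal/mol, Å, e; hartree is accepted only at the
external-backend boundary (1 hartree = 627.5095 kcal/mol).  The energy
store is a single-file sqlite database keyed by SHA-256 of the canonical id
tuple, level tag and backend descriptor, giving insert-once semantics,
permutation deduplication, and no re-evaluation across reopenings.

## Synthetic fixtures

`make_cluster` packs N rigid water-like triatomics (0.9572 Å bonds, 104.52°
angle, TIP3P-like charges, α = 1.2 Å³) into a cube at 30 Å³ per fragment
with a 2.6 Å minimum center separation, by seeded rejection sampling
bounded at 10⁵ attempts per fragment.  These values are condensed-phase
molecular numbers: at this density a 40-fragment cluster screened with
d₂ = 6 Å, d₃ = 5 Å retains only a few percent of the C(40,3) trimers,
which is the sparse regime the graph machinery targets.

`make_toy_complex` emulates a metalloenzyme binding site: a five-atom
ligand of net charge −1, a +2 single-atom ion 2.9 Å from the ligand
centroid (inside 3 Å, outside every residue's 2.5 Å merge cutoff — like a
catalytic divalent ion coordinating the ligand, it must stay a separate
fragment), one −1 acidic residue adjacent at ~4.6 Å, and neutral triatomics
shell-packed between 5 Å and the configured radius.  All fragments are
polarizable (ligand α = 2.5 Å³) so three-body and higher terms are real.
By construction the ligand–ion pair is the largest two-body term and
neutralising the ion shrinks |ΔE_int| — both asserted in tests.

What the fixtures do *not* emulate: real force-field physics, charge
transfer, exchange, conformational flexibility, or actual PDB binding
sites.  Passing tests therefore demonstrate the correctness of the
expansion, screening and resummation *bookkeeping* under a many-body
potential, and say nothing about the accuracy of any electronic-structure
method on real complexes.

## Numerical choices and problem sizes

* "Zero" tolerance for additivity/telescoping assertions: 1×10⁻⁸ kcal/mol.
* Test and acceptance problem sizes: exact identities on N ≤ 8 (where the
  complete expansion is enumerable), coefficient checks to N = 10, the
  counting-regime demonstration at N = 40 with k = 3; these sizes already
  make every property binding while keeping the whole suite in seconds.
* Ties: distance and energy inequalities are strict everywhere, so values
  exactly at a threshold survive; float equality at a cutoff is measure-zero
  but the convention is still fixed deliberately.
* Degenerate inputs: empty keys, order-1 distance queries, coincident
  atoms, missing subset energies, absent ligand and unparseable files all
  raise typed errors (`mbescreen.errors`) naming the offender.

## Known limitations

* No bundled quantum chemistry, solvation, counterpoise correction or
  basis-set handling; the external backend expects a command that prints a
  single energy.
* No overlapping-fragment (MFCC-style) schemes and no ligand
  fragmentation; the ligand is always one monomer.
* Graph construction is serial and in-memory; it is comfortable to
  N ≈ a few hundred fragments at n ≤ 4 but is not a distributed engine.
* The toy induction model is linear response with fragment-level isotropic
  polarizabilities — a fixture for exercising many-body structure, not a
  force field.
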