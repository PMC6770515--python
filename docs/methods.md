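# Methods

This note documents the models, conventions and design choices behind
`interfrag`, in the spirit of a methods section: what is computed, under
which assumptions, and where the package deliberately stops.

## Interface extraction

The extraction operates on a complex partitioned into target, ligand
and water residues.  Waters are recognised purely by residue name
(default set WAT, SOL, H2O, HOH — the first three are the common MD
dialects, HOH the crystallographic one) on any chain; the name rule
takes precedence over the ligand chain selector, so a water placed on
the ligand chain is still a water.  The ligand is everything else on
the user-selected chain(s); the target is the remainder.

A target residue is selected when `d_cls ≤ d_TL`, where `d_cls` is the
minimum Euclidean distance between heavy atoms of the residue and heavy
atoms of the ligand.  Heavy atoms are used on *both* sides (a symmetric
convention; hydrogens are often absent or unreliable in input
structures, and their inclusion would make selection depend on the
protonation protocol).  Selection is monotone in `d_TL` by
construction.

Selected residues are grouped into maximal contiguous runs per chain.
Sequence adjacency is positional within the chain's residue list, so
insertion-code neighbours count as sequential.  Each run is then

1. grown by up to `n` sequential neighbours on each end (clipped at
   chain termini); the default `n = 0` adds nothing;
2. merged with a neighbouring run when exactly one residue separates
   them, that connector being included (iterated to a fixed point, so
   chains of single gaps collapse; the operation is idempotent);
3. extended by disulfide partners: any cysteine whose SG lies within
   `ss_cutoff` (default 2.3 Å; a covalent S–S bond is ≈ 2.05 Å) of a
   selected cysteine's SG joins as its own run, and gap merging is
   re-applied.  Growth happens before merging; the order is observable
   only when a grown run closes a former double gap, and the
   grow-then-merge order produces the smaller fragment set.

### Capping

A fragment cut out of the chain interior is sealed into a chemically
complete peptide:

* cut N-terminus → acetyl (ACE) group, reusing the preceding residue's
  C, O and CA atoms (the CA becomes the methyl carbon) and adding three
  constructed hydrogens;
* cut C-terminus → N-methylamide (NME) group from the following
  residue's N (plus its amide H when present) and CA as methyl carbon,
  again with three constructed hydrogens;
* true chain N-terminus → protonated amino group: three hydrogens on
  the backbone N;
* true chain C-terminus → carboxylate anion, left unchanged.

Constructed hydrogens sit at 1.09 Å (C–H) or 1.01 Å (N–H) from their
parent atom, at the tetrahedral angle 109.47° from the bond to the
backbone, staggered (dihedrals 60°/180°/300°) relative to a reference
substituent.  These values are standard idealised geometry; the QM
relaxation downstream is expected to refine them.  The construction is
exact, and tests assert bond lengths to 1e-6 Å and angles to 1e-4
degrees.  When the flanking residue is itself an existing ACE/NME cap
(re-extraction of already-capped output), its CH3 atom stands in for
the CA, which makes extraction idempotent on its own output.

### Formal charges

Charges are per-residue formal charges at pH 7: Asp/Glu −1, Lys/Arg +1,
all other standard residues 0, plus +1 for a free (protonated)
N-terminus and −1 for a free C-terminus.  Explicit protons override the
defaults: Asp/Glu with HD2/HE2 score 0; cysteine scores 0 when
disulfide-bonded or carrying HG and −1 otherwise; histidine scores by
ring protons (HD1 and HE2 → +1, exactly one → 0, none → −1 — the
doubly-deprotonated imidazolate, an uncommon state mapped to the only
remaining proton pattern).  The side-chain table is configurable so
non-standard residues can be added; a non-peptidic ligand takes an
explicit `ligand_formal_charge` instead.  The complex charge is the sum
over fragments and ligand (waters are neutral) and is written into the
output PDB as a `REMARK 250 TOTAL CHARGE: <int>` line, which the parser
reads back — so the charge survives a round trip.

## Hydration shells

Water–solute distances are measured from the water oxygen to solute
heavy atoms; hydrogens are ignored because upstream water-placement
tools supply oxygen positions and hydrogen orientations are arbitrary
before QM relaxation.  A water is interfacial when it is within
`d_max` (default 5 Å) of **both** the target and the ligand.  Waters
whose oxygen lies strictly closer than `d_min` (default 1.75 Å) to a
ligand heavy atom are removed as clashes; a water at exactly the limit
is kept.

The shell classification distance is `d_w = max(d_to_target,
d_to_ligand)`.  The max convention is chosen for consistency with the
"both partners" interfacial rule: it makes Shell 3 (all interfacial
waters) coincide exactly with Shell 1 ∪ Shell 2, so the bookkeeping
`|Shell 1| + |Shell 2| = |Shell 3|` holds identically, as it does in
every row of the shipped benchmark table.  A `min` convention is
available as a switch for sensitivity analysis.  Shell 1 is `d_w ≤
3.5 Å`; Shell 2 is the remainder; Shell 3 is always derived, never
stored.

`d_w` (the extraction-time water cutoff) and `d_max` (the
hydration-editing cutoff) default to the same 5 Å but are kept as two
parameters because they act at different stages of the workflow.

## Interaction energy screening

For each extracted target residue the package evaluates

    E_inter = Σ_ij [ A_ij/r_ij^12 − B_ij/r_ij^6 + k_C q_i q_j / (ε_r r_ij) ]

over all (residue atom, ligand atom) pairs, with `A_ij = ε_ij R_ij^12`,
`B_ij = 2 ε_ij R_ij^6`, `R_ij = R_i + R_j`, `ε_ij = √(ε_i ε_j)`.  The
geometric-mean rule for the well depth is the standard Amber/Lorentz–
Berthelot energy rule (and the only reading under which `ε_ij` is a
well depth).  The Coulomb constant is fixed at
`k_C = 332.0636 kcal·Å·mol⁻¹·e⁻²` and `ε_r = 1` by default.  No
distance cutoff is applied — the extracted interface is small, so the
full double sum is exact and cheap.  Waters never enter the sum; it is
a target–ligand screening quantity.  Hydrogens are included whenever
parameters exist (a heavy-atom-only mode is available).

Parameters come from a TSV table keyed by `(res_name, atom_name)` with
an `ALL` wildcard for shared backbone entries and water-name aliasing.
The built-in table carries representative Amber-style values (backbone
atoms of the standard residues, the side chains relevant to the charge
logic, caps, TIP3P-like water) and is meant for interface screening
only; production force-field work should load a complete table.
Missing entries either raise (`strict`, the default when the user
supplies a table) or contribute zero with a warning (`zero`, used when
falling back to the built-in table on arbitrary ligands).

Residues with `E_inter` above +10 kcal/mol (configurable) are flagged
as clashes: at that scale LJ repulsion dominates and the geometry needs
molecular-mechanics relaxation before any QM calculation.

## QM input files

MOPAC-style inputs use the layout: keyword line / title / blank line /
one line per atom with element and `x flag y flag z flag`, coordinates
at 5 decimals, flag 1 = optimise and 0 = frozen.  Default keywords are
PM7 (Hamiltonian), MOZYME (localised molecular orbitals, needed at
interface sizes), EF (eigenvector following), PREC, GEO-OK, MMOK
(molecular-mechanics peptide-bond correction), `GNORM=1` (gradient-norm
exit), and `CHARGE=<total formal charge>`.  `EPS=78.3` — the dielectric
constant of water — selects COSMO implicit solvent; leaving `eps` unset
means a vacuum calculation, and values ≤ 1 are rejected.  Freeze modes:
`none`, `calpha` (atoms named CA), `heavy`, or a custom predicate
(e.g. disulfide sulfurs during COSMO runs, where unconstrained S–S
bridges can open).

PDB I/O is a deliberately small fixed-column reader/writer: ATOM and
HETATM are treated equally, alternate locations resolve to the
highest-occupancy copy (ties to the first encountered), elements come
from the element column when present and otherwise from the atom-name
convention (leading digits stripped, first letter — sufficient for
protein/water/organic atoms; two-letter metals need an element column),
and coordinates are written at the PDB's 3-decimal precision.
Malformed records fail with the line number; duplicate atoms within a
residue fail as integrity errors.  The writer's output is cross-checked
against an independent PDB library in the test suite.

## Thermodynamics and statistics

The end-point reaction heat treats all interfacial waters as coming
from bulk (T = L = 0, s ≥ 0):

    Δ_rH = Δ_fH(complex·[H2O]_s) − Δ_fH(target) − Δ_fH(ligand) − s·Δ_fH(H2O)

The energy-table interface accepts one `Δ_fH(target)` number per
system; whether that is a single QM run over all fragments jointly or a
sum of per-fragment runs is the user's workflow choice — both reduce to
one number here.

The scaling regression `ΔH_b(exp) = α·Δ_rH + β + ε` is ordinary least
squares, optionally through the origin.  The statistics conventions are
fixed, not optional, because they are what makes the published
benchmark numbers reproducible from the printed residuals alone:

* with intercept (p = 2): `SStot = Σ(y − ȳ)²`, error dof `N − 2`;
* without intercept (p = 1): uncentred `SStot = Σy²`, error dof `N − 1`;
* `R² = 1 − SSres/SStot`, `F = (SStot − SSres)/(SSres/dof)`,
  `RMSE = √(SSres/dof)`, and for a single-predictor model
  `t_α = √F`.

`stats_from_residuals` evaluates this block from residual magnitudes
alone (only squares enter, so printed |ε| values suffice).  Applied to
the shipped benchmark residual columns it reproduces the published R²
within 0.01 and F/RMSE/t within the two-decimal rounding of the inputs
— the test suite and the acceptance script both perform this check for
all nine solvent models.  Degenerate cases: zero residuals report
R² = 1 with infinite F; constant-`y` data with nonzero residuals report
R² = −∞ rather than a division error.

Leave-one-out cross-validation refits the model N times excluding each
system, accumulates `PRESS = Σ(y_i − ŷ_(−i))²` and reports
`R²_cv = 1 − PRESS/SStot` with `SStot` in the model's convention and
the full-sample mean (per-fold means would change `SStot` across folds
and break comparability with the in-sample R²).

The regression itself is implemented in closed form; the test suite
verifies the whole statistics block against statsmodels as an
independent implementation, and against hand-evaluated normal
equations.

Unit conversion uses the thermochemical calorie, 1 cal = 4.184 J, i.e.
kcal/mol = kJ/mol ÷ 4.184.

## Synthetic data

The toy generator emulates exactly the geometric features the
algorithms consume: a target chain with ideal backbone geometry
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, extended conformation,
residues ~3.78 Å apart), ligand probe atoms placed so chosen residues
have exact closest-heavy-atom distances, water oxygens placed by
two-sphere intersection at exact (target, ligand) distance pairs,
disulfide SG pairs at ~2.05 Å, and optional explicit protons for the
charge rules.  Every planted quantity is re-measured after generation
and a mismatch raises, so fixtures are self-validating.  Placement is
fully deterministic; the seed only drives optional jitter on atoms
outside all planted distances, and identical specs give byte-identical
PDB output.

What the generator does *not* emulate: realistic side-chain packing and
conformational diversity, crystallographic disorder, genuinely
non-peptidic ligand chemistry, or physical water networks.  Passing
tests therefore demonstrate algorithmic correctness of selection,
capping, classification, energetics and statistics — not the accuracy
of the QM enthalpy pipeline on real complexes, which additionally
depends on water-position prediction and the QM level, both outside
this package.

The synthetic parameter-recovery study mirrors the benchmark's
conditions: 15 systems per replicate, reaction heats uniform in
[−500, −90] kcal/mol (the range implied by enthalpies of −3 to −15.5
kcal/mol under a 0.031 scaling), α = 0.031, Gaussian noise
σ = 2 kcal/mol (the RMSE scale of the best published models).  Under
these conditions the no-intercept fit recovers α within three standard
errors in ≈ 99% of 500 replicates.

## Limitations

* The built-in non-bonded table is minimal by design; `E_inter` values
  for exotic ligands silently use zero parameters unless a full table
  is supplied (with a warning, and `strict` mode to forbid it).
* pKa effects beyond explicit-proton bookkeeping are out of scope; the
  charge rules assume pH 7 and standard residues.
* The published leave-one-out R² values of the benchmark cannot be
  recomputed from residuals alone (they need the underlying reaction
  heats), so `loo_cv_r2` is validated against synthetic oracles only.
* Running MOPAC, molecular-dynamics hydration, and RESP/GAFF parameter
  derivation are outside the package; it prepares inputs and consumes
  resulting heats of formation.
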