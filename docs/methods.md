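# Methods

## Scope and model

`ebdiff` analyzes the *difference* between two per-residue energy
decompositions — a reference structure and a designed mutant of identical
length under a shared 1..N residue numbering.  It does not compute energies
from coordinates: the inputs are score tables in which a structure's total
energy is decomposed into one-body rows (a residue's internal terms) and
two-body rows (the interaction of one residue pair), each split into named
score terms (attraction, repulsion, solvation, electrostatics,
hydrogen-bond classes, a disulfide term, …) in Rosetta Energy Units (REU;
for the standard soluble-protein function roughly 1 kcal/mol per REU).
Totals are read as-is and never recomputed, and the parser takes its term
columns from the file header, so tables produced under other scoring
functions load unchanged.

A pair is *interacting* in a table when it has a row whose |total| exceeds
`presence_eps` (default 1e-9 REU).  Score-table producers only emit rows
for pairs inside the interaction graph, so absence from the table is the
natural non-interaction signal; the epsilon additionally treats an explicit
zero row as non-interacting.  Both tolerances below are configurable.

## Category and type classification

Walking the union of pair keys of the two tables, each pair interacting on
at least one side falls into exactly one of

* present on both sides, |Δtotal| ≤ `change_eps` (default 1e-6 REU) —
  unchanged, not reported;
* present on both sides, changed — category **A** (no member mutated) or
  **B** (≥ 1 member mutated);
* reference only — **C** / **D** by the same mutation criterion;
* mutant only — **E** / **F**.

Pairs in which *both* members are mutated count as mutation-involving
(B/D/F); the one-member wording of the category definitions leaves this
case open and treating it as non-involving would be misleading.  One-body
rows are diffed separately and reported as per-residue deltas, not mixed
into the pair categories.

Physical types are operational reconstructions from the score terms:

* each hydrogen-bond class fires when its term is negative (`hbond_sc`,
  `hbond_bb_sc`, `hbond_sr_bb`, `hbond_lr_bb`);
* disulfide: both residues CYS and `dslf_fa13` ≠ 0;
* salt bridge: one residue in {ARG, LYS, HIS}, the other in {ASP, GLU},
  and `hbond_sc` < 0.  Histidine's protonation state is unknown to a
  score-table analysis, so HIS is included by default and a
  `strict_salt_bridge` mode excludes it;
* every pair belongs to the catch-all type "all".

For pairs present on both sides (A/B) the type set is the union of the
rule evaluated on each side, so a bond existing in only one structure is
still reported.  Geometric criteria (distances, angles) are deliberately
out of scope: the score decomposition is the single source of truth here.

## Significance

Interaction-energy changes larger than +1.0 REU or smaller than −1.0 REU
are significant (strict inequalities; a change of exactly ±1.0 is not).
The total change sums everything; the significant change sums only the
survivors, preventing thousands of sub-0.1-REU fluctuations from masking a
−3 REU salt bridge.  At threshold 0 the two coincide.  Reports sort
ascending by delta (most stabilizing first, ties broken by pair key) so
repeated runs are byte-identical.

## Net residue energy

A residue's net energy is its one-body total plus the totals of all pair
rows it participates in.  By default each pair contributes its full value
to both members — the reading most useful for "how much does this residue
interact" — which double-counts pairs when summed over residues; a
`half_pair` flag charges half to each member instead, making the residue
sum reproduce the table's grand total.  Neither convention is canonical;
the default is documented and switchable.

## Residue depth

Depth is computed natively from a deterministic solvent-accessible dot
surface rather than by delegating to an external molecular-surface binary.
Every heavy atom is sampled with a fixed spherical-spiral (Fibonacci)
pattern of `samples_per_atom` points (default 960) on the sphere of radius
vdW + probe (probe 1.5 Å; vdW radii C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å, unknown elements 1.70 Å with a warning).  Points strictly inside
any other atom's expanded sphere are discarded.  A residue's depth is the
mean over its heavy atoms of the distance to the nearest retained point
(hydrogens excluded, for robustness to protonation differences); this
mean-atom convention, rather than Cα depth, is the package's fixed choice.
Nearest-point and occlusion-neighbour queries run through a k-d tree whose
results equal brute force exactly.

Because a solvent-accessible surface is traced by the probe *center*, it
lies about one probe radius outside a solvent-excluded surface; absolute
depths carry that systematic offset, while relative depths and any
layering analysis are unaffected.

Two properties are engineered rather than incidental:

* **Rigid-motion covariance.**  Each atom's sample directions are laid out
  in a local frame built from smoothly weighted neighbour moments (weights
  (1 − d/cutoff)² over neighbours within a cutoff of 2·(max vdW + probe);
  z-axis from the first moment of unit directions, x-axis from the
  orthogonalized second moment).  The frames rotate rigidly with the
  structure, so depths are invariant under translation and rotation to
  floating-point precision.  Smooth sums make the frames immune to the
  exact distance ties that break nearest-neighbour ordering in symmetric
  point sets; degenerate neighbourhoods (a lone atom, exact collinearity)
  fall back deterministically to laboratory axes.
* **Locality.**  The weight vanishes at the cutoff and occlusion cannot
  act beyond it either, so atoms added ≥ 2·(max vdW + probe) away change
  no existing depth.

## Synthetic ground-truth generator

The generator emulates the two inputs the analysis consumes, with the
truth recorded on the side.

**Mock breakdown tables.**  A plan fixes residue count (default 60),
mutations (default scaled to plan size), per-category planted-change
counts, a type mix, and a seed; a single explicitly seeded generator
drives everything.  For each planted pair the generator constructs
presence/absence on each side, residue types satisfying the intended
physical type (several admissible residue combinations per type;
type-constrained pairs are placed first and preferentially reuse already
typed residues, so dense plans on 60 residues remain satisfiable), and
score terms whose sum *is* the row total.  Planted deltas are drawn from
±[1.2, 4.0] REU (clearly significant) or ±[0.05, 0.9] REU (clearly
insignificant); the band [0.9, 1.2] around the ±1.0 threshold is left
empty so threshold tests never hinge on floating-point luck —
exact-boundary behaviour is tested separately with hand-written values.
Unchanged background pairs and one-body rows (shifted at mutated
positions) complete the tables; grand totals are accumulated independently
while writing, and values are printed at full precision so parsed sums
match the bookkept ones to ~1e-12.

**Toy structures.**  Helix (1.5 Å rise/residue, 100°/residue),
extended chain (3.5 Å/residue), or a layered atom ball for depth tests.
The ball places residues on concentric layers 1.5 Å apart with
within-layer radial stagger (so burial ranks are distinct) and small
coordinate jitter (so symmetry never degenerates the local frames).  The
atom constellation of each residue is centered (zero mean offset), which
removes orientation bias from the mean-atom depth, and boundary-layer
residues carry two tangential rings of stub atoms projected onto their
sphere — a closed, nearly smooth outer shell that the probe cannot
penetrate.  These choices give a clean monotone depth-vs-burial signal
(Spearman ρ ≈ 0.96 at 60 residues) and sampling-density stability
(240 → 960 samples/atom changes depths by < 0.11 Å).

**What the generator does not emulate.**  Energies are bookkeeping
constructs, not physics: terms are not correlated the way a real force
field correlates them, geometry and energy tables are generated
independently of each other, and the toy structures have ideal stub
geometry rather than rotamers.  Passing tests therefore demonstrate that
the bookkeeping, classification, thresholding and geometry algorithms are
correct — not that any particular real protein's energetics are
reproduced.  Real-structure results additionally depend on the upstream
relax/energy software, which is outside this package (an optional
`run-external` CLI adapter shells out to such executables when the user
has them; it is never exercised by the tests).

## Numerical choices

* Grand totals use exact (compensated) summation, so they are independent
  of row order.
* Occlusion uses a 1e-9 Å slack: a point lying exactly on another atom's
  expanded sphere is kept (two coincident atoms keep both point sets).
* CSV writers print floats at full precision (`repr`), making round trips
  bit-exact; data files contain no timestamps (the JSON manifest does), so
  repeated runs are byte-identical.
* Alternate locations collapse to the highest occupancy, ties to the first
  listed; insertion codes are dropped; renumbering is one global 1..N
  counter across chains in file order, and multi-chain inputs are accepted
  with that single counter as the only residue key.
* Sequences of unequal length are rejected outright — the intended use
  compares a design against its template, which shares length; indel
  alignment is explicitly not attempted.  Non-standard residues (e.g.
  MSE) are rejected rather than silently translated.

## Problem sizes

The test and acceptance workloads use 20 plans × 200 planted pairs on 60
residues for the diff chain (sub-second in total) and the 60-residue ball
at 960 samples/atom for depth (~2 s per surface build); both are
comfortably representative — the diff logic is exercised across every
category × type combination, and the ball spans burial depths from ~3 to
~9 Å.

## Known limitations

* Absolute depths are solvent-accessible, not solvent-excluded; compare
  depths only within one convention.
* Type rules are score-term heuristics; a salt bridge here means "opposite
  formal charges with an active side-chain hydrogen-bond term", not a
  geometric contact criterion.
* The analysis is static: conformational ensembles, dynamics and epistatic
  re-relaxation effects are outside its scope, and REU differences are not
  calibrated free energies.
* Reports treat the renumbered index as the universal residue key; users
  must renumber both inputs consistently (the `clean` command does this).
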