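# Methods

## Contact clustering and the cluster count N_c

Two solute molecules are direct contacts in a frame when at least one
pair of their atoms — heavy *or* hydrogen — lies within a cutoff
distance under the minimum-image convention.  A single qualifying atom
pair suffices: requiring more contacts would need a per-chemotype
calibration (molecule shape and flexibility change how many atom pairs
a genuine association presents), whereas the single-contact criterion
applies uniformly across topologies.  A `min_contacts` parameter and a
heavy-atom-only switch exist for sensitivity analysis but default to 1
and `all`.

Clusters are the connected components of the resulting contact graph
(union-find with path compression); isolated molecules count as
singleton clusters, so a fully dispersed frame has N_c = N_mol.  The
comparison at the cutoff is inclusive (distance ≤ cutoff), reading
"within" in the conventional way.

The default cutoff is 3.0 Å for atomistic systems: smaller values miss
nearest-neighbour contacts, while values beyond 5–6 Å begin to join
molecules that are merely adjacent.  For the smooth single-bead systems
produced by the bundled simulator the atomistic value is meaningless
(bound bead centres sit near 2^(1/6) σ apart); there
`recommended_contact_cutoff` returns 1.5 σ, the first-minimum-of-g(r)
bonding criterion conventional in colloidal cluster analysis.

## Periodic geometry

Cells are stored as three lattice vectors.  The truncated octahedron —
the standard cell for solvated small-molecule MD — is represented as
the triclinic cell with a = b = c and α = β = γ = arccos(−1/3)
≈ 109.471°, volume a³√(16/27).  Minimum-image displacements refine the
rounded fractional-coordinate candidate by scanning the 27 surrounding
images; plain rounding alone can select a non-nearest image in skewed
cells, and the truncated octahedron is skewed enough to hit that case
in practice.

Contact search runs either as a vectorised all-pairs scan (`brute`) or
through a cell list built in fractional space (`cell_list`), with grid
dimensions bounded by the cell's perpendicular widths so that any pair
within the cutoff shares adjacent (periodic) grid cells; candidates are
then screened with the same minimum-image metric, so the two methods
agree bit-for-bit.  The cell list is implemented in-house: during
development the grid backend of the general-purpose neighbour search in
MDAnalysis (`nsgrid`) was found to miss genuine contacts in the
truncated-octahedron cell (verified against explicit 125-image
enumeration), so it is used nowhere in the pipeline; the tests retain
MDAnalysis's KD-tree search as an extra independent cross-check on
cubic cells, alongside the explicit 27-image/DFS oracle.

## Population profiles, fC_5 and classification

Analysis operates on a fixed number of equispaced frames (default
5000), always including the first and last frame: index i of n maps to
⌊i·(F−1)/(n−1)⌋.  The population profile is
P(k) = 100·#{frames: N_c = k}/#frames, and
fC_5 = 100·#{frames: N_c < 5}/#frames with a strict inequality —
frames at exactly five clusters do not count.  Both statistics use the
same frame subset.

Classification is aggregator iff fC_5 ≥ 20%.  The threshold
operationalises the observed empirical band: compounds measured as
non-aggregators produce fC_5 below 20%, while known aggregators start
at 36%, leaving a gap in which any threshold would work; 20% sits at
its lower edge so that weak-but-real aggregation is not missed.  It is
exposed as a parameter.

Profile shapes are a labelled heuristic, not a fitted model: the
profile mode strictly inside the lowest 20% of the k-range is
"aggregated-exponential", strictly inside the top 20%
"dispersed-exponential", anything interior "bell"; ties among equal
modes break toward the extremes.  Replicate summaries report the mean
and *sample* (n−1) standard deviation of fC_5 and classify from the
mean; replicas must share analysis parameters.

## The sticky-sphere simulator

The synthetic generator stands in for solvated MD at desk scale:
N = 12 single-bead molecules (optionally rigid linear trimers) in a
periodic 60 Å cubic box, evolved by the position-Langevin update
x ← x + (F/γ)dt + N(0, √(2kT·dt/γ)) with minimum-image pair forces.
The pair potential uses the Weeks–Chandler–Andersen splitting of the
Lennard-Jones potential: the repulsive core acts with at least unit
strength so beads stay impenetrable even with no attraction, and the
attractive tail is scaled by ε (in kT) and truncated at 2.5 σ; for
ε ≥ 1 this is the plain LJ potential of well depth ε.  ε plays the
role solute hydrophobicity plays in explicit solvent: ε = 0 gives a
dispersed near-ideal suspension, ε = 4 kT drives irreversible-looking
aggregation into one or two clusters.

Default conditions, chosen once: σ = 10 Å (so the box is 6 σ — a
volume fraction of ~3%, dilute but concentrated enough that diffusive
encounters occur many times per run), dt = 10⁻⁴ τ (τ = σ²γ/kT; the
step must resolve the stiff ε = 4 kT core, whose relaxation time is
~4×10⁻³ τ), 2×10⁵ steps saving every 200, friction γ = 1 so D = 1 in
reduced units.  Initial placement is random sequential insertion with
a 1 σ separation floor (the stand-in for a high-temperature mixing
phase), raising a density error after 10⁴ consecutive rejections.  Any
step displacing a bead further than σ/2 aborts with an instability
error rather than silently capping forces.  Runs are bitwise
reproducible per seed.

What the generator emulates: diffusive encounter, short-range
attraction-driven self-assembly, and the two limiting population
profiles, with a monotone fC_5 response to ε.  What it does not:
chemistry — no solvent structure, hydrogen bonding, electrostatics,
conformational flexibility, or force-field detail.  Tests passing on
this generator therefore validate the *analysis chain* (geometry,
clustering, metrics, classification), not the ability of any particular
force field to rank real compounds.

In simulator-driven tests the first 20% of frames are discarded as
burn-in before computing fC_5, since the run starts from an artificial
dispersed placement; the analysis layer itself never drops frames.

## Protocol and composition writers

The emitted protocol encodes the reference solvated-MD schedule:
minimisation, NVT heating 0→500 K over 20 ps (to distribute the
solutes), NVT cooling 500→300 K over 20 ps, 2 ns NPT at 300 K/1 atm,
and 1 µs production at 300 K saving every 20 ps — all dynamics stages
at dt = 2 fs with hydrogen-bond constraints, a 10 Å non-bonded cutoff
and Langevin friction 1.0 ps⁻¹.  Step counts are exact integers
(production: 5×10⁸ steps, save stride 10⁴).  Files are AMBER-style
namelists with sorted keys and fixed number formats, so re-emission is
byte-identical.  Minimisation cycle counts and the NPT
pressure-coupling scheme have no authoritative source values; the files
mark them as defaults in comment lines.

Composition arithmetic: solute molarity n/(N_A·V); NaCl pairs
round(c·N_A·V) with banker's rounding; DMSO count from a named molar
volume constant (71.3 cm³ mol⁻¹ at 25 °C, configurable) rather than a
magic number.  The "~180 Å octahedral box" is interpreted as the
truncated-octahedron cell parameter (cubic available by flag), giving
V ≈ 4.49×10⁶ Å³ and hence 4.07 mM for 11 solutes — the millimolar
regime, far above micromolar critical aggregation concentrations —
and 135 ion pairs at 50 mM.

## Descriptor screen

Threshold rules are strict by default ("logD > 3" leaves a compound at
exactly 3.0 a non-aggregator), with an inclusive variant by flag.
Success rates are reported to one decimal (31/32 → 96.9).  Descriptors
are consumed from CSV, never computed.  The bundled 32-compound table
is synthetic except for a few published single values noted in its
header; its error structure (logD misclassifying three compounds, the
MD call one) exercises the comparison machinery with realistic
disagreement patterns.

## Degenerate inputs and numerical choices

Cells with |det| ≤ 10⁻⁹ Å³ are rejected as degenerate.  The cell-list
method refuses cutoffs ≥ half the smallest perpendicular cell width
(falling back to `brute` is suggested in the error).  Empty N_c series,
empty selections, truncated trajectory records (reported with the
offending frame index), non-contiguous molecule ids and mixed replica
parameters all raise early with specific messages.  Population sums are
validated to 10⁻⁹; XYZ round-trips are exact to the 10⁻³ Å the format's
six-decimal output allows.

## Problem sizes

Validation uses 200 random frames (5–50 molecules of 1–40 atoms) for
oracle equivalence, 500 random point pairs for minimum-image checks,
100 random series for profile invariants, and 3 seeds × 4 ε values ×
2×10⁵ steps for the simulator sweep — sizes at which the brute-force
oracles remain exact and the whole suite runs in a few minutes on one
CPU.

## Known limitations

- The fC_5 threshold k = 5 is calibrated for ~11–12 solute copies; at
  very different N_mol the metric needs re-anchoring (it is a
  parameter).
- The profile-shape labels are a coarse heuristic and are reported as
  such; no functional form is fitted.
- The simulator's rigid trimers translate without rotational
  diffusion; they exist to exercise multi-atom bookkeeping (heavy vs
  all-atom masks), not to model anisotropic assembly.
- No cluster-lifetime/kinetics analysis, interaction-energy
  decomposition, or mapping from fC_5 to experimental critical
  aggregation concentrations.
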