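# Methods

## System model

The package analyses a protein–RNA complex of four parts: an Argonaute
protein (682 declared residues, of which 18 are unresolved, leaving 664
Cα positions for per-residue analyses), a 15-nt guide (miRNA) strand, a
15-nt perfectly complementary target (mRNA) strand, and Mg²⁺ ions — two
"inner" catalytic ions buried near the PIWI domain plus, in the high-ion
condition, ten additional ions free to diffuse in a cubic periodic box of
edge 152 Å (10 ions in that volume ≈ 4.73 mM, i.e. 5 mM to the nearest
mM). Domains follow author residue numbering: PAZ is the union of
20–100 and 170–260, MID is 326–462, PIWI is 463–678; all ranges are
configurable on `DomainMap`.

Residue numbering is 1-based author numbering throughout. Missing
residues are inferred per chain as the gaps between a declared residue
range and the residue ids observed in the coordinate file; the accounting
invariant resolved + missing = declared is enforced at construction and
violating input is rejected, never repaired. Selections simply omit
missing residues. Hydrogens are read and kept but excluded by default
from superposition selections (`heavy_only=True`).

Trajectories are multi-model PDB on disk (a TSV per-frame coordinate
table is accepted for fixtures); PDB carries no time stamps, so frame
times come from a configurable start/stride (default 1 ps). Coordinates
survive a write/read round trip to the stored precision (3 decimals).

## Duplex pairing energy

Pair k joins target position k (5′→3′) with guide position L−k+1; in
strict Watson–Crick mode every pair must be A–U or G–C. The duplex is
partitioned into Region1 = pairs 1–4, Region2 = 5–11, Region3 = 12–15
(configurable, must be contiguous and disjoint). The regional average at
a frame is the mean of that region's per-pair energies; the whole-duplex
average is the mean over all 15.

The per-pair energy is a pairwise nonbonded sum over the atoms of the two
nucleotides: Coulomb kₑ qᵢqⱼ/(εᵣ rᵢⱼ) with kₑ = 332.0636 kcal·Å/(mol·e²),
plus a 12-6 Lennard-Jones term with Lorentz-style combination
εᵢⱼ = √(εᵢεⱼ), Rᵢⱼ = Rmin½ᵢ + Rmin½ⱼ. Distances are min-imaged when the
system is periodic (cubic boxes only). Parameters come from a TSV table
keyed by (residue name, atom name); a missing entry raises, so energies
are never silently computed with zeroed parameters. Terms are accumulated
with exact summation (`math.fsum`) so the energy is bit-exact symmetric
in its two nucleotides.

Two atom-inclusion modes exist because "base-pairing energy" is
ambiguous about backbone atoms: the default includes only base atoms
(heavy plus base hydrogens; pairing is a base–base interaction), and a
whole-nucleotide mode adds the ribose/phosphate set. The relative
dielectric defaults to 1 (no implicit-solvent screening; generalized-Born
style screening is out of scope). Neither mode claims to reproduce any
particular force field's absolute energies — the analysis is about
regional *differences* between conditions, which the factorial model
estimates from whatever energies are supplied.

Default sampling for energy profiles is every 5 ps over the 7–10 ns
window (601 time points, inclusive endpoints), configurable down for
desk-scale fixtures.

## Conformational entropy

Per-residue Cα RMSF is computed after aligning all frames on the same
selection being profiled: frames are first aligned to the raw
time-average structure (making the result invariant to frame order), the
aligned mean is formed, and frames are re-aligned to it;
RMSF_i = √(mean_t |r_i(t) − r̄_i|²). Residues are binned ordered
(RMSF < 3 Å, strict) versus disordered, and S = −Σ pᵢ ln pᵢ in nats, with
0·ln 0 := 0, so S ∈ [0, ln 2]. The 3 Å threshold is configurable. When a
condition has several replicates, S is computed per replicate and
averaged; a pooled mode is available since either reading of "one S per
system" is defensible.

## Factorial model and contrasts

Observations are long-format rows (energy, region, group, replicate,
time). The full-interaction model Energy ~ Region + Group + Region×Group
is fitted by OLS with treatment coding and reference levels (Region1,
high); all six cells must be populated. Each region's ΔE =
mean(low) − mean(high) is a linear contrast L·β̂ with SE from the
full-model residual variance, t = ΔE/SE on n − 6 df, two-sided p. On
balanced data the contrast estimate equals the raw cell-mean difference
exactly, and the choice of coding is immaterial.

One property worth knowing: the full-model contrast pools the residual
variance across all six cells. When cell variances differ (as the
regional SDs do), the 95% CI over-covers regions quieter than the pooled
average and under-covers louder ones; across the family of three regional
contrasts, coverage is nominal (~0.95 in seeded simulations). This is a
property of the pooled-variance test itself, retained deliberately
because it is the prescribed analysis; a per-region Welch test is
available (`two_sample_t`) for comparison.

The whole-duplex comparison uses a two-sample t test (Welch by default,
pooled optional) on the per-observation whole-duplex averages. The paired
comparison of the two conditions' RMSF profiles uses a one-sample t on
per-residue differences (one-sided "greater" option for directional
hypotheses); all-zero differences give t = 0 by convention, while
constant nonzero differences raise (`ZeroVarianceError`) rather than
reporting an infinite t. Entropy-versus-ion-count trends use simple least
squares (slope, intercept, R²), with the convention slope = 0, R² = 0 for
a constant response.

## Superposition and contacts

Superposition is the Kabsch algorithm: SVD of the cross-covariance of the
centered point sets, with the smallest singular direction negated when
needed to force det(R) = +1, so mirror images superpose with nonzero RMSD
rather than through a reflection. Degenerate inputs (< 3 points, or
fewer than 3 non-collinear) are rejected. Tests cross-check against
scipy's quaternion-based `Rotation.align_vectors` to 1e-9 Å; the two
routes are independent implementations.

Domain reports superpose each domain (PAZ = union of both subranges) and
the whole protein independently over the heavy atoms common to both
structures, matched by (chain, residue, atom name); a domain with no
common atoms is flagged, not dropped. Condition-versus-condition
comparisons use the last frame of each trajectory as the "final
structure" (no averaging). Closest-pair traces report the minimal
inter-set heavy-atom distance per frame, ties resolved to the lowest
(residue_a, residue_b).

An ion is bound when its minimum-image distance to any target atom is
strictly below the cutoff (default 5 Å); equality at the cutoff is free.
Minimum-image arithmetic supports cubic boxes only and is never applied
when `periodic=False`.

## Synthetic systems: what they emulate, and what they do not

`generate_complex` builds a coarse protein — Cα plus two dummy heavy
atoms per residue on a 5 Å serpentine grid, self-avoiding by
construction — and the duplex as an ideal ladder (3.4 Å rise) whose
Watson–Crick donor–acceptor contacts sit 2.9 Å apart: three polar
contacts for G–C, two for A–U. The shipped toy parameter table gives
donors positive and acceptors negative partial charges balanced to make
every base net-neutral (so separated pairs decay like dipoles), which
makes G–C pair energies strictly below A–U on the ladder. The two inner
ions are placed within 5 Å of PIWI-range Cα atoms; extra ions start
uniform in the box.

`generate_trajectory` draws, per frame, one isotropic Gaussian
displacement per residue applied to all its atoms. The σ parameter is
the *target radial RMSF* (per-axis sd σ/√3), so a residue generated at
σ = 1 Å recovers RMSF ≈ 1 Å; with 10⁴ frames the estimator lands within
5%. Default profiles make the high-ion condition uniformly stiffer
(least so in PIWI, most in PAZ) with a disordered fraction of 0.08 (low)
versus 0.065 (high) at σ = 4.5 Å; the disordered sets are nested across
conditions so paired RMSF differences are non-negative residue-by-
residue. Extra ions random-walk (2 Å steps, periodic wrapping); a free
ion within 10 Å of the complex binds with per-frame probability 0.05,
sticks 3 Å from its anchor atom, and releases with probability 0.001.
An optional rigid per-frame drift exercises alignment. Every trajectory
ships a ground-truth record (true σ per residue, disorder fraction, true
per-frame bound-ion counts).

`generate_energy_table` draws i.i.d. Normal observations per
Region × Group cell directly at the observation level; defaults are the
six reported cell means/SDs with 4 replicates × 601 time points
(= 2,404 observations) per cell, each (group, replicate) pair on its own
seeded stream. This observation-level path feeds the statistics tests;
the geometric energy kernel is validated separately on ladder fixtures,
and the two routes are never mixed in one test.

What passing tests therefore show: the estimators (superposition, RMSF,
entropy, contrasts, counts) recover known ground truth under the stated
noise model, with correct determinism, conventions and error handling.
What they do not show: anything about real MD trajectories — absolute
pairing energies, the printed entropy values, domain RMSDs or binding
kinetics all depend on a real force field and solvent model, which this
package deliberately does not run. Time-correlated fluctuations,
anisotropy, and conformational transitions of real proteins are likewise
outside the generator's model.

## Numerical and design choices

- Seeds: a single global seed expands to per-purpose, per-replicate
  streams via fixed integer offsets (`default_rng([seed, stream, ...])`);
  all outputs are bit-reproducible under a fixed seed, and written tables
  use fixed float formatting so reruns are byte-identical.
- Altloc policy on PDB read: highest occupancy, first encountered on
  ties. Non-numeric coordinate fields are reported with their line
  number; a trajectory frame with the wrong atom count is reported with
  its (0-based) frame index.
- Empty atom selections are legal but logged as warnings (they usually
  indicate a typo), except where an operation is meaningless without
  atoms (RMSD/RMSF), which raise.
- Pipeline default scale is 4 replicates × 400 frames per condition and
  the full 4 × 601 energy table; a complete two-condition run takes
  ~20 s on one CPU. All sizes are configurable in `RunConfig`/YAML.
- The pipeline retains per-replicate outputs alongside pooled statistics
  so both pooling interpretations of the entropy can be inspected, and
  logs per-stage counts (frames, atoms, residues) to make silent
  truncation visible.

## Known limitations

- The energy kernel is a generic Coulomb + 12-6 LJ pairwise sum; it is
  parameter-table-driven and makes no claim of matching CHARMM or any
  other force field's "base-pairing energy" term set.
- Minimum-image support is cubic-only; triclinic boxes are rejected.
- The ion-kinetics model is Markovian and geometric; it reproduces
  qualitative bind/stick/release behaviour, not physical rate constants
  or the timing of binding events.
- mmCIF and binary trajectory formats (DCD/XTC) are out of scope, as are
  clustering/PCA of trajectories and secondary-structure assignment.
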