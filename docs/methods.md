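# Methods

## The accessibility model

Aliphatic hydroxylation by P450s proceeds through hydrogen-atom transfer
(HAT) to the oxo oxygen of Compound I; the HAT transition state places the
abstracted hydrogen close to the oxo atom with the C–H···O=Fe arrangement
roughly collinear with the attack direction. A force field cannot hold a
trajectory at transition-state distances, so accessibility is scored
against reactant-complex-like geometry instead: per frame, for every
candidate hydrogen, the distance d(H···O) and the angle θ(H–O–Fe) with the
oxo atom at the vertex. θ is defined at the oxo vertex deliberately — the
index is usually drawn, not written, and the vertex choice is the only
reading under which a collinear Fe=O···H approach maps to θ near 180° and
side-on approaches to smaller θ.

A frame is a near-attack configuration for site s when

1. the globally closest candidate hydrogen belongs to s (closest-H rule),
2. d ≤ d_max (default 2.8 Å), and
3. θ_min ≤ θ ≤ θ_max (default 125°–150°),

all bounds inclusive. The closest-H rule makes site attribution exclusive:
at most one site can satisfy per frame, so per-site counts partition the
satisfying frames and the frequencies among satisfying frames sum to 1.
The distance-only variant drops the windows entirely and attributes every
frame to the site of its globally closest hydrogen; those frequencies sum
to 1 over all frames. An alternate normalization of satisfied-site counts
over all frames is reported alongside (`all_frames_frequencies`).

A relaxed mode (`require_global_closest=False`) judges each site on its own
closest hydrogen; the set of per-frame passing sites is then a superset of
the strict rule's single attribution. It exists for sensitivity analysis,
not as the default.

Exact distance ties between hydrogens are broken toward the terminal site
(documented site order: ω before ω-1 before ω-2R …), then by hydrogen atom
name, and are logged; with continuous coordinates they essentially never
occur, but the rule keeps classification total and deterministic.

## Units, indexing, conventions

Coordinates are always Å, angles degrees, energies kJ/mol; conversions
happen only at I/O boundaries. Frames are 0-indexed everywhere, including
reports. Atom selectors are (residue_id, atom_name) pairs — serial numbers
are rewritten too freely by MD tooling to be trusted. Hydrogens must be
explicit in the input; nothing is inferred (the intended inputs are
all-atom models). Trajectories must have constant topology; a mismatch is
an error naming the offending frame, never a silent repair. Multi-model
PDB is the reference trajectory path; XTC/TRR/DCD with a PDB topology are
converted through MDAnalysis behind the same contract. Periodic-boundary
unwrapping and superposition are out of scope — inputs are assumed whole.

## Prochirality

The two hydrogens of an internal methylene become distinguishable (pro-R /
pro-S) because substitution at that carbon would create a stereocenter.
With substituent priority fixed as toward_omega > toward_chain > H, a
hydrogen is pro-R when the determinant of the priority-ordered bond-vector
matrix (v_H, v_omega, v_chain) is negative, pro-S when positive. This is
the isotope-promotion rule in signed-volume form (cyclic row permutation
preserves the determinant sign), and it was cross-checked against an
independent CIP implementation on an idealized tetrahedral fixture; that
fixture and its frozen labels live in the test suite. Mirror-imaging all
coordinates flips every label — a property the tests exercise end to end
through generated trajectories. Centers with |det| < 1e-6 Å³ are rejected
as degenerate rather than guessed. Assignment is made once on frame 0 and
held fixed (topology is constant); which physical hydrogen is R vs S in
any external topology is a convention internal to this package.

## Conformers

The truncated substrate tail has two relevant rotamers differing in the
placement of the chain-truncation carbon. Operationally a frame is
conformer 1 when the terminal branch torsion falls in the anti bins
(120°, 180°] ∪ (−180°, −120°], conformer 2 in the gauche bin (0°, 120°],
and "other" outside both. The bins are configuration, not code: they live
in the site YAML and must partition (−180°, 180°] without overlap. The
census is reported both over all frames and over criteria-satisfying
frames only. Frame clustering for representative-structure selection runs
k-means on sine/cosine-embedded torsions (circular-safe: −179° and +179°
are neighbours) with k-means++ seeding at fixed seed, and returns medoids —
real frames — rather than centroids.

## Uncertainty

Trajectory frames are autocorrelated, so binomial standard errors on
frequencies would be optimistic. The package uses a moving-block bootstrap
over the frame-outcome sequence (default block 50 frames, about 100 ps at
a 2 ps saving interval; 2.5/97.5 percentile intervals; deterministic for a
fixed seed). The defaults are a starting point: the right block length
depends on the occupancy autocorrelation time of the actual system, and
the generator's AR(1) mode exists precisely to exercise this choice.

## The synthetic generator

The generator emulates the statistical structure of an enzyme holding one
end of a substrate near the oxo: per frame it draws a presented site from
the occupancy vector p, a window-pass flag from Bernoulli(q), and a
(d, θ) pair — d from a truncated normal (mean 2.6 Å, sd 0.3 Å), θ from a
von Mises (mean 137.5°, sd ≈ 10°) — conditioned inside or outside the
default windows by resampling, so satisfying_fraction → q and the
frequencies → p are exact analytic truths. Treating pass/fail as an
explicit mixture (rather than letting q emerge from the distribution tails)
is what makes the recovery targets sharp. All other site hydrogens are
pushed out by a +1.5 Å background offset (record level) or by construction
(coordinate level).

The coordinate level builds a minimal Compound I fragment (Fe at the
origin, oxo on +z at 1.62 Å, four pyrrole nitrogens, axial thiolate) and an
isohexane-like tail — terminal methyl (3 H), branched CH (1 H), two
methylenes (2 H each), branch and cap methyls as spectators — from ideal
internal coordinates, then rigidly places it so the presented hydrogen
realizes the sampled (d, θ) exactly on the cone of angle θ about the oxo,
with the tail pointing radially away from the oxo and a rejection step
guaranteeing no competing site hydrogen comes closer. The Fe–oxo distance
and ideal bond parameters are conveniences of the generator, not physical
claims. Per-frame coordinate jitter (σ = 0.01 Å) keeps frames from being
exact copies without threatening any classification margin.

The `vk1-like` preset fixes the study conditions used throughout the tests
and the acceptance script: p = (0.92, 0.05, 0.02, 0.01) over
(ω, ω-1, ω-2R, ω-2S) with zero occupancy at ω-3, q = 0.30, and conformer
fractions (0.85, 0.15) — an ω-dominant regime in which conformer 1
prevails; the conformer split is the generator's own choice of a clearly
dominant-but-not-exclusive mixture.

What the generator does **not** emulate: protein and solvent atoms,
force-field energetics, realistic kinetics of site exchange (the optional
AR(1) persistence is a caricature for testing the block bootstrap), or
correlated d–θ dynamics. Passing recovery tests therefore demonstrates
that the measurement and classification machinery is correct and unbiased
under known truth — not that any particular biological conclusion holds.

## Reactivity reference and ranking

The packaged table carries DFT activation energies (kJ/mol) for HAT at
each site of the truncated substrate tail in both conformers; the three
terminal-methyl hydrogens are separate entries in conformer 1 only, and the
missing conformer-2 entries are absent, not zero. The table is reference
data — recomputing it is electronic-structure work outside this package's
scope. Comparisons are ordinal only; no Boltzmann or transition-state-rate
conversion is applied. For ranking, the ω family collapses to its minimum
(most reactive) barrier. The combined basis orders sites by accessibility
and uses barriers only to break exact frequency ties, recording a note
wherever the two orderings conflict; this encodes the package's central
claim that geometric access dominates intrinsic reactivity for this class
of selectivity.

## Numerical choices

* Angles use the atan2 form (norm of cross, dot), stable at 0° and 180°;
  torsions use the standard signed atan2 construction on successive bond
  normals, range (−180°, 180°].
* PDB coordinates carry three decimals; round-tripping is therefore exact
  to ~1.7e-3 Å in d and ~0.04° in θ at typical distances, and the
  generator's round-trip tests assert 2e-3 Å / 0.1°.
* Bootstrap resampling indexes blocks with a vectorized gather; fixed seeds
  make every stochastic output (generator streams, PDB bytes, bootstrap
  intervals, k-means assignments) reproducible bit-for-bit.
* Degenerate geometry (zero-length rays, collinear torsion atoms,
  near-planar prochiral centers) raises typed errors; nothing is clamped.

## Problem sizes

The default test suite and the acceptance script generate trajectories of
up to 20,000 frames (27 atoms per frame), the size at which the 3-standard-
error recovery bands are decisive for the preset probabilities; smaller
fixtures (hundreds of frames) back the unit tests. These sizes are the
package's own verification choices and complete in about a minute each.

## Known limitations

* The criteria windows (2.8 Å, 125°–150°) are defaults taken from
  reactant-complex geometry arguments for one enzyme–substrate pair; other
  systems will need their own calibration, which is why they are plain
  parameters.
* Site labels are a fixed vocabulary (ω family through ω-3); arbitrary
  substrates need only supply their own labels, but the packaged reactivity
  table and presets are specific to the six-carbon tail model.
* The prochirality R/S convention is internally consistent and
  mirror-correct but not anchored to any external topology's naming.
* No free-energy, kinetics, or Markov-state analysis is derived from the
  frequencies; the accessibility profile is a geometric census, nothing
  more.
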