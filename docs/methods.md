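# Methods

## The standardized membrane frame

All geometry is expressed in a frame tied to the receptor dimer and the
membrane. The user designates, per receptor chain, a *membrane anchor*:
the membrane-proximal terminal residue of the structured ectodomain,
whose Cα is the reference point for inter-receptor distance. The frame
is then

* **origin** — midpoint of the two receptor chains' Cα centroids
  ("receptor center" is deliberately defined as the Cα centroid of the
  chain; any consistent center works, and the centroid is reproducible
  without side chains);
* **Z** — unit vector from the midpoint of the two anchor Cα positions
  toward the origin. The membrane is located only through the anchors,
  so Z is "away from the membrane" by construction; no bilayer model is
  involved;
* **X** — component of the fixed→mobile inter-anchor vector orthogonal
  to Z, normalised; **Y = Z × X** (right-handed).

Degenerate inputs (coincident anchors, inter-anchor vector parallel to
Z within 1e−6) raise a frame error rather than producing an arbitrary
basis.

## Rigid-body sampling

One receptor is fixed; the mobile receptor (plus the binder engaging
it) moves rigidly. A transform is six DOFs: rotations about the frame
axes composed in the fixed order **Rz·Ry·Rx** (fixed so that θ_z
extraction from a sampled pose is well defined; a pitch within 1° of
gimbal lock raises a warning) and a translation in frame coordinates.
Gaussian mode draws each DOF independently from N(0, σ_DOF) centred on
the native geometry; grid mode enumerates a Cartesian product in a
documented axis order. The σ values per system are deliberately exposed
configuration, not constants: sensible magnitudes are tens of degrees
for θ_z and a few Å for translations, but they are assay-design
choices.

The rotation center defaults to the mobile receptor's Cα centroid
(pure reorientation). A flag switches to rotation about the frame
origin — orbital motion, which sweeps the mobile anchor through the
membrane plane and is the regime in which lateral deviation changes.
Both motions occur in practice; the default favours the one that keeps
descriptors independent.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; a scan is bit-reproducible given
(structure, configuration, seed), and the CLI records a deterministic
`run_digest` over exactly those inputs in every manifest. The manifest
also carries a wall-clock timestamp for provenance; reproducibility
claims attach to the digest, not the timestamp.

## Clash filtering

A hard-sphere criterion: heavy-atom pairs strictly closer than the
cutoff (default 3.0 Å) between distinct chains; intra-chain pairs are
never counted. A geometry passes when the pair count is at most
`max_allowed_pairs` (default 0). The cutoff is a configuration value —
3 Å heavy-atom is a conventional "severe clash" threshold; there is no
energy function here and none is intended. Neighbor search uses a k-d
tree; correctness is checked in the tests against O(n²) double loops on
random instances.

## Geometry descriptors

For a sampled pose relative to the native complex:

* **termini_distance** — Cα–Cα distance between the two membrane
  anchors (Å); **delta_distance** subtracts the native value;
* **theta_z** — the rotation of the mobile receptor about the frame Z
  axis, extracted from the relative rigid transform (native → sample)
  of the mobile chain via an Rz·Ry·Rx Euler decomposition in the frame
  basis; reported in (−180°, 180°];
* **lateral_deviation** — the angle at the frame origin between the
  XY-plane projections of the native and sampled mobile-anchor
  positions, in [0°, 180°]. This is one precise reading of "lateral
  displacement in the membrane plane"; it is invariant under
  translations parallel to Z and equals the rotation angle for orbital
  motion about the origin.

Descriptors assume the mobile chain moved rigidly; a post-fit Cα RMSD
above 1e−3 Å against the native internal geometry is an error, not a
silently wrong number. Identities used as oracles: the native pose maps
to all-zero deltas; a pure Z-rotation by α gives θ_z = α; a 90°
origin-rotation gives lateral deviation 90°.

## Panel selection

Experimental panels (e.g. 96 designs for a screening plate, 24 for a
quick probe of a novel receptor pairing) are chosen by greedy
farthest-point sampling in descriptor space (Δd, θ_z, lateral), each
descriptor scaled by its spread so Å and degrees are commensurate, with
optional per-descriptor weights. The first pick is the most native-like
passing sample (ties broken by id), so every panel contains an
anchor point near the natural geometry. The procedure is deterministic;
tests verify the selected subset's minimum pairwise separation beats
100 random subsets of the same size.

## Fusion specs and design validation

* **Contig specs.** For each fusion orientation (binder A C-terminus →
  binder B N-terminus, and the reverse) the scaffold gap is the Cα
  distance d between the joined termini; the minimum scaffold length is
  ⌈d / 3.8 Å⌉ — 3.8 Å being the maximal Cα–Cα extension per residue —
  clamped to ≥ 1, and the maximum adds a slack of 40 residues by
  default. The 3.8 Å constant and the slack are configuration. The
  contig grammar is the conventional
  `<chain><start>-<end>/<Lmin>-<Lmax>/<chain><start>-<end>` text form.
* **Redesign mask.** Designable = all scaffold residues plus any binder
  residue with a heavy atom within 5.0 Å of a scaffold heavy atom,
  minus user-supplied receptor-interface residues and any blocked
  positions. The interface list is structure-specific and must be
  supplied; it is returned frozen.
* **Align-back filter.** The native receptors are superposed onto a
  returned design by a least-squares (Kabsch) fit of the shared binder
  Cα atoms; clashes between the repositioned receptors and the new
  scaffold reject the design. The fit requires ≥ 3 shared Cα atoms and
  its RMSD is reported.
* **Score thresholds.** pLDDT and RMSD comparisons are inclusive
  (≥ 85, ≤ 2 Å by default — defaults of this toolkit, exposed in
  config); the PAE comparison is strict (< 10), so a design at exactly
  the limit fails. An optional minimum interface contact count
  (residues within 5 Å) handles early-round triage.

## C2 assemblies and helical extensions

Homodimeric agonists are modeled by rotating the protomer 180° about
the frame Z axis through the origin, remapping chain ids, and reporting
inter-protomer clashes (never silently dropping the assembly). The
symmetry check computes the Cα RMSD between protomer B and the rotated
protomer A. Terminal fusion anchors are produced by continuing a
terminal helix with ideal α-helical Cα geometry (1.5 Å rise, 100° twist
per residue): the local helix axis is the screw axis of the rigid map
sending the terminal Cα window onto itself shifted by one residue,
which requires ≥ 4 Cα and a screw-fit residual ≤ 0.5 Å (otherwise the
terminus is declared non-helical). Extensions are Cα-only placeholders
marked designable; full-backbone reconstruction and helical-fusion
database search are out of scope.

## Dose-response analysis

Responses are fitted to the 4PL model on log-dose by bounded
least-squares with heuristic multi-start initialisation (bottom/top
from the response extremes, EC50 from the mid-response crossing, Hill
slope 1; three additional seeded jittered starts). |Hill| is bounded to
[0.1, 10] to prevent degenerate step fits on sparse grids. The default
loss is ordinary least squares on raw responses; a log-response loss is
available and is the right choice under multiplicative noise.
Zero-dose baseline rows inform the bottom initialisation but are
excluded from the regression (log-dose undefined). Flat data returns a
converged fit with top ≈ bottom and a `no_response` flag rather than an
error. Canonical form: top ≥ bottom, with a negative Hill slope
recording a decreasing curve.

Normalisation: relative Emax = (top − bottom) of the design over that
of the wild-type reference fitted in the same cells and readout;
Δlog10 EC50 = log10(EC50_ref / EC50_design), positive when the design
is more potent (a threefold gain is +0.477).

Phenotype calls use two readouts (canonically pSTAT1 and pSTAT5) and
two thresholds, defaults high = 0.75 and floor = 0.10 — this toolkit's
defaults for classes that are qualitative in origin; both are recorded
in every call. Rule order: both below floor → inactive; pSTAT5
preserved with pSTAT1 attenuated → biased; both preserved → full
agonist-like; otherwise partial. The rule is monotone: raising either
relative Emax never weakens the call.

## Geometry–activity statistics

The permutation test shuffles the response vector (one
`rng.permutation` draw per shuffle, so any straightforward loop with
the same seed reproduces the null stream exactly) and recomputes R²;
p = #{null R² ≥ observed R²} / n_perm with n_perm = 10,000 by default.
That fraction convention can return p = 0, which is flagged; the
add-one convention (k+1)/(n+1) is available and is what the calibration
tests use, since it is exactly uniform under the null. Spearman's ρ is
reported alongside and can replace R² as the permutation statistic,
which makes p invariant to monotone transforms.

Class-wise descriptor comparisons use two-sided Mann–Whitney rank-sum
tests over all class pairs (exact for small tie-free groups, midrank
normal approximation otherwise — scipy's policy), with Holm adjustment
by default and the conventional significance codes (ns > 0.05,
* ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001). Groups below 3 members are skipped
with a warning.

## Synthetic study conditions

The fixture generators define the conditions under which the toolkit is
validated:

* **Toy complexes** — four Cα-only chains (two receptors, one binder
  each), laid as ideal helices (or random coils), with the requested
  chain centroids and anchor positions realised exactly (for helices by
  rescaling the helix pitch, so chains stay perfectly helical). They
  exercise every geometric contract — frames, rigid motion, clashes,
  descriptors, masks, C2 — but have no side chains, no realistic fold,
  and no AF2-like score distributions; passing tests demonstrate
  algorithmic correctness, not structural realism.
* **Dose-response data** — 8 log-spaced doses from 1 pM to 100 nM
  bracketing a 1 nM EC50, triplicates, 5% multiplicative CV by default:
  a typical pSTAT titration layout. Under exactly these conditions the
  Cramér–Rao bound for sd(log10 EC50) is ≈ 0.024, so roughly 8% of
  replicates necessarily fall outside ±10% of the true EC50 even for an
  ideal estimator; the acceptance suite documents this (the median
  |log10 error| criterion passes with a wide margin, the ±10%-coverage
  target sits beyond the information bound and the corresponding test
  records the shortfall honestly).
* **Geometry–activity benchmarks** — descriptors drawn over distance
  20–80 Å, θ_z ±180°, lateral 0–180°, with activity either linear in
  distance, collapsing beyond 90° lateral deviation, or independent
  (null), plus Gaussian noise. These span the regimes in which distance
  dominates for some receptor systems and lateral deviation for others.

## Known limitations

* Hydrogens are dropped and all distances are heavy-atom: reference
  structures rarely carry reliable hydrogens.
* Altloc policy is highest occupancy (tie → 'A'); multi-model files use
  model 1.
* `mutate` blocking is bookkeeping geometry (rename + strip beyond Cβ),
  not side-chain modeling.
* The clash model is hard-sphere counting; no energies, no relaxation.
* Backbone generation, sequence design and structure prediction are
  external tools; this package emits their inputs and consumes their
  score tables only.
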