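# Methods

## The model system

An actin filament is represented at Cα resolution as an ordered list of
subunits indexed along the genetic (single-start) helix. The index
increases toward the pointed end; consecutive indices alternate between
the two long-pitch protofilaments, so longitudinal (same-strand) neighbors
are *n* ± 2 and the lateral neighbor is *n* + 1. Each actin subunit carries
375 residues partitioned into the four canonical subdomains

* SD1 = 1–32 ∪ 70–137 ∪ 338–375
* SD2 = 33–69 (containing the D-loop, residues 44–52)
* SD3 = 138–180 ∪ 270–337
* SD4 = 181–269

with the target-binding cleft at 143–148 ∪ 349–351. Published subdomain
assignments differ by a few residues at the SD boundaries; all ranges are
configurable, and every selection-dependent result is reported against the
ranges in force. A bound cofilin bridges the longitudinal pair (*k*, *k*+2)
and is keyed by its barbed-side actin *k*. Units are Å and degrees
throughout; the conventional "< 1 nm" contact criterion is stored as a
strict 10 Å cutoff (pairs at exactly the cutoff are excluded).

A *periodic* filament marks one repeat of an effectively infinite
filament. Its fully decorated form carries one cofilin per bridgeable
pair **including** the pointed-most cofilin whose partner is the periodic
image one repeat up — so an 11-subunit periodic cofilactin has 10
cofilins, and replicating it once yields 22 subunits and 20 cofilins, the
dangling bridge being completed by the appended copy. On finite
(non-periodic) systems every bridge must be complete and the structure
validator enforces this.

## Observables

**Twist.** For each adjacent pair (*n*, *n*+1) the relative rotation is
estimated by least-squares rigid superposition (Kabsch, via SVD) of the
SD3+SD4 Cα set of subunit *n*+1 onto that of subunit *n*; the reported
twist is the rotation angle θ = arccos((tr **R** − 1)/2) of the fitted
matrix, stored at position *n*. The inner domains are used as the rigid
core because they form the filament's contiguous helical spine and are
least perturbed by the conformational change of interest, which lives in
the outer domain. Angles are reported as magnitudes in (0°, 180°]: the
handedness of the genetic helix is a constant of the system and carrying
its sign through every profile obscures rather than informs. An
alternative estimator (`method="projection"`) measures azimuth increments
of subunit centroids about a least-squares cylinder axis; both agree
exactly on ideal helical filaments and the screw method is the default
because it remains meaningful on bent or locally distorted filaments where
a single global axis does not.

**Flatness and cleft.** φ is the signed torsion of the ordered centroid
quadruple (COM SD2, COM SD1, COM SD3, COM SD4) — a torsion about the
SD1–SD3 axis that separates the outer (SD1+SD2) from the inner (SD3+SD4)
domain, following the right-hand biomolecular torsion convention. Subunit
"flattening" is an outer-domain rotation, which this ordering isolates.
The cleft distance is d = |COM(SD2) − COM(SD4)| (the nucleotide cleft);
the endpoint pair is configurable. Centroids use uniform Cα weights.

**Contacts.** Contact counts are exact pairwise Euclidean computations
(strict inequality at the cutoff). The D-loop profile counts the D-loop
Cα of subunit *n* against **all** Cα of its pointed-end neighbor *n*+2;
a restricted variant against the target cleft only is available through
`ContactSpec`. Interface integrity totals all-vs-all contacts per
longitudinal pair and flags zero-contact interfaces as ruptured.

**RMSD.** Per-frame RMSD of a pooled position selection after optimal
superposition onto a reference frame or external structure.

**Profile statistics.** Per-position means and population SDs over a
trailing window of frames (default: the most recent half), the analogue of
summarising only the equilibrated tail of a trajectory.

## Boundary construction

Slow-severing boundaries are spliced by aligning one cofilactin subunit
onto one bare subunit with a full-subunit Cα superposition and retaining
eight bare subunits (*i*−8..*i*−1) plus ten cofilactin subunits
(*i*..*i*+9). Fast-severing boundaries pool the SD3+SD4 Cα of four
subunits spanning *i*..*i*+3 from each input into a single superposition
(one rigid fit rather than an average of per-subunit fits — the simplest
estimator with a well-defined optimum) and retain cofilactin *i*−8..*i*+1
plus bare *i*+2..*i*+9. In both modes the eight cofilins whose bridged
pairs lie wholly inside the retained cofilactin segment are kept, which
leaves the interfacial subunits *i* and *i*+1 touching exactly one cofilin
each. Output positions are relabelled −8..9 with the interfacial index at
0. The fast construction inherently leaves the interfacial D-loops short
of their longitudinal partners, so its output carries a
`requires_relaxation` flag; no geometric pulling is performed — restoring
those contacts is a simulation-time operation, out of scope here.

A third mode, `fast_alt`, implements the alternative fast construction
(interfacial subunit starting actin-like, cofilactin segment on the barbed
side). Its retention rule necessarily differs: the two pointed-most
cofilins of the kept segment bridge across the splice into bare subunits,
so cofilins are retained whenever both bridged *positions* exist in the
output. The mode exists for completeness; the default fast construction is
the one whose interfacial subunits start cofilactin-like.

Longitudinal replication estimates the per-subunit screw transform from
the first adjacent pair, verifies the input is periodic under it (every
subunit within 0.5 Å RMSD of its helical prediction — configurable), and
appends rigid copies at the pointed end with occupancy keys shifted by one
repeat per copy. Cofilin ablation removes occupancy records without
touching actin coordinates; cluster sizes and arrangements
(longitudinal {*k*, *k*+2}, lateral {*k*, *k*+1}) follow from the kept key
set.

## The synthetic generator

Subunit templates place the four subdomain centroids analytically — SD1
above SD3 along the local filament axis, SD2 offset laterally above SD1,
SD4 offset below SD3 at azimuth φ about the SD1–SD3 axis, with the axis
length solved so the SD2–SD4 distance equals the requested d — then
scatter residues uniformly in boxes recentred on each centroid. Measured
φ and d therefore equal the prescribed values to machine precision, and
the generator is self-consistent with the analyzer's torsion convention by
construction (the SD4 azimuth's chirality is calibrated against the same
dihedral routine). The D-loop sits on a stalk extending toward the pointed
end; its extension is 14 Å in the bare-like template (producing robust
*n*:*n*+2 D-loop contacts) and 2 Å in the cofilactin-like template
(producing none, emulating cofilin's displacement of that contact).
Cluster half-widths (±4 Å laterally, ±17 Å axially for SD1/SD3) are chosen
so consecutive same-strand subunits overlap enough that body–body contacts
never vanish in intact filaments.

Filaments stack one template per position with cumulative rotation about
the filament axis and constant rise; the twist may vary per position.
Defaults are the cryo-EM helical symmetries (167.0°/subunit bare,
162.0°/subunit cofilactin) and the canonical 27.5 Å rise. Default subunit
conformations are φ = −9.0° (bare) and φ = −28.9° (cofilactin) — the
barbed- and pointed-side asymptotes of the slow-boundary flatness
transition — with cleft distances 25.0 Å and 23.0 Å; the flatness values
anchor the generator to the boundary-transition parameter sets used as
generating truth, while the cleft defaults are representative round values
on the few-Å bare/cofilactin contrast, chosen once. Cofilin placeholders
are 150-residue compact balls (radius 12 Å) centered between SD2 of the
barbed-side and SD1 of the pointed-side bridged actin; they exist for
occupancy topology and bridge-site geometry only. Frames add i.i.d.
Gaussian coordinate noise from seeded, frame-indexed streams, so outputs
are bitwise reproducible and individual frames are independent of how many
frames are requested.

Transition profiles are generated directly from the sigmoid
θ(n) = A₂ − (A₂ − A₁)/(1 + exp((n − n₀)/N)) plus Gaussian noise. Four
reference parameter sets (slow/fast × twist/φ) ship with the fitter and
serve as generating truth in recovery tests.

**What passing tests do and do not show.** The generator emulates the
*statistical structure* the estimators assume — helical placement,
position-dependent conformation, presence/absence of D-loop contacts,
bridging occupancy, Gaussian frame noise. It does not emulate protein
shape, sequence, anharmonic or correlated fluctuations, hinge bending, or
rupture kinetics. Exact round-trip recovery therefore validates the
estimators and constructions as algorithms; it says nothing about how
actual filaments behave, and noise-robustness results transfer to real
ensembles only to the extent that their fluctuations are approximately
isotropic and uncorrelated.

## Transition fitting

The fitter targets per-position means (profiles are summarised as means
before fitting, matching how such profiles are plotted and because
per-frame fits would weight high-noise positions identically anyway);
inverse-variance weighting by the per-position SD is optional since no
weighting convention is canonical. Initialisation: A₁ and A₂ from the
three most-barbed and most-pointed positions, n₀ from the first linear
interpolated crossing of their midpoint, N = 1, with N bounded below by
0.05 subunits. A profile whose side estimates differ by under 0.5° raises
a "no transition detected" error rather than returning a degenerate fit.
The printed form of the sigmoid is implemented in the unique reading
consistent with A₁ and A₂ being the barbed/pointed limits. Exponents are
clipped at ±500 so evaluation is finite at any position. Noise-free
recovery is exact to optimizer tolerance (< 1e-3 per parameter, residual
< 1e-8) for all four reference rows.

## Numerical choices and edge cases

* Superposition uses `scipy`'s SVD-based `align_vectors` with the residual
  recomputed from coordinates (the optimiser's reported residual loses
  ~1e-7 to cancellation near zero); proper rotations are guaranteed.
  Collinear point sets raise a numerical error. An independent quaternion
  (Horn) oracle in the test suite agrees to ≤ 1e-8 Å on random clouds.
* Splice minima are enforced per mode (slow: ≥ 9 bare / ≥ 10 cofilactin;
  fast: ≥ 10 / ≥ 12 — the fast alignment window extends two subunits past
  the retained cofilactin segment).
* Alignment transforms are computed on frame 0 and applied to all frames,
  so multi-frame inputs keep their internal fluctuation structure.
* Angle wrap-around: twist magnitudes live in (0°, 180°]; torsions in
  (−180°, 180°].
* Dihedrals of collinear centroid quadruples raise rather than return 0.
* Problem sizes: tests and the acceptance script run on 8–22-subunit
  filaments, up to a few hundred frames (2000 for scalar profile
  statistics) — ample for exact constructions and tight statistical
  checks at interactive runtimes.

## Known limitations

* Cα-only: no side chains, no sequence, no residue chemistry; contact
  counts are Cα-distance proxies, not atomic contacts.
* The twist estimator reports magnitudes; it does not resolve handedness
  changes.
* The boundary splicer produces *initial* models; their junction strain
  (visible as an off-trend twist at the junction pair) is the starting
  point a relaxation engine would work from, and no relaxation is
  provided.
* Auto chain-mapping of third-party PDBs assumes actin-sized (≥ 300
  residues) and cofilin-sized (< 200) chains and infers polarity from
  chain file order; ambiguous files need an explicit chain map.
* The periodic-occupancy convention (one dangling bridge at the pointed
  end) is a modelling choice for representing infinite decorated
  filaments; finite experimental constructs may differ.
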