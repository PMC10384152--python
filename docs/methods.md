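# Methods

This note records the models behind each statistic, the conventions chosen
where the literature leaves them open, and what the synthetic ground-truth
tests do and do not demonstrate.

## Geometry and units

All coordinates are nanometres internally (GRO native); XYZ files are
converted from Ångström on read. The promolecular NCI module works in
atomic units (bohr, a.u. density) because the RDG prefactor
(3π²)^(1/3) presumes them, converting at its boundary. Times are
picoseconds.

Boxes are orthorhombic, periodic in x and y, and by default *not* periodic
in z: the slab geometry puts vacuum above both monolayers, so z-images
carry no physics. Minimum-image displacements wrap each periodic component
into [−L/2, L/2]. Torsions follow the IUPAC convention (cis = 0°,
anti/trans = 180°) and are stored on [0°, 360°), which turns the gauche
test into a single inequality.

Atom identity is carried by role labels (`N1`, `C16`, `C4`, `C15`,
`O_carboxyl`, `OW`, `HW`) assigned from a user-supplied YAML/JSON sidecar
that maps atom names per residue; nothing is hard-coded into the parsers.
`C4` is the first tail carbon bonded to the nitrogen and `C15` the
terminal methyl; both are configurable because real topologies may number
atoms differently.

## Synthetic generator

The generator is the package's ground-truth instrument; its defaults
mirror the studied systems: an 8 × 8 × 24 nm box, a central 8 × 8 × 8 nm
water slab at 33.4 nm⁻³ (≈17 000 waters), equal surfactant counts on both
leaflets.

**Water slab.** Oxygen z-coordinates are rejection-sampled against
ρ(z) = ρ₀/2 [tanh((z−z_lo)/w) − tanh((z−z_hi)/w)], so the binned profile
matches the target within counting noise and the 10–90 width is known in
closed form (2 atanh(0.8) w). Hydrogens are attached with the rigid
3-site geometry (O–H 0.09572 nm, H–O–H 104.52°) at uniformly random
orientations. Orientations are random, not energetically relaxed, so
water–water hydrogen-bond counts in synthetic systems are far below real
water; the generator's planted-geometry constructor exists precisely to
test the detector with exact geometries instead.

**Surfactant chains.** Heavy atoms only, built from internal coordinates
(C–C 0.153 nm, C–N 0.147 nm, tetrahedral backbone angles, planar
carboxylate) by natural-extension placement. Each of the 12 torsions is
drawn trans (180°) or gauche (±60°, fair-coin sign) with its per-torsion
probability, optionally jittered with Gaussian noise. The default
probability profile (0.5, 0.6, 0.08, then a ~0.1 plateau rising to 0.15
at the tail end) emulates the head-high/tail-low pattern characteristic
of these monolayers. Chains with any non-bonded pair closer than 0.15 nm
are redrawn. This excluded-volume rejection removes ~0.7% of draws,
preferentially syn-pentane-like folds of the head over the tail, so the
*accepted* ensemble — not the nominal probabilities — is the planted
truth; the generator therefore records its realized torsion tallies,
drawn tilts and rejected-draw count as trajectory metadata, and the
rejection fraction bounds the depletion |E[realized] − p| exactly.

Heads sit on a jittered square lattice at each interface plane; the whole
chain is rigidly rotated so the C4→C15 axis makes a Normal(mean, sd) angle
with the outward leaflet normal (the rotation is exact, so a zero-sd tilt
is recovered to machine precision). Multi-frame trajectories are
independent conformational redraws at fixed head sites — snapshots for
statistics, not dynamics.

**All-trans length.** For an n-carbon all-trans zigzag each bond advances
b·sin(θ/2) along the chain axis. With an even bond count the end-to-end
length is the familiar (n−1)·b·sin(θ/2); with an odd count (the 11 C–C
bonds of a C12 tail) the endpoints sit on opposite sides of the axis and
the exact length is √(axial² + (b·cos(θ/2))²) = 1.37700 nm. The package
uses the exact, parity-aware form.

**Telegraph kinetics.** Hydrogen-bond occupancies are modeled as
independent two-state Markov chains with rates k_off (bound→free) and
k_on. Sampling uses the exact two-state propagator over dt, so the
intermittent autocorrelation is exactly
C(t) = p + (1−p) e^(−(k_on+k_off) t), p = k_on/(k_on+k_off) — the
closed-form oracle for the correlation and lifetime machinery. Lifetime
recovery is tested at 10⁴ pairs × 2000 steps of 0.1 ps over effective
decay times 2–20 ps.

## Analysis conventions

**RDF.** Pair histograms use minimum-image distances, shell-volume
normalization 4πr²Δr, and a *bulk* target density measured in a central
z-window of the slab (the global box density would not plateau at 1 in an
inhomogeneous slab). Defaults: 0.002 nm bins to 1.2 nm. The first valley
is located on a Savitzky–Golay-smoothed g(r) (5-bin window, quadratic) as
the minimum between the first prominent peak (prominence 0.1) and the
next; ties break to smaller r; a curve with no prominent peak raises an
error rather than guessing. Coordination numbers integrate the binned
g(r) trapezoidally.

**SDF.** Local frames use head-internal atoms only, making the SDF
attitude-independent: for C16, x along the bisector of the two
carboxylate oxygens and z normal to the O–C16–O plane; for N1, x along
N1→C4 and z normal to the N1–methyl–methyl plane (orthonormalized).
Occupancies are normalized by frames × reference sites and exported as
Gaussian cube files; the first-shell radius should be the RDF first
valley measured on the same trajectory.

**Hydrogen bonds.** Distance cutoff 0.35 nm, closed thresholds (planted
boundary geometries count as bonded, with a 1e−9 float epsilon). The
angular criterion's vertex is genuinely ambiguous in common usage, so
both conventions are first-class: `HDA` (angle at the donor between D–H
and D–A, ≤ 30° by default; the GROMACS-style test) and `DHA` (angle at
the hydrogen, ≥ 120° by default). The package default is HDA ≤ 30°. The
quaternary nitrogen is excluded from donating and accepting — it has four
covalent bonds. Correlation uses the intermittent convention (a pair that
breaks and re-forms still counts), estimated with all time origins and a
per-lag denominator so C(0) = 1 exactly.

**Lifetimes.** Finite systems give C(t) a nonzero plateau that a unit-sum
exponential mixture cannot represent, so the lifetime integrates the
plateau-subtracted, renormalized curve: p̂ is the tail mean (last 20% of
lags), Ĉ = (C − p̂)/(1 − p̂), and τ = Σaᵢbᵢ from the constrained fit of Ĉ.
Two numerical guards matter: the fit window stops where Ĉ first drops
below 0.02 (beyond that the curve is Monte-Carlo noise, and a spare
exponential term fitted to noise inflates τ), and timescales are bounded
by 4× the window (nothing slower is observable). Fits use eight
deterministic log-spaced starts; ties go to the smallest leading
timescale. The unwindowed fit of the raw curve is reported alongside as
`tau_raw`; on plateaued input it is dominated by a pseudo-constant term
and is only useful as a diagnostic.

**Conformation.** Gauche means |φ − 180°| > 60° strictly, so 120°/240°
remain trans. Tilt angles are measured against each molecule's outward
leaflet normal (+z above the water slab's center of mass, −z below,
frozen from the first frame; the box midplane is the fallback without
labeled waters); 0° points to vapor, 90° lies in the interface, 180°
points into water. Angle averages are plain arithmetic means in degrees —
the distributions live far from the 0/180 wrap. Chain lengths are
Euclidean C4–C15 distances without minimum-image wrapping (a 1.4-nm tail
cannot legitimately span half of any studied box edge).

**Density profiles and thickness.** Profiles are per-bin counts over
lx·ly·Δz, frame-averaged, 0.02 nm bins by default. The bulk value is the
raw-profile mean over the central 25% of the region above half maximum.
Both the 10% and 90% crossings are located on a lightly smoothed profile
by linear interpolation, taking the *outermost upward* crossing of each
level walking inward from the vacuum side. (An innermost-90% rule was
tried first and discarded: bulk-noise dips below 90% of the plateau make
it latch onto the slab interior.) Crossing positions carry statistical
noise of order σ_ρ/|dρ/dz|; at 10⁵ waters per frame this is ~1–2% of the
width per frame pair, so the ground-truth recovery runs average 200
independent frames to hold a 3σ margin inside its 2% tolerance. Both
flank thicknesses are reported plus their mean.

**Promolecular RDG.** The electron density is the promolecular
approximation: a sum of spherically averaged free-atom densities, each a
three-term Slater fit ρ_elem(r) = Σⱼ cⱼ e^(−r/ζⱼ) for H, C, N, O —
the standard self-contained route to NCI analysis, and the only density
this module claims to describe. Gradients and Hessians are fully
analytic (verified against central differences to <1e−6 relative).
λ₂ is the middle Hessian eigenvalue. Scatter data keep points with
ρ ≤ 0.05 a.u. (the usual NCI window); grids default to 0.1 bohr spacing
with a 3 bohr margin. One empirical note: for a closed-shell O···O
contact the lowest-RDG spike points sit at the bond-critical-point region
with λ₂ slightly negative; positive-λ₂ points appear off-axis at RDG well
below the isolated-atom floor, and the tests assert exactly that.

## Pipeline

`slabstats run` executes configured stages in order on one input (a
generator spec or a GRO file plus annotation sidecar), writes per-stage
text outputs and a JSON summary, and logs every applied default. Exit
codes separate configuration errors (2), input/parse errors (3) and
numerical failures (4). Identical config and seed reproduce deterministic
stages byte-for-byte.

## Problem sizes

The bundled checks are sized for a desk machine: thickness recovery uses
3 × 200 frames of 10⁵ waters; lifetime recovery 4 rate points of
10⁴ × 2000 telegraph samples; gauche/tilt recovery 288 molecules × 50
frames; detector equivalence 100 random 50-water boxes; RDG scans use
dimers and single atoms at 0.12–0.15 bohr spacing. The full suite runs in
about a minute.

## Limitations

* Synthetic frames are independent redraws; nothing in the generator
  produces realistic time correlations except the telegraph module, which
  is kinetics without geometry. Passing recovery tests therefore
  demonstrates estimator correctness, not force-field realism.
* Synthetic water orientations are random, so absolute hydrogen-bond
  counts in generated systems are not water-like.
* The promolecular density ignores charge transfer and relaxation; RDG
  features are qualitative indicators, as in any promolecular NCI
  analysis.
* Orthorhombic boxes only; no binary trajectory formats; no energetics.
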