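# slabstats

Structure statistics for zwitterionic-surfactant monolayers at the
air–water interface.

Surfactants such as n-dodecyl betaine (NDB) — a quaternary ammonium and a
carboxylate in one head group, a C12 alkyl tail — adsorb at the water–vapor
interface as two monolayers flanking a planar water slab. Characterizing
those monolayers from molecular configurations is a standard battery of
analyses, and this package implements the full battery as a tested library
with a thin CLI:

* **Hydration structure** — radial distribution functions g(r) of water
  around the head-group nitrogen (N1) and carboxylate carbon (C16), first
  RDF valley location, coordination numbers
  n = 4πρ_bulk ∫₀^r_v g(r) r² dr, and spatial distribution functions (SDFs)
  of first-shell waters in a head-fixed local frame, exported as Gaussian
  cube files.
* **Hydrogen bonding** — geometric detection (donor–acceptor distance
  ≤ 3.5 Å plus an angular test, both common vertex conventions supported),
  per-head bond counts, the intermittent time-correlation function
  C(t) = ⟨h(0)h(t)⟩/⟨h⟩ with multiple time origins, constrained
  multi-exponential fits C(t) ≈ Σᵢ aᵢ e^(−t/bᵢ) (Σaᵢ = 1), and lifetimes
  τ = Σᵢ aᵢbᵢ.
* **Chain conformation** — the 12 backbone torsions from the head CCNC
  dihedral to the terminal CCCC dihedral, gauche-defect probabilities
  (|φ − 180°| > 60°), tilt angles of the tail (C4→C15), whole molecule
  (C16→C15) and polar head (C16→C4) against the outward surface normal,
  and tail end-to-end length distributions.
* **Interface geometry** — water number-density profiles along the normal,
  the 10–90 interfacial thickness (for a tanh profile of width parameter w
  the closed form is 2 atanh(0.8) w ≈ 2.1972 w), and per-surfactant area
  bookkeeping A = lx·ly/(N/2).
* **Weak interactions** — promolecular NCI analysis: reduced density
  gradient RDG = |∇ρ| / (2(3π²)^{1/3} ρ^{4/3}) and sign(λ₂)ρ on a grid,
  with analytic gradients and Hessians of a Slater-fit atomic density sum;
  hydrogen bonds appear as low-RDG spikes at negative sign(λ₂)ρ.

A first-class synthetic generator (`slabstats.synth`) builds water slabs
with a tanh density profile of known width, surfactant leaflets with
prescribed per-torsion gauche probabilities and tilt distribution, waters
planted at exact hydrogen-bond geometries, and two-state (telegraph) bond
kinetics with a closed-form autocorrelation — so every statistic in the
package is testable against planted ground truth without any MD engine.

## Worked example

Generate a synthetic system — 32 NDB per leaflet (area 2 nm² per molecule)
on an 8 × 8 × 24 nm box with a central 8-nm water slab (~17k waters),
tilt drawn from N(30°, 8°), 5 frames — then analyze it:

```bash
cat > spec.yaml <<EOF
n_surfactant_per_leaflet: 32
n_frames: 5
tilt_mean: 30.0
tilt_sd: 8.0
water_number_density: 33.4
EOF
slabstats generate --config spec.yaml --seed 1 --out system.gro
slabstats tilt system.gro --annotation system.annotation.yaml
slabstats gauche system.gro --annotation system.annotation.yaml
slabstats thickness system.gro --annotation system.annotation.yaml
slabstats area --n-total 64
```

prints

```
wrote system.gro (52519 atoms, 5 frames)
A_Tail    29.67 deg
A_Whole   32.26 deg
A_Polar   65.28 deg
0.512 0.613 0.066 0.184 0.094 0.097 0.078 0.100 0.125 0.087 0.103 0.138
{
 "thickness_mean_nm": 0.44398196061016737,
 ...
}
2.0
```

Reading the numbers: the measured mean tail tilt (29.67°) recovers the
planted 30° distribution; the twelve gauche fractions reproduce the
generator's head-high/tail-low torsion profile (0.5, 0.6, 0.08, …); the
10–90 thickness of the water profile, 0.444 nm, matches the closed form
2.1972 × w for the generator's interface width w = 0.2 nm; and 64
molecules over two 64-nm² interfaces give the 2.0 nm² area label.

The same stages run as one reproducible pipeline
(`slabstats run --config pipeline.yaml --seed 1 --out rundir`), which
writes a `summary.json` plus per-stage text outputs and echoes every
applied default.

## Scope

The package analyzes configurations; it does not generate physical
dynamics (no force fields, thermostats or electrostatics), does not read
binary trajectory formats, and supports orthorhombic boxes only. See
`docs/methods.md` for the models, conventions and known limitations.
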