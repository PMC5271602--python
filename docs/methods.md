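# Methods

## The model

`chromofiber` implements a mesoscopic model of regular, symmetric two-start
chromatin fibers. A fiber is generated by four parameters: the cylindrical
radius `r` (Å), per-nucleosome rise `h` (Å) and polar angle `φ` (degrees) of
the nucleosome centers about the fiber axis, plus the inclination `ρ`
(degrees), a rotation of each nucleosome disk about its own dyad axis.
Left-handed two-start fibers correspond to `φ` between 150° and 180°; one
fixed screw motion (rotation `φ`, translation `h`) maps nucleosome k onto
k+1, so the whole fiber is defined by a single repeat unit.

The nucleosome core is rigid: 147 base-pair frames on a left-handed
superhelix (radius 41.9 Å, pitch 25.9 Å, 1.67 turns — canonical
crystal-structure values). Frames are built by parallel transport with a
uniform twist rate calibrated so that the extracted per-step twist is
exactly the B-DNA rest twist (34.5°); the rigid core then contributes no
twist change relative to relaxed DNA, which pins the ΔLk reference state
unambiguously. The dyad axis passes through the central base pair and, in
the fiber, points toward the fiber axis, so the DNA entry/exit sites that
flank the dyad face the interior where the linkers run. An optional PDB
loader builds the same representation from a crystal structure (bp frames
from paired C1' atoms, superhelical axis by least-squares helix fit); the
idealized core is the reproducible default.

Linker DNA is a chain of base-pair steps (Twist, Roll, Tilt, Shift, Slide,
Rise) under the mid-step-triad convention. Elastic energy is harmonic in
the deviation from the rest state (Twist 34.5°, Rise 3.35 Å, rest
otherwise zero) with a 6×6 dinucleotide-averaged stiffness matrix
(defaults: twist 0.0427, roll 0.0204, tilt 0.0370 kT/deg²; shift 1.72,
slide 2.27, rise 7.04 kT/Å²; twist–roll coupling +0.012 kT/deg²; all
replaceable through the run configuration).

### The linker boundary-value problem

The linker conformation minimizes the elastic energy subject to an exact
end-frame constraint: its L+1 steps must carry the exit frame of one
nucleosome onto the entry frame of the next (the two junction steps to the
core terminal base pairs are included, so NRL = L + 147). Because the
orientation constraint does not fix the number of helical turns
accumulated along the linker, the problem splits into twist topoisomer
branches whose total twist differs by 360°. Each branch is optimized
separately, starting from a reference chain (rest state plus uniformly
distributed excess twist) and converging by SQP: the energy is exactly
quadratic, so each iteration solves the KKT system of the linearized
constraint in closed form, with the constraint Jacobian assembled
analytically from per-step se(3) twists and suffix transforms. A
quadratic-penalty relaxation with escalating weight, followed by SQP
projection, handles starts far from the constraint manifold; pose
continuation is the last resort. Solutions that relax into an
already-found twist basin are deduplicated, so distinct topoisomers are
returned with their distinct energies.

For landscape work a second-order "compliance" estimate is precomputed per
branch — the constrained minimum of the quadratic energy under the
linearized constraint, a 6×6 quadratic form in the pose mismatch. It is
used only to rank candidate geometries and prune branches; every reported
energy comes from the exact solver.

## The four energy terms

Total fiber energy (reported per nucleosome, kT) is the exact sum of:

1. **Elastic** — the linker deformation energy above, one linker per
   repeat unit, reused across the regular fiber.
2. **Electrostatic** — one effective point charge per bp center, pair
   energy `scale·(1/d − 1/30)` below the 30 Å cutoff (shifted so the
   potential is continuous there), pairs within 2 bp along the chain
   excluded. Intra-core pairs are omitted: the rigid core's internal
   repulsion is a constant. The scale (default 0.5 kT·Å) is an effective
   screened-charge factor, calibrated once so the optimal short-linker
   fibers land in the stable (negative, tens-of-kT) energy range.
3. **Steric** — soft-core quadratic overlap penalties, capped per pair at
   10³ kT. The nucleosome envelope (55 Å radius × 57 Å height disk) is
   packed with nine 28.5 Å spheres for disk–disk checks; DNA is a chain of
   10 Å beads. DNA beads are checked against a 30 Å histone-octamer sphere
   at each disk center rather than against the full disk envelope — the
   envelope contains the core DNA itself, so an entering or exiting linker
   would otherwise "clash" with its own nucleosome by construction. The
   linker of nucleosome i is additionally exempt from the envelope of
   nucleosome i+1, which it enters. DNA–DNA overlaps ignore pairs closer
   than 10 bp along the chain (bonded neighbors).
4. **Stacking** — the histone-tail/acidic-patch attraction between
   same-stack neighbors (k, k+2), a Gaussian well `−E0·exp(−(d−d0)²/2σ²)`
   in the distance between the facing flat-face anchor points (disk center
   ± height/2 along the core axis). Defaults E0 = 8 kT, σ = 6 Å,
   d0 = 3 Å anchor-to-anchor — equivalently 60 Å center-to-center for
   coaxially stacked disks. E0 and σ were calibrated once so that the
   stacked minima of the short 10n linkers are negative (stable).

Because the fiber is regular, every pairwise term between repeat units
depends only on the unit separation d; energies for any N are assembled
from O(d_max) block interactions (numba-compiled kernels, with equivalent
numpy fallbacks).

## Nested optimization

The outer cycle minimizes the per-nucleosome total energy (evaluated at
N = 20 nucleosomes, where edge effects are small) over (r, h, φ) at fixed
(ρ, L): a deterministic coarse grid (r 30–150 Å step 10, h 10–60 Å step 5,
φ 150–180° step 5) screened by a cheap placement score, followed by
Nelder–Mead refinement. The screening score combines the compliance
elastic estimate with stacking and disk-overlap terms from rigid
placement; because the narrow stacking well is easily missed, the
stacking-engaged cells are ranked separately and always contribute starts.
The radius grid stops at 150 Å because a 70-bp linker cannot span larger
center distances.

Scanning ρ at fixed L maps two energy basins: T2 at negative inclinations
(optimal for linkers L = 10n) and T1 near +90–115° (optimal for
L = 10n+5), carrying different linking numbers. The per-L optimal-fiber
series samples each basin's open ρ window at 10° steps; along L the search
continues from the L−10 optimum (a linker 10 bp longer has nearly the same
helical register, making it the physically matched predecessor) and from
the L−1 neighborhood, with periodic fresh grid restarts to keep the
continuation honest. All stages are deterministic; there is no stochastic
restart.

## Topology

The double helix is reduced to a ribbon: the bp-center polygon carries the
writhe, the bp frames the twist. Open fibers are closed by four auxiliary
points — two on the fiber axis 350 Å beyond the extreme bp-center
projections ("fiber periphery"), two shifted 500 Å perpendicular to the
axis in the plane of the axis and the entry point — so the closing chain
is planar with the axis and adds no writhe of its own. Writhe is evaluated
exactly per segment pair as the signed area of the Gauss-map spherical
quadrilateral, computed with the van Oosterom–Strackee arctangent form
(numerically stable where arcsine-based variants lose all precision for
far-apart pairs); pairs sharing an endpoint contribute exactly zero and
are masked. ΔTw sums the extracted per-step twist deviations from 34.5°
over real DNA steps only; the closure carries no excess twist by
convention. ΔLk = Wr + ΔTw holds exactly by construction, and measures
supercoiling relative to open relaxed B-DNA of the same length.

The closure construction carries a small end bias: moving the axial
closure points from 350 Å to infinity changes the total ΔLk by ~0.01–0.03
turns (converging as the inverse offset), independent of the fiber size —
a per-nucleosome effect below 0.003 turns that vanishes in ΔLk/N.  The
lateral legs are exactly writhe-neutral.

For the regular fiber the writhe double sum decomposes into unit-pair
terms that depend only on the unit separation (screw symmetry), so ΔLk at
any N — including the full ΔLk(N) curves — costs O(N) block interactions
instead of O(N²) segment pairs; the decomposition is verified against the
direct full-polygon computation in the tests.

## The NRL pipeline and its generator

Dyad maps are tables of (gene, dyad position relative to TSS, fragment
length). The occupancy profile counts dyads per bp over [−200, +1000] bp
(fragments 147–152 bp by default), normalizes by the number of genes and
smooths with a centered 51-bp running average (truncated at the edges).
Peaks are local maxima within ±40 bp, above 10% of the profile maximum;
maxima within 40 bp of the window edges are not called (their neighborhood
is incomplete and edge-truncated smoothing distorts them). The NRL is the
mean of consecutive peak spacings; the quoted ± value is the sample
standard deviation of those spacings.

The synthetic generator emulates the features of genome-wide MNase maps
that drive this analysis: per gene, nucleosome k sits at
`first_dyad_offset + k·NRL` plus Gaussian phase noise of standard
deviation `phase_sd·√(k+1)` (positioning decays with distance from the
TSS); read counts are Poisson with mean `reads_per_dyad·decay^k`; dyads
upstream of the NDR edge are dropped; fragment lengths are uniform on
147–152 bp. Defaults: first dyad at +60 bp, NDR width ≈ 140 bp, phase SD
10 bp, decay 0.88, 4 reads per dyad, 7 nucleosomes, 860 genes per group.
The UP/DOWN presets (NRL 161 vs 167 bp, phase SD 13 vs 9 bp, occupancy
decay 0.85 vs 0.90) reflect that lowly expressed genes carry a longer
repeat, tighter phasing and higher occupancy. What the generator does not
emulate: sequence-dependent positioning, MNase digestion bias, replication
or transcription-coupled remodeling, and gene-to-gene NRL heterogeneity
beyond phase noise — so parameter-recovery tests demonstrate that the
estimator is unbiased and precise on idealized maps, not that a particular
organism's NRL takes any specific value.

## Numerical choices and conventions

* Lengths in Å, angles in degrees at every interface; radians internally;
  bp indices 0-based; frames right-handed (axis columns X, Y, Z).
* Linker end-frame tolerance 1e-4 (rad/Å mixed norm), well inside the
  1e-3 Å / 1e-3 rad contract; step round-trip residual < 1e-8.
* Topoisomer multistarts at 0, ±360, ±720° excess twist for the public
  solver; the fiber optimizer tracks 0, ±360 (the ±2-turn branches are
  never competitive at these linker lengths).
* Tie-breaks in the outer grid are by score order, then lexicographic
  (r, h, φ); Nelder–Mead tolerances xatol 0.3, fatol 0.05.
* Boundaries farther than 4.5 Å per step are unreachable for B-DNA and are
  rejected before any optimization; geometries whose DNA paths collide
  below 0.1 Å are treated as sterically impossible.
* Problem sizes: fiber energies at N = 20; topology at N = 100 (the
  asymptotic regime — ΔLk/N changes by < 0.05 beyond N ≈ 30); landscape
  scans sample ρ at 5–10° and L at 1 bp.

## Design choices where the design was open

* The inclination basins emerge from the energy model at slightly less
  negative (T2) and slightly more positive (T1) angles than the
  conventional windows; the basin *assignment* by linker series (10n → T2,
  10n+5 → T1), the topoisomer transition angle and all linking numbers are
  robust to this offset. The window-restricted basin search reports optima
  inside the conventional ranges.
* The stacking pair distance uses the face-anchor points; d0 = 3 Å
  anchor-to-anchor is the same geometry as 60 Å center-to-center for
  coaxial disks.
* All six step parameters are free in the linker minimization.
* The H3/H4 tail identity is immaterial to the phenomenological stacking
  term; it is labelled generically tail–acidic-patch.

## Known limitations

* Absolute energies depend on the phenomenological calibration
  (electrostatic scale, stacking depth, steric constants); topological
  quantities (ΔTw, Wr, ΔLk) are robust because they depend only on the
  optimal geometry, not on the energy scale.
* The idealized core reproduces the crystal superhelix's dimensions but
  not its irregular local geometry; per-step contour spacing is 3.03 Å
  (set by radius/pitch/turns), slightly below the straight B-DNA rise.
* One-start solenoid and interdigitated architectures, linker histones and
  sequence-dependent stiffness are out of scope.
* The outer optimization is local (grid + simplex); the continuation
  scheme makes the reported series reproducible but cannot guarantee
  global optimality at every L.
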