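# Model and methods

`invadosim` simulates a single cancer cell pushing invadopodia — actin-rich
ventral protrusions — into a three-dimensional collagen type-1 fiber
matrix. The model couples three subsystems, all advanced together by one
explicit overdamped integrator:

1. **Cell mechanics.** Five closed triangulated surfaces share one
   icosphere topology: the invadopodial membrane (CI), the
   force-transduction layer (CT) 50 nm beneath it, the actin cortex layer
   (CC) 50 nm further in, and two nuclear surfaces (perinuclear actin
   layer PAL and nuclear membrane surface NMS). Every line element is a
   Kelvin–Voigt unit (spring plus dashpot in parallel); CI and the
   nuclear surfaces additionally carry an area-strain energy. Paired
   layers are coupled node-by-node by vertical springs (κ_T = 8×10⁻³ N/m
   for CI↔CT, κ_C = 1×10⁻² N/m for CT↔CC; PAL↔NMS reuses κ_C since no
   separate constant is published). Inside, a branched actin network of
   polyline filaments carries stretch (κ = A·E/L₀ with E = 1.8 GPa,
   A = πr², r = 3.5 nm; 0.46 N/m at the initial 150-nm element) and
   bending (κ_b = E·I) elasticity, Arp2/3 branch springs (0.01 N/m, rest
   30 nm) with branch-angle (70°) and dihedral restoring terms, and
   crosslinkers: fascin (bundler), filamin (orthogonal linker, also
   tethering filaments to the PAL), α-actinin and bipolar myosin
   minifilaments (perinuclear, active only while retracting). Myosin
   endpoints slide toward barbed ends at the Hill force–velocity rate
   (160 nm/s unloaded, 1.24 nN stall, shape constant 4.761).

2. **Matrix mechanics.** Collagen fibers are random chords of the domain
   box, discretized at ~0.5 µm, welded into junctions where they pass
   close to one another, and carrying the same stretch/bend element type
   with the collagen fibril modulus. Integrin clusters on CI form focal
   complexes with nearby fiber segments; the bonded-integrin count obeys
   d n_b/dt = k_on (n_tot − n_b) − k_off n_b with a Gaussian-in-extension
   association rate (confinement partition function Z₀) and Bell
   slip-bond dissociation (k_off = k_off⁰ exp[κ_LR(L_b−λ)x_b/k_BT],
   intrinsic force k_BT/x_b ≈ 200 pN). Volume-exclusion penalties keep
   fibers outside the membrane and actin between nucleus and cortex.

3. **Reaction–diffusion.** Six normalized concentrations on a regular
   0.5-µm grid: MMP-2 (φ1), TIMP-2 (φ2), MT1-MMP (φ3), the ternary
   MT1-MMP:TIMP-2:proMMP-2 complex (φ4), free ligand (φ5) and intact ECM
   (φ6). φ1, φ2, φ5 diffuse (7-point stencil, zero-flux box faces);
   reactions are mass-action exactly as the model's rate table writes
   them, including MMP-2 activation through +k₃₄·φ3·φ4. Secretion of φ2
   and φ3 happens only at tip-source grid nodes (the cap of CI nodes with
   the top 5 % projection on the polarity axis) and only during the
   protrusive phase. A fiber element is irreversibly degraded when local
   φ6 falls below 0.2 of its initial value.

The motion cycle has three phases: **protrusive** (Brownian-ratchet
polymerization pushes the cortex; MT1-MMP secretion on), **retractile**
(tip barbed ends force-capped; α-actinin and myosin engage and contract
the perinuclear network), and **severing** (buckled filaments — end-to-end
below 0.9× contour — are fragmented into ≤300-nm pieces that
depolymerize in parallel). Capping protein also binds growing or
ratcheting barbed ends stochastically at 0.3 s⁻¹; everything uncaps when
protrusion resumes.

## Filament lifecycle

A filament is in one of seven states: nucleated, growth, adhesion
(barbed end within 100 nm of the cortex surface), detach (adhesion
tension above 20 pN), ratchet, capped, uncapped. The ratchet force on
the cortex node is F_p·log(v₀/|n̂·(v_b−v_a)|) with F_p = 20 pN and
v₀ = 50 nm/s, clamped to [0, 100 pN] because the law diverges at zero
relative normal speed and turns negative above v₀; an equal-opposite
reaction acts on the barbed end (configurable), so filaments that are
not braced by crosslinkers recoil and lose ratchet efficiency — this is
what makes the filamin/fascin knockout mechanically, rather than
procedurally, slower. Growth at a cortex-engaged barbed end follows the
load-dependent law v_g = v₀·exp(−f_cortex/(n_F·f₀)); free ends grow at
20 nm/s; pointed ends shrink at 10 nm/s in every phase.

Arp2/3 nucleation is treated as a cell-wide Poisson process (the
published 50 s⁻¹; miniature fixtures scale it down) over mother segments
lying in the leading-edge cone (<60° from polarity) within a 600-nm
sub-cortical shell — dendritic nucleation is membrane-proximal, which is
what densifies the network at the invadopodium tip. Daughters branch at
70° with the azimuth chosen toward the membrane (inward daughters never
engage and only add cost).

## Numerics

All lengths are nm, forces pN, times s (1 pN/nm = 10⁻³ N/m). Every
elastic force is the exact analytic gradient of its energy; the test
suite checks each family against central finite differences at 10⁻⁶
relative tolerance. Angular terms clamp cos θ to ±(1−10⁻¹²); the branch
dihedral is skipped (and counted) within ~3° of plane collapse, where
its lever arm vanishes and the gradient direction is undefined.

The coupled equations of motion are the explicit per-node quotients of
the dissipation-split form: each structure's velocity is its assembled
force, plus a lagged "dissipated force" carrying the neighbours'
previous-step velocities, divided by its summed dashpot coefficients.
Note a physical consequence used by the tests: pairwise dashpots cancel
for rigid translation, so a uniformly forced body drifts at F/c_ground.
Steps run inside a step-doubling controller (one full versus two half
steps, both with frozen lag velocities); a step is accepted when the
maximum nodal discrepancy relative to a characteristic length (the cell
radius, 2 µm by default) is below 10⁻⁴, otherwise dt halves (fault below
1 µs). Accepted steps grow by 1.5× up to 20 ms. Dashpot values are
effective cytoplasmic coefficients chosen so this scheme is stable in
the 1–20 ms range; they are configuration, recorded per run. Element
stiffness κ = A·E/L₀ diverges for the transient sub-discretization
segments of depolymerizing filaments, so the dynamics kernels floor L₀
at the 150-nm initial element length when forming κ (the closed-form
stiffness law itself is exact); pointed-end segments merge into their
neighbour below 100 nm, barbed segments split above 300 nm.

The RD field is sub-cycled inside each accepted mechanical step at the
diffusive stability bound h²/(6·max D). The printed φ3/φ4 reaction pair
is cross-catalytic (+k₃₄φ3φ4 feeds φ4, k_off recycles φ4 into φ3);
implemented exactly as written, it is linearly unstable once
k₃₄·φ3 exceeds roughly k₃ᵈ·k₄ᵒᶠᶠ/(2k₂₃φ2 + k₃ᵈ). The default rate
constants (dimensionless species) are chosen well inside that bound and
verified stable over 960 s of cyclic secretion; raising the secretion
rates or k₃₄ can make the printed system blow up in finite time.

Contact handling: cortex contact of a barbed end is measured radially
(barbed-end radius against the nearest cortex node's radius) because the
surface is far finer than its node spacing; actin confinement penalties
act along the smooth radial direction (a nearest-normal scheme is
discontinuous across surface Voronoi cells and stalls the adaptive
stepper); fiber–membrane exclusion uses the nearest membrane node's
outward normal. Focal complexes anchor at the closest point of a fiber
segment (stored fraction), formed within twice the 30-nm binding radius
— fiber nodes are sparser than the physical binding radius, so a
node-to-node gate would never fire; the Eq.-level binding radius is kept
inside the k_on prefactor.

## ECM generator and calibration

The generator matches a target mean pore size (twice the mean distance
from a sampling grid to the nearest fiber surface; for Poisson lines
this is 1/√(length density), which makes the fiber-count iteration a 1-D
fixed point, accepted within 2.5 %, best draw within 5 % otherwise).
Welding captures junctions within 0.75 µm — a genuine 41-nm contact rule
leaves a random line network almost entirely disconnected — and any
remaining components are bridged at their closest approach, so the
network always percolates. As-built kink angles at welds are stored as
bending rest angles, leaving the generated network exactly stress-free.
For simulations the cell volume is carved free of fibers at placement.

The collagen fibril modulus is the one calibrated constant: the relaxed
configuration of the network minimizes E·f(x) and is independent of E,
so the measured bulk modulus is exactly linear in E. A single sweep at a
reference modulus (scripts/calibrate_ecm.py) fixes E = 269.7 pN/nm²
(≈270 MPa, within the measured range for collagen fibrils) so that the
simulated volumetric stretch test — boundary nodes displaced affinely to
1–3 % volumetric strain, interior relaxed by L-BFGS, pressure read from
the relaxed energies, modulus from the linear stress–strain fit — 
reports ≈2.56 kPa for the default 3-µm-pore network. A single 15-µm
network segment contains only ~30 fibers, so its modulus fluctuates by
~20 % between realizations; reported values are means over many seeds.

## Scenarios, fixtures, and what reduced scale shows

`ScenarioConfig` captures phase durations, the two initial filament
patterns (500 radial leading-edge filaments spanning nucleus to
membrane; 500 perinuclear filaments encircling the nucleus,
pre-crosslinked pairwise by myosin and α-actinin), ECM pore size and
box, knockout flags, and the seed. Knockouts act mechanistically:
crosslinker knockouts suppress placement of that species, MT1-MMP
knockout zeroes tip secretion, Arp2/3 inhibition suppresses nucleation.
In the stiffness-interface scenario the polarity points toward a
half-space whose fiber elements are stiffened and ligand-enriched, and
secretion scales with local ligand (the printed α(x_tip)·φ5 form; in
uniform scenarios the source is a constant rate, since with the
published-silent zero initial ligand the printed form never starts).

The `tiny` fixture (20 filaments, subdivision-1 surfaces, 8-µm ECM
patch with a dense 1.2-µm-pore gel — the density of the experimental
collagen gels that induce invadopodia, and the density at which the
miniature cell's tip cap reliably meets fibers) and `small` (200
filaments, subdivision-2) reproduce the seeding patterns statistically
and run full cycles in minutes; the default test suite exercises trends
at this scale with two cycles and proportionally shortened phases. What passing reduced-scale tests show
is that the mechanisms move the observables in the right direction —
longer protrusion gives more tip advance, knockouts slow the tip,
silencing MT1-MMP stops degradation — not that the absolute published
speeds are reproduced; those require the full 500+500-filament,
subdivision-2, 45×30×20-µm configuration run for ~10³ s.

Definitions used by the analysis module (the source figures do not
define them operationally): "migrated distance of the invadopodial tip"
is the net displacement of the maximal-projection membrane node;
"speed" is the window-averaged path speed (default 180-s windows,
mirroring the 3-min imaging interval); "traction at the tip" is the
summed focal-complex force over tip-cap membrane nodes; "intracellular
force at the tip" is the summed adhesion-clutch force through tip-cap
cortex nodes.

## Known limitations

* The membrane topology is fixed; narrow filopodia-like protrusions
  cannot form, only broad invadopodial bumps.
* Crosslinker unbinding is a fixed turnover time (60 s), not load
  dependent.
* Concentrations are dimensionless; rate constants are magnitudes chosen
  for stability and for degradation to complete within a protrusive
  phase at the tip, not fitted kinetic constants.
* The branch angular/dihedral moduli are not published with usable
  units; defaults (10⁴ pN·nm²) give soft angular guidance, and network
  architecture is insensitive to them within an order of magnitude.
* Reduced-scale runs use a nucleation rate and filament cap scaled to
  the fixture size; absolute speeds at that scale are smaller than the
  published full-scale values.
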