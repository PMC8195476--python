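# Methods

## The model

Contractile injection systems (R-type pyocins, phage tails, the T6SS) drive
a rigid inner tube through a target membrane by contraction of an outer
helical sheath. `dmad` models this transition as a deterministic,
layer-wise propagation of a per-subunit progress variable — the
*contracted fraction* λ ∈ [0, 1] — through a two-end-state description of
the assembly.

**Geometry.** Each sheath layer carries the cylindrical COM coordinates of
a reference subunit in the extended and contracted states plus a fixed
rotation axis (polar angles ω, φ in the COM frame) and total rotation
angle κ_cnt. At fraction λ the pose is the linear blend

    (r, θ, z, κ) = (1−λ)(r_ext, θ_0, z_ext, 0) + λ(r_cnt, θ_0+Δθ, z_cnt, κ_cnt),

so every COM travels a conical-cylindric geodesic. Sixfold symmetry is
assumed throughout (the tube's near-perfect roundness and the mesh
topology of the sheath do not allow large deviations from it), and the
subunit fold is treated as rigid apart from a 101-frame morph between the
end-state conformations.

**Dynamics.** Contraction starts from a perturbation of the bottom
(baseplate-proximal) layer, λ₁⁽ⁱ⁾ = P·k₁^(i−1) with P = 10⁻³ (about
1/1000 of the full motion). Each iteration advances layer i by

* a parabolic velocity v = v_max(λ − λ²) evaluated at the previous
  iteration and mixed with the neighbours through the intra-strand
  coupling k₁ (weights 1:k₁, normalised; both-sided in the interior);
* an inter-strand spring k₂·s², where s is the positive stretch of the
  inter-strand link (azimuthal offset π/3, one layer down) beyond its
  resting length — the bottom layer is retarded by the stretch above it,
  interior layers feel the difference of the stretches below and above,
  the top layer is pulled up by the stretch below;
* a drag term D·d, with d the previous iteration's COM displacement.

λ is clamped at 1 from above and deliberately not clamped from below (the
update rules have none); negative values are truncated only when a pose is
built, with a warning. The dynamics contains no randomness: identical
inputs give bit-identical trajectories. If an iterate overflows (large
drag or strong springs make the unclamped update unstable), the trajectory
is truncated with a warning and flagged unconverged rather than raising.

**Parameters and defaults.**

| parameter | meaning | unit | default |
|---|---|---|---|
| k₁ | intra-strand velocity coupling; 1 = rigid (synchronous) | — | 0.7 |
| k₂ | inter-strand spring constant | Å⁻² | 2.5×10⁻⁴ |
| D | drag on moving subunits | Å⁻¹ | 5×10⁻⁴ |
| P | initial perturbation | — | 10⁻³ |
| v_max | max geodesic fraction per iteration | — | 0.05 |
| completion tolerance | top-layer fractional completion | — | 10⁻³ |

The completion criterion generalises the raw "top-layer radius reached its
contracted value" to fractional completion of the top layer, which remains
meaningful for lattices without radial motion and terminates cleanly when
drag makes the strict condition oscillate at the boundary.

**Energetics.** Because subunits move as near-rigid bodies, the energy
change of the complex is dominated by inter-subunit interfaces. Every
intermediate is scored by a SASA-based solvation free energy: G = Σ_atoms
σ(element)·SASA(atom), with a standard atomic-solvation-parameter table
(apolar elements positive, polar negative; swappable text files under
`dmad/params/`). SASA uses the Shrake–Rupley point-sampling algorithm on
a deterministic golden-spiral sphere, 960 points, probe 1.4 Å. Association
energies add per-bond hydrogen-bond and salt-bridge terms (heavy-atom
distance criteria, 3.5/4.0 Å; disulfides implemented but off by default).
The per-bond energies ship as literature-scale defaults and are
*uncalibrated*: the single published anchor for this style of calculation
is an external crystal structure that this package does not download.

Two frame conventions matter for point-sampled SASA, whose result depends
at the ~0.1% level on the orientation of the sample sphere:

* single-structure and association energies are evaluated in a canonical
  principal-axes frame (deterministic sign convention), which makes them
  invariant under rigid motion of the input to ~10⁻⁹ relative, and for
  association energies the complex and its isolated components share one
  frame so that ΔG is exactly zero at infinite separation;
* energy *profiles* over a trajectory are evaluated in the common lab
  frame, since consecutive intermediates differ by internal motion only —
  canonicalising each frame independently would add ~3 kcal/mol of
  spurious frame-to-frame jitter for near-symmetric assemblies.

**Pathway search.** Pathways are generated on a 5×5×4 grid of
(k₁, k₂, D) — 100 parameter sets bracketing the couplings a pyocin-like
machine requires — and scored by activation energy (profile maximum above
the extended reference). The most probable pathway must additionally keep
the mesh intact (COM separations under the lattice tolerance) and be free
of substantial local minima, since semi-contracted intermediates are not
observed; a minimum's depth is measured to the highest downstream barrier
(the climb needed to continue contraction), which matches the worked
depth convention used in the tests. Ties break by smaller k₂, then
smaller drag.

**Extrapolation.** For a given parameter set, the energy of a nonterminal
layer is (approximately) a function of its own contracted fraction alone,
and the four terminal layers contribute the same in a machine of any
length. The 12-layer fragment therefore yields five energy-vs-λ curves
(interior mean ± SD over layers 3–10, plus four terminal curves) on a
101-point λ grid with linear interpolation, and the full-length profile is
the sum of curves over the 28 layers. Before propagating the full-length
machine, k₂ is rescaled by X² and D by X, where X is the ratio of mean
geodesic path lengths (fragment over full length; ≈ 1/2.41 for the default
geometry); k₁ multiplies velocities, which are path-independent, and is
untouched. The SD band is propagated as the root of summed interior
variances (independence assumed).

*Known limitation.* The independence assumption holds when the contraction
wave is at least as long as the fragment (the regime the extrapolation is
applied to; reapplying the curves to their source trajectory then
reproduces the direct profile within one propagated SD, plus a 1 kcal/mol
surface-sampling granularity floor). For steeper waves the layer
deviations become correlated — the hyper-extension of a link grows with
layer index times the λ-gradient — and the root-sum-square band
underestimates the extrapolation error by a factor of ~2–3.

**Force and pressure.** Tube displacement follows the top sheath layer
(z_ext − z, Å → nm). G(z) is smoothed by a least-squares quartic (the
first 1 nm of motion is excluded — displacements there are below the
model's resolution) and the force is F = −dG/dz, converted with
1 kcal·mol⁻¹·Å⁻¹ = 69.479 pN applied exactly once. The 95% confidence
band propagates the fit's coefficient covariance through the derivative.
The terminal branch is a linear extension spring F = k(z_final − z) with
the AFM-measured stiffness of the contracted sheath (default 117 pN/nm,
consumed as a constant); the first crossing of the two curves estimates
the maximum force. Cross-sections are convex hulls of vdW-inflated atom
circles in a horizontal slab (hull rather than a concave polygon: it is
deterministic and conservative; slab default 2 Å, widened to one helical
rise for bead tubes whose rings are a full rise apart). Mean pressure is
force/area with 1 pN/nm² = 10⁶ Pa ≈ 9.87 atm.

**Kinetics.** Bulk contraction time courses are fit as single
exponentials S(t) = S_∞ + (S₀−S_∞)e^(−kt) (endpoint and half-life
initial guesses; fits with amplitude below five times the residual noise
are rejected as degenerate; the first 2 minutes can be trimmed as heating
equilibration, and averaged-control subtraction is supported). Activation
energies come from unweighted ordinary least squares of ln k on 1/T
(Ea = −slope·R, R = 1.98720×10⁻³ kcal·mol⁻¹·K⁻¹), with the 95% CI from
the slope's standard error and the t distribution.

## The synthetic machine

All tests and the reproduction script run on a generated two-state,
6-start helical bead lattice; nothing is downloaded. Defaults emulate a
pyocin-scale machine: 28 layers (12 for the fragment), per-layer rise
halving from 43 to 21.5 Å (the machine shortens by ~58 nm), COM radius
growing 42 → 60 Å, twist 0.40 → 0.56 rad, subunit rotation κ = 0.6 rad.
Subunits are reproducible pseudo-random bead clusters (10 beads of 8 Å
radius in a ±21 Å ellipsoid) whose contact areas grow from the extended to
the contracted state; the tube is a rigid stack of 6-bead rings at 30 Å
radius. The bead mesh's own tolerance is 70 Å (≈ the cluster contact
range plus slack) — the 55 Å default on `LatticeSpec` is the measured
property of the real machine's handshake domain and is kept for
user-supplied lattices.

Under these defaults the 12-layer fragment shows the qualitative pyocin
phenomenology: a positive activation barrier from transient strand
hyper-extension (the ballista-like overshoot of COM separations before
collapse), a strongly negative total energy, a contraction wavelength
longer than the fragment, and a full-length feasibility pattern in which
only the lowest-drag delayed pathways survive the mesh screen.

What the fixture does **not** reproduce: bead contacts are monotone in
distance, so the synchronous pathway (k₁ = 1), which avoids
hyper-extension entirely, shows a *lower* barrier than delayed waves —
for the real machine the opposite holds, because atomic interfaces must
break and re-form through unfavourable intermediate geometry that a
soft-sphere burial model cannot represent. Passing tests therefore
validate the machinery (propagation, scoring, extrapolation, force
derivation), not the claim that delayed pathways are energetically
preferred. Quantities reported for the synthetic machine (barriers in the
hundreds of kcal/mol, forces of hundreds of pN) are of the right order
but are properties of the fixture, not measurements of any real system.

The kinetics generator produces first-order courses with
Arrhenius-distributed rates. The recovery check uses five temperatures
spanning 66–74 °C, 1% Gaussian noise, and observes each temperature over
six of its own half-lives (the experimental habit of recording until the
reaction completes), which makes the ln-rate errors homoscedastic; the
95% CI then shows its nominal coverage, verified over 1000 derandomised
replicates against a 93% bound (1000 rather than 100 keeps the binomial
noise of the coverage estimate below the margin being tested).

## Numerical choices

* Geodesic lengths: 1000-segment polylines (converged to <0.01% on
  pyocin-scale geometry; <10⁻⁶ relative change between 10⁴ and 10⁵ steps).
* Morph frames: `round(100·λ)` half-up; morphing is linear Cartesian
  interpolation after optimal superposition — a documented approximation
  to corkscrew-style morphing, adequate for the rigid-body regime.
* Inter-strand quantities are undefined for the bottom layer (no link
  below); they are stored as NaN and never referenced by the update rules.
* Energy-profile sampling: ~100 intermediates evenly spaced in reaction
  coordinate (configurable; the reproduction script uses 40 for the
  reference pathway and 15 per grid row to keep the full 100-pathway scan
  inside a few minutes on one CPU).
* Grid rows that diverge numerically are recorded per-row with the error
  and do not abort the scan; caches (JSON per parameter triple) make scans
  resumable.
* Surface fits (barrier fraction vs k₁, k₂ at fixed drag) use a bivariate
  cubic with k₂ rescaled to O(1) for conditioning; rank deficiency raises
  rather than returning a silently underdetermined fit.
* Tube motion follows both Δz and Δθ of the top sheath layer by default;
  a translation-only mode exists because the rotation of the real tube
  during contraction is not established.
* Clash reporting (inter-subunit pairs closer than 0.6× summed vdW radii)
  is attached to built intermediates but never "fixed": geometry
  regularisation is out of scope, and the solvation score is tolerant of
  imperfect linker geometry.

## Limitations

* No thermal noise, no kinetics of the dynamics itself: iteration count is
  not time, and the method finds a most-probable path, not an ensemble.
* No electrostatics beyond the bond-count terms; no entropy estimate (for
  this system the measured entropic contribution is small).
* The solvation parameter set and bond energies are order-of-magnitude
  defaults; absolute energies for real atomic structures should be
  interpreted only after calibrating against a known association energy.
* Extrapolation error bars assume independent layer deviations (see
  above); they are honest for long-wavelength pathways only.
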