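# Methods

`thermosort` implements two coupled mesoscale models of adhesion-based cell
sorting on microstructured thermoresponsive coatings, plus the geometry and
analysis layer that connects them to scanning-probe observations of real
surfaces. This note records the models, their assumptions, the parameters
that matter, and the numerical choices made where the design was open.

## 1. Surface geometry: spherical caps (`capgeom`, `heightmap`)

Phase-separated PGMA domains on a PNIPAM-co-GMA matrix are modelled as
spherical caps of sphere radius `R_sp` and height `H` on a basal plane, with
the matrix forming a near-uniform level `h_PNIPAM` that buries the cap base.
All cap identities follow from elementary geometry:

- base radius `R_d' = sqrt(H (2 R_sp − H))`,
- slice radius at height `h`: `r(h) = sqrt(R_sp² − (R_sp − H + h)²)`,
- exposed (projected) area above the matrix: `π r(h_PNIPAM)²`.

Heights are always measured in background-subtracted coordinates (the basal
roughness level is set to zero). Summary statistics use median and
interquartile range because fabricated domain heights are broad and skewed;
spacing `d` is the per-domain mean distance to its 4 nearest neighbours, with
domains whose neighbourhood would cross the scan border excluded (scans are
finite; periodic wrapping would be wrong for real data). Surface coverage is
reported as `ρ × A` (domain density times median exposed area). Note `ρ×A`
computed this way need not equal the product of independently rounded table
columns; the module always reports the product of its own statistics.

The synthetic scan generator places caps by random sequential adsorption
(no base-disc overlap) with log-normal heights (median/IQR parameterised),
renders `max(basal noise, matrix + noise, cap surface)` on a 256–1024 pixel
grid, and returns the exact ground truth next to the image. Its defaults
emulate a mid-range fabricated sample: density 6.5 µm⁻², height median
41.5 nm (IQR 7.4 nm), matrix 19.4 nm, basal roughness 5 nm. Two deliberate
idealisations: Gaussian uncorrelated pixel noise (no scanner line noise or
tip convolution) and strictly non-overlapping base discs, whereas real
domain bases crowd beneath the matrix; the default aspect ratio
`R_sp/H = 4` keeps RSA placement feasible at these densities. Passing
round-trip tests therefore shows the slicing analysis is self-consistent,
not that it is robust to instrument artefacts.

The analyzer inverts the generator: background = 10th height percentile
(configurable), matrix level = median, connected components above each slice
level with 8-connectivity (caps are convex; 4-connectivity splits blobs at
diagonals), border-touching components dropped, and `R_sp` fitted per domain
by least squares on `r²(h) + (H−h)² = 2 R_sp (H−h)` across slices (default:
5 evenly spaced slices between the matrix level plus a 5-MAD noise margin
and 90 % of the maximum height). The noise margin matters: slicing exactly
at the matrix median percolates half the matrix pixels into one giant
border-touching component.

The unit map between reduced simulation lengths and nanometres is computed
separately for heights (`σ = H_exp/H_sim`) and lateral radii
(`σ' = R_d,exp/R_d,sim`); their ratio (≈4 for the systems modelled here)
quantifies how much less immersed simulated domains are than fabricated
ones.

## 2. Monte Carlo model of cell sorting (`mc_cellsort`)

Cells are hard spheres of diameter `D = 10` (reduced units) above a periodic
`L × L = 240 × 240` substrate decorated with fixed, non-overlapping
cylindrical adhesive domains of diameter `D_d` and height `H_d = D_d` at
coverage `σ_d = 0.48` (RSA placement; the count is
`round(σ_d L²/(π (D_d/2)²))`). These numbers are fixed by the printed
monolayer density `ρ_c = (N₁+N₂)/L² = 3.472×10⁻³` and packing fraction
0.273 with `N₁ = N₂ = 100`.

Energies (units of the effective noise temperature `T_eff ≡ 1`):

- **Adhesion.** A cell touching the domain-top plane deforms into a flat
  circular facet of radius `a = sqrt((D/2)² − u²)` (`u` = center height above
  the domain tops, hard wall at `u ≥ D/2 − δ_max`). The adhesion energy is
  `A_kd` × (sum of facet∩domain-top disc lens areas), `A_1d = −0.4`,
  `A_2d = −0.3`.
- **Polymer repulsion.** The swollen polymer presents a surface at
  `H_d + h_p`; the repulsion is `B_p` × (area of the sphere's cross-section
  at that plane, clamped at the equator, minus its lens overlaps with domain
  tops). Collapsed polymer exerts nothing.
- **Gravity** `g_w·z`, and hard-sphere exclusion between cells.

Dynamics are single-cell Metropolis moves (uniform displacement in a cube of
half-width `Δ`), modelling nonthermal agitation (flow, vibration) as an
effective temperature. Lateral boundaries are periodic; the top is a
reflecting wall at `z = 60` — with barometric length `T_eff/g_w ≈ 7` the
occupancy above `z ≈ 40` is negligible, so a taller box only slows the
adsorption stage.

**Protocol.** Stage 1 (adsorption): collapsed polymer, `B_p = 0`, until the
potential energy saturates (600 k attempted moves by default; saturation is
detected from the energy trace and all cells end attached). Stage 2
(desorption): polymer swollen at the requested `B_p`, starting from the
adsorbed configuration; attached counts (`z − H_d ≤ r_cut = D/2`, measured
from the domain-top plane so resting deformed cells always count) and the
density profile are averaged over the final half of a 1.2 M-move window.
The desorption window is deliberately a fixed observation window over a
slowly relaxing transient, not an exhaustive equilibration — the separation
factor of the physical experiment is likewise a property of a finite
detachment protocol.

**Calibration.** The model definition leaves four numbers free: the polymer
rise `h_p`, the deformation limit `δ_max`, gravity `g_w`, and the move size
`Δ`. A single set — `h_p = 0.5`, `δ_max = 3.0`, `g_w = 0.14`, `Δ = 1.0` —
was calibrated once against the published sorting working points
(≈35 %/≈3 % of type-1/type-2 cells attached at `D_d = 0.5, B_p = 0.32`;
≈2.5 % type 2 at `D_d = 2.0, B_p = 0.37`) and is the package default,
recorded in every run manifest. No per-experiment retuning is done.

**Separation factor.** `SF = (attached₁/attached₂)/(initial₁/initial₂)`.
With 100 cells per type, SF is only measurable while at least about one
type-2 cell remains attached on average; below that the ratio is shot-noise
dominated, so sweep results flag SF undefined there (the natural extension
of "undefined at zero attached"). The SF maximum emerges where type-1 cells
are still largely attached but type-2 occupancy approaches the counting
floor — mirroring the few-cell peak values of the original observations.
Domain-size ordering (larger domains peak at larger `B_p` with a higher
peak) emerges from lateral heterogeneity: under a facet spanning many small
domains the covered fraction self-averages to `σ_d`, while large domains let
cells sit on favourable spots.

## 3. DPD model of the grafted film (`dpd_film`)

Standard DPD: soft conservative force `a_ij (1 − r)` within `r_c = 1`,
pairwise dissipative (`γ = 4.5`) and random forces tied by
fluctuation–dissipation (`σ² = 2γkT`, uniform unit-variance noise), modified
velocity-Verlet (`λ = 0.65`, `Δt = 0.04`), bead density `ρ_b = 3`, `kT = 1`.
Chains are harmonic bead springs (`k = 4`, zero natural length); grafts and
pins are identical springs to fixed sites. The substrate and ceiling are
frozen wall-bead layers plus bounce-back reflection (velocity reversal), so
solvent cannot leak and the thermostat is undisturbed.

Bead types: PGMA, PNIPAM, GMA (cross-linkable comonomer, otherwise identical
to PNIPAM), WATER, WALL. Interactions: `a_ii = 25`,
`a(PGMA,PNIPAM) = 40` (strong incompatibility), `a(PGMA,WATER) = 27`
(near-theta; the tuning script `scripts/tune_theta_solvent.py` verifies
`R_g ~ N^0.5` within tolerance at this value). The LCST is a force-field
switch on a single pair: `a(PNIPAM,WATER) = 17` below the LCST (strongly
hydrated) and `50` above it (dehydrated). This contrast is the one
calibrated quantity of the film model: it sets the collapse/swelling
magnitude and was chosen once so the grafted-network swelling ratio matches
the experimentally reported scale (≈2.4–2.8 at chain length 100,
`ρ_g = 0.2`, `ν_cr = 5–7 %`). No explicit temperature dependence is
modelled.

**Cross-linking.** All GMA beads start active (fraction 0.30 of matrix
beads in the cross-linking stage); each step, overlapping active pairs bond
with probability 0.1 in randomized order, both partners becoming inert, and
a bead consumed within a step is skipped for later pairs of that step.
Linking stops when `ν_cr = 2 N_b / N_matrix × 100 %` reaches its target;
leftover active beads then become plain PNIPAM. The bond-count trace
saturates well within the stage.

**Swelling protocol.** Chains are initialised as a compact layer (the
experimental network is formed in the collapsed melt — cross-linking an
extended configuration would freeze the wrong topology), equilibrated above
the LCST (8 k steps), cross-linked, sampled for the collapsed height `h₂`,
switched below the LCST and sampled for `h₁`. Heights are first moments,
`h = 2⟨z⟩` over matrix beads. Because brush swelling is Rouse-slow
(relaxation ~N² steps), the swollen state is entered through an affine
z-pre-stretch (factor 2) and relaxed downward — an equilibration
accelerator that changes no observable, only the approach direction. The
result carries the achieved `ν_cr`, standard errors, and a drift flag; the
cap-geometry runs in particular use a fixed late observation window rather
than full network equilibration, and flag residual drift instead of
extending runs.

**Cap-pinned geometry.** Two frozen spherical-cap obstacles (shell of
beads, thickness `r_c`) sit at opposite sides of a narrow box, their
periodic images forming the domain array; the matrix is grafted to the
substrate strip between them (`ρ_g = 0.2`) and pinned to cap-surface sites
below the pinning height at density `ρ_pd` — each sampled pin site binds
its nearest matrix bead within 1.5 `r_c` after assembly, emulating
contact-epoxy grafting.

**Phase separation.** Mixed tethered PGMA/PNIPAM chains (a fraction `f` of
chains PGMA) in a theta-like solvent demix into PGMA domains; domains are
identified by distance-based clustering (cutoff `r_c`) and each is sliced
into unit slabs whose convex-hull areas give equivalent-disc radii for the
same spherical-cap fit used on height maps.

## 4. Problem sizes and tolerances

Default problem sizes are desk scale, chosen so the full test suite and the
acceptance sweep each run on a single CPU core in tens of minutes: MC stages
of 0.6/1.2 M attempted moves (energy saturation occurs well before the
window ends), DPD boxes of 10³–10⁴ beads with 10⁴–2×10⁴ steps per swelling
run, reduced cap radii for trend scans. Full-scale settings (2 M MC moves,
5×10⁴-step cross-linking, 5×10⁵-step phase separation, cap radii 30–100)
are plain config values. Consequences of reduced scale: swelling ratios
carry a few-percent finite-box bias (the acceptance band allows ±0.3), the
cap-trend runs are intentionally not fully equilibrated (flagged), and SF
curves carry seed noise of roughly ±1 unit near the peak.

Numerical tolerances: DPD thermostat holds `kT` within 3 %; the virial
pressure matches the quadratic equation-of-state fit within 5 % at
`ρ_b = 5` (the fit itself is poor at `ρ_b = 3`, where the true pressure of
this potential is ≈8 % below it — verified against an independent Metropolis
oracle, so the check is run at the density where the reference formula is
valid); lens/cross-section areas agree with 10⁵-point sampling oracles
within 1 %; RSA placements are verified overlap-free by pair scan; the
barometric limit of the MC dynamics passes a KS test against the closed
form. Degenerate inputs (empty fields, fully buried caps, zero densities,
unstable time steps, jamming coverages) raise typed errors rather than
returning silently wrong numbers.

## 5. Known limitations

- No hydrodynamics, shear flow, or cell–cell adhesion in the MC model; cell
  deformation is the flat-facet approximation with a hard cutoff.
- LCST response is a solvent-quality switch; no temperature kinetics.
- The coarse force field is a caricature pending an experimental
  parameterisation; only trends and calibrated magnitudes are meaningful.
- The synthetic scans idealise instrument noise; analysis robustness claims
  extend only to the modelled noise.
- At 100 cells per type, separation factors beyond ~30 are not measurable;
  sweep outputs flag that region rather than report it.
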