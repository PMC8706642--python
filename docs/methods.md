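# Model and methods

`granupbm` simulates high-shear wet granulation of a two-solid blend — a
hydrophobic API and a hydrophilic excipient (think ibuprofen or
acetaminophen with microcrystalline cellulose) — granulated with an
aqueous binder sprayed as monodisperse drops.

## State space

Each granule is described by three internal coordinates: API solid
volume `s1`, excipient solid volume `s2` and pore volume `p`, plus two
lumped liquid coordinates: external (surface) liquid `le` and internal
(pore-held) liquid `li`. Derived properties are

    v   = s1 + s2 + le + p            total (envelope) volume
    a   = pi^(1/3) (6 v)^(2/3)        sphere-equivalent surface area
    eps = p / v                       porosity
    q   = s1 / v                      volumetric API content

Internal liquid occupies pores (`li <= p` per granule) and does not add
to the envelope. The number density `F(s1, s2, p)` lives on a shared
geometric volume grid per coordinate (default: 12 bins spanning
sphere-equivalent diameters 31.5–6000 µm, ratio fitted to the span; a
fixed-ratio-4 mode and a 20-bin grid are available). Liquids are stored
as cell totals so every transport operation conserves binder volume
exactly; per-particle averages are formed on demand.

Granules created off-grid are re-binned by a tensor-product cell-average
rule: each coordinate splits between its two bracketing bins so that
number and that coordinate's first moment are conserved exactly;
attached liquid follows the number fractions. Targets outside the span
clamp to the boundary bin and the signed volume defect is logged to a
ledger that closes the conservation audit.

## Mechanisms

**Nucleation.** While binder remains, drops of volume `v_d` hitting the
powder bed either immerse (probability `P_im(f1)`) — drawing in solids
at the bed composition until the critical-packing liquid fraction
`phi_cp = 0.2` is reached, so `v_im = v_d (1 + (1-phi_cp)/phi_cp)` with
pore volume `v_d`, fully saturated — or form solid-spread nuclei
("liquid marbles"): drops coated by a shell of API primary particles,
`v_ss = (pi/6)(d_d + 2 d_p)^3`. `P_im` comes from a pluggable provider;
the default is a logistic in the API mass fraction fitted through
(0.5, 0.67) and (0.6, 0.33), standing in for an upstream data-driven
wettability classifier (only its probabilities enter the model). The
marble class is tracked as a count plus API/drop volume totals; the API
mass drawn per marble is `f1 rho_s1 v_ss_s1` at the current bed
fraction, and exactly that volume is booked to the class, so the API
balance closes identically. The fraction of spray hitting un-granulated
powder defaults to the remaining bed mass fraction (configurable,
`f_bed`); the rest rewets granule surfaces in proportion to `F v`.

**Layering.** Wet granules (`le > 0`) collect fine excipient at
`ds2/dt = k_layer a Ms2 / rho_s2`, with mass-consistent depletion of the
excipient reservoir.

**Surface growth.** A marble impacting a granule spreads to
`D_max = D (1 + 0.12 We)` before rupturing; only granules at least that
large collect the shell. Two channels deliver it: the continuous rate
law `ds1/dt = k_sg v^(2/3)` drawn from the marble reservoir, and a
collision-driven transfer at rate `beta0 beta* Fss F` per eligible cell
in which one marble deposits its API shell and drop (as surface liquid)
onto the granule without changing the granule count. The collision
channel is what moves marble volume on the process time scale; the
printed `k_sg` makes the continuous law a small correction. Marble–
marble collisions coalesce within the class: the count falls, the
volume totals stay, so the mean marble payload grows.

**Aggregation.** Kernel `beta = beta0 beta*` with
`beta* = min(1, (W_c + W_d)/E_k)`: the work of the capillary and viscous
bridge forces against the rebound kinetic energy
`E_k = 1/2 m e_coag^2 v_r^2` (reduced mass = harmonic mean; relative
velocity from the granular temperature, `Theta ∝ gamma^2 d^2`).
`W_d = (3 pi mu d~^2 e_coag v_r / 4) ln(h/h_a)` vanishes when the binder
layer `h = mean(le/a)` is thinner than the asperity height.
`W_c = Ca(f_api) W_d` with a log-linear capillary-number regression in
the pair's API solid fraction (anchors configurable per formulation).
Granule restitutions are solid-mass-weighted (`e_pore = 0`), and the
pair softness `zeta = 1 - e_A e_B` interpolates the merged volume
between an area-conserving hard limit (extra void created) and a
pore-conserving plastic limit (volumes additive); external liquid is
partly drawn into the new internal volume by a geometric-mean transfer
with overlap caps, and internal liquid exceeding the merged pores is
squeezed back out. The symmetric pair loop over occupied cells uses
`F(F-1)/2` self-pair counts and deposits merged granules by cell
average; cells below a relative occupancy threshold (default 1e-6 of
total number) keep their mass but skip pairing.

**Consolidation.** Per step `d_eps = k_con U dt (eps - eps_min)` where
`U` is the granular-temperature collision velocity at the cell
diameter, applied only where the result stays at or above `eps_min`;
pores re-close at fixed solids and surface liquid, and internal liquid
no longer fitting the pores is squeezed to the surface. The porosity
floor is resolved only to within the (coarse) geometric pore grid: the
two-bin splitting can park part of a population slightly below
`eps_min`, where the guard freezes it.

**Breakage.** Optional (default off): shear-proportional binary
breakage `K = p_brk gamma d^n` with daughters splitting every
coordinate and the attached liquid in fixed proportions — conservative
by construction. The published source keeps its breakage sub-model in
an appendix not available here; this configurable stand-in preserves
the interface.

## Time stepping

First-order explicit Euler with an adaptive step: the CFL-type bound
(no cell loses more granules per step than it holds, safety 0.5), a
drift limit on the continuous coordinate rates (per-step coordinate
movement below 20% of the granule volume), and `dt_max` (default
0.1 s). Operator order within a step is fixed: nucleation, rewetting,
layering, surface growth, aggregation, breakage, consolidation, each
followed by re-binning and pore-saturation enforcement. Aggregation
rates are assembled once per step from the pre-step state; if the
intervening sub-steps would make the fixed step overdraw a cell, the
whole aggregation rate set is scaled down uniformly, preserving its
conservation properties. The forward model contains no randomness.

Conservation audits run at every snapshot: API, excipient and binder
inventories across the grid, the marble class, the powder/binder
reservoirs and the boundary-clamp ledger. On the reference run they
close to ~1e-14 relative (tolerances asserted: 1e-9 solids, 1e-6
binder).

## Parameters and unit conventions

The six tuned constants default to published optimized values printed
without units: `beta0 = 4.34e-10` (per pair count per second),
`e_s1 = 0.162` (ibuprofen; 0.103 acetaminophen), `e_s2 = 0.07` (MCC),
`k_con = 1.67e-3`, `k_layer = 2.01e-8`, `k_sg = 4.59e-11`. No single
length unit renders the last three simultaneously active on a process
time scale (we checked cm, mm, µm and bin-normalized volumes), so each
is assigned a fixed per-mechanism convention once: `k_con` per cm
(0.167 m⁻¹ — partial consolidation over minutes), `k_layer` per mm² per
second (2.01e-2 m⁻² s⁻¹ — layering acts within the spray phase),
`k_sg` in cm/s (4.59e-13 m/s — a small correction next to the collision
channel). These conventions are part of the package's definition of its
calibration truths.

Operating conditions not fixed by the published study were chosen once
on realism grounds: 1 kg powder charge, liquid-to-solid ratio 0.6,
200 µm drops, spray rate 1.5e-5 m³/s (40 s addition), shear rate
1000 s⁻¹, particle volume fraction 0.3, water binder (1 mPa·s,
0.07 N/m), primary particles 25 µm (API) and 75 µm (excipient),
asperity height 1 µm, minimum porosity 0.05, capillary-number anchors
(0.4, 1.0)–(0.6, 3.0).

## Analysis outputs

Volume-weighted cumulative size distributions with d10/d50/d90 by
monotone interpolation; number- and volume-weighted granule averages of
porosity, liquid fraction and API content; `dq`, the gap between the
blend API solid-volume fraction and the volume-weighted mean `q`; and
the demixing potential across size classes,
`DP% = (100/x_bar) sqrt(sum w (x - x_bar)^2)` with `x` the class API
mass fraction and `w` the class weight fraction. The published formula
prints without the radical; the square root is included here because
the quantity is defined by analogy to a relative standard deviation.
The one-at-a-time sensitivity scan perturbs each tuned constant by
±10/20% and reports `(Y0 - Yi)/Y0` for d10/d50/d90, porosity and API
content.

## Calibration

`make_fixture` runs the forward model at known parameters, samples the
cumulative size curve at 12 log-spaced diameters and the per-class API
content on 6 diameter classes, and (optionally) corrupts them with
seeded multiplicative Gaussian noise — a stand-in for sieve/assay data.
`pareto_fit` estimates the six constants by weighted-sum scalarization
of (size SSE, content SSE): per weight, a seeded Latin-hypercube
presample followed by bounded Powell refinement in a unit-cube
parameterization (log10 for `beta0`, `k_con`, `k_layer`, `k_sg`),
pruning to the non-dominated set and reporting a knee-point compromise.
On noiseless self-generated fixtures the well-identified constants
(`beta0`, `k_con`) recover to within ~5–12%; the restitutions and
growth constants are weakly identified, consistent with their low
sensitivity.

## What the synthetic data do and do not show

Fixtures come from the forward model itself, so parameter-recovery
results demonstrate identifiability and optimizer correctness, not
fidelity to any laboratory system. Real granulation data add drop-size
distributions, spatially inhomogeneous shear and binder, wall effects,
attrition and assay error structure that the generator does not
emulate.

## Known limitations

- With the published restitution values, the collision-efficiency
  ratio `(W_c + W_d)/E_k ~ 1/e_coag` exceeds one for essentially every
  small wet pair at realizable shear rates, so `beta*` saturates at 1
  and the total number follows the universal constant-kernel decay.
  Composition then enters final sizes only weakly (merge-void and
  marble-retention terms of ~1%), and the simulated d50 is nearly flat
  across API fractions 30–60% rather than monotonically increasing;
  likewise `dq` is dominated by liquid dilution (it grows with the
  blend API fraction at fixed liquid-to-solid ratio). The demixing
  potential does reproduce the expected monotone improvement of content
  uniformity with API fraction, and d50 rises from the 50% to the 60%
  blend. The corresponding acceptance test is left failing rather than
  weakened; see the sweep itself for the numbers.
- The porosity floor and all internal coordinates are resolved to a
  coarse geometric grid (volume ratio ~4 at 12 bins); quantiles of the
  size distribution carry ~1% grid noise.
- Marble payload transfer and granule aggregation share the `beta0 F`
  collision clock, so some marble volume is always still in transit at
  the end of a finite run.
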