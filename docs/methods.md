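# Methods

## Scope and model structure

`nihsim` simulates neointimal hyperplasia (NIH) in peripheral vein grafts
as a two-way coupling between wall biology and hemodynamics. The wall of
each axial station of the graft is a well-mixed two-compartment patch
(tunica intima and tunica media) evolved by eight ODEs; the blood flow is
a reduced-order pulsatile model that delivers one number per station and
remodeling epoch — the time-averaged wall shear stress (TAWSS) — plus the
oscillatory shear index (OSI) and relative residence time (RRT) for
reporting. The deliberate simplifications are:

* **No spatial transport in the wall.** Cells and molecules are uniform
  within a patch; patches interact only through the shared hemodynamics.
* **Quasi-steady Poiseuille shear instead of 3-D CFD.** Station shear is
  `τ(t) = 4 μ Q(t) / (π r³)` with the instantaneous flow propagated
  through the tree by the outlet-conductance split. This resolves the
  radius and flow dependence of shear but not flow separation, secondary
  flow or Womersley effects. Because the biochemistry consumes only
  TAWSS, which at these radii is dominated by the cycle-mean flow, this
  is an acceptable stand-in at desk scale; the separation-induced shear
  depression near anastomoses and bifurcations is emulated by an explicit
  multiplicative *disturbance profile* (below). The remodeling loop is
  agnostic to the shear provider: `run_remodeling(..., tawss_source=f)`
  accepts any per-station TAWSS map, including values read from a CFD
  export.
* **Rigid vessel within an epoch.** Geometry changes only at epoch
  boundaries, when the accumulated intimal volume is applied.

## Wall kinetics

Per patch, with intima `i` and media `m`:

```
dQ/dt   = β Q (1 − Q/Q_max)                       quiescent SMCs, logistic
dS_i/dt = γ Q_i + (p_i − a_i) S_i + m S_m + φ(G_P + G_F)
dS_m/dt = γ Q_m + (p_m − a_m − m) S_m             synthetic SMCs
dC/dt   = λ S − χ C                               collagen
dG_P/dt = ζ_g − ζ_d G_P                           PDGF
dG_F/dt = θ_g − θ_d G_F                           FGF-2
```

Layer volumes are `V = (S + Q)/ρ_s + C/ρ_c`. The carrying capacity is
volume-derived, `Q_max = V_max ρ_s`.

Shear enters through nitric oxide. NO production is linear in shear,
`R_NO = c0 + c1·WSS` with c0 = 1.74, c1 = 7.52 (nM/s; see unit note
below), and the intimal proliferation, apoptosis and migration
coefficients are the medial constants scaled by `1 − R_NO/R_NO_MAX`.
Growth-factor degradation is linear in shear: `ζ_d = k_P·WSS`,
`θ_d = k_F·WSS`, so the steady pools `G* = production/(k·WSS)` grow
without bound as shear → 0 — a second, independent low-shear growth
drive beside the proliferation term.

The migration coefficient `m` appearing as an outflow in the media
equation is the same shear-dependent `m = m0(1 − R_NO/R_NO_MAX)` that
feeds the intima, so migrating cells are conserved between layers.

### Parameters

Constant rates (per day unless noted): β = 5×10⁻⁴, γ = 10⁻⁴,
p_m = 0.122, a_m = 0.0715, m0 = 0.0251, λ = 2.16×10⁻¹³ g/(day·cell),
χ = 0.033, ζ_g = 0.0776 ng/day, θ_g = 0.1394 ng/day,
k_P = 1.94×10⁻⁴ /(day·Pa), k_F = 6.97×10⁻⁴ /(day·Pa),
ρ_s = 2.18×10¹⁴ cells/m³, ρ_c = 2×10³ g/m³. These are literature-derived
experimental values and are the package defaults.

**NO unit convention.** The linear NO law is reported in the source
literature with an intercept of 1.74 against a saturation rate quoted as
0.1 µM/s. Read on a common scale of M/s the production/saturation ratio
would exceed 1 already at zero shear, making the intimal rates negative
everywhere. `nihsim` therefore reads the law's output as nM/s, i.e.
`R_NO_MAX = 100 nM/s`, and additionally clamps the ratio to [0, 1] so
that fully NO-saturated shear simply switches intimal turnover off. Both
the scale (`no_unit_scale`) and the clamp (`clamp_ratio`) are
config-exposed.

**φ has no experimental value.** The growth-factor-to-cell-production
coupling φ [cells/(ng·day)] is not constrained by published data; the
YAML loader refuses a parameter file without an explicit `phi`. The
shipped default (1.0) makes the φ(G_P+G_F) inflow the same order as the
differentiation inflow γQ_i on the default fixture (~10³ cells/day at
~1 Pa).

**Media constancy.** With the printed constants, `p_m − a_m − m0 =
+0.0254/day`, so the medial synthetic pool grows slowly rather than
staying exactly stationary. The default integrates the equations
literally; `media_equilibrium: true` rescales the medial apoptosis rate
so the zero-shear balance is exact. In either mode the media never
changes the geometry.

### Initial conditions and capacities

Published initial conditions do not exist; the healthy-baseline
convention is: quiescent cells at 95% of capacity, synthetic cells
seeded at 10⁻⁴ of Q, collagen at its turnover steady state `S λ/χ`,
growth factors at their shear steady state (empty when degradation is
zero). The intimal capacity volume is the annulus from the lumen down to
90% of the initial radius — i.e. a healthy intimal layer about a tenth
of the radius thick; the media is a fixed annulus of 0.5 mm. All of
these are `RemodelingConfig` fields.

The seed fraction and capacity convention were chosen so that the
120-day femoropopliteal run lands in the physiologically reported regime
for this kind of graft — intimal thickening of order 1 mm concentrated
at the anastomoses, crossing the 50% restenosis threshold there without
wholesale occlusion of the graft. Larger seeds or a deeper capacity
annulus make the exponential synthetic-cell term overshoot the entire
lumen volume within two epochs, which no clinical series shows at
4 months; the exponential sensitivity to these two knobs is a genuine
property of the kinetics and is why they are surfaced prominently.

### Numerics

The wall ODE is integrated with adaptive RK45 (`rtol 1e-8`, `atol
1e-6`), sampled at the 1-day biochemical step. Output samples are
projected onto the non-negative orthant: violations under 10⁻⁹ relative
are clipped, anything larger aborts with a diagnostic. The adaptive
solution is tested against an independent fixed-step explicit-Euler
oracle (dt = 10⁻³ day) to 10⁻⁴ relative over 30 days, and growth-factor
trajectories against their closed-form exponentials to 10⁻⁶ relative.

## Hemodynamics

* **Waveform processing.** Inflow is one period of a sampled signal,
  velocity- or flow-tagged (velocity converts via the parabolic-profile
  relation `Q = v_max π R²/2` at the inlet radius; in the remodeling
  loop this conversion happens once, at the post-surgery inlet radius,
  so the prescribed mass inflow stays fixed as the lumen narrows).
  Doppler-like traces are denoised with a centered, periodic
  moving-average filter (odd window; the cycle mean is preserved
  exactly).
* **Indices.** TAWSS = cycle mean of |τ| (trapezoid with the periodic
  seam closed); OSI = ½(1 − |∫τ|/∫|τ|) ∈ [0, 0.5];
  RRT = 1/((1 − 2·OSI)·TAWSS), the standard composite.
* **Windkessel bank.** Each tree outlet carries an RC(L) element; all
  elements hang in parallel off one junction fed by the prescribed
  inflow, capacitors at the junction, resistor (plus optional series
  inertance) to ground. Fixed-step RK4 from zero pressure; cycles repeat
  until the cycle-to-cycle peak-pressure change is below 0.5%, and the
  last cycle is returned. Pure-resistive banks conserve mass at every
  instant and split flow by conductance exactly; compliant banks
  conserve the cycle mean within 1%. Outlet resistances can be
  calibrated to target mean flows by fixed-point conductance rescaling.
* **Blood**: Newtonian, μ = 0.0035 Pa·s, ρ = 1050 kg/m³.

## Geometry and remodeling loop

Stations are axial slices with radius, length and tags. Intimal volume
gained in an epoch is laid down as an axisymmetric inward ring,
`r' = √(r² − ΔV_i/(π L))` — the simplest exactly volume-conserving map.
A radius that would fall below the occlusion floor (0.1 mm) is clamped
there and the station flagged occluded (shear is then evaluated at the
floor, which saturates NO and halts further growth — mirroring that the
model cannot follow a vessel through complete closure).

One epoch = compute shear field → integrate every wall patch for the
coupling interval at frozen TAWSS → apply growth → snapshot. The default
coupling interval is 60 days (a clinical follow-up step); a single-epoch
run reproduces the one-cycle protocol used for very long grafts. Epoch
durations always sum exactly to the requested horizon. The loop is fully
deterministic — randomness exists only in the synthetic-data generators,
under a single seed.

A note on monotonicity: the *stimulus* (net intimal proliferation rate
`p_i − a_i`) is non-increasing across epochs at every station, because
radii only shrink and shear only rises. Absolute per-epoch volume gain
is **not** monotone — the synthetic-cell pool compounds roughly
exponentially, so later epochs can add more volume even as the stimulus
weakens. The tests assert the former, which is the well-defined feedback
property.

## Synthetic data

The generators replace clinical inputs that cannot be shared:

* **Grafts.** `femoropopliteal`: one 30 cm segment, radius tapering
  2.72 → 2.67 mm, anastomosis-tagged ends. `femorodistal`: 90 cm trunk
  tapering 6.29 → 0.96 mm with collateral outlets of 2.71 mm (deep
  femoral, anterior), 1.63 mm (deep femoral, posterior) and 1.0 mm
  (posterior distal) branching at 20/40/75% of the trunk (branch
  positions are not clinically constrained; config-exposed), four
  outlets in all. `straight_tube`: uniform control.
* **Windkessel constants** for the femorodistal bank use the published
  clinical calibration: shared C = 12.6×10⁻⁶ ml/Pa and resistances
  5.5×10⁵ / 4.5×10⁵ / 4.5×10⁵ Pa·s/ml for the collaterals and
  2×10³ Pa·s/ml for the main popliteal outlet. The published table lists
  five resistances for four outlets (one row is duplicated); the
  popliteal-anterior entry (3×10³) is the one left unmapped in this
  four-outlet reduction and is used for the single-outlet presets.
* **Doppler waveform.** Three-Gaussian triphasic template (systolic
  peak, early-diastolic reverse flow, late rebound) with period 1.1 s,
  normalized to a 1.3 m/s systolic peak; cycle-mean velocity ≈ 0.41 m/s,
  which at the femoropopliteal inlet gives ≈ 5 ml/s and a baseline TAWSS
  ≈ 1.1 Pa — the physiological mid-range for such grafts. Seeded
  multiplicative noise plus sparse large spikes emulate raw Doppler
  extraction; the defaults need an 11-sample moving average to recover
  the template.
* **Disturbance profile.** Gaussian shear dips centered on tagged
  stations: depth 0.81 at distal anastomoses and 0.7×0.81 at proximal
  anastomoses/bifurcations, width 3 stations. With the baseline above,
  the distal anastomosis starts at ≈ 0.22 Pa — the reported pre-remodeling
  minimum for this graft type — and the proximal at ≈ 0.47 Pa, just
  under the 0.5 Pa criticality threshold.

What the synthetic fixtures do **not** emulate: real Doppler spectral
broadening, patient-specific lumen irregularity, curvature-induced
secondary flow, or any correlation between geometry and waveform. A
passing end-to-end test therefore shows that the *mechanism* (low-shear
localization of growth at the distal anastomosis, shrinking critical
area, feedback quenching) is implemented correctly — not that the model
is validated against any particular patient.

## Sensitivity study

One-at-a-time perturbations rerun the identical loop with a single rate
scaled by `1 + fraction`; per-station fold-change is (perturbed total
ΔV_i)/(baseline total ΔV_i), reported where the baseline is positive,
with a 20-equal-width-bin histogram. On the default fixture, +20%
proliferation (p_m) yields ≈ 2.7–2.9-fold growth at every station. +20%
apoptosis (a_m) yields ≈ 0.57-fold: in these equations a larger
apoptosis rate lowers intimal accumulation, so the magnitude of the
apoptosis sensitivity (order three-fold per ±20%) is reproduced while
its sign is a model property that the package reports without asserting
a direction.

## Known limitations

* The Poiseuille + disturbance-profile shear model cannot predict *where*
  flow separates; locations of low shear are inputs (tags), not outputs.
* Occluded stations stop evolving geometrically; the model does not
  redistribute flow away from a nearly-closed branch within an epoch
  (the Windkessel split is conductance-based, not geometry-based).
* No endothelium, monocytes/macrophages, or inflammation species; no
  wall stress, FSI or non-Newtonian rheology.
* The femorodistal preset inherits an unphysiologically high shear in
  its narrow distal trunk from the combination of printed radii with a
  parabolic velocity inflow; NO saturation then suppresses growth there.
  Quantitative study of that geometry needs a calibrated inflow.
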