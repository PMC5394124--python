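# nihsim

Desk-scale, multiscale simulation of **neointimal hyperplasia (NIH)** in
peripheral vein grafts — the tissue growth that narrows and ultimately
occludes femoropopliteal and femorodistal bypasses.

NIH is driven by a feedback between blood flow and wall biology: regions of
low wall shear stress (WSS) produce little nitric oxide, which lets smooth
muscle cells switch to a synthetic phenotype, proliferate, migrate from the
media into the intima and lay down collagen; the thickened intima narrows
the lumen, which in turn reshapes the shear field. `nihsim` couples

* a **biochemical wall model** — eight ordinary differential equations per
  wall patch for quiescent cells (Q), synthetic cells (S) and collagen (C)
  in intima and media, plus the growth factors PDGF (G_P) and FGF-2 (G_F) —
  with shear-dependent kinetics, and
* a **reduced-order pulsatile hemodynamics model** — station-wise Poiseuille
  shear on an axisymmetric vessel tree, driven by a periodic inflow
  waveform, with lumped-parameter (Windkessel) outflow boundaries setting
  the flow split at bifurcations —

in a remodeling loop that alternates days of wall growth (at frozen
time-averaged WSS) with recomputation of the shear field on the narrowed
geometry. It is aimed at researchers in vascular mechanobiology who want a
fast, fully scriptable testbed for the shear–growth feedback, not a
replacement for 3-D CFD on patient geometry.

## Model core

Wall kinetics per patch (rates per day):

```
dQ/dt   = β Q (1 − Q/Q_max)                      (intima and media)
dS_i/dt = γ Q_i + (p_i − a_i) S_i + m S_m + φ (G_P + G_F)
dS_m/dt = γ Q_m + (p_m − a_m − m) S_m
dC/dt   = λ S − χ C                              (intima and media)
dG_P/dt = ζ_g − ζ_d G_P,   dG_F/dt = θ_g − θ_d G_F
V_i = (S_i + Q_i)/ρ_s + C_i/ρ_c                  (layer volume)
```

The mechanical input enters through nitric oxide, `R_NO = 1.74 + 7.52·WSS`
(nM/s), which scales the intimal rates:

```
p_i = p_m (1 − R_NO/R_NO_MAX),  a_i = a_m (1 − ·),  m = m0 (1 − ·)
ζ_d = 1.94×10⁻⁴ · WSS /day,     θ_d = 6.97×10⁻⁴ · WSS /day
```

Hemodynamics: Poiseuille shear `τ = 4 μ Q /(π r³)` per station, cycle
indices TAWSS, OSI and RRT, flow splits from outlet conductances, and an
RC(L) Windkessel bank solved by fixed-step RK4. Growth maps to geometry as
an axisymmetric inward ring: `r' = √(r² − ΔV_i/(π L))`.

## Worked example

Generate a synthetic femoropopliteal fixture (30 cm graft, inlet radius
2.72 mm tapering to 2.67 mm, 1.1-s triphasic Doppler-like inflow) and run
120 days of remodeling with the shear field refreshed every 60 days:

```
nihsim synth --preset femoropopliteal --seed 42 --out fx/
nihsim simulate --config fx/run.yaml --out results/
```

prints

```
 day  low_wss_area_cm2  min_tawss_pa min_tawss_station             min_tawss_tags  max_tawss_pa max_tawss_station            max_tawss_tags  max_occlusion_pct
 0.0         14.480498      0.218853         graft:019  distal_anastomosis,outlet      1.113143         graft:010                     plain           0.000000
60.0         14.240290      0.232242         graft:019  distal_anastomosis,outlet      1.149415         graft:010                     plain           3.881154
120.0         0.000000      2.057259         graft:000 inlet,proximal_anastomosis      5.531566         graft:020 distal_anastomosis,outlet          88.383814
```

Reading: at day 0 the lowest shear (0.22 Pa) sits at the distal
anastomosis and 14.5 cm² of wall sees TAWSS below the 0.5 Pa threshold
that marks NIH-prone tissue. As growth narrows the lumen, shear rises
everywhere and the critical low-shear area shrinks to zero, but the damage
is already localized: the largest lumen loss (88% of the initial
cross-section — past the 50% restenosis threshold) is at the
distal-anastomosis stations, with the proximal anastomosis next
(`results/summary.json` has the full per-station table). A
one-at-a-time sensitivity study, e.g.

```
nihsim sensitivity --config fx/run.yaml --perturb p_m=+0.2 --perturb a_m=+0.2 --out sens/
```

writes per-station growth fold-change tables: +20% proliferation roughly
triples growth at every station, while +20% apoptosis reduces it to about
0.57× (the model's sign for apoptosis; see `docs/methods.md`).

Python API mirrors the CLI: `make_graft`, `synth_doppler`,
`disturbance_profile`, `run_remodeling`, `sensitivity_study`, and the
low-level operations (`nitric_oxide_rate`, `shear_dependent_rates`,
`integrate_wall_state`, `solve_windkessel`, `tawss`, `osi`, `rrt`, ...).

## Layout

```
src/nihsim/
  biochemistry.py     wall ODEs, shear-dependent kinetics, steady states
  hemodynamics.py     waveforms, shear indices, Windkessel network
  vessel_geometry.py  station/tree types, growth ring, occlusion metrics
  remodeling.py       the feedback loop and its summaries
  sensitivity.py      one-at-a-time perturbation studies
  synthetic_data.py   graft presets, Doppler-like waveforms, disturbance profiles
  io.py / cli.py      file formats (JSON/CSV/YAML/VTK-legacy) and `nihsim` commands
docs/methods.md       model assumptions, parameter provenance, limitations
```
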