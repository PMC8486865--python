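# Methods

This note documents the model underlying `oncotherm`: its assumptions, the
parameters that matter, how the calibrated constants were fixed, the
numerical choices, and what the desk-scale setup can and cannot say about
real tumors.

## Scope and geometry

The simulator targets a preclinical-scale solid tumor: a sphere of radius
5 mm inside a 5 mm shell of normal tissue, discretized on a 1-D spherically
symmetric finite-volume grid (default spacing 0.1 mm, 101 nodes; at least 50
nodes must resolve the tumor radius).  Geometry and physiology are frozen in
time — treatment horizons (≤ 24 h plus an 80 h regrowth projection) are short
against tumor-growth timescales.  By microvessel density the tumor is split
into three concentric zones at r/R = 1/3 and 2/3: hypoxic, quiescent and
proliferative, with vascular surface density S/V = 0.1×, 0.5× and 1.0× of the
nominal 2×10⁴ m⁻¹ and perfusion scaled identically (nominal 2×10⁻³ s⁻¹,
≈ 0.12 ml g⁻¹ min⁻¹).  Normal tissue has S/V = 7×10³ m⁻¹, perfusion
1×10⁻³ s⁻¹ and the only functional lymphatics.  The zone boundaries and the
nominal magnitudes are standard Baxter–Jain-class choices; the in-tumor
ordering (hypoxic < quiescent < proliferative) is structural and enforced.

The focused-ultrasound stage runs on its own small axisymmetric (r, z) grid
around the focus (±8 mm, 0.15 mm spacing — six points per wavelength at
1.44 MHz); its lesion is projected back onto spherical shells for the 1-D
protocol stages.

## Interstitial fluid flow

Steady Darcy flow with a Starling source and lymphatic sink.  Defaults
(tumor/normal): K = 1.9×10⁻¹³ / 6.4×10⁻¹⁴ m² Pa⁻¹ s⁻¹, L_p = 2.1×10⁻¹¹ /
2.7×10⁻¹² m Pa⁻¹ s⁻¹, p_v = 2080 Pa, σ = 0.82 / 0.91, π_v = 2660 Pa,
π_i = 2000 / 1330 Pa, lymphatic coefficient 5×10⁻⁸ Pa⁻¹ s⁻¹ in normal tissue
only.  These give the expected phenomenology: an interstitial-pressure
plateau near the effective pressure p_e = p_v − σ(π_v − π_i) ≈ 1.54 kPa over
the tumor interior (variation < 1 % over the inner half-radius) collapsing at
the rim, with the interstitial velocity peaking at the tumor boundary.  Flow
is steady because it equilibrates in minutes against multi-hour
pharmacokinetics.  The solver is validated against the closed-form uniform-
sphere solution `p = p_e[1 − (R/r)sinh(αr/R)/sinh α]`, α² = L_p(S/V)R²/K, to
better than 0.01 % on a fine grid.

## Thermal response functions

Vascular permeability and transmembrane exchange scale with temperature as
pure, stateless fold-change functions: linear ramps from 1 at 37 °C through
an anchor, held constant above 43 °C (the end of the mild-hyperthermia
regime; ablative effects act through perfusion damage instead).  The
transmembrane anchor is (42.6 °C → 2.4), i.e. f(43 °C) = 2.5.  The
permeability anchor (42.6 °C → 2.0) is this package's calibrated choice: a
doubling at peak mild hyperthermia reproduces the thermochemotherapy gain in
interstitial free drug over classical chemotherapy while keeping the effect
subordinate to intravascular release.  The permeability fold applies equally
to the diffusive permeability and to the convective sieving factor (1 − σ_f)
(clipped at 1), consistent with a pore-widening interpretation.

## MNP hyperthermia

Maghemite particles (core 18 nm, M_s = 3×10⁵ A/m, K_anis = 4.7×10³ J/m³,
τ₀ = 10⁻⁹ s, solvent viscosity 10⁻³ Pa·s) pre-accumulated uniformly in the
tumor heat under a 13 kA/m, 300 kHz field (H·f = 3.9×10⁹ A m⁻¹ s⁻¹, inside
the 5×10⁹ safety envelope) via Rosensweig linear response: Debye
out-of-phase susceptibility with the parallel Néel/Brownian relaxation time,
P = π μ₀ χ″ f H².  At these parameters Néel relaxation dominates
(τ ≈ 2.8×10⁻⁸ s) and the specific power is 2.86×10⁸ W/m³ per unit volume
fraction.

The one free parameter is the cluster volume fraction.  It is calibrated by
bisection so that one hour of heating peaks at 42.6 °C on the default
domain: φ = 1.249×10⁻³ (≈ 6 mg Fe₂O₃ per cm³ tumor, a direct-accumulation
loading).  Conduction dominates the heat balance at this tumor size, so the
temperature profile falls roughly parabolically from the center (42.6 °C) to
≈ 39.8 °C at the rim, with a volume-weighted tumor mean of ≈ 40.9 °C; the
whole tumor sits inside the release window of the carrier while never
crossing the 43 °C mild-hyperthermia ceiling.  The Pennes solver uses
backward-Euler diffusion with implicit perfusion (unconditionally stable,
dt = 1 s during heating), a Dirichlet 37 °C far boundary, and a per-step
discrete energy audit.

## HIFU ablation

A single-element spherically curved bowl (default aperture radius 40 mm,
curvature radius 48 mm) delivers 30 W at 1.44 MHz for 60 s focused at the
tumor center.  The linear lossy field is computed by direct quadrature of
the Rayleigh integral over the bowl with complex wavenumber
k = ω/c + iα (α = 5 Np m⁻¹ MHz⁻¹); the implementation is checked on-axis
against the O'Neil closed form (< 0.1 % away from nulls).  Heating uses
Q = 2 α_abs I with an absorption fraction α_abs/α = 0.18 — attenuation
(beam decay) and absorption (heat conversion) are separated, as usual in
thermal ultrasound modeling, with the split chosen jointly with the bowl
geometry so that the 60 s sonication produces a center-confined lesion
(focal peak ≈ 70 °C) rather than coagulating the entire tumor: the
treatment's premise is that the proliferative rim stays viable and
drug-accessible.  Both the bowl geometry and the absorption fraction are
configuration, not physics claims.

An explicit axisymmetric Pennes solve (dt = 20 ms, 60 s sonication + 60 s
cool-down) accumulates CEM43 = Σ R^(43−T) Δt (R = 0.5 at/above 43 °C, 0.25
below).  Lesion zones: α (coagulative necrosis) at CEM43 ≥ 240 min;
β (sublethal) at 30–240 min, extended to any node whose peak exceeded 45 °C
so the zones always nest; γ at peak T in [43, 45) °C — vessels vulnerable,
cells unharmed in 60 s.  Perfusion damage: α → 0, β → 0.2 (inside the
"under a quarter" bound), γ → 0.5, elsewhere 1.  With the defaults the α
core reaches ≈ 2.2 mm from the focus, β ≈ 4.5 mm, γ ≈ 5.4 mm.  The damage
map scales the Starling source, the bioheat perfusion sink, and the
drug-exchange surface node-wise (one perfusion truth source).

## Pharmacokinetics

Species: liposome-encapsulated (T), free (F) and protein-bound (B) drug,
all in doxorubicin-equivalent kg/m³.  Doses map linearly to injected plasma
concentration at 3.82×10⁻⁴ kg m⁻³ per mg m⁻², so 50/100/150 mg/m² give
0.0191/0.0382/0.0573 kg/m³.  The bolus is an initial condition (whole-body
exposure within the mixing minute); free-drug boluses start at the binding
equilibrium.

Binding: k_a = 3×10⁻³, k_d = 1×10⁻³ s⁻¹ — a quarter of circulating drug
free, bound at three times the free level.  Free and bound drug clear at the
same rate k_el = 5.78×10⁻⁴ s⁻¹ (terminal half-life 20 min — equal clearance
keeps the 3:1 ratio undistorted; clearing only free drug would push it to
~5:1).  The carrier clears at k_el_T = 4.3×10⁻⁵ s⁻¹ (half-life ≈ 4.5 h,
multi-hour bioavailability) and leaks at 3.9×10⁻⁵ s⁻¹ at body temperature
(~30 % over 2.5 h).  Above the 39–41 °C lipid melting range the release rate
ramps to k_burst = 2.5 s⁻¹: 95 % of the payload in 1.2 s, a "within seconds"
burst that empties the tumor-vessel carrier pool by > 90 % against the
perfusion refill (Q_perf = 0.085 s⁻¹, the zone-mean perfusion divided by the
2 % vascular plasma fraction).

For free-drug protocols the systemic and tumor-microvessel plasma pools are
treated as a single compartment (the classical-chemotherapy simplification
of the underlying model); carrier protocols resolve the microvessel pool
(V_Tp/V_Sp = 10⁻³) so that intravascular release is perfusion-limited, which
is the entire point of the ThermoDox mechanism.  Because of that volume
ratio, tumor-vessel dynamics perturb systemic concentrations by < 0.1 %.

## Interstitial transport

Each species diffuses (D_F = 5×10⁻¹¹, D_B = D_F/3, D_T = 5×10⁻¹³ m²/s — the
carrier is nearly immobile and accumulates at the rim), advects with the
(small) Darcy velocity, exchanges with the vasculature through the Patlak
flux, binds to interstitial protein (k_a_i = k_d_i = 10⁻³ s⁻¹; interstitial
protein is sparser than plasma protein, so half the extracellular drug is
free), is removed by normal-tissue lymphatics at the fluid drainage rate,
and — free drug only — crosses the cell membrane with uptake ξ = 5×10⁻⁴ s⁻¹
and efflux ε (both scaled by the transmembrane temperature multiplier).
Vessel-wall permeabilities: P_F = 10⁻⁷ m/s in both tissues (doxorubicin is
small and lipophilic), P_T = 10⁻⁹ m/s in tumor and exactly 0 in normal
tissue (the 100 nm carrier cannot pass 5–6 nm normal pores); bound drug does
not cross walls or membranes.  Concentrations are per tissue volume with
phase fractions folded into the effective rates.

## Pharmacodynamics

`dN/dt = (k_p − k_deg − ω(C_int))N` per node, with proliferation
k_p = 3×10⁻⁶ s⁻¹ and physiological degradation k_deg = 2.6×10⁻⁶ s⁻¹, so
drug-free tissue grows ≈ 12 % in 80 h — the regrowth signature used to call
recurrence.  The kill law is saturable, ω = f_max C_int/(EC50 + C_int).
α-zone cells are removed outright at sonication; β-zone cells survive with
full proliferative capacity by default (the worst case for recurrence; an
optional instant fractional β kill is available).  Growth onset is the first
time the tumor-average viable density rises monotonically for at least an
hour.

## Calibration

Four constants are not pinned directly by published anchor values and were
fixed by a documented calibration pass (re-runnable via `oncotherm
calibrate`); each was frozen into the defaults:

| constant | value | target |
|---|---|---|
| MNP volume fraction | 1.249×10⁻³ | 1-h heating peak = 42.6 °C (bisection) |
| cellular efflux ε | 1.086×10⁻³ s⁻¹ | intracellular peak lags extracellular free-drug peak by 20 min (bisection) |
| f_max, EC50 | 4.65×10⁻⁵ s⁻¹, 6.22×10⁻⁴ kg/m³ | classical-chemo 6-h kill ≈ 15 % with growth onset ≈ 6 h (alternating bisection) |
| carrier clearance k_el_T | 4.3×10⁻⁵ s⁻¹ | ThermoDox 24-h kill ≥ 40 % with onset ≈ 15–16 h |

With these, the model reproduces its remaining anchors without further
tuning: kill ordering ThermoDox > thermochemo > classical, dose-monotone
kill, the ≥ 2.6-fold free-drug gain of intravascular release (the model
gives ≈ 5.5×), and dose-linear PK throughout.

## Numerics

Flow: conservative finite volumes, direct sparse solve, residual tolerance
10⁻¹⁰; discrete mass balance to machine precision.  Bioheat (1-D): backward
Euler, banded solves, dt = 1 s while heating; energy audit < 10⁻⁶.  Bioheat
(2-D): explicit with dt safely inside the stability limit.  Transport:
implicit conservative diffusion, explicit first-order upwind advection
(velocities are tiny, so diffusion carries the accuracy burden), explicit
reactions, and sub-stepped (≤ 5 s), exactly mass-paired plasma exchange
with exact relaxation factors for the stiff release and perfusion terms;
base step 60 s, 1 s during the heating window.  Negative concentrations are
floored at zero with the clipped mass audited (≪ 10⁻⁶ of injected).  A
whole-system mass ledger (plasma + interstitium + cells + cleared +
endothelial + lymphatic) is checked at every output step; runs abort if it
drifts beyond 0.5 % (in practice it holds to ~10⁻¹³).  The Patlak flux is
verified against a numerically integrated pore-transport boundary-value
problem to 10⁻⁶ relative.  Everything is deterministic: identical
configurations produce bit-identical results, and provenance (config hash,
package version) is recorded in every result.

## Limitations

* The geometry is a static, radially symmetric idealization: no deforming
  mesh, vascular network, patient anatomy, or growth during treatment.
* Acoustics are linear (no cavitation or shock formation) and the
  acoustic–MNP interaction is neglected; the bowl geometry and absorption
  split are tuned defaults, not measurements.
* The zonal vasculature retains a slow-draining drug reservoir in the
  poorly vascularized zones: tumor-average intracellular drug falls to ~2 %
  of its peak 5 h post-injection and below 1 % by about 6 h, so "complete"
  washout statements hold on a ±1 h timescale.
* The thermal response functions are minimal monotone ramps through their
  anchors; mechanistic endothelial-gap or thermotolerance models are out of
  scope, as is multi-session scheduling.
* All results are desk-scale model outcomes under literature-typical
  parameters; passing the test suite shows internal consistency and
  agreement with the anchor behaviors, not predictive validity for any
  specific tumor.
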