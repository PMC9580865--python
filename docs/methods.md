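# Methods

## Model structure

The simulator couples two submodels.

**Membrane diffusion.** Oxygen flow across the blood–gas barrier obeys
Fick's law, ν = DM_O₂ · ΔpO₂ with DM_O₂ = K_O₂ · s/τ. The permeation
coefficient K_O₂ = 5.504 × 10⁻¹⁴ ml O₂ s⁻¹ mmHg⁻¹ μm⁻¹ (per μm² of
surface) is the package's one calibrated constant: it is fixed so that
the default morphology (s = 121,000 μm², τ = 1.11 μm) yields
DM_O₂ = 6 × 10⁻⁹ ml/(s·mmHg) per alveolus, equivalent to the classical
morphometric Krogh coefficient of ≈3.3 × 10⁻⁸ cm² min⁻¹ mmHg⁻¹. Every
other reported quantity is then an independent consequence of the
model.

**Hemoglobin binding.** Saturation is a Hill function of pO₂ with
midpoint p50 and cooperativity nH. Both follow the published
Dash–Korman–Bassingthwaighte forms: nH(pO₂) = 2.82 − 1.20·10^(−pO₂/29.25),
and p50 equal to 26.8 mmHg at standard erythrocyte conditions
(pCO₂ 40 mmHg, 37 °C, pH_rbc 7.24, 2,3-DPG 4.65 mM), shifted by four
polynomial factors in the deviations of pCO₂, temperature, pH_rbc and
DPG, combined multiplicatively. Each factor is exactly p50 at the
standard point, so the shift machinery is an identity there. Blood O₂
content combines dissolved O₂ (solubility 3.1 × 10⁻⁵ ml O₂ ml⁻¹ mmHg⁻¹)
with Hb-bound O₂ (capacity 0.201 ml O₂/ml blood, i.e. 1.34 ml/g ×
150 g/L); both constants are package conventions exposed on
`BindingParameters`. The Hill coefficient is evaluated at each
section's local pO₂; evaluating it at a fixed reference pO₂ instead
changes the reaction half-time by under 3 % (sensitivity checked during
development), so the choice is not load-bearing.

## Capillary discretization and update scheme

The capillary (L = 500 μm) is split into n equal sections (default
n = 100). A parcel advances in its own frame with Δt = L/(n·v). Per
section, O₂ is transferred first:

    transferred = (DM_eff/n) · (pA_O₂ − pO₂) · Δt,

added to the parcel's O₂ content, and the new pO₂ is recovered by
bracketed root finding (Brent) on the strictly monotone content
function (round-trip error < 10⁻⁶ mmHg). Then CO₂: the respiratory
exchange ratio (0.82, mixed diet) converts the O₂ gain into a CO₂ loss,
which lowers pCO₂ through a linear CO₂ capacitance and thereby
left-shifts p50 for the next section (Bohr feedback). Computing CO₂
before O₂ instead shifts results by less than the discretization error
at n = 100.

The content is carried forward exactly (each new state's content is the
previous plus the transfer), so the conservation identity — total
uptake equals the sum of section fluxes — holds to machine precision,
not just to solver tolerance. The explicit step is protected by an
equilibrium clamp: a section transfer cannot carry the blood past the
content it would have in equilibrium with alveolar gas. The clamp is
inactive in all physiological regimes (at defaults the shortest local
relaxation time is ≈23 ms against a 5 ms step) and engages only when
the residence time far exceeds the relaxation time (e.g. velocity
0.01 mm/s), where the physical answer is equilibrium.

Alveolar gas tensions are held fixed — ventilation is treated as
instantaneous replenishment, and breathing patterns are out of scope —
so one pass is the steady state, and instance time-stepping
(`SimulationInstance.advance`) integrates a stationary uptake rate
between parameter changes (piecewise-linear cumulative uptake).

## Recruitment semantics

Capillary recruitment is represented by the perfused blood volume V_b
(default 404,000 μm³ = 50 % of the 808,000 μm³ bed). Two consequences
follow from the geometry of recruitment, i.e. from whole capillaries
being open or closed:

1. Only the membrane overlying perfused capillaries exchanges gas:
   the flux coefficient in the solver is DM_eff = DM_O₂ × recruitment.
   The *reported* DM_O₂ remains K_O₂·s/τ — the conductance of the whole
   exposed surface, which is what morphometric estimates measure.
2. Per-parcel oxygenation kinetics are recruitment-independent (each
   parcel sees its own wall): the relaxation rate DM_eff/(V_b·β) does
   not contain the recruitment fraction.

An alternative convention — full DM_O₂ acting on the perfused volume —
was rejected because conservation then forces D_LO₂ ≡ DM_O₂
independent of recruitment (see below), contradicting the basic
physiology that diffusing capacity rises with recruitment and
destroying the 50 %/50 % peak of the antiparallel sweep.

## Diffusing capacity

D_LO₂ = V̇O₂ / mean(ΔpO₂), scaled by 480 × 10⁶ alveoli and reported in
ml/(mmHg·min). The mean gradient is the arithmetic mean over the equal-
time sections of (alveolar pO₂ − section pO₂), taken at the entry
states the fluxes were computed from. Because V̇O₂ is exactly the sum
of the section fluxes (DM_eff/n)·Δp_i, this definition collapses to the
identity D_LO₂ = DM_eff per alveolus — independent of the binding
model, the carriage constants and the section count. It is therefore
exactly reproducible and converges trivially, but it also means D_LO₂
here is a conductance, not a flow-limited quantity: at the default
configuration it evaluates to 86.4 ml/(mmHg·min) and at full exposure/
recruitment to 295.6 ml/(mmHg·min). A logarithmic-mean variant
(`mean_pressure_gradient(..., "log")`) is provided for comparison but
is numerically fragile once the profile equilibrates (the outlet
gradient underflows), which is why it is not the default.

The blood-flow reconstruction interprets whole-lung blood flow Q as a
per-alveolus blood volume V_b = (Q/N)·L/v at a constant velocity of
1.5 mm/s, capped at the maximal bed volume (the bed cannot recruit
beyond 100 %).

## Parameters

| Parameter | Default | Range | Unit |
|---|---|---|---|
| alveolar pO₂ / pCO₂ | 100 / 40 | 1–150 | mmHg |
| inflowing blood pO₂ / pCO₂ | 40 / 45 | 1–150 | mmHg |
| surface area | 121,000 (58 % exposure) | 0–210,000 | μm² |
| barrier thickness | 1.11 | 0.1–3.0 | μm |
| blood flow velocity | 1 | 0.01–2 | mm/s |
| blood volume | 404,000 (50 % recruitment) | 1–808,000 | μm³ |
| blood temperature | 37 | 20–44 | °C |
| erythrocyte pH | 7.24 | 5.8–8.2 | — |
| 2,3-DPG | 4.65 | 1–10 | mM |
| capillary length / bed volume / radius | 500 / 808,000 / 3.15 | fixed | μm / μm³ / μm |

Defaults describe a healthy resting alveolus; ranges bound the
empirical validity of the binding submodel, and out-of-range inputs
raise rather than extrapolate. A blood volume of exactly zero is
accepted as the no-perfusion limit (zero uptake, D_LO₂ = 0).

The CO₂ capacitance defaults to 8 × 10⁻³ ml CO₂ ml⁻¹ mmHg⁻¹, the slope
of the whole-blood CO₂ dissociation curve between the venous
(45 mmHg) and arterial (40 mmHg) points (~0.8 ml/dl/mmHg). With it,
the RER-coupled CO₂ loss takes the outlet pCO₂ from 45 to ≈39.9 mmHg —
consistent with the boundary values, since an RER of 0.82 with these
O₂ and CO₂ gradients is what makes them mutually compatible. Because
CO₂ is bookkept through the RER rather than driven by its own
gradient, a non-physiological capacitance can push pCO₂ below the
alveolar value; the 0.1 mmHg residual undershoot at the default is the
visible trace of that simplification.

Pathology presets encode only shift *directions* established for each
condition (e.g. fibrosis: barrier ↑, alveolar pCO₂ ↓); the magnitudes —
30 % for a single-arrow shift, 80 % for a double arrow, +2 °C for fever
— are package conventions, clamped to the parameter ranges and
overridable. The traffic-light classifier's bands (healthy within 10 %
of default, absolute ±1 °C and ±0.1 pH; pathological outside the middle
50 % of the range) are likewise conventions for display, not clinical
thresholds.

## Numerical choices and problem sizes

- n = 100 sections by default; outlet pO₂ and uptake change by < 10⁻⁶ %
  between n = 100 and 200 at defaults, and D_LO₂ is n-invariant by the
  identity above. Tests and the acceptance script use n = 100–400.
- Content inversion: Brent on [0, 2000] mmHg, xtol 10⁻⁹.
- Half-time: linear interpolation of the saturation series at the
  midpoint between entry and outlet saturation (the published midpoint
  convention: 89 % between 81 % and 97 %). On a synthetic exponential
  trajectory the estimator recovers τ·ln 2 to < 1 % with ≥ 100 samples.
- No randomness anywhere: identical inputs give bit-identical outputs,
  asserted by a double-run byte comparison.

## Limitations

- No axial diffusion between sections, no pulsatile flow, no discrete
  erythrocytes: blood is a homogeneous plasma/Hb mixture in plug flow.
- CO₂ has no independent transport physics (no bicarbonate/carbamino
  speciation, no Haldane effect); it exists only as RER bookkeeping and
  as the Bohr input to p50.
- Alveolar composition is fixed; breathing dynamics and multi-alveolus
  ventilation/perfusion heterogeneity are out of scope.
- D_LO₂ follows the conductance identity described above; in strongly
  flow-limited regimes (very low velocity) the arithmetic-mean
  definition and the clamp make it an upper bound rather than a
  flow-limited estimate, and no claims are made there.
- The oxygenation half-time is computed for capillaries only;
  precapillary oxygenation, which in vivo lengthens apparent
  half-times, is not modeled.
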