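# alvgas

A scriptable, deterministic simulator of gas exchange in a single human
alveolus, with spatial and temporal resolution along the alveolar
capillary.

## The problem

The alveolus is the smallest functional unit of the lung: a thin-walled
air sac wrapped in a net of about 52 capillaries through which venous
blood transits in roughly half a second. Whether that transit suffices
to oxygenate the blood depends on morphology (exchange surface, barrier
thickness), perfusion (blood volume and velocity) and blood chemistry
(the hemoglobin dissociation curve and its Bohr shifts). `alvgas` models
the full chain — membrane diffusion into a discretized capillary coupled
to hemoglobin binding — and derives the physiological summary numbers
from it: the membrane diffusing capacity DMO₂, the reaction half-time of
capillary oxygenation, and the pulmonary diffusing capacity D_LO₂ as a
function of alveolar surface exposure and capillary recruitment. It is
aimed at physiology teaching and at plausibility-checking published
diffusing-capacity estimates.

## The model

Oxygen crosses the tissue barrier by Fick's law. For exchange surface
*s* and barrier thickness *τ*,

    ν = DM_O₂ · ΔpO₂,      DM_O₂ = K_O₂ · s / τ,

with K_O₂ the Krogh-type permeation coefficient of the barrier. The
capillary is divided into *n* equal sections; a blood parcel is updated
section by section, receiving oxygen from its section's membrane share
during its residence time, so one pass is simultaneously the
steady-state spatial profile and the time course of a parcel. Only the
membrane overlying perfused capillaries exchanges gas, so the flux
coefficient is DM_O₂ times the recruitment fraction. CO₂ leaves the
blood in fixed proportion to the O₂ taken up (respiratory exchange
ratio 0.82) and feeds back on the O₂ affinity via the Bohr effect.

Hemoglobin saturation follows a Hill law,

    S_HbO₂ = (pO₂/p50)^nH / (1 + (pO₂/p50)^nH),

with a pO₂-dependent Hill coefficient nH and a p50 shifted from its
standard 26.8 mmHg by blood pCO₂, temperature, erythrocyte pH and
2,3-DPG (the published Dash–Korman–Bassingthwaighte polynomial forms).
The pulmonary diffusing capacity is

    D_LO₂ = V̇O₂ / mean(ΔpO₂),

the steady oxygen uptake divided by the mean alveolar–capillary pressure
gradient, extrapolated to the whole lung (480 × 10⁶ alveoli).

## Worked example

```bash
$ alvgas halftime
half-time 0.0494 s  (saturation 0.809 -> 0.974, midpoint 0.891)
```

Deoxygenated blood entering at pO₂ 46 mmHg under an alveolar pO₂ of
97 mmHg starts at 81 % saturation and equilibrates at 97 %; half of that
oxygenation is complete after ~49 ms — about a tenth of the 0.5 s
transit time, which is why a healthy lung has so much transit-time
reserve.

```bash
$ alvgas dlo2 --exposure 1.0 --recruitment 1.0
VO2 7.988e-08 ml O2/s per alveolus; mean gradient 7.782 mmHg; D_LO2 295.6 ml/(mmHg x min) whole lung

$ alvgas simulate --sections 100 --check-determinism
outlet pO2 100.00 mmHg, saturation 0.9762, uptake 3.994e-08 ml O2/s
```

The first command evaluates a fully expanded, fully recruited alveolus;
the second writes the default steady-state profile (pO₂, pCO₂,
saturation and flux per section) to `profile.csv` and verifies that a
repeated run is byte-identical. Other subcommands: `curves`
(dissociation-curve families), `sweep` (D_LO₂ over the surface-exposure
× recruitment plane; the antiparallel combination peaks at 50 %/50 %),
`presets` (pathology parameter sets such as pulmonary fibrosis) and
`compare` (several configurations side by side). Python API mirrors the
CLI: see `alvgas.solve_profile`, `alvgas.diffusing_capacity`,
`alvgas.sweep`.

Configuration files are flat JSON/YAML maps of parameter names
(`alvgas presets --name pneumonia` emits one); unknown keys are
rejected, missing keys take the healthy defaults.

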