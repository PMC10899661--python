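# Methods

`tiltsim` simulates the acute response of the systemic circulation, the
cerebrovascular bed, and the eye to tilt-table maneuvers between head-up
tilt (HUT) and head-down tilt (HDT). This note documents the model, its
assumptions, the parameters that matter, the numerical choices, and the
limits of what the simulations show.

## Model architecture

The closed loop combines:

* **Heart and pulmonary circulation.** Four time-varying elastance
  chambers with cosine activation (ventricular systole scales with the
  square root of the beat period; atrial systole precedes ventricular
  onset by 0.12 s). Ventricular pressure blends an end-systolic law
  `E_max (V - V0)` with an end-diastolic law
  `E_min (V - V0) + k_dia (V - V0)^3`; the cubic stiffening caps the
  Frank–Starling response when head-down filling rises. Valves are
  rectified resistances. All cardio-pulmonary compartments feel the
  intrathoracic pressure ITP(α) = ITP_supine + (ITP_upright −
  ITP_supine)·sin α (−4 mmHg supine, −6.5 mmHg upright).

* **Arterial tree.** 63 tapered vessels (packaged CSV table: name,
  parent, lengths, radii, reference wave speed, elevation gain,
  terminal bed). Two interchangeable representations:
  * *1D mode*: cross-sectionally averaged mass/momentum balance with the
    elastic tube law `p = p_d + β/A0 (√A − √A0)` (β = 2ρc0²√A0), a
    visco-elastic rate term handled as an operator-split diffusion on Q,
    Poiseuille-profile friction, and the gravity source
    `−g A (dz/dx) sin α`. MacCormack predictor–corrector (2nd order),
    Riemann-invariant boundary treatment (W = u ± 4c), Newton junction
    coupling enforcing mass and total-pressure continuity, and
    characteristic-impedance terminals Q = (p − p_0D)/Zc.
  * *Reduced mode* (default): each vessel collapses to one R–L–C segment
    preserving the resistance, inertance and compliance integrals and the
    elevation gain. The full protocol then runs in about half a minute.
    An equivalence test drives both representations of an
    aorta–carotid–ICA path with identical inflow and terminal loads and
    requires beat-mean ICA pressure agreement within 5%.

* **Regional beds.** Six 0D beds (extra-cerebral head, arms, coronary,
  upper and lower abdomen, legs), each arterioles → capillaries/venules →
  veins → vena cava, with venous valves in arms and legs and effective
  elevations for the hydrostatic columns. Flows between compartments use
  piezometric differences `Δ(p + ρg z sin α)/R`.

* **Cerebrovascular bed.** ICA siphon and basilar inlet nodes feed a
  lumped circle of Willis (MCA/ACA/PCA per side, communicating arteries),
  six pial territories whose resistances and compliances are under
  autoregulation and CO2 reactivity, one capillary node, a nonlinear
  cerebral venous compartment (compliance inversely related to its
  transmural pressure), and a Starling-resistor (vascular waterfall)
  outflow: Q = (p_cv − max(ICP, p_dvs))/R_vs. The waterfall is essential:
  it makes cerebral perfusion effectively driven by p_ICA − ICP, which is
  what allows CBF to *rise* slightly at HDT even though the piezometric
  arterial-to-sinus gradient shrinks.

* **CSF and ICP.** A single craniospinal CSF volume state. ICP solves

      V_cranial(ICP) + C_sp · (ICP + col_sp · sin α) = V_stored,

  where the cranial store has the monoexponential elastance
  dV/dICP = 1/(k_E (ICP − p_0)) (Monro–Kellie: intracranial vascular
  volume is part of the cranial contents) and the spinal dural sac is a
  linear compliance whose local pressure carries the head-to-lumbar CSF
  column (0.55 m). Tilting therefore redistributes CSF between skull and
  sac at constant volume — this is the mechanism behind the ~+11 mmHg ICP
  rise at HDT, and it is exactly reversible on return to HUT. The
  redistribution follows posture with a 12 s first-order lag (resistive
  CSF pathway). CSF formation (capillaries → CSF) and absorption
  (CSF → dural sinus) are rectified and deliberately slow
  (R_f = 6.7·10⁴, R_o = 4.7·10⁴ mmHg s/ml), so the 10-minute HDT response
  is redistribution-dominated; the model's CSF turnover is far below
  textbook rates, a trade made so that the posture response and its
  reversibility match the acute observations.

* **Eye.** Per eye (two symmetric eyes share the state; boundary flows
  are doubled): ocular arterial, choroid/capillary and ocular venous
  compartments referenced to IOP, an aqueous chamber, a Friedenwald-type
  exponential globe envelope IOP = p_orbit + IOP_ref·exp(k_w (V_g −
  V_ref)) with rigidity k_w = 46 ml⁻¹ (a ~5 µl volume change moves IOP by
  ~4 mmHg — the globe is nearly isovolumetric), and a retrobulbar
  interface through which a fraction (0.15) of ICP loads the globe.
  Aqueous inflow is constant secretion plus rectified ultrafiltration;
  outflow is trabecular (against episcleral venous pressure = eye venous
  pressure + 7 mmHg) plus uveoscleral (against the orbit). The eye
  arterial boundary is the ICA pressure minus the hydrostatic offset of
  the globe: an axial part (sin α) plus the anterior offset from the
  mid-coronal plane (2.86 cm, cos α) — this is why eye-level arterial
  pressure rises *less* than ICA pressure when tilting toward horizontal.
  The eye venous boundary drains through a node whose effective elevation
  is near heart level, emulating the collapse-limited jugular pathway
  upright.

* **Autonomic control.** Arterial baroreflex (afferent: carotid-sinus
  *local* pressure, which includes the heart-to-sinus column, so posture
  changes the sensed pressure at identical aortic pressure) and
  cardiopulmonary reflex (right-atrial transmural pressure). A shared
  sympathetic drive from two tanh afferents moves heart period,
  ventricular contractility, arteriolar resistance and venous unstressed
  volume through first-order effector dynamics; heart rate changes apply
  only at beat boundaries.

## Posture

The tilt angle α is measured from the horizontal (+80° = 80° HUT,
−6° = 6° HDT); protocols are piecewise dwells joined by linear ramps
(default 15 s — tilt-table speed is a free choice; steady-state
comparisons are insensitive to it). Gravity enters through (i) the
hydrostatic columns between connected compartments, (ii) ITP(α),
(iii) the craniospinal redistribution term, and (iv) the eye-level
offsets. Compartment elevations are *effective* lumped values calibrated
against the cited physiological operating points (e.g. the superior vena
cava centroid at 0.035 m encodes jugular collapse upright; the
intracranial nodes at 0.345 m carry the ~27 mmHg heart-to-ICA column at
80° HUT; the dural sinus sits one 13.5 cm column above the cava).

## Calibration

The subject is a generic healthy 25-year-old male (75 kg, 175 cm). The
cerebral resistance ladder is calibrated algebraically at the 80° HUT
operating point (ICA 65.8, MCA 63.4, distal 36.5, capillary 14.4, venous
4.2, sinus −10.8 mmHg at CBF 11.63 ml/s); reflex set-points are centered
at the same operating point so the pre-tilt state is the controlled
equilibrium. Autoregulation gains are set so a sustained ~+7% CBF error
produces about +13% distal resistance and −17% distal compliance.
Aqueous outflow resistances are set by requiring the IOP flux balance at
both postures (trabecular facility ≈ 0.45 µl/min/mmHg equivalent,
uveoscleral/trabecular ratio 0.85, net turnover ≈ 9 µl/min for the
doubled eye — higher than textbook secretion, the price of an aqueous
time constant of ~4 min so the 10-minute dwell reaches steady state).
Total blood volume (5260 ml) sets CVP; the global arteriolar scale sets
systemic resistance.

## Numerics

* Reduced closed loop: 189 states, fixed-step RK4 at dt = 0.25 ms
  (stability is set by the fastest R·C products, ~0.5 ms), compiled with
  numba; output resampled at 200 Hz; the beat clock quantizes heart-rate
  updates at beat onsets. Blood volume is conserved to machine precision
  by construction (every flow moves volume between two compartments).
* Initialization: analytic starting point at the protocol's first angle
  followed by a settling phase; the run errors out if the beat-mean
  aortic drift has not fallen below 0.05 mmHg/beat within 300 beats.
  Runs are deterministic: identical configurations give bitwise-identical
  outputs.
* 1D solver: Δx = 2.5 mm default, CFL ≤ 0.9 with the visco-elastic
  diffusion limit included; junction Newton tolerance 1e-11. The interior
  update conserves mass to round-off per step; the characteristic
  boundary updates leak ~5·10⁻⁵ of network volume per pulse transit
  (tested), which is why global conservation statements are made on the
  0D loop.
* The ICP Newton solve (monotone scalar function) converges in a few
  iterations; the compliance law raises an error outside its validity
  range, as do negative compartment volumes.
* Closed-loop 1D co-simulation (`--mode 1d`) advances the 1D tree and the
  0D remainder with a shared step (clamped to the network CFL limit);
  a full protocol at 1D resolution is far beyond desk scale (hours) and
  is intended for short verification horizons.

## Problem sizes used in the shipped analyses

The default protocol is 300 s at 80° HUT, 600 s at 6° HDT, and 900 s back
at 80° HUT (the long return dwell lets the slow ocular/CSF states settle
for the reversibility check), preceded by a 240 s settling phase. Steady
metrics average the final 10 beats of a 60 s window at each dwell end.
The acceptance script runs exactly this configuration.

## What the tests do and do not show

The test suite verifies: conservation, determinism, the analytic oracles
(Poiseuille drop, Moens–Korteweg transit, craniospinal elastance
exponential, RC relaxation), the autoregulation plateau and its absence
when disabled, the static hydrostatic columns, monotone
proximal-to-distal amplification of mean and pulse pressure changes,
pre/post-return equality, and the headline operating points within the
±15%-or-2 mmHg band. They do not validate against raw subject data, and
several quantities are reproduced only qualitatively:

* Pulse pressures at individual cerebral sites are less quantitatively
  calibrated than the means (the reduced tree's reflection pattern
  differs from a full 1D tree); their directions and the distal
  amplification trend are correct.
* The stroke-volume rise at HDT (~+10%) is smaller than measured
  (~+30%); the direction and the HR/CO/MAP directions are correct. The
  diastolic stiffening that keeps pre-tilt stroke volume physiological
  also limits the head-down rise.
* The CBF overshoot peak reaches +18% versus the reported +35%
  (within the study's own ±15% band); autoregulation engages during the
  ramp and caps the transient.

## Known limitations

No gas transport or CO2 forcing during protocols (PaCO2 held at 40 mmHg;
the reactivity pathway itself is implemented and tested), no long-term
renal/hormonal volume control or capillary filtration, no tissue-weight
effects, no true-microgravity CVP behaviour (head-down tilt raises CVP
here, as on a tilt table), and no optic-nerve or globe-wall remodeling —
the model addresses the acute (minutes) response only.
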