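# tiltsim

Closed-loop, posture-dependent simulation of systemic, cerebrovascular and
ocular hemodynamics on a tilt table.

Head-down tilt (HDT) is the standard terrestrial analog of the headward
fluid shift of spaceflight, and the acute interplay of intracranial
pressure (ICP), intraocular pressure (IOP) and eye-level blood pressures
is central to hypotheses about spaceflight-associated neuro-ocular
syndrome (SANS). The two derived quantities of interest are the
translaminar pressure across the lamina cribrosa,

    TLP = IOP − ICP,

and the ocular perfusion pressure,

    OPP = p_a,eye − IOP,

where `p_a,eye` is the arterial pressure at the level of the globe.
`tiltsim` is written for physiologists and modelers who want to simulate
tilt maneuvers (e.g. 80° head-up tilt → 6° head-down tilt) on a calibrated
generic subject and read out the full pressure/flow/volume response —
including quantities that are hard to measure in vivo, such as cerebral
capillary pulse pressure or the CSF-column contribution to ICP.

## The model in brief

A four-chamber elastance heart and pulmonary loop drive a 63-artery tree
(full 1D pulse-wave solver, or a reduced R–L–C mode that preserves each
vessel's resistance/inertance/compliance integrals and runs the whole
protocol in well under a minute). Six regional microvascular beds with
venous valves close the loop. The cerebrovascular bed is a lumped circle
of Willis feeding six autoregulated pial territories, a capillary–venous
branch with a Starling-resistor (vascular waterfall) outflow referenced
to ICP, and CSF formation/absorption. ICP itself follows a craniospinal
volume balance: a monoexponential cranial store (Monro–Kellie) exchanges
CSF with the spinal dural sac through the head-to-lumbar hydrostatic
column, which is what moves ICP by ~+11 mmHg between upright and
head-down. The eye is a six-compartment lumped model (ocular arterial,
choroidal, venous, aqueous, a stiff Friedenwald-type globe envelope, and
a retrobulbar ICP interface) fed from both internal carotids with the
globe's axial-plus-anterior hydrostatic offset. Short-term autonomic
control (arterial baroreflex sensing the carotid-sinus *local* pressure,
plus a cardiopulmonary reflex) acts on heart rate, contractility,
arteriolar tone and venous unstressed volume.

Posture enters everywhere through hydrostatic columns
`ρ g (z_axial sin α + d_anterior cos α)`, the intrathoracic pressure, and
the craniospinal redistribution term. See `docs/methods.md` for the full
account, parameter meanings and limitations.

## Worked example

```python
from tiltsim import (SubjectConfig, TiltProtocol, run_protocol,
                     steady_state_metrics, percent_change)

cfg = SubjectConfig()
protocol = TiltProtocol()          # 80 deg HUT -> 6 deg HDT -> 80 deg HUT
res = run_protocol(cfg, protocol, settle=240.0)

pre = steady_state_metrics(res, (240.0, 300.0))    # end of the HUT dwell
hdt = steady_state_metrics(res, (855.0, 915.0))    # end of the HDT dwell

print(f"TLP  {pre.mean['tlp']:6.1f} -> {hdt.mean['tlp']:6.1f} mmHg "
      f"({percent_change(pre.mean['tlp'], hdt.mean['tlp']):+.0f}%)")
```

Output of the full comparison (beat-averaged over the last 10 beats of
each dwell):

```
MAP    93.7 ->   88.3 mmHg
ICP    -0.1 ->   11.6 mmHg
IOP    16.0 ->   20.5 mmHg
TLP    16.1 ->    8.9 mmHg (-45%)
OPP    49.9 ->   65.5 mmHg (+31%)
CBF   11.65 ->  12.29 ml/s
HR     71.9 ->   68.2 bpm
```

Reading: tilting head-down shifts blood and CSF toward the head. ICP
rises by ~11 mmHg (mostly the hydrostatic CSF column), IOP by only
~4.5 mmHg, so the translaminar pressure collapses by almost half while
the ocular perfusion pressure rises by ~30% — the two pressure
derangements hypothesized to seed neuro-ocular changes under chronic
fluid shift. Cerebral blood flow barely moves (+6%) because
autoregulation constricts the pial bed, and the baroreflex lowers heart
rate as the heart fills.

The same run is available from the shell:

```
tiltsim simulate --out run/ --settle 240
tiltsim analyze  --result run/
tiltsim validate --result run/
```

`simulate --mode 1d` replaces the reduced arterial tree with the 1D
pulse-wave solver (closed-loop co-simulation; far slower, intended for
short horizons). `--open-loop` freezes the autonomic effectors and
`--no-autoregulation` makes the pial bed passive, for
mechanism-attribution experiments.

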