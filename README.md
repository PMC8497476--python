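# railpattern

Design rules and quasi-static simulation for **aspiration-mediated hydrogel
patterning in rail-based open microfluidic devices**.

In these devices a 3D-printed structure of *high rails* (HR, gap height `H`)
and surrounding *low rails* (LR, gap height `h`) stands above a transparent
adhesive film. A hydrogel precursor overfills the whole footprint; a single
suction through one port then removes liquid **only from under the high
rails**, leaving hollow microchannels flanked by hydrogel pinned under the low
rails — the geometry does the patterning, not the operator's pipetting skill.
This package is for people designing such devices (organ-on-chip and 3D
co-culture platforms): it predicts whether a geometry patterns successfully,
which aspiration pressures are safe, and in which order multiple channels
form.

## The model

Each pinned gas–liquid interface withstands a critical capillary pressure
(Young–Laplace at the receding contact angle θ_R,c ≈ 0):

| interface | critical pressure |
|---|---|
| open port, diameter `D` | Δp_O = 4γ/D |
| side meniscus under a low rail, gap `h` | Δp_L = 2γ·cosθ_R,c/h (+ γ/η optional) |
| lane meniscus under a high rail, gap `H`, width `w_H` | Δp_H = 2γ(1/w_H + 1/H) |

Patterning succeeds iff the low rail out-pins everything, i.e. Δp_L is the
largest of the three; Δp_O vs Δp_H only decides whether the lane clears
continuously or stepwise. Since all pressures are linear in the surface
tension γ, the classification is **fluid-independent**, with closed-form
design boundaries

* `D = 2h` — the port must burst before the low rail, and
* `H = h·w_H/(w_H − h)` — the lane interface must be weaker than the low-rail
  meniscus.

A lane clears at suction `max(Δp_O, Δp_H)`; the **safe aspiration window** is
`(max(Δp_O, Δp_H), Δp_L)`. In multi-lane devices the liquid body under the
footprint is continuous, so lanes clear in ascending threshold order —
i.e. from the largest opposing port to the smallest — which makes the
formation *order* a design parameter. A non-aspiration lane with two
equal-diameter ports admits air from both ends and traps a liquid film that
does not rupture at modelled pressures.

Two conventions for Δp_H ship behind a flag: the two-interface `FACTOR2` form
above (default; consistent with the `H = h/(1−h)` boundary) and a
`SINGLE_INTERFACE` form γ(1/w_H + 1/H) that matches the widely quoted worked
value of 311.9 Pa. See `docs/methods.md`.

## Worked example

```python
import railpattern as rp

water = rp.get_fluid("water_numeric")           # γ = 71.97 mN/m
device = rp.make_basic_device(600, 100, 300, 1000, 5000)  # D,h,H,w,l in μm

single = rp.PressureModelOptions(hr_convention=rp.HRConvention.SINGLE_INTERFACE)
ps = rp.critical_pressures(device, water, single)
print(ps.dp_open, ps.dp_low, ps.dp_high)
```

prints `479.80 1439.4 311.87` (Pa): the port bursts at 479.8 Pa, the lane
interface at 311.9 Pa, and the low rail holds until 1439 Pa, so any suction
between the lane threshold and 1439 Pa empties the channel while the hydrogel
stays pinned under the low rails. Running `python examples/design_rules.py`
continues:

```
outcome: SUCCESS_STEPWISE  (success=True)
safe aspiration window: 623.7 .. 1439.4 Pa
boundary port diameter D* = 200 um (D = 2h)
boundary high rail    H* = 111.1 um (H = h*w/(w-h))
```

and `python examples/multi_channel.py` simulates the three-lane S/N/U replica
(clearing order `['S', 'N', 'U']`, largest opposing port first, aspiration
lane last) and a 98-lane array cleared by one aspiration with zero low-rail
invasions. `examples/phase_diagram_sweep.py` and `examples/uniformity_demo.py`
cover the design-map sweep and the mean-deviation uniformity statistic
`U = [1 − (Max − Min)/(2·Avg)] × 100 %`.

A thin CLI wraps the same functions:

```bash
railpattern synth device --preset snu --out snu.json
railpattern classify snu.json --lane S
railpattern simulate snu.json --pressure 1500
railpattern phase-diagram D_vs_h --out pd.csv --figure pd.png
```

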