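"""Critical pressures and design-rule classification of one device.

Builds the reference single-lane device (D=600 μm port, h=100 μm low
rail, H=300 μm high rail, 1 mm wide, 5 mm long), evaluates the three
critical capillary pressures for water, classifies the patterning
outcome, and reports the safe aspiration window.
"""

import railpattern as rp

water = rp.get_fluid("water_numeric")
device = rp.make_basic_device(600, 100, 300, 1000, 5000)
assert rp.validate_device(device) == []

single = rp.PressureModelOptions(hr_convention=rp.HRConvention.SINGLE_INTERFACE)
ps = rp.critical_pressures(device, water, single)
print(f"open port   dp_O = {ps.dp_open:7.1f} Pa   (4*gamma/D)")
print(f"low rail    dp_L = {ps.dp_low:7.1f} Pa   (2*gamma/h)")
print(f"high rail   dp_H = {ps.dp_high:7.1f} Pa   (gamma*(1/w+1/H), single-interface)")

ps2 = rp.critical_pressures(device, water)  # default two-interface convention
outcome = rp.classify_outcome(ps2)
window = rp.safe_aspiration_window(ps2)
print(f"\noutcome: {outcome.value}  (success={outcome.is_success})")
print(f"safe aspiration window: {window[0]:.1f} .. {window[1]:.1f} Pa")
print(
    "\nAny suction inside the window empties the lane under the high rail\n"
    "while the low-rail meniscus stays pinned; above the upper bound the\n"
    "hydrogel under the low rail is removed too and patterning fails."
)

# the two closed-form design boundaries for this low rail
h = 100e-6
print(f"\nboundary port diameter D* = {rp.boundary_port_diameter(h)*1e6:.0f} um (D = 2h)")
print(f"boundary high rail    H* = {rp.boundary_high_rail(h, 1e-3)*1e6:.1f} um (H = h*w/(w-h))")
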