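"""Ordered formation of multiple channels from a single aspiration.

Replicates the three-lane S/N/U device (opposing port diameters
strictly decreasing, aspiration on the smallest-port lane) and a
98-lane array.  Because the liquid body under the footprint is
continuous, one suction lowers the pressure everywhere; interfaces
burst at the largest opposing port first, so lanes clear in descending
port-diameter order and the aspiration lane clears last.
"""

import railpattern as rp
from railpattern.simulate import EventType

water = rp.get_fluid("water_numeric")

snu = rp.preset_device("snu")
print("three-lane device, predicted clearing order:",
      rp.predicted_clearing_order(snu, water))
res = rp.simulate_aspiration(snu, water, rp.SimulationConfig(applied_suction=1500.0))
for e in res.events:
    print(f"  {e.order_index}: {e.event_type.value:<12} {e.location_id:<8} at {e.threshold:7.1f} Pa")
print(f"  success={res.success}, retained: {sorted(res.retained_regions)}")

array98 = rp.preset_device("array98")
res98 = rp.simulate_aspiration(array98, water, rp.SimulationConfig(applied_suction=1300.0))
order = [e.location_id for e in res98.events if e.event_type is EventType.LANE_CLEARED]
print(f"\n98-lane array: {len(res98.cleared_lanes)} channels cleared by one aspiration,")
print(f"  first lane {order[0]} (largest opposing port), last lane {order[-1]} "
      f"(the aspiration lane: its opposing hole is smallest), "
      f"low-rail invasion: {'LR_INVASION' in res98.warnings}")
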