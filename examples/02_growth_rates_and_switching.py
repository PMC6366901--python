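"""Estimate microcolony growth rates and detect a growth-rate switch.

The growth rate is the maximum slope of ln(area) over all 3-timepoint
windows with R^2 >= 0.9, which ignores lag phases and late slowdowns.
A colony whose pointwise rate drops from fast to slow for long enough is
classified as switching.
"""

import numpy as np

from microhet import growth
from microhet.growth import SwitchConfig
from microhet.imaging import ColonyTrack

t = np.arange(9) * 1.5
# colony with a 3 h lag, then clean exponential growth at 0.4 1/h
areas = np.where(t < 3.0, 120.0, 120.0 * np.exp(0.4 * (t - 3.0)))
track = ColonyTrack(colony_id=0, frames=list(range(9)), times=list(t),
                    areas=list(areas), centroids=[(0, 0)] * 9)
est = growth.estimate_growth_rate(track)
print(f"lagging colony: rate {est.rate:.3f} 1/h "
      f"(window starting at frame {est.window_start_index}, R^2 {est.r_squared:.3f})")
# The max-window rule reports 0.400 despite the flat lag prefix.

# a colony that switches from fast to slow growth mid-observation
areas2 = np.concatenate([100 * np.exp(0.40 * t[:5]),
                         100 * np.exp(0.40 * t[4]) * np.exp(0.05 * (t[5:] - t[4]))])
track2 = ColonyTrack(colony_id=1, frames=list(range(9)), times=list(t),
                     areas=list(areas2), centroids=[(0, 0)] * 9)
series = growth.pointwise_growth_rates(track2)
print("pointwise rates:", np.round(series, 3))
call = growth.classify_switching(series,
                                 SwitchConfig(c1=0.15, c2=0.3, run_length=2,
                                              edge_exclusion=2))
print(f"switch call: {call.direction} at frame {call.switch_index}")
# fast_to_slow with the switch frame outside the final exclusion window.

print("survivor at 0.05 1/h:", growth.survival_call(0.05))
print("survivor at 0.02 1/h:", growth.survival_call(0.02))
# The survival cutoff is strict: exactly 0.02 1/h is a non-survivor.
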