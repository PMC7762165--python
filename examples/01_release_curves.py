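"""Evaluate the one- and two-phase release models for a swelling disc.

Builds the reference kinetics of a 5-mm bacterial-cellulose hydrogel disc
(asymptotic swelling ratio 2) and prints hourly fractional release under a
single effective diffusivity versus the two-phase schedule that switches
from a slow pre-swollen coefficient to a faster swollen one at tc = 2 h.
"""

import numpy as np

from swellrelease import (
    OnePhaseParams,
    SwellingParams,
    TwoPhaseParams,
    logistic_radius,
    release_one_phase,
    release_two_phase,
)

sw = SwellingParams(L=5.0, m=2.0, g=1.17298e-4)
one = OnePhaseParams(D=8.58865e-4)
two = TwoPhaseParams(D0=3.25908e-4, D1=1.49489e-3, tc=7200.0)

times = np.arange(13) * 3600.0
print(f"{'t (h)':>6} {'X(t) mm':>9} {'R one-phase':>12} {'R two-phase':>12}")
for t, x, r1, r2 in zip(times, logistic_radius(times, sw),
                        release_one_phase(times, sw, one),
                        release_two_phase(times, sw, two)):
    print(f"{t/3600:6.0f} {x:9.3f} {r1:12.4f} {r2:12.4f}")

print("\nThe disc swells from 5 mm towards 10 mm; the two-phase curve rises")
print("more slowly before tc = 2 h (small D0) and then overtakes as the")
print("swollen network diffuses faster (D1 ~ 4.6x D0).")
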