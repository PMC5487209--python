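"""How fast can the feedback respond before rebound disappears?

Scans the feedback speed alpha for the omalizumab example and bisects
for the largest alpha that still produces a detectable rebound
(relative threshold 1e-6).  Slower feedback -> larger, later rebound.
"""

import numpy as np

import tmdd_rebound as tr
from tmdd_rebound.simulate import find_rebound_endpoint, scan_alpha

cfg = tr.omalizumab()
p = cfg.build_params()
h = cfg.build_feedback()

table = scan_alpha(p, h, np.geomspace(0.02, 1.1, 8))
print(table.to_string(index=False, float_format=lambda x: f"{x:.5g}"))
# rmax_over_r0 is the post-nadir receptor peak relative to baseline;
# it shrinks toward 1 and the peak time shortens as feedback speeds up

endpoint = find_rebound_endpoint(p, h, alpha_lo=1e-2, alpha_hi=1.2, xtol=1e-3)
print(f"\nrebound ends at alpha ≈ {endpoint:.3f} /day")
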