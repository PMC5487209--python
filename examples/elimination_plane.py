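"""Where in the (keL, kout) elimination plane does rebound occur?

Classifies a grid of elimination rates for the no-feedback and
direct-feedback models.  Feedback enlarges the rebound region by
lowering the receptor-elimination boundary from kout = keP to
kout = keP/(1 + R0*H0).
"""

from tmdd_rebound.feedback import make_mainly_linear
from tmdd_rebound.rebound import region_grid

FIXED = dict(keP=0.201, kon=0.592, R0=2.688, koff=0.9, L0=14.8148)
h = make_mainly_linear(2.688, 0.5)   # dimensional slope H0 = 1/nM

for model, kw in [("nofeedback", {}), ("direct", {"feedback": h})]:
    df, meta = region_grid((0.05, 0.6), (0.02, 0.6), model=model, n=25, **FIXED, **kw)
    counts = df.verdict.value_counts().to_dict()
    print(f"{model:10s}: {counts}")
    if model == "direct":
        print(f"  rebound boundary dropped to kout = "
              f"{meta['kout_eq_keP_over_1h0']:.4f}/day "
              f"(was keP = {meta['kout_eq_keP']}/day)")
# counts show the rebound (red) region growing once feedback is present
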