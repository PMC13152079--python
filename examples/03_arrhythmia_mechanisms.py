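"""Cellular arrhythmia mechanisms under their standard provocations.

* Drug-induced AP prolongation: slow pacing (0.25 Hz) with 85% IKr block
  prolongs the AP massively (the substrate for early afterdepolarizations;
  this model prolongs without discrete EAD oscillations -- see the methods
  note on limitations).
* DADs: after rapid prepacing under beta-adrenergic stimulation with high
  extracellular calcium, the SR overloads; with the stochastic
  store-overload release variant, spontaneous diastolic releases drive NCX
  inward current and delayed afterdepolarizations / triggered beats.
* Alternans: at a 240 ms cycle length SR release alternates beat to beat,
  dragging APD along (concordant alternans); pacing at 1000 ms is stable.
* Steep S1-S2 restitution: the premature beat's APD falls steeply near the
  shortest captured coupling interval; a maximum slope above 1 is
  proarrhythmic.
"""

import numpy as np

from myocyte import build_parameters
from myocyte.protocols import alternans_assay, ead_assay, s1s2_restitution
from myocyte.signaling import set_bars
from myocyte.snapshots import steady_state
from myocyte.stochastic import StochasticReleaseConfig, simulate_stochastic
from myocyte.biomarkers import detect_dads

p = build_parameters("male")
y0 = steady_state("male", 1.0)

r = ead_assay(p, rate_hz=0.25, ikr_mult=0.15, n_beats=10, s0=y0)
print(f"85% IKr block @ 0.25 Hz: APD90 {r['apd90']:.0f} ms "
      f"(baseline ~340 ms at this rate), {r['ead_count']} EAD(s) detected")

q = set_bars(p, True)
q.set("cao", 3.25)
res = simulate_stochastic(q, 400.0, 60, StochasticReleaseConfig(seed=3),
                          n_trials=1, y0=y0, tail_ms=4000.0)
tr = res["trials"][0]["trace"]
m = tr.t > 60 * 400.0 + 400.0
dads, trig = detect_dads(tr.t[m], tr.y[m, 0])
print(f"DAD assay (stochastic store-overload variant): "
      f"{len(res['trials'][0]['events'])} spontaneous release event(s), "
      f"{len(dads)} DAD(s), {len(trig)} triggered AP(s) in diastole")

a = alternans_assay(p, bcls=[1000.0, 240.0], n_beats=100, s0=y0)
for _, row in a.iterrows():
    print(f"alternans at bcl {row.bcl:.0f} ms: dAPD {row.delta_apd:.1f} ms, "
          f"dCaT {1e6 * row.delta_cat:.0f} nM -> "
          f"{'ALTERNANS' if row.alternans else 'stable'}")

s = s1s2_restitution(p, s1=1000.0, n_s1=20, s0=y0)
print(f"S1-S2 restitution: max slope {s['max_slope']:.2f} at "
      f"S2 = {s['s2_at_max_slope']:.0f} ms (steady APD {s['apd_ss']:.0f} ms)")
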